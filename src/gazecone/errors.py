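"""Exception hierarchy for the gazecone package.

All package-raised errors derive from :class:`GazeConeError`, so callers can
catch one type at a pipeline boundary while tests assert the precise subclass.
"""


class GazeConeError(Exception):
    """Base class for all errors raised by gazecone."""


class GeometryError(GazeConeError, ValueError):
    """Invalid viewing geometry (non-positive distance, non-finite offset, |angle| >= 90 deg)."""


class DesignError(GazeConeError, ValueError):
    """Invalid stimulus design (no steps, non-distinct directions, empty series plan)."""


class ConfigError(GazeConeError, ValueError):
    """Malformed cohort/simulation configuration."""


class NonIdentifiableError(GazeConeError, ValueError):
    """Psychometric fit cannot be identified from the data (e.g. all responses identical)."""


class MissingCellError(GazeConeError, ValueError):
    """A required (series, side) cell of an adjustment design has no trials."""

    def __init__(self, series: str, side: str):
        self.series = series
        self.side = side
        super().__init__(f"no trials in adjustment cell (series={series!r}, side={side!r})")


class InsufficientDataError(GazeConeError, ValueError):
    """Too few observations for the requested statistic."""


class SchemaError(GazeConeError, ValueError):
    """Trial/report file does not conform to its declared schema."""


class JoinError(GazeConeError, ValueError):
    """Observer ids do not align across the inputs of a comparison."""

    def __init__(self, message: str, offenders=()):
        self.offenders = sorted(offenders)
        if self.offenders:
            message = f"{message}: {self.offenders}"
        super().__init__(message)
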