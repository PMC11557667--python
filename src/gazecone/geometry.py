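"""Viewing geometry for gaze-direction experiments.

A looker sits at a fixed distance from the observer and fixates points that
are offset horizontally from the observer's face. The gaze *rotation* that a
screen offset induces is ``arctan(offset / distance)`` — exact, with no
small-angle approximation. All angles are in degrees. The sign convention is
the observer's: gaze to the observer's left is negative, to the right
positive; one-sided designs store non-negative magnitudes and carry a
``sides`` flag.
"""

from __future__ import annotations

import math
from dataclasses import dataclass, field

import numpy as np

from .errors import DesignError, GeometryError

__all__ = [
    "GeometryContext",
    "StimulusDesign",
    "ConeWidth",
    "offset_to_angle",
    "angle_to_offset",
    "vergence_per_eye",
    "exponential_stimulus_design",
    "linear_stimulus_design",
    "cone_width",
]


@dataclass(frozen=True)
class GeometryContext:
    """Fixed viewing geometry of one experimental setup.

    Parameters
    ----------
    viewing_distance_cm
        Distance between looker and observer along the line of sight, in cm.
        Must be strictly positive.
    ipd_cm
        Looker interpupillary distance in cm (>= 0). Only needed for
        vergence computations.
    """

    viewing_distance_cm: float
    ipd_cm: float = 6.5

    def __post_init__(self):
        if not math.isfinite(self.viewing_distance_cm) or self.viewing_distance_cm <= 0:
            raise GeometryError(
                f"viewing_distance_cm must be finite and > 0, got {self.viewing_distance_cm}"
            )
        if not math.isfinite(self.ipd_cm) or self.ipd_cm < 0:
            raise GeometryError(f"ipd_cm must be finite and >= 0, got {self.ipd_cm}")


def offset_to_angle(offset_cm, ctx: GeometryContext):
    """Gaze rotation (degrees) induced by a screen offset (cm).

    Odd and strictly monotonic in the offset; accepts scalars or arrays.
    """
    offset = np.asarray(offset_cm, dtype=float)
    if not np.all(np.isfinite(offset)):
        raise GeometryError("offset must be finite")
    angle = np.degrees(np.arctan(offset / ctx.viewing_distance_cm))
    return float(angle) if np.isscalar(offset_cm) else angle


def angle_to_offset(angle_deg, ctx: GeometryContext):
    """Screen offset (cm) that induces a given gaze rotation (degrees).

    Exact inverse of :func:`offset_to_angle`; requires ``|angle| < 90``.
    """
    angle = np.asarray(angle_deg, dtype=float)
    if not np.all(np.isfinite(angle)) or np.any(np.abs(angle) >= 90.0):
        raise GeometryError("angle must be finite with |angle| < 90 deg")
    offset = ctx.viewing_distance_cm * np.tan(np.radians(angle))
    return float(offset) if np.isscalar(angle_deg) else offset


def vergence_per_eye(ctx: GeometryContext) -> float:
    """Per-eye inward rotation (degrees) required to fixate the observer.

    Each eye sits IPD/2 off the midline, so the natural vergence per eye is
    ``arctan((IPD/2) / distance)``. Zero for IPD = 0 and decreasing with
    distance.
    """
    return offset_to_angle(ctx.ipd_cm / 2.0, ctx)


@dataclass(frozen=True)
class StimulusDesign:
    """An ordered set of gaze directions with a repetition count.

    ``sides`` is ``"one-sided"`` (directions are non-negative magnitudes,
    all on one side of straight gaze) or ``"two-sided"`` (signed directions
    spanning both sides).
    """

    directions_deg: tuple
    repetitions: int
    sides: str = "one-sided"
    base_step_cm: float | None = None

    def __post_init__(self):
        if self.repetitions < 1:
            raise DesignError(f"repetitions must be >= 1, got {self.repetitions}")
        if self.sides not in ("one-sided", "two-sided"):
            raise DesignError(f"sides must be 'one-sided' or 'two-sided', got {self.sides!r}")
        dirs = tuple(float(d) for d in self.directions_deg)
        if len(dirs) < 1:
            raise DesignError("design needs at least one direction")
        if len(set(dirs)) != len(dirs):
            raise DesignError(f"directions are not distinct: {dirs}")
        if self.sides == "one-sided" and any(d < 0 for d in dirs):
            raise DesignError("one-sided design must contain only non-negative magnitudes")
        object.__setattr__(self, "directions_deg", dirs)

    @property
    def n_trials(self) -> int:
        return len(self.directions_deg) * self.repetitions


@dataclass(frozen=True)
class ConeWidth:
    """Gaze-cone width: the threshold of direct gaze is half the cone."""

    half_width_deg: float
    full_width_deg: float = field(init=False)

    def __post_init__(self):
        if not math.isfinite(self.half_width_deg) or self.half_width_deg < 0:
            raise GeometryError(f"half width must be finite and >= 0, got {self.half_width_deg}")
        object.__setattr__(self, "full_width_deg", 2.0 * self.half_width_deg)


def cone_width(half_deg: float) -> ConeWidth:
    """Full (two-sided) cone width from the one-sided threshold of direct gaze."""
    return ConeWidth(half_width_deg=float(half_deg))


def exponential_stimulus_design(
    base_cm: float,
    n_steps: int,
    ctx: GeometryContext,
    repetitions: int = 25,
) -> StimulusDesign:
    """One-sided design whose screen offsets are successive powers of a base.

    Offsets are ``{0, base, base**2, ..., base**n_steps}`` cm, converted to
    gaze angles via :func:`offset_to_angle`. With a 2.5 cm base at 165 cm this
    yields 0, 0.9, 2.2, 5.4 and 13.3 degrees (to one decimal).
    """
    if n_steps < 1:
        raise DesignError(f"n_steps must be >= 1, got {n_steps}")
    if base_cm <= 0:
        raise DesignError(f"base_cm must be > 0, got {base_cm}")
    offsets = [0.0] + [base_cm**k for k in range(1, n_steps + 1)]
    if len(set(offsets)) != len(offsets):
        raise DesignError(f"exponential base {base_cm} yields non-distinct offsets {offsets}")
    angles = tuple(offset_to_angle(o, ctx) for o in offsets)
    return StimulusDesign(
        directions_deg=angles,
        repetitions=repetitions,
        sides="one-sided",
        base_step_cm=base_cm,
    )


def linear_stimulus_design(
    step_deg: float,
    max_deg: float,
    repetitions: int = 35,
) -> StimulusDesign:
    """Two-sided design with equally spaced directions from -max to +max.

    A 3 degree step up to 15 degrees gives the 11-direction avatar design.
    """
    if step_deg <= 0 or max_deg <= 0:
        raise DesignError("step_deg and max_deg must be > 0")
    n = int(round(max_deg / step_deg))
    if not math.isclose(n * step_deg, max_deg, rel_tol=0, abs_tol=1e-9):
        raise DesignError(f"max_deg {max_deg} is not a multiple of step_deg {step_deg}")
    angles = tuple(k * step_deg for k in range(-n, n + 1))
    return StimulusDesign(directions_deg=angles, repetitions=repetitions, sides="two-sided")
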