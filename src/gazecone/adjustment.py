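"""Per-observer summaries of method-of-adjustment trials.

The threshold of direct gaze is the unweighted mean of the (series x side)
cell means — "four means per observer" in the two-sided design, two in the
one-sided design — so that ascending and descending series contribute
equally and symmetric hysteresis cancels. Left-side cell means are folded by
sign before entering the overall threshold (the fold is configurable); cell
means themselves are reported signed.
"""

from __future__ import annotations

from dataclasses import dataclass

import numpy as np
import pandas as pd

from .errors import InsufficientDataError, MissingCellError
from .stats import StatResult, paired_t, pearson_r_test

__all__ = ["AdjustmentSummary", "HysteresisResult", "summarize_adjustment", "hysteresis_contrast"]

SERIES = ("ascending", "descending")


@dataclass(frozen=True)
class AdjustmentSummary:
    """One observer's adjustment block reduced to cell means and a threshold.

    ``mean_ascending`` / ``mean_descending`` are folded magnitudes averaged
    over sides; ``cell_means`` holds the signed per-(series, side) means;
    ``within_sd`` is the SD of all stop magnitudes (sample SD, ddof=1).
    """

    observer_id: object
    mean_ascending: float
    mean_descending: float
    cell_means: dict
    overall_threshold: float
    within_sd: float
    n_per_cell: dict


def summarize_adjustment(trials: pd.DataFrame, sides: str = "one", fold: bool = True) -> AdjustmentSummary:
    """Summarize one observer's adjustment trials.

    Parameters
    ----------
    trials
        Columns ``series`` (ascending/descending), ``side`` (left/right; a
        one-sided design may omit the column), ``stop_deg`` (signed), and
        optionally ``observer_id``.
    sides
        ``"one"`` or ``"two"`` — which (series, side) cells must be present.
    fold
        Fold left-side magnitudes by sign before averaging into the overall
        threshold. With ``fold=False`` the overall threshold is the mean of
        the signed cell means (only sensible for one-sided data).

    Raises
    ------
    MissingCellError
        If a required (series, side) cell has no trials.
    """
    df = trials.copy()
    if "side" not in df.columns:
        df["side"] = "right"
    side_labels = ("right",) if sides == "one" else ("left", "right")

    cell_means, n_per_cell = {}, {}
    for series in SERIES:
        for side in side_labels:
            cell = df[(df["series"] == series) & (df["side"] == side)]["stop_deg"]
            if cell.empty:
                raise MissingCellError(series, side)
            cell_means[(series, side)] = float(cell.mean())
            n_per_cell[(series, side)] = int(cell.size)

    def folded(series):
        vals = [
            abs(cell_means[(series, side)]) if fold else cell_means[(series, side)]
            for side in side_labels
        ]
        return float(np.mean(vals))

    mean_asc, mean_desc = folded("ascending"), folded("descending")
    observer = df["observer_id"].iloc[0] if "observer_id" in df.columns else None
    stops = df["stop_deg"].to_numpy(dtype=float)
    magnitudes = np.abs(stops) if fold else stops
    return AdjustmentSummary(
        observer_id=observer,
        mean_ascending=mean_asc,
        mean_descending=mean_desc,
        cell_means=cell_means,
        overall_threshold=float(np.mean([mean_asc, mean_desc])),
        within_sd=float(np.std(magnitudes, ddof=1)) if magnitudes.size > 1 else 0.0,
        n_per_cell=n_per_cell,
    )


def summarize_cohort(trials: pd.DataFrame, sides: str = "one", fold: bool = True) -> pd.DataFrame:
    """Apply :func:`summarize_adjustment` per observer; one row per observer."""
    rows = []
    for obs_id, group in trials.groupby("observer_id"):
        s = summarize_adjustment(group, sides=sides, fold=fold)
        rows.append(
            {
                "observer_id": obs_id,
                "mean_ascending": s.mean_ascending,
                "mean_descending": s.mean_descending,
                "overall_threshold": s.overall_threshold,
                "within_sd": s.within_sd,
            }
        )
    return pd.DataFrame(rows)


@dataclass(frozen=True)
class HysteresisResult:
    """Cohort-level ascending-vs-descending contrast."""

    mean_contrast: float  # mean over observers of (descending - ascending), folded
    se_contrast: float
    t_test: StatResult
    correlation: StatResult | None  # None when r is undefined (n < 3 or a flat series)


def hysteresis_contrast(summaries) -> HysteresisResult:
    """Paired test of descending vs ascending stop-points across observers.

    ``summaries`` is a list of :class:`AdjustmentSummary` or the DataFrame
    from :func:`summarize_cohort`. Returns the mean contrast with its
    standard error, the paired t (with Cohen's d), and the Pearson
    correlation between the two series.
    """
    if isinstance(summaries, pd.DataFrame):
        asc = summaries["mean_ascending"].to_numpy(dtype=float)
        desc = summaries["mean_descending"].to_numpy(dtype=float)
    else:
        asc = np.array([s.mean_ascending for s in summaries], dtype=float)
        desc = np.array([s.mean_descending for s in summaries], dtype=float)
    if asc.size < 2:
        raise InsufficientDataError("hysteresis contrast needs >= 2 observers")
    diff = desc - asc
    try:
        correlation = pearson_r_test(asc, desc)
    except InsufficientDataError:
        correlation = None
    return HysteresisResult(
        mean_contrast=float(diff.mean()),
        se_contrast=float(diff.std(ddof=1) / np.sqrt(diff.size)),
        t_test=paired_t(desc, asc),
        correlation=correlation,
    )
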