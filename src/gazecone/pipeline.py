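"""End-to-end comparison of constant-stimuli and adjustment thresholds.

Given per-observer thresholds from both dyadic methods and per-observer
piece-wise triadic regressions, :func:`compare_methods` builds the full
method-comparison report: cohort means and SDs, the between-method threshold
ratio, paired t and Pearson correlation, and the same block again after
correcting every threshold with the observer's own triadic regression
(segment selected by the threshold itself).
"""

from __future__ import annotations

import json
from dataclasses import asdict, dataclass
from pathlib import Path

import numpy as np
import pandas as pd

from .errors import JoinError
from .io import write_report
from .stats import StatResult, paired_t, pearson_r_test
from .triadic import PiecewiseFit, correct_threshold

__all__ = ["ComparisonReport", "compare_methods", "threshold_ratio"]


def threshold_ratio(adjustment_mean: float, constant_mean: float) -> float:
    """Mean adjustment threshold over mean constant-stimuli threshold.

    Computed on unrounded means; round only for presentation.
    """
    return float(adjustment_mean) / float(constant_mean)


@dataclass(frozen=True)
class MethodBlock:
    """Cohort summary of one uncorrected-or-corrected comparison."""

    mean_cs: float
    sd_cs: float
    mean_adj: float
    sd_adj: float
    ratio: float
    paired: StatResult
    correlation: StatResult


@dataclass(frozen=True)
class ComparisonReport:
    uncorrected: MethodBlock
    corrected: MethodBlock | None
    mean_bias_cs: float | None
    mean_bias_adj: float | None
    per_observer: pd.DataFrame

    def to_dict(self) -> dict:
        def block(b):
            if b is None:
                return None
            d = asdict(b)
            return d

        return {
            "uncorrected": block(self.uncorrected),
            "corrected": block(self.corrected),
            "mean_bias_cs": self.mean_bias_cs,
            "mean_bias_adj": self.mean_bias_adj,
        }

    def write(self, out_dir) -> dict:
        """Serialize to ``report.json`` (raw precision) and
        ``per_observer.csv`` (presentation rounding)."""
        out = Path(out_dir)
        out.mkdir(parents=True, exist_ok=True)
        json_path = out / "report.json"
        json_path.write_text(json.dumps(self.to_dict(), indent=2, default=float))
        csv_path = write_report(self.per_observer, out / "per_observer.csv")
        return {"json": json_path, "csv": csv_path}


def _block(t_cs: np.ndarray, t_adj: np.ndarray) -> MethodBlock:
    return MethodBlock(
        mean_cs=float(t_cs.mean()),
        sd_cs=float(t_cs.std(ddof=1)),
        mean_adj=float(t_adj.mean()),
        sd_adj=float(t_adj.std(ddof=1)),
        ratio=threshold_ratio(t_adj.mean(), t_cs.mean()),
        paired=paired_t(t_cs, t_adj),
        correlation=pearson_r_test(t_cs, t_adj),
    )


def compare_methods(
    fits_cs: pd.DataFrame,
    fits_adj: pd.DataFrame,
    triadic_fits: dict | None = None,
) -> ComparisonReport:
    """Build the method-comparison report.

    Parameters
    ----------
    fits_cs
        Columns ``observer_id`` and ``threshold_deg`` (constant stimuli).
    fits_adj
        Columns ``observer_id`` and either ``threshold_deg`` or
        ``overall_threshold`` (method of adjustment).
    triadic_fits
        Optional ``{observer_id: PiecewiseFit}``; when given, a corrected
        block is produced by applying each observer's own piece-wise
        regression to both of that observer's thresholds.

    Raises
    ------
    JoinError
        If observer ids do not match across inputs (offenders listed).
    """
    cs = fits_cs[["observer_id", "threshold_deg"]].copy()
    adj = fits_adj.copy()
    if "threshold_deg" not in adj.columns:
        adj = adj.rename(columns={"overall_threshold": "threshold_deg"})
    adj = adj[["observer_id", "threshold_deg"]]

    ids_cs, ids_adj = set(cs["observer_id"]), set(adj["observer_id"])
    if ids_cs != ids_adj:
        raise JoinError(
            "observer ids differ between constant-stimuli and adjustment fits",
            offenders=ids_cs ^ ids_adj,
        )
    if triadic_fits is not None:
        missing = ids_cs - set(triadic_fits)
        if missing:
            raise JoinError("observers missing a triadic fit", offenders=missing)

    merged = cs.merge(adj, on="observer_id", suffixes=("_cs", "_adj")).sort_values("observer_id")
    t_cs = merged["threshold_deg_cs"].to_numpy(dtype=float)
    t_adj = merged["threshold_deg_adj"].to_numpy(dtype=float)
    uncorrected = _block(t_cs, t_adj)

    corrected = None
    mean_bias_cs = mean_bias_adj = None
    per_obs = merged.rename(
        columns={"threshold_deg_cs": "t_cs_deg", "threshold_deg_adj": "t_adj_deg"}
    )
    if triadic_fits is not None:
        corr_rows = []
        for row in per_obs.itertuples():
            fit: PiecewiseFit = triadic_fits[row.observer_id]
            c_cs = correct_threshold(row.t_cs_deg, fit)
            c_adj = correct_threshold(row.t_adj_deg, fit)
            corr_rows.append(
                {
                    "observer_id": row.observer_id,
                    "t_cs_corrected_deg": c_cs.corrected_threshold,
                    "t_adj_corrected_deg": c_adj.corrected_threshold,
                    "segment_cs": c_cs.segment_index,
                    "segment_adj": c_adj.segment_index,
                    "bias_cs": c_cs.estimation_bias,
                    "bias_adj": c_adj.estimation_bias,
                }
            )
        corr = pd.DataFrame(corr_rows)
        per_obs = per_obs.merge(corr, on="observer_id")
        corrected = _block(
            per_obs["t_cs_corrected_deg"].to_numpy(dtype=float),
            per_obs["t_adj_corrected_deg"].to_numpy(dtype=float),
        )
        mean_bias_cs = float(np.nanmean(per_obs["bias_cs"]))
        mean_bias_adj = float(np.nanmean(per_obs["bias_adj"]))

    return ComparisonReport(
        uncorrected=uncorrected,
        corrected=corrected,
        mean_bias_cs=mean_bias_cs,
        mean_bias_adj=mean_bias_adj,
        per_observer=per_obs.reset_index(drop=True),
    )
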