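"""Regression analysis of triadic gaze-direction reports.

Reports are read off a centimetre scale, converted back to gaze angles with
the viewing geometry, and regressed on the true gaze direction. Two fits are
provided: a single ordinary least-squares line (its slope is the classical
overestimation factor), and a four-piece regression with fixed breakpoints
at the measured gaze directions, each segment fitted independently on the
points of its closed interval (so boundary points enter both neighbours and
discontinuities between segments are permitted).

The piece-wise fit drives the threshold correction: a threshold ``T``
measured in a dyadic task selects the segment whose interval contains it,
and the corrected threshold is that segment's regression evaluated at ``T``
(``T* = slope * T + intercept``); the estimation bias is ``T*/T``.
"""

from __future__ import annotations

from dataclasses import dataclass

import numpy as np
import pandas as pd

from .errors import DesignError, InsufficientDataError
from .geometry import GeometryContext, offset_to_angle

__all__ = [
    "DEFAULT_BREAKPOINTS",
    "LinearFit",
    "PiecewiseFit",
    "CorrectionResult",
    "points_from_trials",
    "fit_linear",
    "fit_piecewise",
    "select_segment",
    "correct_threshold",
]

DEFAULT_BREAKPOINTS = (0.0, 0.9, 2.2, 5.4, 13.9)


@dataclass(frozen=True)
class LinearFit:
    slope: float
    intercept: float
    r_squared: float
    n_points: int


@dataclass(frozen=True)
class PiecewiseFit:
    """Four independent per-segment OLS fits over fixed breakpoints.

    ``segments[k]`` is a :class:`LinearFit` for the closed interval
    ``[breakpoints[k], breakpoints[k+1]]`` (k = 0..3, reported to users as
    sections 1..4).
    """

    breakpoints: tuple
    segments: tuple

    def __post_init__(self):
        bp = tuple(float(b) for b in self.breakpoints)
        if any(b1 <= b0 for b0, b1 in zip(bp, bp[1:])):
            raise DesignError(f"breakpoints must be strictly increasing, got {bp}")
        if len(self.segments) != len(bp) - 1:
            raise DesignError("need exactly one segment per breakpoint interval")
        object.__setattr__(self, "breakpoints", bp)


@dataclass(frozen=True)
class CorrectionResult:
    raw_threshold: float
    segment_index: int  # 1-based section number
    corrected_threshold: float
    estimation_bias: float  # corrected / raw; NaN when raw == 0


def points_from_trials(trials: pd.DataFrame, ctx: GeometryContext) -> np.ndarray:
    """(true_deg, perceived_deg) pairs from a triadic trial table.

    The centimetre report is converted to a gaze angle at the scale plane so
    both regression axes are in degrees.
    """
    true = trials["true_deg"].to_numpy(dtype=float)
    perceived = offset_to_angle(trials["reported_cm"].to_numpy(dtype=float), ctx)
    return np.column_stack([true, perceived])


def fit_linear(points) -> LinearFit:
    """Exact OLS line through (x, y) points via the normal equations."""
    pts = np.asarray(points, dtype=float)
    if pts.ndim != 2 or pts.shape[1] != 2 or pts.shape[0] < 2:
        raise InsufficientDataError("fit_linear needs an (n, 2) array with n >= 2")
    x, y = pts[:, 0], pts[:, 1]
    if np.unique(x).size < 2:
        raise InsufficientDataError("degenerate abscissae: all x values identical")
    xc = x - x.mean()
    slope = float(np.dot(xc, y - y.mean()) / np.dot(xc, xc))
    intercept = float(y.mean() - slope * x.mean())
    resid = y - (slope * x + intercept)
    ss_tot = float(np.dot(y - y.mean(), y - y.mean()))
    r2 = 1.0 - float(np.dot(resid, resid)) / ss_tot if ss_tot > 0 else 1.0
    return LinearFit(slope=slope, intercept=intercept, r_squared=r2, n_points=x.size)


def fit_piecewise(points, breakpoints=DEFAULT_BREAKPOINTS) -> PiecewiseFit:
    """Independent OLS per closed breakpoint interval.

    Every segment must contain at least two distinct abscissae; the error for
    an under-populated segment names its interval.
    """
    pts = np.asarray(points, dtype=float)
    bp = tuple(float(b) for b in breakpoints)
    if any(b1 <= b0 for b0, b1 in zip(bp, bp[1:])):
        raise DesignError(f"breakpoints must be strictly increasing, got {bp}")
    x = pts[:, 0]
    segments = []
    for lo, hi in zip(bp, bp[1:]):
        mask = (x >= lo) & (x <= hi)
        seg_pts = pts[mask]
        if seg_pts.shape[0] < 2 or np.unique(seg_pts[:, 0]).size < 2:
            raise InsufficientDataError(
                f"segment [{lo}, {hi}] has fewer than 2 distinct gaze directions"
            )
        segments.append(fit_linear(seg_pts))
    return PiecewiseFit(breakpoints=bp, segments=tuple(segments))


def select_segment(threshold: float, fit: PiecewiseFit) -> int:
    """1-based section whose closed interval contains the threshold.

    Interior boundary ties go to the higher section; a threshold above the
    last breakpoint extrapolates with the last section.
    """
    if threshold < 0:
        raise DesignError(f"threshold must be >= 0, got {threshold}")
    bp = fit.breakpoints
    n_seg = len(fit.segments)
    for k in range(n_seg - 1, -1, -1):
        if threshold >= bp[k]:
            return min(k + 1, n_seg)
    return 1


def correct_threshold(threshold: float, fit: PiecewiseFit) -> CorrectionResult:
    """Evaluate the threshold-containing segment's regression at the threshold.

    ``T* = slope_k * T + intercept_k``; the estimation bias ``T*/T`` is NaN
    at ``T = 0``.
    """
    k = select_segment(threshold, fit)
    seg = fit.segments[k - 1]
    corrected = seg.slope * threshold + seg.intercept
    bias = corrected / threshold if threshold != 0 else float("nan")
    return CorrectionResult(
        raw_threshold=float(threshold),
        segment_index=k,
        corrected_threshold=float(corrected),
        estimation_bias=float(bias),
    )


def piecewise_to_frame(fits: dict) -> pd.DataFrame:
    """Long table (observer_id, segment, slope, intercept, n_points) from
    a {observer_id: PiecewiseFit} mapping."""
    rows = []
    for obs_id, fit in fits.items():
        for k, seg in enumerate(fit.segments, start=1):
            rows.append(
                {
                    "observer_id": obs_id,
                    "segment": k,
                    "lo_deg": fit.breakpoints[k - 1],
                    "hi_deg": fit.breakpoints[k],
                    "slope": seg.slope,
                    "intercept": seg.intercept,
                    "n_points": seg.n_points,
                }
            )
    return pd.DataFrame(rows)


def piecewise_from_frame(frame: pd.DataFrame) -> dict:
    """Inverse of :func:`piecewise_to_frame`."""
    fits = {}
    for obs_id, group in frame.groupby("observer_id"):
        group = group.sort_values("segment")
        bp = tuple(group["lo_deg"].tolist()) + (float(group["hi_deg"].iloc[-1]),)
        segments = tuple(
            LinearFit(
                slope=float(r.slope),
                intercept=float(r.intercept),
                r_squared=float("nan"),
                n_points=int(r.n_points),
            )
            for r in group.itertuples()
        )
        fits[obs_id] = PiecewiseFit(breakpoints=bp, segments=segments)
    return fits
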