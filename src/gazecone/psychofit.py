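"""Maximum-likelihood psychometric fits for yes/no gaze judgments.

Two threshold definitions are implemented, matching the two dyadic designs:

* One-sided data are fitted with a **cumulative Gaussian** on the proportion
  of *averted* judgments, ``P(averted | theta) = (1 - lapse) * Phi((theta - T)
  / sigma) + lapse / 2``; the 50% point ``T`` is the threshold of direct
  gaze.
* Two-sided data are fitted with a **Gaussian bell** on the proportion of
  *direct* judgments, ``P(direct | theta) = a * exp(-(theta - c)^2 /
  (2 w^2))``; the bell's standard deviation ``w`` is the threshold and ``c``
  the center of the gaze cone.

Both maximize the exact binomial log-likelihood (0% and 100% cells are
handled by the likelihood itself, not by transforms) with bounded L-BFGS-B
from several deterministic quantile-based starts. A brute-force grid oracle
(:func:`grid_fit_oracle`) provides an independent check of the optimizer.
"""

from __future__ import annotations

import logging
from dataclasses import dataclass

import numpy as np
import pandas as pd
from scipy.optimize import minimize
from scipy.special import gammaln, ndtr

from .errors import InsufficientDataError, NonIdentifiableError
from .simulate import p_direct  # noqa: F401  (re-exported convenience for tests)

__all__ = [
    "DyadicProportions",
    "PsychometricFit",
    "BellFit",
    "fit_cumulative_gaussian",
    "fit_gaussian_bell",
    "grid_fit_oracle",
]

log = logging.getLogger(__name__)

_P_FLOOR = 1e-12


@dataclass(frozen=True)
class DyadicProportions:
    """Yes/no judgments aggregated by gaze direction.

    ``n_direct`` may be non-integral to represent expected counts from a
    noiseless generative model; the likelihood uses the gamma-function form
    of the binomial coefficient, which extends continuously.
    """

    angles_deg: np.ndarray
    n_trials: np.ndarray
    n_direct: np.ndarray

    def __post_init__(self):
        a = np.asarray(self.angles_deg, dtype=float)
        n = np.asarray(self.n_trials, dtype=float)
        k = np.asarray(self.n_direct, dtype=float)
        if not (a.shape == n.shape == k.shape) or a.ndim != 1:
            raise InsufficientDataError("angles, n_trials and n_direct must be 1-D and aligned")
        if np.unique(a).size != a.size:
            raise InsufficientDataError("gaze angles must be distinct after aggregation")
        if np.any(k < 0) or np.any(k > n) or np.any(n <= 0):
            raise InsufficientDataError("need 0 <= n_direct <= n_trials and n_trials > 0")
        order = np.argsort(a)
        object.__setattr__(self, "angles_deg", a[order])
        object.__setattr__(self, "n_trials", n[order])
        object.__setattr__(self, "n_direct", k[order])

    @classmethod
    def from_trials(cls, trials: pd.DataFrame) -> "DyadicProportions":
        """Aggregate a trial table (gaze_deg, response with 1 = direct)."""
        g = trials.groupby("gaze_deg")["response"]
        agg = g.agg(["count", "sum"])
        return cls(
            angles_deg=agg.index.to_numpy(dtype=float),
            n_trials=agg["count"].to_numpy(dtype=float),
            n_direct=agg["sum"].to_numpy(dtype=float),
        )

    @property
    def proportion_direct(self) -> np.ndarray:
        return self.n_direct / self.n_trials


@dataclass(frozen=True)
class PsychometricFit:
    """Cumulative-Gaussian fit: threshold = 50% point on the averted curve."""

    threshold_deg: float
    sigma_deg: float
    lapse: float
    loglik: float
    converged: bool


@dataclass(frozen=True)
class BellFit:
    """Gaussian-bell fit: threshold = bell SD (width), center = cone center."""

    center_deg: float
    width_deg: float
    amplitude: float
    loglik: float
    converged: bool


def binomial_loglik(k, n, p) -> float:
    """Sum of binomial log-pmfs, continuous in k via the gamma function."""
    k = np.asarray(k, dtype=float)
    n = np.asarray(n, dtype=float)
    p = np.clip(np.asarray(p, dtype=float), _P_FLOOR, 1.0 - _P_FLOOR)
    coef = gammaln(n + 1) - gammaln(k + 1) - gammaln(n - k + 1)
    return float(np.sum(coef + k * np.log(p) + (n - k) * np.log1p(-p)))


def _p_averted_cs(theta, threshold, sigma, lapse):
    return (1.0 - lapse) * ndtr((theta - threshold) / sigma) + lapse / 2.0


def _p_direct_bell(theta, center, width, amplitude):
    return amplitude * np.exp(-((theta - center) ** 2) / (2.0 * width**2))


def _check_identifiable(data: DyadicProportions):
    if np.all(data.n_direct == data.n_trials) or np.all(data.n_direct == 0):
        raise NonIdentifiableError(
            "all responses identical across all gaze angles; "
            "threshold is not identifiable from these data"
        )


def fit_cumulative_gaussian(
    data: DyadicProportions,
    free_lapse: bool = False,
    lapse: float = 0.0,
    tol: float = 1e-8,
) -> PsychometricFit:
    """Fit the cumulative Gaussian to one-sided yes/no proportions.

    Direct judgments are inverted internally: the curve is the probability of
    an *averted* judgment rising from 0 to 1 with eccentricity, and the
    threshold of direct gaze is its 50% point.

    Parameters
    ----------
    data
        Aggregated proportions (>= 3 distinct angles, >= 10 trials total).
    free_lapse
        Estimate the lapse rate within [0, 0.05] instead of fixing it.
    lapse
        The fixed lapse rate when ``free_lapse`` is False.

    The optimizer restarts from five deterministic quantile-based initial
    thresholds; ``converged`` is False when no restart converged (the best
    point found is still returned, with a warning).
    """
    if data.angles_deg.size < 3:
        raise InsufficientDataError("need >= 3 distinct gaze angles for a psychometric fit")
    if data.n_trials.sum() < 10:
        raise InsufficientDataError("need >= 10 trials in total")
    _check_identifiable(data)

    theta = data.angles_deg
    k_averted = data.n_trials - data.n_direct
    span = float(theta.max() - theta.min()) or 1.0
    bounds = [
        (theta.min() - span, theta.max() + span),
        (1e-2, 5.0 * span),
    ]
    if free_lapse:
        bounds.append((0.0, 0.05))

    def nll(params):
        t, s = params[0], params[1]
        lam = params[2] if free_lapse else lapse
        return -binomial_loglik(k_averted, data.n_trials, _p_averted_cs(theta, t, s, lam))

    t_starts = np.quantile(theta, [0.2, 0.35, 0.5, 0.65, 0.8])
    best, best_conv = None, False
    for t0 in t_starts:
        x0 = [t0, span / 4.0] + ([0.01] if free_lapse else [])
        res = minimize(nll, x0, method="L-BFGS-B", bounds=bounds, options={"ftol": tol})
        if best is None or res.fun < best.fun:
            best = res
        best_conv = best_conv or res.success
    if not best_conv:
        log.warning("cumulative-Gaussian fit did not converge; returning best point found")
    return PsychometricFit(
        threshold_deg=float(best.x[0]),
        sigma_deg=float(best.x[1]),
        lapse=float(best.x[2]) if free_lapse else float(lapse),
        loglik=-float(best.fun),
        converged=bool(best_conv),
    )


def fit_gaussian_bell(
    data: DyadicProportions,
    fix_amplitude: float | None = None,
    tol: float = 1e-8,
) -> BellFit:
    """Fit the Gaussian bell to two-sided proportion-direct data.

    Requires >= 5 distinct angles spanning both signs. The amplitude is free
    in (0, 1] unless ``fix_amplitude`` pins it.
    """
    if data.angles_deg.size < 5:
        raise InsufficientDataError("need >= 5 distinct gaze angles for a bell fit")
    if not (data.angles_deg.min() < 0 < data.angles_deg.max()):
        raise InsufficientDataError("bell fit requires angles on both sides of 0")
    _check_identifiable(data)
    props = data.proportion_direct
    if np.allclose(props, props[0]):
        raise NonIdentifiableError("proportions are flat across angles; bell is not identifiable")

    theta = data.angles_deg
    span = float(theta.max() - theta.min())
    free_a = fix_amplitude is None
    bounds = [(theta.min(), theta.max()), (1e-2, 2.0 * span)]
    if free_a:
        bounds.append((1e-3, 1.0))

    def nll(params):
        c, w = params[0], params[1]
        a = params[2] if free_a else fix_amplitude
        return -binomial_loglik(
            data.n_direct, data.n_trials, _p_direct_bell(theta, c, w, a)
        )

    # Moment-style starts: proportion-weighted mean and spread.
    wsum = props.sum()
    c_moment = float((theta * props).sum() / wsum) if wsum > 0 else 0.0
    c_starts = [c_moment, 0.0, float(np.quantile(theta, 0.35)), float(np.quantile(theta, 0.65))]
    best, best_conv = None, False
    for c0 in c_starts:
        for w0 in (span / 6.0, span / 3.0):
            x0 = [c0, w0] + ([min(1.0, max(0.05, float(props.max())))] if free_a else [])
            res = minimize(nll, x0, method="L-BFGS-B", bounds=bounds, options={"ftol": tol})
            if best is None or res.fun < best.fun:
                best = res
            best_conv = best_conv or res.success
    if not best_conv:
        log.warning("Gaussian-bell fit did not converge; returning best point found")
    return BellFit(
        center_deg=float(best.x[0]),
        width_deg=float(best.x[1]),
        amplitude=float(best.x[2]) if free_a else float(fix_amplitude),
        loglik=-float(best.fun),
        converged=bool(best_conv),
    )


def grid_fit_oracle(
    data: DyadicProportions,
    param_grid: dict,
    model: str = "cumulative",
    lapse: float = 0.0,
    fix_amplitude: float = 1.0,
):
    """Exhaustive grid-search maximum likelihood (verification oracle).

    Parameters
    ----------
    data
        Aggregated proportions.
    param_grid
        For ``model="cumulative"``: ``{"threshold": array, "sigma": array}``.
        For ``model="bell"``: ``{"center": array, "width": array}`` (amplitude
        fixed at ``fix_amplitude``).

    Returns
    -------
    (best_params: dict, best_loglik: float, surface: ndarray)
        ``surface[i, j]`` is the log-likelihood at the (i-th, j-th) grid
        point of the two swept parameters.
    """
    if model == "cumulative":
        names = ("threshold", "sigma")
    elif model == "bell":
        names = ("center", "width")
    else:
        raise ValueError(f"unknown model {model!r}")
    grids = [np.asarray(param_grid[n], dtype=float) for n in names]
    if any(g.size == 0 for g in grids):
        raise InsufficientDataError("empty parameter grid")

    theta = data.angles_deg[None, None, :]
    g0 = grids[0][:, None, None]
    g1 = grids[1][None, :, None]
    if model == "cumulative":
        p = _p_averted_cs(theta, g0, g1, lapse)
        k = (data.n_trials - data.n_direct)[None, None, :]
    else:
        p = _p_direct_bell(theta, g0, g1, fix_amplitude)
        k = data.n_direct[None, None, :]
    n = data.n_trials[None, None, :]
    p = np.clip(p, _P_FLOOR, 1.0 - _P_FLOOR)
    coef = gammaln(n + 1) - gammaln(k + 1) - gammaln(n - k + 1)
    surface = np.sum(coef + k * np.log(p) + (n - k) * np.log1p(-p), axis=2)
    i, j = np.unravel_index(np.argmax(surface), surface.shape)
    best = {names[0]: float(grids[0][i]), names[1]: float(grids[1][j])}
    return best, float(surface[i, j]), surface
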