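"""Self-contained cohort statistics: paired t, Pearson r, one-way rm-ANOVA.

These are implemented from the defining sums rather than delegated, so every
pipeline statistic can be verified against an independent brute-force oracle
in the tests. All p-values are two-sided; no multiple-testing adjustment is
applied anywhere in the pipeline.
"""

from __future__ import annotations

from dataclasses import dataclass, field

import numpy as np
from scipy import stats as sps

from .errors import InsufficientDataError

__all__ = ["StatResult", "paired_t", "pearson_r_test", "rm_anova_slopes"]


@dataclass(frozen=True)
class StatResult:
    """A test statistic with its degrees of freedom, p-value and effect size.

    ``kind`` labels the statistic ('paired_t', 'pearson_r', 'rm_anova_F');
    ``df`` is a float for t/r and a (numerator, denominator) tuple for F.
    ``aux`` carries secondary quantities (e.g. the t value accompanying r).
    """

    kind: str
    statistic: float
    df: object
    p_value: float
    effect_size: float | None = None
    effect_label: str | None = None
    n: int = 0
    aux: dict = field(default_factory=dict)

    def __post_init__(self):
        if not (np.isnan(self.p_value) or 0.0 <= self.p_value <= 1.0):
            raise ValueError(f"p-value outside [0, 1]: {self.p_value}")


def paired_t(x, y) -> StatResult:
    """Two-sided paired t-test of x against y.

    t = mean(d) / (sd(d)/sqrt(n)) with d = x - y and df = n - 1; Cohen's d
    for the paired contrast is mean(d)/sd(d). A zero-variance, zero-mean
    difference yields t = 0, p = 1.
    """
    x = np.asarray(x, dtype=float)
    y = np.asarray(y, dtype=float)
    if x.shape != y.shape or x.ndim != 1:
        raise InsufficientDataError("paired_t requires two 1-D arrays of equal length")
    n = x.size
    if n < 2:
        raise InsufficientDataError("paired_t requires at least 2 pairs (df = n - 1 >= 1)")
    d = x - y
    sd = d.std(ddof=1)
    if sd == 0.0:
        t = 0.0 if d.mean() == 0.0 else np.inf * np.sign(d.mean())
        p = 1.0 if t == 0.0 else 0.0
        cohen = 0.0 if t == 0.0 else np.inf * np.sign(d.mean())
    else:
        t = d.mean() / (sd / np.sqrt(n))
        p = 2.0 * sps.t.sf(abs(t), df=n - 1)
        cohen = d.mean() / sd
    return StatResult(
        kind="paired_t",
        statistic=float(t),
        df=float(n - 1),
        p_value=float(p),
        effect_size=float(cohen),
        effect_label="cohen_d",
        n=n,
    )


def pearson_r_test(x, y) -> StatResult:
    """Pearson correlation with its t-test (df = n - 2).

    r from the covariance sums; t = r * sqrt(n - 2) / sqrt(1 - r^2). Zero
    variance in either input is an error (the correlation is undefined).
    """
    x = np.asarray(x, dtype=float)
    y = np.asarray(y, dtype=float)
    if x.shape != y.shape or x.ndim != 1:
        raise InsufficientDataError("pearson_r_test requires two 1-D arrays of equal length")
    n = x.size
    if n < 3:
        raise InsufficientDataError("pearson_r_test requires n >= 3 (df = n - 2 >= 1)")
    xc, yc = x - x.mean(), y - y.mean()
    sxx, syy = np.dot(xc, xc), np.dot(yc, yc)
    if sxx == 0.0 or syy == 0.0:
        raise InsufficientDataError("correlation undefined: an input has zero variance")
    r = float(np.clip(np.dot(xc, yc) / np.sqrt(sxx * syy), -1.0, 1.0))
    if abs(r) == 1.0:
        t, p = np.inf * np.sign(r), 0.0
    else:
        t = r * np.sqrt(n - 2) / np.sqrt(1.0 - r * r)
        p = 2.0 * sps.t.sf(abs(t), df=n - 2)
    return StatResult(
        kind="pearson_r",
        statistic=r,
        df=float(n - 2),
        p_value=float(p),
        effect_size=r,
        effect_label="r",
        n=n,
        aux={"t": float(t)},
    )


def rm_anova_slopes(matrix) -> StatResult:
    """One-way repeated-measures ANOVA over an observers x conditions matrix.

    Classical sums-of-squares decomposition: SS_total = SS_subjects +
    SS_condition + SS_error; F = MS_condition / MS_error with df
    (k - 1, (k - 1)(n - 1)); eta-squared (partial) = SS_condition /
    (SS_condition + SS_error). The matrix must be complete.
    """
    m = np.asarray(matrix, dtype=float)
    if m.ndim != 2:
        raise InsufficientDataError("rm_anova_slopes requires a 2-D observers x conditions matrix")
    if np.any(~np.isfinite(m)):
        raise InsufficientDataError("incomplete design: matrix contains missing cells")
    n, k = m.shape
    if n < 2 or k < 2:
        raise InsufficientDataError("rm_anova_slopes requires >= 2 observers and >= 2 conditions")
    grand = m.mean()
    ss_cond = n * np.sum((m.mean(axis=0) - grand) ** 2)
    ss_subj = k * np.sum((m.mean(axis=1) - grand) ** 2)
    ss_total = np.sum((m - grand) ** 2)
    ss_err = ss_total - ss_cond - ss_subj
    df1, df2 = k - 1, (k - 1) * (n - 1)
    ms_err = ss_err / df2
    if ms_err <= 0.0:
        f = 0.0 if ss_cond == 0.0 else np.inf
        p = 1.0 if f == 0.0 else 0.0
    else:
        f = (ss_cond / df1) / ms_err
        p = sps.f.sf(f, df1, df2)
    eta = ss_cond / (ss_cond + ss_err) if (ss_cond + ss_err) > 0 else 0.0
    return StatResult(
        kind="rm_anova_F",
        statistic=float(f),
        df=(float(df1), float(df2)),
        p_value=float(p),
        effect_size=float(eta),
        effect_label="eta_squared",
        n=n,
        aux={"ss_condition": float(ss_cond), "ss_error": float(ss_err), "ss_subjects": float(ss_subj)},
    )
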