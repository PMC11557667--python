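"""Regress triadic position reports on true gaze direction.

Per observer: a global OLS line (the classical overestimation factor) and a
four-piece regression with breakpoints at the measured directions
(0, 0.9, 2.2, 5.4, 13.9 deg). Cohort level: a one-way repeated-measures
ANOVA over the four section slopes, with post-hoc paired t-tests of section
1 against the others. Writes linear_fits.csv and triadic_fits.csv.
"""

import sys
from pathlib import Path

sys.path.insert(0, str(Path(__file__).resolve().parent))
from _common import cli, ensure_cohorts  # noqa: E402

import numpy as np  # noqa: E402
import pandas as pd  # noqa: E402

import gazecone as gz  # noqa: E402
from gazecone.io import read_trials, write_report  # noqa: E402
from gazecone.triadic import piecewise_to_frame  # noqa: E402


def main():
    args = cli(__doc__)
    sims = ensure_cohorts(args.results, args.seed)
    ctx = gz.GeometryContext(viewing_distance_cm=165.0, ipd_cm=6.5)

    trials = read_trials(sims["exp1"] / "triadic_trials.csv", "triadic_trials")
    linear_rows, piecewise = [], {}
    for oid, grp in trials.groupby("observer_id"):
        points = gz.points_from_trials(grp, ctx)
        lin = gz.fit_linear(points)
        linear_rows.append(
            {
                "observer_id": oid,
                "slope": lin.slope,
                "intercept": lin.intercept,
                "r_squared": lin.r_squared,
            }
        )
        piecewise[oid] = gz.fit_piecewise(points)

    linear = pd.DataFrame(linear_rows)
    write_report(linear, args.results / "exp1" / "linear_fits.csv")
    pw_frame = piecewise_to_frame(piecewise)
    write_report(pw_frame, args.results / "exp1" / "triadic_fits.csv")

    print(
        f"[exp1] linear fit: mean slope {linear.slope.mean():.2f} "
        f"(overestimation factor), mean intercept {linear.intercept.mean():.2f}"
    )
    seg_means = pw_frame.groupby("segment")[["slope", "intercept"]].mean()
    for k, row in seg_means.iterrows():
        print(f"[exp1] section {k}: mean slope {row.slope:.2f}, mean intercept {row.intercept:.2f}")

    slopes = pw_frame.pivot(index="observer_id", columns="segment", values="slope").to_numpy()
    anova = gz.rm_anova_slopes(slopes)
    print(
        f"[exp1] rm-ANOVA on section slopes: F({anova.df[0]:.0f}, {anova.df[1]:.0f}) = "
        f"{anova.statistic:.2f}, p = {anova.p_value:.3f}, eta^2 = {anova.effect_size:.2f}"
    )
    for k in range(1, 4):
        t = gz.paired_t(slopes[:, 0], slopes[:, k])
        print(
            f"[exp1] section 1 vs {k + 1}: t({t.df:.0f}) = {t.statistic:.2f}, "
            f"p = {t.p_value:.3f}, d = {t.effect_size:.2f}"
        )


if __name__ == "__main__":
    main()
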