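"""Compare the two dyadic methods, before and after triadic correction.

Joins the per-observer constant-stimuli and adjustment thresholds of cohort
1, computes cohort means, the between-method ratio, the paired t and the
correlation; then corrects every threshold with the observer's own
piece-wise triadic regression (segment selected by the threshold) and
repeats the block. Writes report.json and per_observer.csv.
"""

import subprocess
import sys
from pathlib import Path

sys.path.insert(0, str(Path(__file__).resolve().parent))
from _common import cli, ensure_cohorts  # noqa: E402

import pandas as pd  # noqa: E402

import gazecone as gz  # noqa: E402
from gazecone.triadic import piecewise_from_frame  # noqa: E402


def main():
    args = cli(__doc__)
    ensure_cohorts(args.results, args.seed)
    exp1 = args.results / "exp1"
    for script in ("02_fit_constant_stimuli.py", "03_fit_adjustment.py", "04_fit_triadic.py"):
        if not (exp1 / "fits_cs.csv").exists() or not (exp1 / "triadic_fits.csv").exists():
            subprocess.run(
                [sys.executable, str(Path(__file__).parent / script),
                 "--seed", str(args.seed), "--results", str(args.results)],
                check=True,
            )

    fits_cs = pd.read_csv(exp1 / "fits_cs.csv")
    adj = pd.read_csv(exp1 / "adj_summary.csv")
    triadic = piecewise_from_frame(pd.read_csv(exp1 / "triadic_fits.csv"))

    report = gz.compare_methods(fits_cs, adj, triadic_fits=triadic)
    report.write(exp1)

    u, c = report.uncorrected, report.corrected
    print(
        f"[exp1] thresholds: constant stimuli {u.mean_cs:.2f} deg vs adjustment "
        f"{u.mean_adj:.2f} deg -> ratio {u.ratio:.2f} "
        f"(t({u.paired.df:.0f}) = {u.paired.statistic:.2f}, p = {u.paired.p_value:.3f}, "
        f"d = {u.paired.effect_size:.2f})"
    )
    print(f"[exp1] between-method correlation r = {u.correlation.statistic:.2f}")
    print(
        f"[exp1] corrected: {c.mean_cs:.2f} vs {c.mean_adj:.2f} deg -> ratio {c.ratio:.2f} "
        f"(t({c.paired.df:.0f}) = {c.paired.statistic:.2f}, p = {c.paired.p_value:.3f})"
    )
    print(
        f"[exp1] mean estimation bias: constant stimuli {report.mean_bias_cs:.2f}, "
        f"adjustment {report.mean_bias_adj:.2f}"
    )


if __name__ == "__main__":
    main()
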