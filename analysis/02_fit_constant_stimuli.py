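"""Fit psychometric functions to the constant-stimuli blocks.

Cohort 1 (one-sided): yes/no judgments are inverted and fitted with a
cumulative Gaussian per observer; the 50% point is the threshold of direct
gaze. Cohort 2 (two-sided): a Gaussian bell is fitted to proportion-direct;
its SD is the threshold and its center the gaze-cone center. Writes
fits_cs.csv per cohort and a diagnostic figure of the cohort-1 curves.
"""

import sys
from pathlib import Path

sys.path.insert(0, str(Path(__file__).resolve().parent))
from _common import cli, ensure_cohorts  # noqa: E402

import matplotlib

matplotlib.use("Agg")
import matplotlib.pyplot as plt  # noqa: E402
import numpy as np  # noqa: E402
import pandas as pd  # noqa: E402

import gazecone as gz  # noqa: E402
from gazecone.io import read_trials, write_report  # noqa: E402


def fit_exp1(sim_dir: Path, out_dir: Path):
    trials = read_trials(sim_dir / "dyadic_trials.csv", "dyadic_trials")
    rows, curves = [], []
    for oid, grp in trials.groupby("observer_id"):
        data = gz.DyadicProportions.from_trials(grp)
        fit = gz.fit_cumulative_gaussian(data)
        rows.append(
            {
                "observer_id": oid,
                "threshold_deg": fit.threshold_deg,
                "sigma_deg": fit.sigma_deg,
                "lapse": fit.lapse,
                "loglik": fit.loglik,
                "converged": fit.converged,
            }
        )
        curves.append((data, fit))
    fits = pd.DataFrame(rows)
    write_report(fits, out_dir / "exp1" / "fits_cs.csv")

    fig, ax = plt.subplots(figsize=(6, 4))
    xs = np.linspace(0, 14, 200)
    for data, fit in curves:
        ax.plot(data.angles_deg, 1 - data.proportion_direct, ".", alpha=0.3, color="tab:blue")
        from gazecone.psychofit import _p_averted_cs

        ax.plot(xs, _p_averted_cs(xs, fit.threshold_deg, fit.sigma_deg, fit.lapse), "-", alpha=0.3)
    ax.set(xlabel="gaze direction (deg)", ylabel="p(judged averted)", title="Cohort 1 cumulative fits")
    fig.tight_layout()
    fig_dir = out_dir / "figures"
    fig_dir.mkdir(parents=True, exist_ok=True)
    fig.savefig(fig_dir / "exp1_psychometric.png", dpi=120)
    plt.close(fig)
    return fits


def fit_exp2(sim_dir: Path, out_dir: Path):
    trials = read_trials(sim_dir / "dyadic_trials.csv", "dyadic_trials")
    rows = []
    for oid, grp in trials.groupby("observer_id"):
        fit = gz.fit_gaussian_bell(gz.DyadicProportions.from_trials(grp))
        rows.append(
            {
                "observer_id": oid,
                "threshold_deg": fit.width_deg,
                "center_deg": fit.center_deg,
                "amplitude": fit.amplitude,
                "loglik": fit.loglik,
                "converged": fit.converged,
            }
        )
    fits = pd.DataFrame(rows)
    write_report(fits, out_dir / "exp2" / "fits_cs.csv")
    return fits


def main():
    args = cli(__doc__)
    sims = ensure_cohorts(args.results, args.seed)

    fits1 = fit_exp1(sims["exp1"], args.results)
    truth1 = pd.read_csv(sims["exp1"] / "truth.csv")
    print(
        f"[exp1] mean threshold of direct gaze {fits1.threshold_deg.mean():.2f} deg "
        f"(range {fits1.threshold_deg.min():.2f}..{fits1.threshold_deg.max():.2f}; "
        f"generative mean {truth1.criterion.mean():.2f})"
    )
    print(f"[exp1] implied full cone width {gz.cone_width(fits1.threshold_deg.mean()).full_width_deg:.1f} deg")

    fits2 = fit_exp2(sims["exp2"], args.results)
    truth2 = pd.read_csv(sims["exp2"] / "truth.csv")
    print(
        f"[exp2] mean bell width {fits2.threshold_deg.mean():.2f} deg, "
        f"mean center {fits2.center_deg.mean():.2f} deg "
        f"(generative criterion {truth2.criterion.mean():.2f}, "
        f"center shift {truth2.center_shift.mean():.2f})"
    )


if __name__ == "__main__":
    main()
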