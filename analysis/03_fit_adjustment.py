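"""Summarize the method-of-adjustment blocks and test for hysteresis.

Per observer: ascending/descending (x side) cell means, the overall
threshold (unweighted mean of folded cell means) and the within-observer SD
of stop magnitudes. Cohort level: paired t of descending vs ascending series
(hysteresis) and the between-series correlation. Writes adj_summary.csv per
cohort.
"""

import sys
from pathlib import Path

sys.path.insert(0, str(Path(__file__).resolve().parent))
from _common import cli, ensure_cohorts  # noqa: E402

import pandas as pd  # noqa: E402

import gazecone as gz  # noqa: E402
from gazecone.io import read_trials, write_report  # noqa: E402


def analyze(name: str, sim_dir: Path, out_dir: Path, sides: str):
    trials = read_trials(sim_dir / "adjustment_trials.csv", "adjustment_trials")
    summaries = gz.summarize_cohort(trials, sides=sides)
    write_report(summaries, out_dir / name / "adj_summary.csv")
    hyst = gz.hysteresis_contrast(summaries)
    print(
        f"[{name}] ascending {summaries.mean_ascending.mean():.2f} deg, "
        f"descending {summaries.mean_descending.mean():.2f} deg, "
        f"overall threshold {summaries.overall_threshold.mean():.2f} deg "
        f"(between-subject SD {summaries.overall_threshold.std(ddof=1):.2f})"
    )
    t = hyst.t_test
    print(
        f"[{name}] hysteresis contrast {hyst.mean_contrast:+.2f} deg "
        f"(t({t.df:.0f}) = {t.statistic:.2f}, p = {t.p_value:.3f}, d = {t.effect_size:.2f})"
    )
    if hyst.correlation is not None:
        r = hyst.correlation
        print(f"[{name}] series correlation r = {r.statistic:.2f}, p = {r.p_value:.3f}")
    return summaries


def main():
    args = cli(__doc__)
    sims = ensure_cohorts(args.results, args.seed)
    analyze("exp1", sims["exp1"], args.results, sides="one")
    analyze("exp2", sims["exp2"], args.results, sides="two")


if __name__ == "__main__":
    main()
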