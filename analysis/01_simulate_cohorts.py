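"""Simulate the two study cohorts and persist their trial-level CSVs.

Cohort 1 (live-looker style): 18 observers, one-sided exponential design
(5 directions x 25 repetitions), 12 one-sided adjustment trials, 125 triadic
reports each. Cohort 2 (avatar style): 20 observers, 11 two-sided directions
x 35 repetitions, and a 2 side x 2 series x 15 adjustment block with strong
hysteresis. Ground-truth generative parameters go to truth.csv next to the
trial tables — they are the reference for every recovery check downstream.
"""

import sys
from pathlib import Path

sys.path.insert(0, str(Path(__file__).resolve().parent))
from _common import cli  # noqa: E402

import gazecone as gz  # noqa: E402


def main():
    args = cli(__doc__)
    for name, cfg in [
        ("exp1", gz.exp1_cohort_config(18, master_seed=args.seed)),
        ("exp2", gz.exp2_cohort_config(20, master_seed=args.seed + 1)),
    ]:
        data = gz.simulate_cohort(cfg)
        out = args.results / "sim" / name
        data.write(out)
        print(f"[{name}] {cfg.n_observers} observers -> {out}")
        print(
            f"    dyadic {len(data.dyadic)} trials, adjustment {len(data.adjustment)}, "
            f"triadic {len(data.triadic)}"
        )
        print(
            f"    true mean dyadic criterion {data.truth.criterion.mean():.2f} deg, "
            f"adjustment criterion {data.truth.adjust_criterion.mean():.2f} deg"
        )


if __name__ == "__main__":
    main()
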