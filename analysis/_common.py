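"""Shared plumbing for the numbered analysis scripts."""

import argparse
from pathlib import Path

REPO_ROOT = Path(__file__).resolve().parents[1]


def cli(description: str) -> argparse.Namespace:
    parser = argparse.ArgumentParser(description=description)
    parser.add_argument("--seed", type=int, default=0, help="master seed for the simulated cohorts")
    parser.add_argument(
        "--results",
        type=Path,
        default=REPO_ROOT / "results",
        help="directory for simulated data, fits and reports",
    )
    return parser.parse_args()


def ensure_cohorts(results: Path, seed: int) -> dict:
    """Simulate the two study cohorts if their CSVs are not already present."""
    import gazecone as gz

    paths = {}
    for name, cfg in [
        ("exp1", gz.exp1_cohort_config(18, master_seed=seed)),
        ("exp2", gz.exp2_cohort_config(20, master_seed=seed + 1)),
    ]:
        out = results / "sim" / name
        if not (out / "dyadic_trials.csv").exists():
            gz.simulate_cohort(cfg).write(out)
        paths[name] = out
    return paths
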