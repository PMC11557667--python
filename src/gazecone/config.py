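"""YAML configuration for cohort simulations.

Example::

    viewing_distance_cm: 165
    ipd_cm: 6.5
    n_observers: 18
    master_seed: 7
    design:
      type: exponential     # or linear
      base_cm: 2.5
      n_steps: 4
      repetitions: 25
      sides: one-sided
    adjustment:
      sides: one
      reps_per_cell: 6
      range_max_deg: 13.9
      step_deg: 0.05
    triadic:
      positions_deg: [0, 0.9, 2.2, 5.4, 13.9]
      repetitions: 25
    params:
      criterion: {mean: 3.3, sd: 1.0}
      adjust_criterion: {mean: 5.2, sd: 1.28}
"""

from __future__ import annotations

from pathlib import Path

import yaml

from .errors import ConfigError
from .geometry import GeometryContext, exponential_stimulus_design, linear_stimulus_design
from .simulate import AdjustmentPlan, CohortConfig, ParamDist, TriadicDesign

__all__ = ["load_cohort_config"]


def _design_from_dict(d: dict, ctx: GeometryContext):
    kind = d.get("type", "exponential")
    reps = int(d.get("repetitions", 25))
    if kind == "exponential":
        return exponential_stimulus_design(
            float(d.get("base_cm", 2.5)), int(d.get("n_steps", 4)), ctx, repetitions=reps
        )
    if kind == "linear":
        return linear_stimulus_design(
            float(d.get("step_deg", 3.0)), float(d.get("max_deg", 15.0)), repetitions=reps
        )
    raise ConfigError(f"unknown design type {kind!r} (expected exponential or linear)")


def load_cohort_config(path) -> CohortConfig:
    """Parse a YAML cohort configuration into a :class:`CohortConfig`."""
    raw = yaml.safe_load(Path(path).read_text())
    if not isinstance(raw, dict):
        raise ConfigError(f"{path}: expected a mapping at the top level")
    try:
        ctx = GeometryContext(
            viewing_distance_cm=float(raw.get("viewing_distance_cm", 165.0)),
            ipd_cm=float(raw.get("ipd_cm", 6.5)),
        )
        params = {}
        for name, spec in (raw.get("params") or {}).items():
            if isinstance(spec, dict):
                params[name] = ParamDist(mean=float(spec["mean"]), sd=float(spec.get("sd", 0.0)))
            else:
                params[name] = ParamDist(mean=float(spec))
        adj = raw.get("adjustment") or {}
        tri = raw.get("triadic") or {}
        return CohortConfig(
            n_observers=int(raw["n_observers"]),
            params=params,
            dyadic_design=_design_from_dict(raw.get("design") or {}, ctx),
            adjustment_plan=AdjustmentPlan(
                sides=adj.get("sides", "one"),
                reps_per_cell=int(adj.get("reps_per_cell", 6)),
                range_max_deg=float(adj.get("range_max_deg", 13.9)),
                step_deg=float(adj.get("step_deg", 0.05)),
            ),
            triadic_design=TriadicDesign(
                positions_deg=tuple(float(p) for p in tri.get("positions_deg", (0, 0.9, 2.2, 5.4, 13.9))),
                repetitions=int(tri.get("repetitions", 25)),
            ),
            geometry=ctx,
            master_seed=int(raw.get("master_seed", 0)),
        )
    except KeyError as exc:
        raise ConfigError(f"{path}: missing required key {exc}") from exc
    except (TypeError, ValueError) as exc:
        raise ConfigError(f"{path}: {exc}") from exc
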