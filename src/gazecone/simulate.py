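"""Synthetic observers for the three gaze-measurement tasks.

No trial-level human data are available for this paradigm, so the pipeline is
validated by parameter recovery on simulated cohorts. The generative model is
deliberately minimal — one parameter per reported phenomenon:

* **Dyadic yes/no (constant stimuli).** The probability of judging a gaze of
  ``theta`` degrees as direct is a fold of a cumulative Gaussian around the
  observer's criterion ``T``::

      P(direct | theta) = (1 - lapse) * Phi((T - |theta - c|) / sigma) + lapse / 2

  where ``c`` is a center shift (two-sided designs only; one-sided designs
  use ``|theta|``), ``sigma`` the psychometric width and ``lapse`` a small
  stimulus-independent error rate.

* **Method of adjustment.** Ascending series (start averted, stop when just
  looked at) stop at ``T - h/2 + eps``; descending series (start direct, stop
  when no longer looked at) at ``T + h/2 + eps``; ``eps ~ N(0, adjust_noise_sd)``.
  The symmetric ``+-h/2`` split makes the ascending/descending average an
  unbiased estimate of ``T`` for any hysteresis ``h``. Stops are quantized to
  the device step and clipped to the adjustable range; on the left side the
  sign is negative.

* **Triadic position report.** Perceived gaze direction is a continuous
  two-slope gain ``g(theta) = sign(theta) * [near_gain * min(|theta|, knot)
  + far_gain * max(0, |theta| - knot)]`` — shallow near straight gaze,
  overestimating in the periphery — converted to centimetres at the scale
  plane, perturbed with Gaussian read-off noise, and rounded to the whole
  centimetre the observer reads off the scale.

With every noise term, the lapse and the hysteresis at zero, each task
returns the deterministic image of the generative model, which the analysis
modules must recover exactly (the noiseless-closure tests).
"""

from __future__ import annotations

from dataclasses import dataclass, field, fields, replace
from pathlib import Path

import numpy as np
import pandas as pd
from scipy.stats import norm

from .errors import ConfigError, DesignError, GeometryError
from .geometry import (
    GeometryContext,
    StimulusDesign,
    angle_to_offset,
    exponential_stimulus_design,
    linear_stimulus_design,
)

__all__ = [
    "ObserverParams",
    "AdjustmentPlan",
    "TriadicDesign",
    "CohortConfig",
    "ParamDist",
    "CohortData",
    "simulate_dyadic_constant",
    "simulate_adjustment",
    "simulate_triadic",
    "simulate_cohort",
    "exp1_cohort_config",
    "exp2_cohort_config",
]

# Sub-stream labels for the counter-based seed derivation (see _task_rng).
_TASK_CODES = {"params": 0, "dyadic": 1, "adjustment": 2, "triadic": 3}


@dataclass(frozen=True)
class ObserverParams:
    """Generative truth for one virtual observer.

    Defaults describe a typical live-looker observer: dyadic criterion near
    3.3 deg with a ~1.5 deg psychometric width, an adjustment criterion near
    5.2 deg, mild hysteresis, ~1 deg adjustment scatter (deconvolved from the observed within-observer SD), and a triadic gain
    that underestimates below ~0.9 deg (slope 0.18) and overestimates beyond
    it (slope 1.8).

    ``adjust_criterion`` is the criterion the observer applies in the
    adjustment task; ``None`` means "same as the dyadic criterion". The two
    are separate because the methods empirically disagree, and the simulator
    must be able to reproduce that disagreement.
    """

    criterion: float = 3.3
    psycho_width: float = 1.5
    lapse: float = 0.02
    center_shift: float = 0.0
    hysteresis: float = -0.37
    adjust_noise_sd: float = 1.03
    adjust_criterion: float | None = None
    triadic_near_gain: float = 0.18
    triadic_far_gain: float = 1.8
    triadic_knot: float = 0.9
    triadic_noise_sd: float = 1.5
    seed: int = 0

    def __post_init__(self):
        if self.criterion <= 0:
            raise ConfigError(f"criterion must be > 0, got {self.criterion}")
        if self.psycho_width <= 0:
            raise ConfigError(f"psycho_width must be > 0, got {self.psycho_width}")
        if not 0.0 <= self.lapse <= 0.1:
            raise ConfigError(f"lapse must be in [0, 0.1], got {self.lapse}")
        for name in ("adjust_noise_sd", "triadic_noise_sd"):
            if getattr(self, name) < 0:
                raise ConfigError(f"{name} must be >= 0")
        if self.triadic_knot < 0:
            raise ConfigError(f"triadic_knot must be >= 0, got {self.triadic_knot}")
        if self.adjust_criterion is not None and self.adjust_criterion <= 0:
            raise ConfigError(f"adjust_criterion must be > 0, got {self.adjust_criterion}")

    @property
    def effective_adjust_criterion(self) -> float:
        return self.criterion if self.adjust_criterion is None else self.adjust_criterion


@dataclass(frozen=True)
class AdjustmentPlan:
    """Series plan for a method-of-adjustment block.

    ``sides`` is ``"one"`` (a single side, stops stored as non-negative
    magnitudes) or ``"two"`` (left and right, left stops negative).
    ``reps_per_cell`` repeats each (series, side) combination. ``step_deg``
    is the device granularity to which stops are quantized.
    """

    sides: str = "one"
    reps_per_cell: int = 6
    range_max_deg: float = 13.9
    step_deg: float = 0.05

    def __post_init__(self):
        if self.sides not in ("one", "two"):
            raise DesignError(f"sides must be 'one' or 'two', got {self.sides!r}")
        if self.reps_per_cell < 1:
            raise DesignError("reps_per_cell must be >= 1")
        if self.range_max_deg <= 0:
            raise DesignError(f"range_max_deg must be > 0, got {self.range_max_deg}")
        if self.step_deg < 0:
            raise DesignError("step_deg must be >= 0")

    @property
    def side_labels(self) -> tuple:
        return ("right",) if self.sides == "one" else ("left", "right")

    @property
    def n_trials(self) -> int:
        return 2 * len(self.side_labels) * self.reps_per_cell


@dataclass(frozen=True)
class TriadicDesign:
    """Fixation positions (degrees) and repetitions for the triadic task.

    ``round_to_cm`` is the read-off granularity of the scale: observers
    report whole centimetres. It can be switched off for noiseless-closure
    analyses, where the unquantized perceived position is wanted.
    """

    positions_deg: tuple = (0.0, 0.9, 2.2, 5.4, 13.9)
    repetitions: int = 25
    scale_max_cm: float = 100.0
    round_to_cm: bool = True

    def __post_init__(self):
        if self.repetitions < 1:
            raise DesignError("repetitions must be >= 1")
        if self.scale_max_cm <= 0:
            raise DesignError("scale_max_cm must be > 0")


def _rng(seed) -> np.random.Generator:
    return np.random.default_rng(seed)


def perceived_gaze_deg(theta_deg, params: ObserverParams):
    """Noiseless perceived gaze direction g(theta) of the triadic model."""
    theta = np.asarray(theta_deg, dtype=float)
    mag = np.abs(theta)
    g = params.triadic_near_gain * np.minimum(mag, params.triadic_knot)
    g = g + params.triadic_far_gain * np.maximum(0.0, mag - params.triadic_knot)
    return np.sign(theta) * g


def p_direct(theta_deg, params: ObserverParams, sides: str = "one-sided"):
    """Generative probability of a 'direct' judgment at gaze ``theta``."""
    theta = np.asarray(theta_deg, dtype=float)
    x = np.abs(theta) if sides == "one-sided" else np.abs(theta - params.center_shift)
    p = (1.0 - params.lapse) * norm.cdf(
        (params.criterion - x) / params.psycho_width
    ) + params.lapse / 2.0
    return p


def simulate_dyadic_constant(
    params: ObserverParams,
    design: StimulusDesign,
    seed=None,
) -> pd.DataFrame:
    """Simulate one observer's yes/no block under the method of constant stimuli.

    Returns one row per trial with columns ``trial``, ``gaze_deg`` and
    ``response`` (1 = judged direct, 0 = judged averted), in the randomized
    presentation order.
    """
    rng = _rng(params.seed if seed is None else seed)
    gaze = np.repeat(np.asarray(design.directions_deg, dtype=float), design.repetitions)
    rng.shuffle(gaze)
    p = p_direct(gaze, params, sides=design.sides)
    responses = (rng.random(gaze.size) < p).astype(int)
    return pd.DataFrame(
        {"trial": np.arange(1, gaze.size + 1), "gaze_deg": gaze, "response": responses}
    )


def simulate_adjustment(
    params: ObserverParams,
    plan: AdjustmentPlan,
    seed=None,
) -> pd.DataFrame:
    """Simulate one observer's adjustment block (ascending and descending series).

    Columns: ``trial``, ``series`` in {ascending, descending}, ``side`` in
    {left, right}, ``stop_deg`` (signed; left negative).
    """
    rng = _rng(params.seed if seed is None else seed)
    T = params.effective_adjust_criterion
    h = params.hysteresis
    cells = [
        (series, side)
        for side in plan.side_labels
        for series in ("ascending", "descending")
        for _ in range(plan.reps_per_cell)
    ]
    order = rng.permutation(len(cells))
    rows = []
    for trial, idx in enumerate(order, start=1):
        series, side = cells[idx]
        offset = -h / 2.0 if series == "ascending" else h / 2.0
        stop = T + offset + rng.normal(0.0, params.adjust_noise_sd)
        if plan.step_deg > 0:
            stop = round(stop / plan.step_deg) * plan.step_deg
        stop = float(np.clip(stop, 0.0, plan.range_max_deg))
        if side == "left":
            stop = -stop
        rows.append((trial, series, side, stop))
    return pd.DataFrame(rows, columns=["trial", "series", "side", "stop_deg"])


def simulate_triadic(
    params: ObserverParams,
    design: TriadicDesign,
    ctx: GeometryContext,
    seed=None,
) -> pd.DataFrame:
    """Simulate one observer's triadic block (position reports on a cm scale).

    The perceived direction is mapped to the scale plane at the viewing
    distance, perturbed with read-off noise and rounded to the whole
    centimetre. Columns: ``trial``, ``true_deg``, ``reported_cm`` (integer).
    """
    max_angle = float(
        np.degrees(np.arctan(design.scale_max_cm / ctx.viewing_distance_cm))
    )
    for pos in design.positions_deg:
        if abs(pos) > max_angle:
            raise GeometryError(
                f"position {pos} deg lies beyond the scale "
                f"(+-{design.scale_max_cm} cm = +-{max_angle:.1f} deg)"
            )
    rng = _rng(params.seed if seed is None else seed)
    true = np.repeat(np.asarray(design.positions_deg, dtype=float), design.repetitions)
    rng.shuffle(true)
    perceived_cm = angle_to_offset(perceived_gaze_deg(true, params), ctx)
    reported = perceived_cm + rng.normal(0.0, params.triadic_noise_sd, true.size)
    if design.round_to_cm:
        reported = np.rint(reported).astype(int)
    return pd.DataFrame(
        {
            "trial": np.arange(1, true.size + 1),
            "true_deg": true,
            "reported_cm": reported,
        }
    )


# ---------------------------------------------------------------------------
# Cohorts


@dataclass(frozen=True)
class ParamDist:
    """Normal distribution (sd=0 means fixed) for one ObserverParams field."""

    mean: float
    sd: float = 0.0

    def __post_init__(self):
        if self.sd < 0:
            raise ConfigError(f"sd must be >= 0, got {self.sd}")


@dataclass(frozen=True)
class CohortConfig:
    """A cohort of virtual observers and the designs of their three tasks.

    ``params`` maps ObserverParams field names to :class:`ParamDist`; fields
    not listed stay at their ObserverParams default (fixed). Criterion-like
    draws are truncated below at ``min_criterion`` so every observer stays in
    the model's domain.
    """

    n_observers: int
    params: dict = field(default_factory=dict)
    dyadic_design: StimulusDesign | None = None
    adjustment_plan: AdjustmentPlan | None = None
    triadic_design: TriadicDesign | None = None
    geometry: GeometryContext = GeometryContext(viewing_distance_cm=165.0)
    master_seed: int = 0
    min_criterion: float = 0.2

    def __post_init__(self):
        if self.n_observers < 1:
            raise ConfigError("n_observers must be >= 1")
        valid = {f.name for f in fields(ObserverParams)} - {"seed"}
        for name, dist in self.params.items():
            if name not in valid:
                raise ConfigError(f"unknown ObserverParams field {name!r}")
            if not isinstance(dist, ParamDist):
                raise ConfigError(f"params[{name!r}] must be a ParamDist")


@dataclass
class CohortData:
    """Simulated trial tables plus the generative ground truth."""

    dyadic: pd.DataFrame
    adjustment: pd.DataFrame
    triadic: pd.DataFrame
    truth: pd.DataFrame

    def write(self, out_dir) -> dict:
        """Write the four RFC-4180 CSVs; returns {name: path}."""
        out = Path(out_dir)
        out.mkdir(parents=True, exist_ok=True)
        paths = {}
        for name, df in [
            ("dyadic_trials", self.dyadic),
            ("adjustment_trials", self.adjustment),
            ("triadic_trials", self.triadic),
            ("truth", self.truth),
        ]:
            path = out / f"{name}.csv"
            df.to_csv(path, index=False)
            paths[name] = path
        return paths


def _task_rng(master_seed: int, observer_index: int, task: str) -> np.random.Generator:
    """Counter-based seed split: stream (master_seed, observer_index, task_code).

    Every observer/task pair gets an independent, reproducible stream; the
    triple is fed to ``SeedSequence`` so no two streams collide.
    """
    return np.random.default_rng(
        np.random.SeedSequence([master_seed, observer_index, _TASK_CODES[task]])
    )


def _draw_params(cfg: CohortConfig, observer_index: int) -> ObserverParams:
    rng = _task_rng(cfg.master_seed, observer_index, "params")
    overrides = {}
    for name, dist in cfg.params.items():
        value = dist.mean if dist.sd == 0 else rng.normal(dist.mean, dist.sd)
        if name in ("criterion", "adjust_criterion"):
            value = max(value, cfg.min_criterion)
        elif name == "lapse":
            value = float(np.clip(value, 0.0, 0.1))
        elif name in ("psycho_width", "adjust_noise_sd", "triadic_noise_sd", "triadic_knot"):
            value = max(value, 1e-6 if name == "psycho_width" else 0.0)
        overrides[name] = value
    overrides["seed"] = observer_index
    return replace(ObserverParams(), **overrides)


def simulate_cohort(cfg: CohortConfig) -> CohortData:
    """Simulate every task for every observer of a cohort.

    Per-observer parameters are drawn from ``cfg.params`` and persisted in the
    ``truth`` table (the ground truth for recovery tests). Observer/task
    random streams are split deterministically from ``master_seed``, so the
    same config always yields byte-identical CSVs.
    """
    dyadic_design = cfg.dyadic_design or exponential_stimulus_design(
        2.5, 4, cfg.geometry, repetitions=25
    )
    plan = cfg.adjustment_plan or AdjustmentPlan()
    triadic_design = cfg.triadic_design or TriadicDesign()

    dyadic_parts, adj_parts, tri_parts, truth_rows = [], [], [], []
    for i in range(1, cfg.n_observers + 1):
        obs = _draw_params(cfg, i)
        d = simulate_dyadic_constant(obs, dyadic_design, seed=_task_rng(cfg.master_seed, i, "dyadic"))
        a = simulate_adjustment(obs, plan, seed=_task_rng(cfg.master_seed, i, "adjustment"))
        t = simulate_triadic(
            obs, triadic_design, cfg.geometry, seed=_task_rng(cfg.master_seed, i, "triadic")
        )
        for part, acc in ((d, dyadic_parts), (a, adj_parts), (t, tri_parts)):
            part.insert(0, "observer_id", i)
            acc.append(part)
        row = {"observer_id": i}
        for f in fields(ObserverParams):
            row[f.name] = getattr(obs, f.name)
        row["adjust_criterion"] = obs.effective_adjust_criterion
        truth_rows.append(row)

    return CohortData(
        dyadic=pd.concat(dyadic_parts, ignore_index=True),
        adjustment=pd.concat(adj_parts, ignore_index=True),
        triadic=pd.concat(tri_parts, ignore_index=True),
        truth=pd.DataFrame(truth_rows),
    )


def exp1_cohort_config(n_observers: int = 18, master_seed: int = 0) -> CohortConfig:
    """Live-looker-style cohort: one-sided exponential design at 165 cm.

    18 analyzable observers; 5 directions x 25 repetitions (125 dyadic
    trials); 12 one-sided adjustment trials in 0.05 deg steps; 125 triadic
    reports. Dyadic criteria ~ N(3.3, 1.0), adjustment criteria
    ~ N(5.2, 1.28), hysteresis -0.37 deg, within-observer adjustment scatter
    1.05 deg, triadic gains 0.18 / 1.8 around a 0.9 deg knot.
    """
    ctx = GeometryContext(viewing_distance_cm=165.0, ipd_cm=6.5)
    return CohortConfig(
        n_observers=n_observers,
        params={
            "criterion": ParamDist(3.3, 1.0),
            "psycho_width": ParamDist(1.5, 0.3),
            "lapse": ParamDist(0.02, 0.0),
            "adjust_criterion": ParamDist(5.2, 1.28),
            "hysteresis": ParamDist(-0.37, 0.5),
            "adjust_noise_sd": ParamDist(1.03, 0.3),
            "triadic_near_gain": ParamDist(0.18, 0.1),
            "triadic_far_gain": ParamDist(1.8, 0.3),
            "triadic_knot": ParamDist(0.9, 0.0),
            "triadic_noise_sd": ParamDist(1.5, 0.3),
        },
        dyadic_design=exponential_stimulus_design(2.5, 4, ctx, repetitions=25),
        adjustment_plan=AdjustmentPlan(sides="one", reps_per_cell=6, range_max_deg=13.9, step_deg=0.05),
        triadic_design=TriadicDesign(positions_deg=(0.0, 0.9, 2.2, 5.4, 13.9), repetitions=25),
        geometry=ctx,
        master_seed=master_seed,
    )


def exp2_cohort_config(n_observers: int = 20, master_seed: int = 0) -> CohortConfig:
    """Avatar-style cohort: two-sided designs at 165 cm.

    11 directions (-15..15 deg in 3 deg steps) x 35 repetitions (385 dyadic
    trials); 2 sides x 2 series x 15 repetitions (60 adjustment trials) in
    1 deg steps with strong hysteresis (+4.4 deg); a slight rightward center
    shift (0.69 deg) in the dyadic criterion.
    """
    ctx = GeometryContext(viewing_distance_cm=165.0, ipd_cm=6.5)
    return CohortConfig(
        n_observers=n_observers,
        params={
            "criterion": ParamDist(3.51, 1.44),
            "psycho_width": ParamDist(1.5, 0.3),
            "lapse": ParamDist(0.02, 0.0),
            "center_shift": ParamDist(0.69, 0.5),
            "adjust_criterion": ParamDist(4.73, 1.3),
            "hysteresis": ParamDist(4.4, 1.0),
            "adjust_noise_sd": ParamDist(2.39, 0.6),
        },
        dyadic_design=linear_stimulus_design(3.0, 15.0, repetitions=35),
        adjustment_plan=AdjustmentPlan(sides="two", reps_per_cell=15, range_max_deg=15.0, step_deg=1.0),
        triadic_design=TriadicDesign(positions_deg=(0.0, 0.9, 2.2, 5.4, 13.9), repetitions=25),
        geometry=ctx,
        master_seed=master_seed,
    )
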