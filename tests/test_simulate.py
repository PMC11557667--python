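"""Synthetic observers: determinism, noiseless limits, trial bookkeeping."""

import numpy as np
import pandas as pd
import pytest

import gazecone as gz
from gazecone.errors import ConfigError, GeometryError
from gazecone.simulate import p_direct, perceived_gaze_deg


def small_plan(**kw):
    defaults = dict(sides="one", reps_per_cell=6, range_max_deg=13.9, step_deg=0.05)
    defaults.update(kw)
    return gz.AdjustmentPlan(**defaults)


class TestDyadic:
    def test_exp1_trial_count(self, exp1_design):
        trials = gz.simulate_dyadic_constant(gz.ObserverParams(), exp1_design, seed=0)
        assert len(trials) == 125
        counts = trials.groupby("gaze_deg").size()
        assert (counts == 25).all()

    def test_exp2_trial_count(self, exp2_design):
        trials = gz.simulate_dyadic_constant(gz.ObserverParams(), exp2_design, seed=0)
        assert len(trials) == 385

    def test_step_function_limit(self, exp1_design):
        obs = gz.ObserverParams(criterion=3.0, psycho_width=1e-6, lapse=0.0)
        trials = gz.simulate_dyadic_constant(obs, exp1_design, seed=1)
        inside = trials[trials.gaze_deg.abs() < 3.0]
        outside = trials[trials.gaze_deg.abs() > 3.0]
        assert (inside.response == 1).all()
        assert (outside.response == 0).all()

    def test_determinism(self, exp1_design):
        obs = gz.ObserverParams(seed=42)
        a = gz.simulate_dyadic_constant(obs, exp1_design)
        b = gz.simulate_dyadic_constant(obs, exp1_design)
        pd.testing.assert_frame_equal(a, b)

    def test_generative_probability_in_unit_interval(self):
        thetas = np.linspace(-30, 30, 121)
        for obs in [
            gz.ObserverParams(),
            gz.ObserverParams(criterion=0.5, psycho_width=0.1, lapse=0.1),
            gz.ObserverParams(criterion=10, psycho_width=5, center_shift=3.0),
        ]:
            for sides in ("one-sided", "two-sided"):
                p = p_direct(thetas, obs, sides=sides)
                assert np.all((p >= 0) & (p <= 1))

    def test_lapse_out_of_range_rejected(self):
        with pytest.raises(ConfigError):
            gz.ObserverParams(lapse=0.2)


class TestAdjustment:
    def test_exp2_trial_count(self):
        plan = small_plan(sides="two", reps_per_cell=15, range_max_deg=15.0, step_deg=1.0)
        trials = gz.simulate_adjustment(gz.ObserverParams(), plan, seed=0)
        assert len(trials) == 60
        assert set(trials.series) == {"ascending", "descending"}
        assert set(trials.side) == {"left", "right"}

    def test_noiseless_stops_at_criterion(self):
        obs = gz.ObserverParams(
            criterion=5.0, adjust_criterion=5.0, hysteresis=0.0, adjust_noise_sd=0.0
        )
        plan = small_plan(sides="two")
        trials = gz.simulate_adjustment(obs, plan, seed=3)
        assert np.allclose(trials.stop_deg.abs(), 5.0)
        assert np.allclose(trials[trials.side == "left"].stop_deg, -5.0)

    def test_hysteresis_splits_series_symmetrically(self):
        obs = gz.ObserverParams(adjust_criterion=5.0, hysteresis=4.4, adjust_noise_sd=0.0)
        trials = gz.simulate_adjustment(obs, small_plan(), seed=4)
        asc = trials[trials.series == "ascending"].stop_deg.mean()
        desc = trials[trials.series == "descending"].stop_deg.mean()
        assert desc - asc == pytest.approx(4.4, abs=1e-9)
        assert (asc + desc) / 2 == pytest.approx(5.0, abs=1e-9)

    def test_stops_inside_adjustable_range(self):
        obs = gz.ObserverParams(adjust_criterion=12.0, adjust_noise_sd=6.0)
        plan = small_plan(sides="two", range_max_deg=13.9)
        trials = gz.simulate_adjustment(obs, plan, seed=5)
        assert trials.stop_deg.abs().max() <= 13.9
        assert trials.stop_deg.abs().min() >= 0.0

    def test_quantization_to_device_step(self):
        obs = gz.ObserverParams(adjust_noise_sd=2.0)
        trials = gz.simulate_adjustment(obs, small_plan(step_deg=1.0), seed=6)
        assert np.allclose(trials.stop_deg, np.round(trials.stop_deg))


class TestTriadic:
    def test_origin_maps_to_zero(self, ctx165):
        obs = gz.ObserverParams(triadic_noise_sd=0.0)
        design = gz.TriadicDesign(positions_deg=(0.0,), repetitions=10)
        trials = gz.simulate_triadic(obs, design, ctx165, seed=0)
        assert (trials.reported_cm == 0).all()

    def test_reports_are_whole_centimetres(self, ctx165):
        trials = gz.simulate_triadic(gz.ObserverParams(), gz.TriadicDesign(), ctx165, seed=1)
        assert trials.reported_cm.dtype.kind == "i"

    def test_nearest_centimetre_rounding(self, ctx165):
        # An identity-gain observer perceiving exactly 4.4 / 4.6 cm.
        obs = gz.ObserverParams(
            triadic_near_gain=1.0, triadic_far_gain=1.0, triadic_knot=0.1, triadic_noise_sd=0.0
        )
        for cm, expected in [(4.4, 4), (4.6, 5)]:
            theta = gz.offset_to_angle(cm, ctx165)
            design = gz.TriadicDesign(positions_deg=(theta,), repetitions=1)
            trials = gz.simulate_triadic(obs, design, ctx165, seed=0)
            assert trials.reported_cm.iloc[0] == expected

    def test_noiseless_two_slope_gain_recovered(self, ctx165):
        obs = gz.ObserverParams(
            triadic_near_gain=0.18, triadic_far_gain=1.8, triadic_knot=0.9, triadic_noise_sd=0.0
        )
        positions = tuple(np.linspace(0.0, 13.9, 150))
        design = gz.TriadicDesign(positions_deg=positions, repetitions=1, round_to_cm=False)
        trials = gz.simulate_triadic(obs, design, ctx165, seed=2)
        fit = gz.fit_piecewise(gz.points_from_trials(trials, ctx165))
        assert fit.segments[0].slope == pytest.approx(0.18, abs=1e-6)
        assert fit.segments[3].slope == pytest.approx(1.8, abs=1e-6)

    def test_position_beyond_scale_rejected(self, ctx165):
        design = gz.TriadicDesign(positions_deg=(40.0,), repetitions=1, scale_max_cm=100.0)
        with pytest.raises(GeometryError):
            gz.simulate_triadic(gz.ObserverParams(), design, ctx165, seed=0)

    def test_perceived_gaze_is_odd(self):
        obs = gz.ObserverParams()
        thetas = np.linspace(0, 15, 50)
        assert np.allclose(
            perceived_gaze_deg(-thetas, obs), -perceived_gaze_deg(thetas, obs)
        )


class TestCohort:
    def test_all_fixed_gives_identical_observers(self):
        cfg = gz.CohortConfig(
            n_observers=6,
            params={"criterion": gz.ParamDist(3.3, 0.0), "adjust_criterion": gz.ParamDist(5.2, 0.0)},
            master_seed=9,
        )
        truth = gz.simulate_cohort(cfg).truth
        assert truth.criterion.nunique() == 1
        assert truth.adjust_criterion.nunique() == 1

    def test_byte_identical_across_runs(self, tmp_path):
        cfg = gz.exp1_cohort_config(4, master_seed=11)
        paths_a = gz.simulate_cohort(cfg).write(tmp_path / "a")
        paths_b = gz.simulate_cohort(cfg).write(tmp_path / "b")
        for name in paths_a:
            assert paths_a[name].read_bytes() == paths_b[name].read_bytes()

    def test_master_seed_changes_data(self):
        a = gz.simulate_cohort(gz.exp1_cohort_config(3, master_seed=1)).dyadic
        b = gz.simulate_cohort(gz.exp1_cohort_config(3, master_seed=2)).dyadic
        assert not a.equals(b)

    def test_sampled_criteria_near_population_mean(self):
        # n=18 with criterion ~ N(3.3, 1.0): sample mean within 3 standard errors.
        deviations = []
        for seed in range(5):
            cfg = gz.CohortConfig(
                n_observers=18, params={"criterion": gz.ParamDist(3.3, 1.0)}, master_seed=seed
            )
            truth = gz.simulate_cohort(cfg).truth
            deviations.append(abs(truth.criterion.mean() - 3.3))
        bound = 3.0 * 1.0 / np.sqrt(18)
        assert np.mean(np.array(deviations) <= bound) >= 0.8  # ~99.7% each, allow one excursion

    def test_truth_persists_generative_params(self):
        data = gz.simulate_cohort(gz.exp1_cohort_config(3, master_seed=0))
        for col in ("criterion", "psycho_width", "lapse", "hysteresis", "triadic_near_gain"):
            assert col in data.truth.columns
        assert list(data.truth.observer_id) == [1, 2, 3]

    def test_unknown_param_rejected(self):
        with pytest.raises(ConfigError):
            gz.CohortConfig(n_observers=2, params={"not_a_field": gz.ParamDist(1.0)})
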