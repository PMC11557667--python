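"""Psychometric fitting: MLE vs grid oracle, symmetry, recovery."""

import numpy as np
import pytest

import gazecone as gz
from gazecone.errors import InsufficientDataError, NonIdentifiableError
from gazecone.psychofit import binomial_loglik


def proportions(angles, n, k):
    return gz.DyadicProportions(
        angles_deg=np.asarray(angles, float),
        n_trials=np.full(len(angles), n, float) if np.isscalar(n) else np.asarray(n, float),
        n_direct=np.asarray(k, float),
    )


def simulate_props(criterion, sigma, design, seed, lapse=0.0):
    obs = gz.ObserverParams(criterion=criterion, psycho_width=sigma, lapse=lapse, seed=seed)
    trials = gz.simulate_dyadic_constant(obs, design)
    return gz.DyadicProportions.from_trials(trials)


class TestCumulativeGaussian:
    def test_separation_case_brackets_threshold(self):
        # Perfectly separated data: all direct up to 2.2 deg, all averted beyond.
        data = proportions([0.0, 0.9, 2.2, 5.4, 13.9], 25, [25, 25, 25, 0, 0])
        fit = gz.fit_cumulative_gaussian(data)
        assert 2.2 < fit.threshold_deg < 5.4
        assert fit.sigma_deg < 1.0  # driven toward the lower bound
        assert fit.loglik <= 0.0

    def test_matches_grid_oracle_on_simulated_data(self, exp1_design):
        data = simulate_props(3.33, 1.5, exp1_design, seed=7)
        fit = gz.fit_cumulative_gaussian(data)
        grid = {
            "threshold": np.arange(0.5, 8.0, 0.05),
            "sigma": np.arange(0.2, 6.0, 0.05),
        }
        best, best_ll, _ = gz.grid_fit_oracle(data, grid, model="cumulative")
        assert abs(fit.threshold_deg - best["threshold"]) <= 0.05
        assert abs(fit.sigma_deg - best["sigma"]) <= 0.05
        assert fit.loglik >= best_ll - 1e-6  # continuous optimum beats the grid

    def test_mirror_symmetry_of_inversion(self, exp1_design):
        # Negating angles and swapping yes/no flips the threshold's sign.
        data = simulate_props(3.0, 1.2, exp1_design, seed=3)
        mirrored = proportions(-data.angles_deg, data.n_trials, data.n_trials - data.n_direct)
        fit = gz.fit_cumulative_gaussian(data)
        fit_m = gz.fit_cumulative_gaussian(mirrored)
        assert fit_m.threshold_deg == pytest.approx(-fit.threshold_deg, abs=1e-4)
        assert fit_m.sigma_deg == pytest.approx(fit.sigma_deg, abs=1e-4)

    def test_free_lapse_bounded(self, exp1_design):
        data = simulate_props(3.3, 1.5, exp1_design, seed=11, lapse=0.05)
        fit = gz.fit_cumulative_gaussian(data, free_lapse=True)
        assert 0.0 <= fit.lapse <= 0.05

    def test_all_identical_responses_rejected(self):
        with pytest.raises(NonIdentifiableError, match="identical"):
            gz.fit_cumulative_gaussian(proportions([0, 1, 2, 3], 10, [10, 10, 10, 10]))

    def test_too_few_angles_rejected(self):
        with pytest.raises(InsufficientDataError):
            gz.fit_cumulative_gaussian(proportions([0, 5], 20, [18, 2]))

    def test_mean_recovery_and_monotonicity_across_cohorts(self, exp1_design):
        # Mean fitted threshold tracks the generative criterion, and raising
        # the criterion by 1 degree raises the recovered mean (paired by seed).
        recovered = {3.3: [], 4.3: []}
        for crit in recovered:
            for seed in range(8):
                data = simulate_props(crit, 1.5, exp1_design, seed=seed, lapse=0.02)
                recovered[crit].append(gz.fit_cumulative_gaussian(data).threshold_deg)
        assert np.mean(recovered[3.3]) == pytest.approx(3.3, abs=0.3)
        diffs = np.array(recovered[4.3]) - np.array(recovered[3.3])
        assert diffs.mean() > 0.5

    def test_step_limit_converges_to_step_location(self, ctx165):
        # Dense angles, near-zero generative width: threshold -> step location.
        angles = np.round(np.linspace(0.5, 6.5, 25), 3)
        obs = gz.ObserverParams(criterion=3.5, psycho_width=1e-4, lapse=0.0)
        from gazecone.simulate import p_direct

        n = 40
        k = np.rint(n * p_direct(angles, obs, sides="one-sided"))
        fit = gz.fit_cumulative_gaussian(proportions(angles, n, k))
        assert fit.threshold_deg == pytest.approx(3.5, abs=0.15)


class TestGaussianBell:
    def test_recovers_avatar_cohort_parameters(self, exp2_design):
        obs = gz.ObserverParams(
            criterion=3.51, psycho_width=1.0, lapse=0.02, center_shift=0.69, seed=5
        )
        trials = gz.simulate_dyadic_constant(obs, exp2_design)
        data = gz.DyadicProportions.from_trials(trials)
        fit = gz.fit_gaussian_bell(data)
        grid = {
            "center": np.arange(-3.0, 3.0, 0.05),
            "width": np.arange(1.0, 8.0, 0.05),
        }
        best, _, _ = gz.grid_fit_oracle(data, grid, model="bell", fix_amplitude=fit.amplitude)
        assert abs(fit.center_deg - best["center"]) <= 0.05
        assert abs(fit.width_deg - best["width"]) <= 0.05

    def test_symmetric_data_centered_at_zero(self, exp2_design):
        angles = np.asarray(exp2_design.directions_deg)
        p = np.exp(-(angles**2) / (2 * 3.5**2))
        n = 200
        data = proportions(angles, n, np.rint(n * 0.98 * p))
        fit = gz.fit_gaussian_bell(data)
        assert fit.center_deg == pytest.approx(0.0, abs=0.05)

    def test_width_scale_equivariance_on_noiseless_proportions(self, exp2_design):
        angles = np.asarray(exp2_design.directions_deg)
        n = 1000.0
        fits = []
        for w in (2.0, 4.0):
            p = 0.95 * np.exp(-(angles**2) / (2 * w**2))
            data = proportions(angles, n, n * p)  # expected counts, continuous
            fits.append(gz.fit_gaussian_bell(data))
        assert fits[1].width_deg == pytest.approx(2.0 * fits[0].width_deg, rel=0.02)

    def test_flat_proportions_rejected(self, exp2_design):
        angles = np.asarray(exp2_design.directions_deg)
        with pytest.raises(NonIdentifiableError):
            gz.fit_gaussian_bell(proportions(angles, 20, np.full(angles.size, 10.0)))

    def test_one_sided_data_rejected(self):
        with pytest.raises(InsufficientDataError):
            gz.fit_gaussian_bell(proportions([0, 1, 2, 3, 4], 20, [18, 15, 10, 5, 1]))


class TestGridOracle:
    def test_single_point_grid_returns_that_point(self, exp1_design):
        data = simulate_props(3.0, 1.5, exp1_design, seed=0)
        best, ll, surface = gz.grid_fit_oracle(
            data, {"threshold": [3.0], "sigma": [1.5]}, model="cumulative"
        )
        assert best == {"threshold": 3.0, "sigma": 1.5}
        assert surface.shape == (1, 1)
        assert ll == pytest.approx(surface[0, 0])

    def test_empty_grid_rejected(self, exp1_design):
        data = simulate_props(3.0, 1.5, exp1_design, seed=0)
        with pytest.raises(InsufficientDataError):
            gz.grid_fit_oracle(data, {"threshold": [], "sigma": [1.0]})

    def test_surface_unimodal_in_threshold(self, exp1_design):
        data = simulate_props(3.3, 1.0, exp1_design, seed=13)
        grid = {"threshold": np.arange(0.5, 8.0, 0.1), "sigma": np.arange(0.3, 4.0, 0.1)}
        _, _, surface = gz.grid_fit_oracle(data, grid, model="cumulative")
        profile = surface.max(axis=1)  # profile likelihood over threshold
        signs = np.sign(np.diff(profile))
        changes = np.count_nonzero(np.diff(signs[signs != 0]))
        assert changes <= 1  # rises then falls

    def test_loglik_agrees_with_scipy_binom(self):
        from scipy.stats import binom

        k, n, p = np.array([3.0, 7.0]), np.array([10.0, 12.0]), np.array([0.3, 0.6])
        assert binomial_loglik(k, n, p) == pytest.approx(
            binom.logpmf(k, n, p).sum(), abs=1e-10
        )
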