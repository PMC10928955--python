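import math

import numpy as np
import pytest
import scipy.stats

import dynfpca as dp
from dynfpca.simulate import (
    CalibrationError,
    _cumulative_hazard,
    calibrate_censoring,
)

WEIBULL_MEAN = 8.4 * math.gamma(1.0 + 1.0 / 3.0)  # ~7.50 years


class TestSplitFourierBasis:
    def test_single_component_is_normalized_constant(self):
        basis = dp.split_fourier_basis(1, 1, np.linspace(0, 15, 61))
        vals = basis.values[0, 0]
        assert np.allclose(vals, vals[0])
        assert basis.gram_matrix()[0, 0] == pytest.approx(1.0, abs=1e-10)

    def test_multivariate_orthonormality_under_quadrature(self, quarter_grid):
        basis = dp.split_fourier_basis(6, 3, quarter_grid)
        gram = basis.gram_matrix()
        assert np.abs(gram - np.eye(6)).max() < 1e-2

    def test_orthonormality_tightens_with_grid_refinement(self):
        coarse = dp.split_fourier_basis(6, 3, np.linspace(0, 15, 16))
        fine = dp.split_fourier_basis(6, 3, np.linspace(0, 15, 241))
        dev_coarse = np.abs(coarse.gram_matrix() - np.eye(6)).max()
        dev_fine = np.abs(fine.gram_matrix() - np.eye(6)).max()
        assert dev_fine < dev_coarse

    def test_shapes_match_study_design(self, quarter_grid):
        basis = dp.split_fourier_basis(6, 3, quarter_grid)
        assert basis.values.shape == (6, 3, 61)

    def test_rejects_impossible_sizes(self):
        with pytest.raises(ValueError):
            dp.split_fourier_basis(0, 3, np.linspace(0, 15, 61))
        with pytest.raises(ValueError):
            dp.split_fourier_basis(100, 1, np.linspace(0, 15, 5))


class TestSampleScores:
    def test_rejects_nonpositive_variance(self):
        rng = np.random.default_rng(0)
        with pytest.raises(ValueError):
            dp.sample_scores(10, [1.0, 0.0], rng)
        with pytest.raises(ValueError):
            dp.sample_scores(10, [-1.0], rng)

    def test_column_variances_and_independence(self):
        rng = np.random.default_rng(42)
        variances = np.asarray([1, 5 / 6, 2 / 3, 0.5, 1 / 3, 1 / 6])
        scores = dp.sample_scores(100_000, variances, rng)
        emp = scores.var(axis=0, ddof=1)
        assert np.all(np.abs(emp / variances - 1) < 0.02)
        corr = np.corrcoef(scores, rowvar=False)
        off = corr[~np.eye(6, dtype=bool)]
        assert np.abs(off).max() < 0.02


class TestEvaluateMean:
    def test_time_on_study_values(self):
        mu = dp.evaluate_mean("time_on_study", 9.0)
        assert mu[0, 0] == pytest.approx(20.0)
        mu0 = dp.evaluate_mean("time_on_study", 0.0)
        assert mu0[1, 0] == pytest.approx(0.0)

    def test_age_scale_peaks_at_age_73(self):
        peak = dp.evaluate_mean("age_at_observation", 3.0, age=70.0)[0, 0]
        assert peak == pytest.approx(20.0)
        nearby = dp.evaluate_mean("age_at_observation", 3.5, age=70.0)[0, 0]
        assert nearby < peak

    def test_log_domain_guard(self):
        with pytest.raises(ValueError):
            dp.evaluate_mean("age_at_observation", 0.0, age=40.0)
        with pytest.raises(ValueError):
            dp.evaluate_mean("age_at_observation", 1.0)


class TestSimulateLongitudinal:
    def test_zero_noise_returns_underlying_process(self, quarter_grid):
        cfg = dp.SimConfig(n_subjects=20, noise_sd=0.0, seed=1)
        basis = dp.split_fourier_basis(6, 3, quarter_grid)
        rng = np.random.default_rng(1)
        scores = dp.sample_scores(20, cfg.score_variances, rng)
        ages = rng.uniform(40, 90, 20)
        y, x = dp.simulate_longitudinal(cfg, scores, basis, ages, rng)
        assert np.array_equal(y, x)

    def test_zero_scores_give_mean_trajectories(self, quarter_grid):
        cfg = dp.SimConfig(n_subjects=5, noise_sd=0.0, seed=1)
        basis = dp.split_fourier_basis(6, 3, quarter_grid)
        rng = np.random.default_rng(1)
        y, _ = dp.simulate_longitudinal(
            cfg, np.zeros((5, 6)), basis, np.full(5, 60.0), rng
        )
        mu = dp.evaluate_mean("time_on_study", quarter_grid)
        assert np.allclose(y, np.broadcast_to(mu, y.shape))

    def test_observation_noise_variance(self, quarter_grid):
        cfg = dp.SimConfig(n_subjects=400, noise_sd=0.1, seed=3)
        basis = dp.split_fourier_basis(6, 3, quarter_grid)
        rng = np.random.default_rng(3)
        scores = dp.sample_scores(400, cfg.score_variances, rng)
        ages = rng.uniform(40, 90, 400)
        y, x = dp.simulate_longitudinal(cfg, scores, basis, ages, rng)
        noise_var = np.var(y - x)
        assert abs(noise_var / 0.01 - 1) < 0.05


class TestSimulateSurvival:
    def test_null_loadings_give_weibull_mean(self, quarter_grid):
        basis = dp.split_fourier_basis(6, 3, quarter_grid)
        rng = np.random.default_rng(9)
        t = dp.simulate_survival(np.zeros((50_000, 6)), basis, [0, 0, 0], 3.0, 8.4, rng)
        assert t.mean() == pytest.approx(WEIBULL_MEAN, rel=0.02)

    def test_constant_hazard_matches_exponential_law(self, quarter_grid):
        # shape=1 reduces the baseline to a constant hazard 1/scale
        basis = dp.split_fourier_basis(6, 3, quarter_grid)
        rng = np.random.default_rng(10)
        rate = 0.5
        t = dp.simulate_survival(
            np.zeros((10_000, 6)), basis, [0, 0, 0], 1.0, 1.0 / rate, rng, cap=120.0
        )
        ks = scipy.stats.kstest(t, scipy.stats.expon(scale=1.0 / rate).cdf)
        assert ks.statistic < 0.02

    def test_inversion_agrees_with_refined_quadrature(self, quarter_grid):
        basis = dp.split_fourier_basis(6, 3, quarter_grid)
        scores = np.array([[0.9, -0.4, 0.5, -0.2, 0.3, 0.1]])
        alpha = np.array([1.0, -1.0, 2.0])
        rng = np.random.default_rng(11)
        t = dp.simulate_survival(scores, basis, alpha, 3.0, 8.4, rng)
        # oracle: same uniform draw inverted through a 10x finer quadrature
        u = np.random.default_rng(11).uniform(size=1)
        fine = np.arange(0.0, 30.0001, 0.001)
        lam = _cumulative_hazard(scores, basis, alpha, 3.0, 8.4, fine)[0]
        t_oracle = np.interp(-np.log(u[0]), lam, fine)
        assert abs(t[0] - t_oracle) < 1e-3

    def test_hazard_overflow_names_subject(self, quarter_grid):
        basis = dp.split_fourier_basis(6, 3, quarter_grid)
        scores = np.zeros((3, 6))
        scores[1, 0] = 1e4  # absurd trajectory -> exp overflow
        with pytest.raises(FloatingPointError, match="subject"):
            dp.simulate_survival(scores, basis, [50.0, 0, 0], 3.0, 8.4, np.random.default_rng(0))


class TestCalibrateCensoring:
    @staticmethod
    def _weibull_sampler(n, rng):
        return 8.4 * rng.weibull(3.0, size=n)

    def test_achieves_target_on_fresh_replicate(self):
        rng = np.random.default_rng(21)
        rate = calibrate_censoring(0.4, self._weibull_sampler, rng)
        fresh = np.random.default_rng(99)
        t = self._weibull_sampler(10_000, fresh)
        c = fresh.exponential(1.0 / rate, 10_000)
        censored = ~((t <= c) & (t <= 15.0))
        assert abs(censored.mean() - 0.4) < 0.02

    def test_rate_monotone_in_target(self):
        r20 = calibrate_censoring(0.2, self._weibull_sampler, np.random.default_rng(5))
        r40 = calibrate_censoring(0.4, self._weibull_sampler, np.random.default_rng(5))
        assert r40 > r20

    def test_unattainable_target_reports_failure(self):
        with pytest.raises(CalibrationError):
            calibrate_censoring(
                0.2, lambda n, rng: np.full(n, np.inf), np.random.default_rng(0)
            )
        with pytest.raises(ValueError):
            calibrate_censoring(1.5, self._weibull_sampler, np.random.default_rng(0))


class TestSimulateScenario:
    def test_seeded_determinism(self):
        cfg = dp.scenario_config(1, n_subjects=50, seed=123)
        a = dp.simulate_scenario(cfg)
        b = dp.simulate_scenario(dp.scenario_config(1, n_subjects=50, seed=123))
        assert a.dataset.equals(b.dataset)
        assert np.array_equal(a.true_scores, b.true_scores)

    def test_median_censoring_fraction(self, study_median):
        frac = 1.0 - study_median.dataset.baseline["event"].mean()
        assert abs(frac - 0.4) < 0.05  # n=400 draw of the calibrated mechanism

    def test_observed_time_and_indicator_consistency(self, study_median):
        s = study_median
        expected = np.minimum.reduce(
            [s.uncensored_times, s.censor_times, np.full(len(s.censor_times), 15.0)]
        )
        assert np.allclose(s.dataset.time_observed, expected)
        delta = (s.uncensored_times <= np.minimum(s.censor_times, 15.0)).astype(int)
        assert np.array_equal(s.dataset.event, delta)

    def test_truth_oracle_is_a_valid_survival_curve(self, study_median):
        oracle = study_median.oracle
        t = np.arange(9.0, 15.01, 0.5)
        pi = oracle.conditional_survival(t, 9.0)
        assert np.allclose(pi[:, 0], 1.0)  # pi(t_LM | t_LM) = 1
        assert np.all(np.diff(pi, axis=1) <= 1e-12)  # nonincreasing
        lam = oracle.cumhaz
        assert np.all(lam[:, 0] == 0.0)
        assert np.all(np.diff(lam, axis=1) >= 0)
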