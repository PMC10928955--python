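import numpy as np
import pandas as pd
import pytest

import dynfpca as dp
from dynfpca.fpca import (
    CovarianceModel,
    MeanFunction,
    UnivariateFPCA,
    eigendecompose,
    estimate_covariance,
    estimate_mean,
    fit_ufpca,
    pace_scores,
)
from dynfpca.smoothing import PenalizedSpline1D

from conftest import make_dataset


def trapezoid_weights(grid):
    w = np.zeros_like(grid)
    d = np.diff(grid)
    w[:-1] += d / 2
    w[1:] += d / 2
    return w


def exact_model(grid, eigenvalues, eigenfunctions, sigma2=0.0, mean_values=None):
    """UnivariateFPCA built from known components (no estimation error)."""
    mean_values = np.zeros_like(grid) if mean_values is None else mean_values
    spline = PenalizedSpline1D(n_basis=max(4, min(10, len(grid) - 1))).fit(grid, mean_values)
    surface = (eigenfunctions.T * eigenvalues) @ eigenfunctions
    return UnivariateFPCA(
        grid=grid,
        mean=MeanFunction("study", spline),
        eigenvalues=np.asarray(eigenvalues, dtype=float),
        eigenfunctions=np.asarray(eigenfunctions, dtype=float),
        n_components=len(eigenvalues),
        pve_target=1.0,
        sigma2=sigma2,
        surface=surface,
    )


class TestEstimateMean:
    def test_constant_data_recovered(self, quarter_grid):
        vals = np.full((8, len(quarter_grid)), 4.25)
        data = make_dataset({"v": vals}, quarter_grid)
        mean = estimate_mean(data, "v")
        assert np.allclose(mean.evaluate(quarter_grid), 4.25, atol=1e-6)

    def test_known_mean_recovery_dense_noiseless(self, quarter_grid):
        # every subject observes mu1 exactly -> smoother must recover it
        mu = 20.0 - (quarter_grid / 3.0 - 3.0) ** 2
        vals = np.tile(mu, (200, 1))
        data = make_dataset({"v": vals}, quarter_grid)
        mean = estimate_mean(data, "v")
        rmse = np.sqrt(np.mean((mean.evaluate(quarter_grid) - mu) ** 2))
        assert rmse < 0.05

    def test_age_scale_pools_translated_abscissae(self):
        # values equal to age+t: the age-scale mean is the identity line,
        # so a subject aged 60 seen at t=2 pins the fit near 62 at abscissa 62
        grid = np.linspace(0, 4, 9)
        ages = np.array([60.0, 55.0, 70.0, 62.0])
        vals = ages[:, None] + grid[None, :]
        data = make_dataset({"v": vals}, grid, ages=ages)
        mean = estimate_mean(data, "v", time_scale="age")
        assert mean.evaluate(np.array([2.0]), ages=60.0)[0] == pytest.approx(62.0, abs=0.05)
        lo, hi = mean.domain
        assert lo <= 55.0 and hi >= 74.0

    def test_too_few_abscissae_error_names_variable(self):
        grid = np.array([0.0, 1.0, 2.0])
        vals = np.ones((5, 3))
        data = make_dataset({"v": vals}, grid)
        with pytest.raises(ValueError, match="'v'"):
            estimate_mean(data, "v")


class TestEstimateCovariance:
    def test_error_variance_recovered(self, study_median):
        data = study_median.dataset
        mean = estimate_mean(data, "var1")
        cov = estimate_covariance(data, "var1", mean)
        assert abs(cov.sigma2 / 0.01 - 1.0) < 0.5  # true sigma^2 = 0.01

    def test_diagonal_excess_estimates_noise(self, study_median):
        # the raw diagonal mean exceeds the smoothed surface diagonal by sigma^2
        data = study_median.dataset
        mean = estimate_mean(data, "var2")
        cov = estimate_covariance(data, "var2", mean)
        wide = data.wide("var2").to_numpy()
        resid = wide - mean.evaluate(data.grid)
        raw_diag = np.nanmean(resid**2, axis=0)
        inner = slice(len(data.grid) // 4, 3 * len(data.grid) // 4)
        excess = np.mean(raw_diag[inner] - np.diag(cov.surface)[inner])
        assert abs(excess / 0.01 - 1.0) < 0.5

    def test_rank_one_truth_recovered(self):
        grid = np.linspace(0, 15, 31)
        phi = np.cos(grid / 5.0)
        phi = phi / np.sqrt(trapezoid_weights(grid) @ phi**2)
        rng = np.random.default_rng(2)
        xi = rng.normal(0, np.sqrt(2.0), 400)
        vals = xi[:, None] * phi[None, :]
        data = make_dataset({"v": vals}, grid)
        mean = estimate_mean(data, "v")
        cov = estimate_covariance(data, "v", mean, n_basis=8)
        truth = 2.0 * np.outer(phi, phi)
        emp = np.cov(vals, rowvar=False)
        # surface within sampling error of the empirical covariance's truth
        assert np.max(np.abs(cov.surface - truth)) < np.max(np.abs(emp - truth)) + 1e-2

    def test_single_observation_subjects_rejected(self):
        grid = np.linspace(0, 4, 5)
        vals = np.full((4, 5), np.nan)
        vals[:, 0] = 1.0
        data = make_dataset({"v": vals}, grid)
        mean_spline = PenalizedSpline1D(n_basis=4).fit(grid, np.zeros_like(grid))
        with pytest.raises(ValueError):
            estimate_covariance(data, "v", MeanFunction("study", mean_spline))


class TestEigendecompose:
    def test_rank_one_identity(self):
        grid = np.linspace(0, 15, 61)
        w = trapezoid_weights(grid)
        phi = np.sin(grid / 4.0 + 0.3)
        phi = phi / np.sqrt(w @ phi**2)
        cov = CovarianceModel(grid=grid, surface=2.0 * np.outer(phi, phi), sigma2=0.0, meta={})
        u = eigendecompose(cov, 0.95)
        assert u.n_components == 1
        assert u.eigenvalues[0] == pytest.approx(2.0, abs=1e-8)
        align = np.sign(u.eigenfunctions[0] @ (w * phi))
        assert np.allclose(u.eigenfunctions[0], align * phi, atol=1e-6)

    def test_pve_rule_on_decreasing_spectrum(self, quarter_grid):
        # spectrum {1, 5/6, 2/3, 1/2, 1/3, 1/6}: cumulative share hits 0.95 at 5
        basis = dp.split_fourier_basis(6, 1, quarter_grid)
        funcs = basis.values[:, 0, :]
        lam = np.array([1, 5 / 6, 2 / 3, 0.5, 1 / 3, 1 / 6])
        surface = (funcs.T * lam) @ funcs
        cov = CovarianceModel(grid=quarter_grid, surface=surface, sigma2=0.0, meta={})
        assert eigendecompose(cov, 0.95).n_components == 5
        assert eigendecompose(cov, 1.0).n_components == 6

    def test_orthonormality_and_ordering(self, study_median):
        u = fit_ufpca(study_median.dataset, "var1")
        w = trapezoid_weights(u.grid)
        gram = (u.eigenfunctions * w) @ u.eigenfunctions.T
        assert np.abs(gram - np.eye(len(u.eigenvalues))).max() < 1e-8
        assert np.all(np.diff(u.eigenvalues) <= 0)
        assert np.all(u.eigenvalues >= 0)
        assert u.pve[u.n_components - 1] >= u.pve_target

    def test_nonpositive_surface_rejected(self):
        grid = np.linspace(0, 5, 11)
        cov = CovarianceModel(grid=grid, surface=-np.eye(11), sigma2=0.0, meta={})
        with pytest.raises(ValueError):
            eigendecompose(cov, 0.95)


class TestPaceScores:
    def test_matches_quadrature_integral_under_exact_model(self, quarter_grid):
        basis = dp.split_fourier_basis(4, 1, quarter_grid)
        funcs = basis.values[:, 0, :]
        lam = np.array([2.0, 1.0, 0.5, 0.25])
        rng = np.random.default_rng(0)
        xi = rng.standard_normal((50, 4)) * np.sqrt(lam)
        vals = xi @ funcs
        data = make_dataset({"v": vals}, quarter_grid)
        model = exact_model(quarter_grid, lam, funcs, sigma2=0.0)
        scores = pace_scores(data, "v", model).to_numpy()
        quad = vals @ (trapezoid_weights(quarter_grid)[:, None] * funcs.T)
        assert np.abs(scores - quad).max() < 1e-3

    def test_zero_residual_gives_zero_scores(self, quarter_grid):
        mu = np.log(quarter_grid + 1.0)
        basis = dp.split_fourier_basis(3, 1, quarter_grid)
        model = exact_model(
            quarter_grid, np.array([1.0, 0.5, 0.25]), basis.values[:, 0, :],
            sigma2=0.1, mean_values=mu,
        )
        data = make_dataset({"v": np.tile(model.mean.evaluate(quarter_grid), (4, 1))}, quarter_grid)
        scores = pace_scores(data, "v", model).to_numpy()
        assert np.allclose(scores, 0.0, atol=1e-10)

    def test_degenerate_fallback_zeroes_trailing_components(self, quarter_grid):
        basis = dp.split_fourier_basis(3, 1, quarter_grid)
        model = exact_model(
            quarter_grid, np.array([1.0, 0.5, 0.25]), basis.values[:, 0, :], sigma2=0.0
        )
        vals = np.full((2, len(quarter_grid)), np.nan)
        vals[:, 0] = [1.0, -2.0]  # single observation before the landmark
        data = make_dataset({"v": vals}, quarter_grid)
        scores = pace_scores(data, "v", model).to_numpy()
        assert np.all(scores[:, 1:] == 0.0)
        assert np.all(scores[:, 0] != 0.0)

    def test_subject_without_observations_gets_zero_scores(self, quarter_grid):
        basis = dp.split_fourier_basis(2, 1, quarter_grid)
        model = exact_model(quarter_grid, np.array([1.0, 0.5]), basis.values[:, 0, :], sigma2=0.1)
        vals = np.ones((3, len(quarter_grid)))
        vals[1, :] = np.nan
        data = make_dataset({"v": vals}, quarter_grid)
        scores = pace_scores(data, "v", model)
        assert np.all(scores.to_numpy()[1] == 0.0)

    def test_shrinkage_bounds_score_variance(self, study_median):
        data = study_median.dataset
        u = fit_ufpca(data, "var1")
        scores = pace_scores(data, "var1", u).to_numpy()
        emp = scores.var(axis=0, ddof=1)
        assert np.all(emp <= u.eigenvalues[: u.n_components] * (1.0 + 0.05))

    def test_score_recovery_on_low_noise_data(self, study_dense_lownoise):
        # components with variance >= 1/3 must be recovered with |cor| > 0.9
        study = study_dense_lownoise
        data = study.dataset
        models = [fit_ufpca(data, v, pve_target=0.99) for v in data.variables]
        stacked = np.hstack(
            [pace_scores(data, v, u).to_numpy() for v, u in zip(data.variables, models)]
        )
        model, rho = dp.combine_univariate(data.variables, models, pd.DataFrame(stacked))
        rho = rho.to_numpy()
        true = study.true_scores
        for m in range(5):  # nu_m >= 1/3 for the first five components
            best = max(
                abs(np.corrcoef(rho[:, j], true[:, m])[0, 1]) for j in range(rho.shape[1])
            )
            assert best > 0.9, f"component {m + 1} recovered with |cor| {best:.3f}"
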