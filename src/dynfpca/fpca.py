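"""Univariate functional principal component analysis for sparse data.

Per longitudinal variable: a penalized-spline smooth of the mean (on the
study-time or the age-at-observation scale), a tensor-product smooth of the
covariance surface fitted to pooled cross products with the diagonal excluded
(the raw diagonal is biased upward by the observation-error variance, which is
instead recovered from the diagonal excess), a quadrature-weighted
eigendecomposition with proportion-of-variance-explained truncation, and
best-linear-prediction ("PACE") scoring of individual subjects — including
the degenerate fallback needed when strict landmarking leaves too little data
to invert a subject's covariance block.
"""

from __future__ import annotations

import logging
from dataclasses import dataclass

import numpy as np
import pandas as pd
import scipy.linalg

from .dataset import LongitudinalDataset
from .smoothing import PenalizedSpline1D, TensorProductSmoother

logger = logging.getLogger(__name__)

__all__ = [
    "MeanFunction",
    "CovarianceModel",
    "UnivariateFPCA",
    "estimate_mean",
    "estimate_covariance",
    "eigendecompose",
    "pace_scores",
    "fit_ufpca",
]

#: minimum usable B-spline basis dimension (cubic)
_MIN_BASIS = 4


@dataclass
class MeanFunction:
    """Smooth mean of one longitudinal variable on a chosen time scale."""

    time_scale: str  # "study" or "age"
    spline: PenalizedSpline1D

    def evaluate(self, times, ages=None) -> np.ndarray:
        """Mean values at study times ``times``.

        On the age scale the abscissa is ``age + t`` per subject: ``ages`` may
        be a scalar (one subject) or an array broadcast against ``times``.
        """
        times = np.asarray(times, dtype=float)
        if self.time_scale == "age":
            if ages is None:
                raise ValueError("age-scale mean requires baseline ages")
            return self.spline(np.asarray(ages, dtype=float) + times)
        return self.spline(times)

    @property
    def domain(self) -> tuple[float, float]:
        return self.spline.domain

    def to_dict(self) -> dict:
        return {"time_scale": self.time_scale, "spline": self.spline.to_dict()}

    @classmethod
    def from_dict(cls, d: dict) -> "MeanFunction":
        return cls(time_scale=d["time_scale"], spline=PenalizedSpline1D.from_dict(d["spline"]))


@dataclass
class CovarianceModel:
    """Smoothed covariance surface on the planned grid plus error variance."""

    grid: np.ndarray
    surface: np.ndarray  # symmetric, (G, G)
    sigma2: float
    meta: dict

    def __post_init__(self) -> None:
        asym = np.max(np.abs(self.surface - self.surface.T))
        if asym > 1e-10:
            raise ValueError(f"covariance surface not symmetric (max dev {asym:.2e})")
        if self.sigma2 < 0:
            raise ValueError("error variance must be nonnegative")


@dataclass
class UnivariateFPCA:
    """Eigenstructure of one longitudinal variable."""

    grid: np.ndarray
    mean: MeanFunction
    eigenvalues: np.ndarray  # all positive eigenvalues, nonincreasing
    eigenfunctions: np.ndarray  # (len(eigenvalues), G), quadrature-orthonormal
    n_components: int  # retained count M_q (PVE rule)
    pve_target: float
    sigma2: float
    surface: np.ndarray  # smoothed covariance surface, used by PACE

    @property
    def pve(self) -> np.ndarray:
        return np.cumsum(self.eigenvalues) / self.eigenvalues.sum()

    def to_dict(self) -> dict:
        return {
            "grid": self.grid.tolist(),
            "mean": self.mean.to_dict(),
            "eigenvalues": self.eigenvalues.tolist(),
            "eigenfunctions": self.eigenfunctions.tolist(),
            "n_components": self.n_components,
            "pve_target": self.pve_target,
            "sigma2": self.sigma2,
            "surface": self.surface.tolist(),
        }

    @classmethod
    def from_dict(cls, d: dict) -> "UnivariateFPCA":
        return cls(
            grid=np.asarray(d["grid"], dtype=float),
            mean=MeanFunction.from_dict(d["mean"]),
            eigenvalues=np.asarray(d["eigenvalues"], dtype=float),
            eigenfunctions=np.asarray(d["eigenfunctions"], dtype=float),
            n_components=d["n_components"],
            pve_target=d["pve_target"],
            sigma2=d["sigma2"],
            surface=np.asarray(d["surface"], dtype=float),
        )


def _pooled_points(
    data: LongitudinalDataset, variable: str, time_scale: str
) -> tuple[np.ndarray, np.ndarray]:
    sub = data.long[(data.long["variable"] == variable) & np.isfinite(data.long["value"])]
    if not len(sub):
        raise ValueError(f"no non-missing observations for variable {variable!r}")
    x = sub["time"].to_numpy(dtype=float)
    if time_scale == "age":
        ages = data.baseline["age"]
        x = x + ages.loc[sub["subject_id"]].to_numpy(dtype=float)
    elif time_scale != "study":
        raise ValueError(f"unknown time scale {time_scale!r}")
    return x, sub["value"].to_numpy(dtype=float)


def estimate_mean(
    data: LongitudinalDataset,
    variable: str,
    time_scale: str = "study",
    n_basis: int | None = None,
) -> MeanFunction:
    """Penalized-spline mean of the pooled observations of one variable.

    Study scale pools (t_ij, Y_ij); age scale pools the translated points
    (a_i + t_ij, Y_ij).  The basis dimension shrinks automatically when the
    pooled support is short (as under strict landmarking); the smoothing
    parameter is chosen by GCV.
    """
    x, y = _pooled_points(data, variable, time_scale)
    n_distinct = np.unique(x).size
    if n_basis is None:
        n_basis = min(10, n_distinct - 1)
    if n_basis < _MIN_BASIS:
        raise ValueError(
            f"variable {variable!r}: {n_distinct} distinct pooled abscissae support "
            f"at most {n_distinct - 1} basis functions (minimum {_MIN_BASIS})"
        )
    spline = PenalizedSpline1D(n_basis=n_basis).fit(x, y)
    return MeanFunction(time_scale=time_scale, spline=spline)


def estimate_covariance(
    data: LongitudinalDataset,
    variable: str,
    mean: MeanFunction,
    n_basis: int | None = None,
) -> CovarianceModel:
    """Tensor-product smooth of pooled raw covariances, diagonal excluded.

    Raw cross products of mean-centred residuals are accumulated per ordered
    grid-cell pair; the surface smoother is fitted to the off-diagonal cell
    means (weighted by their counts) because the raw diagonal is inflated by
    the observation-error variance sigma^2.  sigma^2 itself is estimated as
    the average positive excess of a 1-d smooth of the raw diagonal over the
    surface diagonal on the central half of the domain, clamped at zero.
    """
    grid = data.grid
    g = len(grid)
    wide = data.wide(variable).to_numpy(dtype=float)
    mask = np.isfinite(wide)
    if not (mask.sum(axis=1) >= 2).any():
        raise ValueError(f"variable {variable!r}: no subject has two or more observations")
    ages = data.baseline["age"].to_numpy(dtype=float)
    if mean.time_scale == "age":
        mu = np.stack([mean.evaluate(grid, ages=a) for a in ages])
    else:
        mu = np.broadcast_to(mean.evaluate(grid), wide.shape)
    resid = np.where(mask, wide - mu, 0.0)
    cross = resid.T @ resid  # (G, G) sums of raw products
    counts = mask.astype(float).T @ mask.astype(float)
    with np.errstate(invalid="ignore"):
        raw = np.where(counts > 0, cross / np.maximum(counts, 1.0), np.nan)

    off = ~np.eye(g, dtype=bool) & (counts > 0)
    ss, tt = np.meshgrid(grid, grid, indexing="ij")
    if n_basis is None:
        n_basis = min(5, g - 1)
    if n_basis < _MIN_BASIS:
        raise ValueError(f"variable {variable!r}: too few grid points for surface smoothing")
    smoother = TensorProductSmoother(n_basis=n_basis).fit(
        ss[off], tt[off], raw[off], weights=counts[off]
    )
    surface = smoother.predict_grid(grid)
    surface = 0.5 * (surface + surface.T)

    # observation-error variance from the diagonal excess
    diag_ok = np.diag(counts) > 0
    sigma2 = 0.0
    if diag_ok.sum() >= _MIN_BASIS + 1:
        diag_smooth = PenalizedSpline1D(n_basis=min(8, int(diag_ok.sum()) - 1)).fit(
            grid[diag_ok], np.diag(raw)[diag_ok], weights=np.diag(counts)[diag_ok]
        )
        lo, hi = grid[0], grid[-1]
        window = (grid >= lo + 0.25 * (hi - lo)) & (grid <= hi - 0.25 * (hi - lo))
        if window.any():
            excess = diag_smooth(grid[window]) - np.diag(surface)[window]
            sigma2 = max(float(np.mean(excess)), 0.0)
    return CovarianceModel(
        grid=grid,
        surface=surface,
        sigma2=sigma2,
        meta={"n_basis": n_basis, "lambda": smoother.lambda_, "edf": smoother.edf_},
    )


def _trapezoid_weights(grid: np.ndarray) -> np.ndarray:
    w = np.zeros_like(grid)
    d = np.diff(grid)
    w[:-1] += d / 2
    w[1:] += d / 2
    return w


def _fix_signs(funcs: np.ndarray) -> np.ndarray:
    """Flip each row so its entry of largest magnitude is positive."""
    out = funcs.copy()
    for m in range(out.shape[0]):
        peak = out[m, np.argmax(np.abs(out[m]))]
        if peak < 0:
            out[m] = -out[m]
    return out


def eigendecompose(
    cov: CovarianceModel, pve_target: float, mean: MeanFunction | None = None
) -> UnivariateFPCA:
    """Quadrature-weighted eigendecomposition of the covariance surface.

    Solves the integral eigenproblem with trapezoid weights, discards
    nonpositive eigenvalues, orients each eigenfunction so that its entry of
    largest magnitude is positive, and retains the smallest number of leading
    components whose cumulative eigenvalue share reaches ``pve_target``.
    """
    if not 0 < pve_target <= 1:
        raise ValueError("pve_target must lie in (0, 1]")
    grid = cov.grid
    w = _trapezoid_weights(grid)
    sqrt_w = np.sqrt(w)
    a = sqrt_w[:, None] * cov.surface * sqrt_w[None, :]
    evals, evecs = np.linalg.eigh(0.5 * (a + a.T))
    order = np.argsort(evals)[::-1]
    evals, evecs = evals[order], evecs[:, order]
    pos = evals > max(1e-12 * max(evals.max(), 0.0), 0.0)
    if not pos.any():
        raise ValueError("covariance surface has no positive eigenvalue")
    evals = evals[pos]
    funcs = (evecs[:, pos] / sqrt_w[:, None]).T  # rows quadrature-orthonormal
    funcs = _fix_signs(funcs)
    ratio = np.cumsum(evals) / evals.sum()
    m_q = int(np.searchsorted(ratio, pve_target - 1e-12) + 1)
    m_q = min(m_q, len(evals))
    return UnivariateFPCA(
        grid=grid,
        mean=mean,
        eigenvalues=evals,
        eigenfunctions=funcs,
        n_components=m_q,
        pve_target=pve_target,
        sigma2=cov.sigma2,
        surface=cov.surface,
    )


def pace_scores(
    data: LongitudinalDataset, variable: str, ufpca: UnivariateFPCA
) -> pd.DataFrame:
    """Best-linear-prediction scores for every subject (PACE).

    For subject i with observations at grid indices J:
    ``xi_m = lambda_m phi_m[J]^T (C[J, J] + sigma^2 I)^{-1} (Y_i[J] - mu[J])``.
    When the restricted system is singular (typically sigma^2 = 0 with fewer
    observations than retained components, a strict-landmark situation) the
    maximal solvable number of leading components — the number of observations
    — is computed from the rank-truncated surface and the remaining components
    are set to exactly zero.  Subjects without any observation get all-zero
    scores with a logged warning.
    """
    m_q = ufpca.n_components
    grid = ufpca.grid
    gidx = pd.Index(grid)
    wide = data.wide(variable)
    # the model grid may be shorter than the data grid (landmarked model)
    cols = gidx.intersection(pd.Index(wide.columns))
    wide = wide[cols.to_numpy()]
    model_cols = gidx.get_indexer(cols)
    vals = wide.to_numpy(dtype=float)
    mask = np.isfinite(vals)
    ages = data.baseline["age"].to_numpy(dtype=float)

    lam = ufpca.eigenvalues[:m_q]
    phi = ufpca.eigenfunctions[:m_q]
    scores = np.zeros((len(vals), m_q))
    # subjects sharing an observation pattern share one factorization
    patterns: dict[tuple, np.ndarray] = {}
    for key in {tuple(row) for row in mask}:
        patterns[key] = np.where(
            (mask == np.asarray(key, dtype=bool)).all(axis=1)
        )[0]
    for key, rows in patterns.items():
        obs = np.asarray(key, dtype=bool)
        if not obs.any():
            logger.warning(
                "variable %r: %d subject(s) without observations; scores set to 0",
                variable,
                rows.size,
            )
            continue
        j = model_cols[obs]
        t_obs = grid[j]
        resid = np.empty((rows.size, obs.sum()))
        for r, i in enumerate(rows):
            mu = ufpca.mean.evaluate(t_obs, ages=ages[i]) \
                if ufpca.mean.time_scale == "age" else ufpca.mean.evaluate(t_obs)
            resid[r] = vals[i, obs] - mu
        scores[rows] = _pace_block(resid, j, lam, phi, ufpca.surface, ufpca.sigma2)
    return pd.DataFrame(
        scores, index=data.baseline.index, columns=[f"{variable}_pc{m + 1}" for m in range(m_q)]
    )


def _pace_block(
    resid: np.ndarray,
    j: np.ndarray,
    lam: np.ndarray,
    phi: np.ndarray,
    surface: np.ndarray,
    sigma2: float,
) -> np.ndarray:
    """PACE scores for a block of subjects sharing observation indices j."""
    m_q = len(lam)
    n_obs = j.size
    phi_obs = phi[:, j]
    if sigma2 > 0 or n_obs >= m_q:
        sigma_y = surface[np.ix_(j, j)] + sigma2 * np.eye(n_obs)
        try:
            cho = scipy.linalg.cho_factor(sigma_y)
            x = scipy.linalg.cho_solve(cho, resid.T)  # (n_obs, n_subj)
            return (lam[:, None] * (phi_obs @ x)).T
        except scipy.linalg.LinAlgError:
            logger.warning("singular observation covariance; using rank-truncated fallback")
    # degenerate fallback: leading k = min(n_obs, M_q) components, rest zero
    k = min(n_obs, m_q)
    sigma_k = (phi_obs[:k].T * lam[:k]) @ phi_obs[:k] + sigma2 * np.eye(n_obs)
    x = np.linalg.pinv(sigma_k) @ resid.T
    out = np.zeros((resid.shape[0], m_q))
    out[:, :k] = (lam[:k, None] * (phi_obs[:k] @ x)).T
    return out


def fit_ufpca(
    data: LongitudinalDataset,
    variable: str,
    time_scale: str = "study",
    pve_target: float = 0.95,
    mean_basis: int | None = None,
    cov_basis: int | None = None,
) -> UnivariateFPCA:
    """Full univariate pipeline: mean, covariance, eigendecomposition."""
    mean = estimate_mean(data, variable, time_scale=time_scale, n_basis=mean_basis)
    cov = estimate_covariance(data, variable, mean, n_basis=cov_basis)
    return eigendecompose(cov, pve_target, mean=mean)
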