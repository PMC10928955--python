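"""Multivariate FPCA via the univariate-to-multivariate correspondence.

Q univariate decompositions are combined into a single multivariate one by
eigendecomposing the empirical covariance of the stacked univariate scores:
the eigenvectors c_m act as correspondence vectors mapping stacked univariate
scores to multivariate scores rho_im, and the multivariate eigenfunction
blocks are psi_m^(q) = sum_j [c_m]_j^(q) phi_j^(q).  Training scores are
empirically uncorrelated with variances equal to the multivariate eigenvalues,
and the total variance (trace) of the stacked scores is preserved.
"""

from __future__ import annotations

from dataclasses import dataclass

import numpy as np
import pandas as pd

from .dataset import LongitudinalDataset
from .fpca import UnivariateFPCA, _fix_signs, pace_scores

__all__ = [
    "MultivariateFPCA",
    "combine_univariate",
    "score_new_subjects",
    "reconstruct_trajectories",
    "fit_mfpca",
]


@dataclass
class MultivariateFPCA:
    """Combined decomposition of Q longitudinal variables."""

    variables: list[str]
    univariate: list[UnivariateFPCA]
    correspondence: np.ndarray  # (sum_q M_q, M), orthonormal columns
    eigenvalues: np.ndarray  # (M,), nonincreasing, >= 0
    eigenfunctions: np.ndarray  # (M, Q, G) blocks psi_m^(q) on the grid

    @property
    def n_components(self) -> int:
        return self.correspondence.shape[1]

    @property
    def grid(self) -> np.ndarray:
        return self.univariate[0].grid

    @property
    def block_sizes(self) -> list[int]:
        return [u.n_components for u in self.univariate]

    def to_dict(self) -> dict:
        return {
            "variables": self.variables,
            "univariate": [u.to_dict() for u in self.univariate],
            "correspondence": self.correspondence.tolist(),
            "eigenvalues": self.eigenvalues.tolist(),
            "eigenfunctions": self.eigenfunctions.tolist(),
        }

    @classmethod
    def from_dict(cls, d: dict) -> "MultivariateFPCA":
        return cls(
            variables=list(d["variables"]),
            univariate=[UnivariateFPCA.from_dict(u) for u in d["univariate"]],
            correspondence=np.asarray(d["correspondence"], dtype=float),
            eigenvalues=np.asarray(d["eigenvalues"], dtype=float),
            eigenfunctions=np.asarray(d["eigenfunctions"], dtype=float),
        )


def _stack_scores(
    data: LongitudinalDataset, variables: list[str], models: list[UnivariateFPCA]
) -> pd.DataFrame:
    frames = [pace_scores(data, v, u) for v, u in zip(variables, models)]
    return pd.concat(frames, axis=1)


def combine_univariate(
    variables: list[str],
    univariate: list[UnivariateFPCA],
    training_scores: pd.DataFrame,
) -> tuple[MultivariateFPCA, pd.DataFrame]:
    """Build the multivariate decomposition from stacked univariate scores.

    ``training_scores`` holds the stacked n x sum_q M_q univariate score
    matrix of the training subjects (degenerate-fallback zeros allowed).  The
    number of multivariate components is sum_q M_q.
    """
    if len(training_scores) < 2:
        raise ValueError("at least two training subjects are required")
    grids = [u.grid for u in univariate]
    if any(not np.array_equal(g, grids[0]) for g in grids[1:]):
        raise ValueError("all univariate models must share the same grid")
    xi = training_scores.to_numpy(dtype=float)
    z = np.cov(xi, rowvar=False, ddof=1)
    z = np.atleast_2d(z)
    evals, evecs = np.linalg.eigh(z)
    order = np.argsort(evals)[::-1]
    evals = np.clip(evals[order], 0.0, None)
    c = evecs[:, order]

    # eigenfunction blocks psi_m^(q) = sum_j [c_m]_j^(q) phi_j^(q)
    g = len(grids[0])
    n_vars = len(univariate)
    m_total = c.shape[1]
    psi = np.zeros((m_total, n_vars, g))
    offset = 0
    for q, u in enumerate(univariate):
        m_q = u.n_components
        block = c[offset : offset + m_q, :]  # (M_q, M)
        psi[:, q, :] = block.T @ u.eigenfunctions[:m_q]
        offset += m_q

    # orient each component by its stacked eigenfunction values
    flat = psi.reshape(m_total, -1)
    flipped = _fix_signs(flat)
    signs = np.where((flipped == flat).all(axis=1), 1.0, -1.0)
    psi = flipped.reshape(psi.shape)
    c = c * signs[None, :]

    model = MultivariateFPCA(
        variables=list(variables),
        univariate=list(univariate),
        correspondence=c,
        eigenvalues=evals,
        eigenfunctions=psi,
    )
    rho = pd.DataFrame(
        xi @ c,
        index=training_scores.index,
        columns=[f"mpc{m + 1}" for m in range(m_total)],
    )
    return model, rho


def fit_mfpca(
    data: LongitudinalDataset,
    time_scale: str = "study",
    pve_target: float = 0.95,
    mean_basis: int | None = None,
    cov_basis: int | None = None,
) -> tuple[MultivariateFPCA, pd.DataFrame]:
    """Fit Q univariate models on training data and combine them."""
    from .fpca import fit_ufpca

    models = [
        fit_ufpca(
            data,
            v,
            time_scale=time_scale,
            pve_target=pve_target,
            mean_basis=mean_basis,
            cov_basis=cov_basis,
        )
        for v in data.variables
    ]
    stacked = _stack_scores(data, data.variables, models)
    return combine_univariate(data.variables, models, stacked)


def score_new_subjects(data: LongitudinalDataset, model: MultivariateFPCA) -> pd.DataFrame:
    """Multivariate scores of unseen subjects under a frozen training model.

    Univariate PACE scores are computed with the training mean, surface and
    error variance, then projected through the correspondence vectors.
    """
    for v in model.variables:
        sub = data.long[(data.long["variable"] == v) & np.isfinite(data.long["value"])]
        if not len(sub):
            raise ValueError(f"variable {v!r} has no observations in the data to score")
    stacked = _stack_scores(data, model.variables, model.univariate)
    rho = stacked.to_numpy(dtype=float) @ model.correspondence
    return pd.DataFrame(
        rho, index=stacked.index, columns=[f"mpc{m + 1}" for m in range(model.n_components)]
    )


def reconstruct_trajectories(
    scores: pd.DataFrame,
    model: MultivariateFPCA,
    ages=None,
    n_components: int | None = None,
) -> np.ndarray:
    """Fitted trajectories on the grid, shape (n, Q, G).

    Truncates the expansion at ``n_components`` (all by default).  Age-scale
    models require the subjects' baseline ages for the mean term.
    """
    m = model.n_components if n_components is None else n_components
    if not 1 <= m <= model.n_components:
        raise ValueError("n_components out of range")
    rho = scores.to_numpy(dtype=float)[:, :m]
    psi = model.eigenfunctions[:m]  # (m, Q, G)
    fitted = np.einsum("im,mqg->iqg", rho, psi)
    grid = model.grid
    age_scale = any(u.mean.time_scale == "age" for u in model.univariate)
    if age_scale and ages is None:
        raise ValueError("age-scale model requires baseline ages for reconstruction")
    ages_arr = None if ages is None else np.asarray(ages, dtype=float)
    for q, u in enumerate(model.univariate):
        if u.mean.time_scale == "age":
            for i in range(fitted.shape[0]):
                fitted[i, q] += u.mean.evaluate(grid, ages=ages_arr[i])
        else:
            fitted[:, q] += u.mean.evaluate(grid)[None, :]
    return fitted
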