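"""Low-rank penalized regression spline smoothers (P-splines).

Both the mean function and the covariance surface of the longitudinal
processes are estimated by penalized least squares on a B-spline basis with a
second-order difference penalty (Eilers & Marx style), the smoothing parameter
chosen by generalized cross-validation (GCV).  The 2-D smoother is a tensor
product of two marginal bases with an isotropic difference penalty.
"""

from __future__ import annotations

from dataclasses import dataclass, field

import numpy as np
from scipy.interpolate import BSpline

__all__ = ["PenalizedSpline1D", "TensorProductSmoother"]

#: default grid of candidate smoothing parameters (log-spaced)
LAMBDA_GRID = np.logspace(-6.0, 8.0, 29)


def _knot_vector(lo: float, hi: float, n_basis: int, degree: int) -> np.ndarray:
    """Clamped, equally spaced knot vector yielding ``n_basis`` B-splines."""
    if n_basis < degree + 1:
        raise ValueError(f"n_basis must be at least degree+1={degree + 1}, got {n_basis}")
    if not hi > lo:
        raise ValueError("domain must have positive length")
    inner = np.linspace(lo, hi, n_basis - degree + 1)[1:-1]
    return np.concatenate([np.full(degree + 1, lo), inner, np.full(degree + 1, hi)])


def _design(x: np.ndarray, knots: np.ndarray, degree: int) -> np.ndarray:
    # values outside the fitted domain are clamped to the boundary
    x = np.clip(x, knots[0], knots[-1])
    return BSpline.design_matrix(x, knots, degree).toarray()


def _difference_penalty(n_basis: int, order: int = 2) -> np.ndarray:
    d = np.diff(np.eye(n_basis), n=order, axis=0)
    return d.T @ d


def _gcv_fit(
    design: np.ndarray,
    y: np.ndarray,
    weights: np.ndarray,
    penalty: np.ndarray,
    lambdas: np.ndarray,
) -> tuple[np.ndarray, float, float, float]:
    """Solve the penalized WLS problem for each lambda; keep the GCV minimizer.

    Returns (coefficients, lambda, edf, gcv).
    """
    w = weights
    bw = design * w[:, None]
    btb = bw.T @ design
    bty = bw.T @ y
    n_eff = float(w.sum())
    best = None
    for lam in lambdas:
        a = btb + lam * penalty
        try:
            coef = np.linalg.solve(a, bty)
            edf = float(np.trace(np.linalg.solve(a, btb)))
        except np.linalg.LinAlgError:  # pragma: no cover - singular for tiny lambda
            continue
        resid = y - design @ coef
        rss = float(w @ resid**2)
        denom = max(n_eff - edf, 1e-8)
        gcv = n_eff * rss / denom**2
        if best is None or gcv < best[3]:
            best = (coef, float(lam), edf, gcv)
    if best is None:
        raise np.linalg.LinAlgError("penalized least squares failed for every lambda")
    return best


@dataclass
class PenalizedSpline1D:
    """Univariate P-spline smoother with GCV-selected smoothing parameter.

    Parameters
    ----------
    n_basis:
        Number of B-spline basis functions (cubic by default).
    degree:
        Spline degree.
    lambdas:
        Candidate smoothing parameters searched by GCV.
    """

    n_basis: int = 10
    degree: int = 3
    lambdas: np.ndarray = field(default_factory=lambda: LAMBDA_GRID.copy())

    knots_: np.ndarray | None = None
    coef_: np.ndarray | None = None
    lambda_: float | None = None
    edf_: float | None = None
    gcv_: float | None = None

    def fit(self, x, y, weights=None) -> "PenalizedSpline1D":
        x = np.asarray(x, dtype=float)
        y = np.asarray(y, dtype=float)
        if x.size != y.size or x.size == 0:
            raise ValueError("x and y must be nonempty and of equal length")
        w = np.ones_like(y) if weights is None else np.asarray(weights, dtype=float)
        self.knots_ = _knot_vector(float(x.min()), float(x.max()), self.n_basis, self.degree)
        design = _design(x, self.knots_, self.degree)
        penalty = _difference_penalty(self.n_basis)
        self.coef_, self.lambda_, self.edf_, self.gcv_ = _gcv_fit(
            design, y, w, penalty, self.lambdas
        )
        return self

    def predict(self, x) -> np.ndarray:
        if self.coef_ is None:
            raise RuntimeError("smoother is not fitted")
        x = np.atleast_1d(np.asarray(x, dtype=float))
        return _design(x, self.knots_, self.degree) @ self.coef_

    def __call__(self, x) -> np.ndarray:
        return self.predict(x)

    @property
    def domain(self) -> tuple[float, float]:
        return float(self.knots_[0]), float(self.knots_[-1])

    def to_dict(self) -> dict:
        return {
            "n_basis": self.n_basis,
            "degree": self.degree,
            "knots": self.knots_.tolist(),
            "coef": self.coef_.tolist(),
            "lambda": self.lambda_,
            "edf": self.edf_,
            "gcv": self.gcv_,
        }

    @classmethod
    def from_dict(cls, d: dict) -> "PenalizedSpline1D":
        obj = cls(n_basis=d["n_basis"], degree=d["degree"])
        obj.knots_ = np.asarray(d["knots"], dtype=float)
        obj.coef_ = np.asarray(d["coef"], dtype=float)
        obj.lambda_ = d["lambda"]
        obj.edf_ = d["edf"]
        obj.gcv_ = d["gcv"]
        return obj


@dataclass
class TensorProductSmoother:
    """Bivariate tensor-product P-spline smoother for scattered surface data.

    Used for the covariance surface: the marginal bases live on the planned
    visit grid and a single smoothing parameter multiplies the sum of the
    row- and column-direction difference penalties.
    """

    n_basis: int = 8
    degree: int = 3
    lambdas: np.ndarray = field(default_factory=lambda: LAMBDA_GRID.copy())

    knots_: np.ndarray | None = None
    coef_: np.ndarray | None = None  # (n_basis, n_basis)
    lambda_: float | None = None
    edf_: float | None = None
    gcv_: float | None = None

    def fit(self, s, t, y, weights=None) -> "TensorProductSmoother":
        s = np.asarray(s, dtype=float)
        t = np.asarray(t, dtype=float)
        y = np.asarray(y, dtype=float)
        if not (s.size == t.size == y.size) or y.size == 0:
            raise ValueError("s, t and y must be nonempty and of equal length")
        w = np.ones_like(y) if weights is None else np.asarray(weights, dtype=float)
        lo = float(min(s.min(), t.min()))
        hi = float(max(s.max(), t.max()))
        self.knots_ = _knot_vector(lo, hi, self.n_basis, self.degree)
        bs = _design(s, self.knots_, self.degree)
        bt = _design(t, self.knots_, self.degree)
        design = (bs[:, :, None] * bt[:, None, :]).reshape(y.size, -1)
        p1 = _difference_penalty(self.n_basis)
        eye = np.eye(self.n_basis)
        penalty = np.kron(p1, eye) + np.kron(eye, p1)
        coef, self.lambda_, self.edf_, self.gcv_ = _gcv_fit(design, y, w, penalty, self.lambdas)
        self.coef_ = coef.reshape(self.n_basis, self.n_basis)
        return self

    def predict_grid(self, grid) -> np.ndarray:
        """Evaluate the fitted surface on ``grid x grid``."""
        if self.coef_ is None:
            raise RuntimeError("smoother is not fitted")
        b = _design(np.asarray(grid, dtype=float), self.knots_, self.degree)
        return b @ self.coef_ @ b.T

    def to_dict(self) -> dict:
        return {
            "n_basis": self.n_basis,
            "degree": self.degree,
            "knots": self.knots_.tolist(),
            "coef": self.coef_.tolist(),
            "lambda": self.lambda_,
            "edf": self.edf_,
            "gcv": self.gcv_,
        }

    @classmethod
    def from_dict(cls, d: dict) -> "TensorProductSmoother":
        obj = cls(n_basis=d["n_basis"], degree=d["degree"])
        obj.knots_ = np.asarray(d["knots"], dtype=float)
        obj.coef_ = np.asarray(d["coef"], dtype=float)
        obj.lambda_ = d["lambda"]
        obj.edf_ = d["edf"]
        obj.gcv_ = d["gcv"]
        return obj
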