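"""Cox proportional-hazards dynamic prediction on baseline covariates + scores.

The hazard model is ``h(t | Z_i, rho_i) = h0(t) exp(beta' Z_i + gamma' rho_i)``
with the baseline covariates Z and multivariate FPCA scores rho.  Coefficients
are estimated by Efron's partial likelihood (unpenalized) or by an L1 path
penalizing only the score coefficients gamma (the baseline covariates stay
unpenalized), with the penalty strength chosen by inner cross-validated
partial-likelihood deviance.  The cumulative baseline hazard is the Breslow
estimator, and conditional survival predictions use

    pi_i(t | t_LM) = (S0(t) / S0(t_LM)) ** exp(beta' Z_i + gamma' rho_i)

which equals 1 at the landmark time by construction.  On a strictly
landmarked training set no event precedes t_LM, so S0(t_LM) = 1.
"""

from __future__ import annotations

import logging
from dataclasses import dataclass

import numpy as np
import pandas as pd
from lifelines import CoxPHFitter

logger = logging.getLogger(__name__)

__all__ = [
    "DynamicCoxModel",
    "PredictionResult",
    "fit_cox",
    "baseline_survival",
    "predict_survival",
]


@dataclass
class DynamicCoxModel:
    """Fitted dynamic Cox model with Breslow baseline hazard."""

    beta: pd.Series  # baseline-covariate coefficients (may be empty)
    gamma: pd.Series  # score coefficients
    baseline_times: np.ndarray  # event times of the Breslow step function
    baseline_cumhaz: np.ndarray  # cumulative baseline hazard at those times
    landmark_time: float
    penalty: dict

    def linear_predictor(self, covariates: pd.DataFrame | None, scores: pd.DataFrame) -> np.ndarray:
        lp = np.zeros(len(scores))
        if len(self.beta):
            if covariates is None:
                raise ValueError("model has baseline covariates but none were supplied")
            lp += covariates[self.beta.index].to_numpy(dtype=float) @ self.beta.to_numpy()
        if len(self.gamma):
            if list(scores.columns) != list(self.gamma.index):
                raise ValueError(
                    f"score columns {list(scores.columns)} do not match model "
                    f"coefficients {list(self.gamma.index)}"
                )
            lp += scores.to_numpy(dtype=float) @ self.gamma.to_numpy()
        return lp

    def cumulative_hazard(self, t) -> np.ndarray:
        """Right-continuous Breslow cumulative baseline hazard H0(t)."""
        t = np.atleast_1d(np.asarray(t, dtype=float))
        if np.any(t < 0):
            raise ValueError("time must be nonnegative")
        idx = np.searchsorted(self.baseline_times, t, side="right")
        padded = np.concatenate([[0.0], self.baseline_cumhaz])
        return padded[idx]

    def to_dict(self) -> dict:
        return {
            "beta": {str(k): float(v) for k, v in self.beta.items()},
            "gamma": {str(k): float(v) for k, v in self.gamma.items()},
            "baseline_times": self.baseline_times.tolist(),
            "baseline_cumhaz": self.baseline_cumhaz.tolist(),
            "landmark_time": self.landmark_time,
            "penalty": self.penalty,
        }

    @classmethod
    def from_dict(cls, d: dict) -> "DynamicCoxModel":
        return cls(
            beta=pd.Series(d["beta"], dtype=float),
            gamma=pd.Series(d["gamma"], dtype=float),
            baseline_times=np.asarray(d["baseline_times"], dtype=float),
            baseline_cumhaz=np.asarray(d["baseline_cumhaz"], dtype=float),
            landmark_time=float(d["landmark_time"]),
            penalty=dict(d["penalty"]),
        )


@dataclass
class PredictionResult:
    """Conditional survival probabilities pi_i(t | t_LM) on a horizon grid."""

    subject_ids: np.ndarray
    landmark_time: float
    times: np.ndarray
    probabilities: np.ndarray  # (n, len(times)), rows nonincreasing in t

    def to_frame(self) -> pd.DataFrame:
        return pd.DataFrame(
            self.probabilities,
            index=pd.Index(self.subject_ids, name="subject_id"),
            columns=self.times,
        )


def _breslow(
    time: np.ndarray, event: np.ndarray, lp: np.ndarray
) -> tuple[np.ndarray, np.ndarray]:
    """Breslow cumulative baseline hazard at the distinct event times."""
    risk = np.exp(lp)
    order = np.argsort(time, kind="stable")
    t_sorted, e_sorted, r_sorted = time[order], event[order], risk[order]
    # risk-set sums: subjects with T >= t (reverse cumulative sum)
    rev = np.cumsum(r_sorted[::-1])[::-1]
    event_times = np.unique(t_sorted[e_sorted == 1])
    increments = np.empty_like(event_times)
    for k, t in enumerate(event_times):
        first = np.searchsorted(t_sorted, t, side="left")
        d = np.sum(e_sorted[t_sorted == t])
        increments[k] = d / rev[first]
    return event_times, np.cumsum(increments)


def _efron_log_likelihood(
    time: np.ndarray, event: np.ndarray, lp: np.ndarray
) -> float:
    """Efron-tie-corrected Cox log partial likelihood at fixed coefficients."""
    risk = np.exp(lp)
    ll = 0.0
    for t in np.unique(time[event == 1]):
        tied = (time == t) & (event == 1)
        d = int(tied.sum())
        at_risk = time >= t
        sum_risk = risk[at_risk].sum()
        sum_tied = risk[tied].sum()
        ll += lp[tied].sum()
        for r in range(d):
            ll -= np.log(sum_risk - (r / d) * sum_tied)
    return float(ll)


def fit_cox(
    covariates: pd.DataFrame | None,
    scores: pd.DataFrame,
    time_observed: np.ndarray,
    event: np.ndarray,
    t_lm: float,
    penalty: str = "none",
    alpha: float | None = None,
    cv_folds: int = 5,
    seed: int = 0,
) -> DynamicCoxModel:
    """Fit the dynamic Cox model on a (landmarked) training set.

    ``penalty="none"`` maximizes Efron's partial likelihood over all
    coefficients.  ``penalty="lasso"`` runs an L1 path over the score
    coefficients only (penalty factor 0 on the baseline covariates), choosing
    the strength by ``cv_folds``-fold cross-validated partial-likelihood
    deviance unless an explicit ``alpha`` is given.  Scores are standardized
    internally for the penalized fit and coefficients back-transformed.
    """
    time_observed = np.asarray(time_observed, dtype=float)
    event = np.asarray(event, dtype=int)
    if event.sum() == 0:
        raise ValueError("cannot fit a Cox model with zero events")
    parts = []
    if covariates is not None and covariates.shape[1] > 0:
        parts.append(covariates.astype(float))
    parts.append(scores.astype(float))
    design = pd.concat(parts, axis=1)
    if not np.all(np.isfinite(design.to_numpy())):
        raise ValueError("non-finite values in the design matrix")
    beta_cols = [] if covariates is None else list(covariates.columns)
    gamma_cols = list(scores.columns)

    if penalty == "none":
        df = design.copy()
        df["__time"] = time_observed
        df["__event"] = event
        fitter = CoxPHFitter()
        fitter.fit(df, duration_col="__time", event_col="__event")
        coefs = fitter.params_
        meta = {"type": "none"}
    elif penalty == "lasso":
        coefs, meta = _fit_lasso(
            design, beta_cols, gamma_cols, time_observed, event, alpha, cv_folds, seed
        )
    else:
        raise ValueError(f"unknown penalty {penalty!r}")

    lp = design.to_numpy(dtype=float) @ coefs.to_numpy()
    bt, bh = _breslow(time_observed, event, lp)
    return DynamicCoxModel(
        beta=coefs[beta_cols],
        gamma=coefs[gamma_cols],
        baseline_times=bt,
        baseline_cumhaz=bh,
        landmark_time=t_lm,
        penalty=meta,
    )


def _fit_lasso(
    design: pd.DataFrame,
    beta_cols: list[str],
    gamma_cols: list[str],
    time: np.ndarray,
    event: np.ndarray,
    alpha: float | None,
    cv_folds: int,
    seed: int,
) -> tuple[pd.Series, dict]:
    from sksurv.linear_model import CoxnetSurvivalAnalysis
    from sksurv.util import Surv

    x = design.to_numpy(dtype=float).copy()
    scales = np.ones(x.shape[1])
    g_idx = [design.columns.get_loc(c) for c in gamma_cols]
    for j in g_idx:
        sd = x[:, j].std(ddof=1)
        if sd > 0:
            scales[j] = sd
            x[:, j] = x[:, j] / sd
    pf = np.zeros(x.shape[1])
    pf[g_idx] = 1.0
    y = Surv.from_arrays(event=event.astype(bool), time=time)

    def fit_path(xm, ym, alphas=None):
        model = CoxnetSurvivalAnalysis(
            l1_ratio=1.0, penalty_factor=pf, alphas=alphas, normalize=False,
            fit_baseline_model=False,
        )
        model.fit(xm, ym)
        return model

    if alpha is None:
        path = fit_path(x, y)
        alphas = np.asarray(path.alphas_)
        rng = np.random.default_rng(seed)
        folds = rng.permutation(len(time)) % cv_folds
        deviance = np.zeros(len(alphas))
        for f in range(cv_folds):
            tr = folds != f
            sub = fit_path(x[tr], y[tr], alphas=list(alphas))
            coefs_path = sub.coef_  # (p, n_fitted); the path may stop early
            fitted = np.asarray(sub.alphas_)
            for a in range(len(alphas)):
                col = int(np.argmin(np.abs(fitted - alphas[a])))
                lp_all = x @ coefs_path[:, col]
                # Verweij-van Houwelingen: ll(all) - ll(train) at train coefs
                dev = _efron_log_likelihood(time, event, lp_all) - _efron_log_likelihood(
                    time[tr], event[tr], lp_all[tr]
                )
                deviance[a] += -2.0 * dev
        best = int(np.argmin(deviance))
        alpha = float(alphas[best])
        meta = {"type": "lasso", "alpha": alpha, "cv_folds": cv_folds}
        model = fit_path(x, y, alphas=list(alphas))
        coef = model.coef_[:, best]
    else:
        model = fit_path(x, y, alphas=[alpha])
        coef = model.coef_[:, 0]
        meta = {"type": "lasso", "alpha": float(alpha), "cv_folds": 0}
    coef = coef / scales
    return pd.Series(coef, index=design.columns), meta


def baseline_survival(model: DynamicCoxModel, t) -> np.ndarray:
    """Breslow baseline survival S0(t) = exp(-H0(t))."""
    return np.exp(-model.cumulative_hazard(t))


def predict_survival(
    model: DynamicCoxModel,
    covariates: pd.DataFrame | None,
    scores: pd.DataFrame,
    horizon,
) -> PredictionResult:
    """Conditional survival pi_i(t | t_LM) for each subject and horizon time."""
    times = np.atleast_1d(np.asarray(horizon, dtype=float))
    if np.any(times < model.landmark_time):
        raise ValueError("horizon times must not precede the landmark time")
    lp = model.linear_predictor(covariates, scores)
    s0 = baseline_survival(model, times)
    s0_lm = float(baseline_survival(model, model.landmark_time)[0])
    ratio = s0 / s0_lm
    with np.errstate(over="ignore"):
        probs = ratio[None, :] ** np.exp(lp)[:, None]
    probs = np.clip(probs, 0.0, 1.0)
    return PredictionResult(
        subject_ids=scores.index.to_numpy(),
        landmark_time=model.landmark_time,
        times=times,
        probabilities=probs,
    )
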