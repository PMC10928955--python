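"""Validation of dynamic survival predictions.

Implements the time-dependent AUC (cumulative cases / dynamic controls, with
inverse-probability-of-censoring weights from a Kaplan-Meier estimate of the
censoring distribution among landmark survivors), the IPCW Brier score, the
mean squared error against simulated true conditional probabilities, and the
repeated k-fold cross-validation driver that honours the strict/relaxed
ordering of landmarking and fold-splitting.
"""

from __future__ import annotations

import logging
from dataclasses import dataclass, field
from typing import Sequence

import numpy as np
import pandas as pd
from lifelines import KaplanMeierFitter

from .cox import PredictionResult, fit_cox, predict_survival
from .dataset import LongitudinalDataset
from .landmark import make_fold_plan, strict_landmark
from .mfpca import fit_mfpca, score_new_subjects
from .simulate import HazardOracle, SimulatedStudy

logger = logging.getLogger(__name__)

__all__ = [
    "td_auc",
    "brier",
    "mse_truth",
    "run_cv_experiment",
    "ExperimentResult",
    "MetricCurve",
]


def _censoring_km(time: np.ndarray, event: np.ndarray) -> KaplanMeierFitter:
    km = KaplanMeierFitter()
    km.fit(time, event_observed=1 - event)
    return km


def _km_at(km: KaplanMeierFitter, t: np.ndarray) -> np.ndarray:
    return km.survival_function_at_times(t).to_numpy(dtype=float)


def _km_left(km: KaplanMeierFitter, t: np.ndarray) -> np.ndarray:
    """Left limit G(t-) of the Kaplan-Meier curve."""
    return _km_at(km, np.nextafter(np.asarray(t, dtype=float), -np.inf))


def td_auc(
    predictions: PredictionResult,
    time_observed: np.ndarray,
    event: np.ndarray,
    t: float,
) -> float:
    """IPCW time-dependent AUC at horizon ``t`` (cumulative/dynamic).

    Cases are subjects with an observed event in (t_LM, t]; controls are
    subjects still at risk past ``t``.  Censoring weights come from the
    Kaplan-Meier estimate of the censoring distribution among the prediction
    (landmark-survivor) subjects.  Returns NaN with a logged flag when there
    is no case or no control, or when a censoring weight degenerates.
    """
    t_lm = predictions.landmark_time
    if t <= t_lm:
        raise ValueError("evaluation time must exceed the landmark time")
    time_observed = np.asarray(time_observed, dtype=float)
    event = np.asarray(event, dtype=int)
    risk = 1.0 - _probs_at(predictions, t)
    is_case = (time_observed > t_lm) & (time_observed <= t) & (event == 1)
    is_ctrl = time_observed > t
    if not is_case.any() or not is_ctrl.any():
        logger.warning("tdAUC undefined at t=%.3g: no cases or no controls", t)
        return float("nan")
    km = _censoring_km(time_observed, event)
    w_case = _km_left(km, time_observed[is_case])
    w_ctrl = _km_at(km, np.array([t]))[0]
    if w_ctrl <= 0 or np.any(w_case <= 0):
        logger.warning("tdAUC undefined at t=%.3g: degenerate censoring weight", t)
        return float("nan")
    w_case = 1.0 / w_case
    # control weights are constant 1/G(t) and cancel between num and denom,
    # but are kept explicit for clarity
    ctrl_risk = np.sort(risk[is_ctrl])
    cum_w = np.cumsum(np.full(ctrl_risk.size, 1.0 / w_ctrl))
    lo = np.searchsorted(ctrl_risk, risk[is_case], side="left")
    hi = np.searchsorted(ctrl_risk, risk[is_case], side="right")
    below = np.where(lo > 0, cum_w[lo - 1], 0.0)
    ties = np.where(hi > 0, cum_w[hi - 1], 0.0) - below
    num = float(np.sum(w_case * (below + 0.5 * ties)))
    denom = float(w_case.sum() * cum_w[-1])
    return num / denom


def brier(
    predictions: PredictionResult,
    time_observed: np.ndarray,
    event: np.ndarray,
    t: float,
) -> float:
    """IPCW Brier score at horizon ``t`` among landmark survivors."""
    t_lm = predictions.landmark_time
    if t <= t_lm:
        raise ValueError("evaluation time must exceed the landmark time")
    time_observed = np.asarray(time_observed, dtype=float)
    event = np.asarray(event, dtype=int)
    pi = _probs_at(predictions, t)
    had_event = (time_observed <= t) & (event == 1)
    at_risk = time_observed > t
    km = _censoring_km(time_observed, event)
    g_event = _km_left(km, time_observed[had_event])
    g_t = _km_at(km, np.array([t]))[0]
    if (at_risk.any() and g_t <= 0) or np.any(g_event <= 0):
        logger.warning("Brier score undefined at t=%.3g: zero censoring weight", t)
        return float("nan")
    contrib = np.zeros_like(pi)
    contrib[had_event] = pi[had_event] ** 2 / g_event
    if at_risk.any():
        contrib[at_risk] = (1.0 - pi[at_risk]) ** 2 / g_t
    return float(contrib.mean())


def mse_truth(predictions: PredictionResult, oracle: HazardOracle, t: float) -> float:
    """Mean squared error against the simulated true conditional survival."""
    pi_true = oracle.conditional_survival(
        [t], predictions.landmark_time, subject_ids=predictions.subject_ids
    )[:, 0]
    pi_hat = _probs_at(predictions, t)
    return float(np.mean((pi_true - pi_hat) ** 2))


def _probs_at(predictions: PredictionResult, t: float) -> np.ndarray:
    idx = np.where(np.isclose(predictions.times, t))[0]
    if idx.size:
        return predictions.probabilities[:, idx[0]]
    # monotone interpolation between horizon times
    out = np.empty(len(predictions.subject_ids))
    for i in range(out.size):
        out[i] = np.interp(t, predictions.times, predictions.probabilities[i])
    return out


@dataclass
class MetricCurve:
    metric: str
    landmark_time: float
    times: np.ndarray
    values: np.ndarray
    n_at_risk: np.ndarray


@dataclass
class ExperimentResult:
    """Raw and aggregated metric values of a repeated-CV experiment."""

    config: dict
    results: pd.DataFrame  # method, repeat, fold, metric, time, value, n_at_risk

    @property
    def aggregated(self) -> pd.DataFrame:
        """Mean over folds within repeat, then over repeats."""
        per_repeat = (
            self.results.groupby(["method", "metric", "time", "repeat"], sort=True)["value"]
            .mean()
            .reset_index()
        )
        return (
            per_repeat.groupby(["method", "metric", "time"], sort=True)["value"]
            .mean()
            .reset_index()
        )

    def mean_metric(self, method: str, metric: str) -> float:
        agg = self.aggregated
        sel = agg[(agg["method"] == method) & (agg["metric"] == metric)]
        return float(sel["value"].mean())


def _method_name(method: dict) -> str:
    return method.get(
        "name",
        f"{method['landmark']}_{'abc' if method.get('abc') else 'std'}"
        + ("_lasso" if method.get("penalty", "none") == "lasso" else ""),
    )


def run_cv_experiment(
    study: SimulatedStudy | LongitudinalDataset,
    methods: Sequence[dict],
    t_lm: float,
    k: int = 5,
    repeats: int = 20,
    seed: int = 0,
    eval_times: np.ndarray | None = None,
    pve_target: float = 0.95,
) -> ExperimentResult:
    """Repeated k-fold cross-validation of dynamic-prediction methods.

    Each method is a dict with keys ``landmark`` ("strict" or "relaxed"),
    ``abc`` (bool: age-based centring), ``penalty`` ("none" or "lasso") and an
    optional ``name``.  Strict methods landmark the data before fold
    splitting; relaxed methods split first and landmark only the test fold.
    The FPCA model is always fitted on the training fold only and frozen
    before scoring the test fold.  When a truth oracle is available (simulated
    study), the MSE against the true conditional probabilities is computed,
    along with metrics of an ``oracle`` reference method that predicts the
    true probabilities themselves.
    """
    if not methods:
        raise ValueError("at least one method is required")
    if isinstance(study, SimulatedStudy):
        data, oracle = study.dataset, study.oracle
    else:
        data, oracle = study, None
    if eval_times is None:
        horizon = float(data.grid[-1])
        eval_times = np.round(np.arange(t_lm + 0.5, horizon + 1e-9, 0.5), 10)
    eval_times = np.asarray(eval_times, dtype=float)

    ss = np.random.SeedSequence(seed)
    plan_seeds = {m: int(s.generate_state(1)[0] % 2**31) for m, s in
                  zip(("strict", "relaxed"), ss.spawn(2))}
    cox_seed = int(ss.spawn(1)[0].generate_state(1)[0] % 2**31)
    plans = {}
    strict_full = None
    rows: list[dict] = []

    for method in methods:
        mode = method["landmark"]
        name = _method_name(method)
        scale = "age" if method.get("abc") else "study"
        penalty = method.get("penalty", "none")
        if mode not in plans:
            plans[mode] = make_fold_plan(data, mode, t_lm, k, repeats, plan_seeds[mode])
        plan = plans[mode]
        if mode == "strict" and strict_full is None:
            strict_full = strict_landmark(data, t_lm)
        for rep in range(repeats):
            for fold in range(k):
                train_ids, test_ids = plan.fold_ids(rep, fold)
                if mode == "strict":
                    train = strict_full.subset(
                        strict_full.baseline.index.intersection(pd.Index(train_ids))
                    )
                    test = strict_full.subset(
                        strict_full.baseline.index.intersection(pd.Index(test_ids))
                    )
                    if test.n_subjects == 0:
                        logger.warning("fold %d/%d: no landmark survivor in test fold", rep, fold)
                        continue
                else:
                    train = data.subset(train_ids)
                    try:
                        test = strict_landmark(data.subset(test_ids), t_lm)
                    except ValueError:
                        logger.warning("fold %d/%d: no landmark survivor in test fold", rep, fold)
                        continue
                preds = _fit_and_predict(
                    train, test, t_lm, scale, penalty, pve_target, eval_times, cox_seed
                )
                rows.extend(
                    _metric_rows(name, rep, fold, preds, test, oracle, eval_times)
                )
        # truth-oracle reference curves (simulation only), once per mode set
    if oracle is not None:
        plan = plans.get("strict")
        if plan is None:
            plan = make_fold_plan(data, "strict", t_lm, k, repeats, plan_seeds["strict"])
            strict_full = strict_landmark(data, t_lm)
        for rep in range(repeats):
            for fold in range(k):
                _, test_ids = plan.fold_ids(rep, fold)
                test = strict_full.subset(
                    strict_full.baseline.index.intersection(pd.Index(test_ids))
                )
                if test.n_subjects == 0:
                    continue
                probs = oracle.conditional_survival(
                    eval_times, t_lm, subject_ids=test.baseline.index.to_numpy()
                )
                preds = PredictionResult(
                    subject_ids=test.baseline.index.to_numpy(),
                    landmark_time=t_lm,
                    times=eval_times,
                    probabilities=probs,
                )
                rows.extend(_metric_rows("oracle", rep, fold, preds, test, oracle, eval_times))

    results = pd.DataFrame(
        rows, columns=["method", "repeat", "fold", "metric", "time", "value", "n_at_risk"]
    )
    config = {
        "landmark_time": t_lm,
        "k": k,
        "repeats": repeats,
        "seed": seed,
        "pve_target": pve_target,
        "eval_times": eval_times.tolist(),
        "methods": [_method_name(m) for m in methods],
    }
    return ExperimentResult(config=config, results=results)


def _fit_and_predict(
    train: LongitudinalDataset,
    test: LongitudinalDataset,
    t_lm: float,
    scale: str,
    penalty: str,
    pve_target: float,
    eval_times: np.ndarray,
    cox_seed: int,
) -> PredictionResult:
    model, train_scores = fit_mfpca(train, time_scale=scale, pve_target=pve_target)
    test_scores = score_new_subjects(test, model)
    covs = train.baseline[train.covariates] if train.covariates else None
    cox = fit_cox(
        covs,
        train_scores,
        train.time_observed,
        train.event,
        t_lm,
        penalty=penalty,
        seed=cox_seed,
    )
    test_covs = test.baseline[test.covariates] if test.covariates else None
    return predict_survival(cox, test_covs, test_scores, eval_times)


def _metric_rows(
    name: str,
    rep: int,
    fold: int,
    preds: PredictionResult,
    test: LongitudinalDataset,
    oracle: HazardOracle | None,
    eval_times: np.ndarray,
) -> list[dict]:
    rows = []
    time_obs, ev = test.time_observed, test.event
    for t in eval_times:
        n_risk = int(np.sum(time_obs > t))
        base = {"method": name, "repeat": rep, "fold": fold, "time": t, "n_at_risk": n_risk}
        rows.append({**base, "metric": "tdauc", "value": td_auc(preds, time_obs, ev, t)})
        rows.append({**base, "metric": "brier", "value": brier(preds, time_obs, ev, t)})
        if oracle is not None:
            rows.append({**base, "metric": "mse", "value": mse_truth(preds, oracle, t)})
    return rows
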