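"""Strict and relaxed landmarking, and cross-validation fold plans.

At a landmark time t_LM, predictions are made for subjects still event-free.
*Strict* landmarking restricts both training and test data to those subjects
and truncates their longitudinal history at t_LM.  *Relaxed* landmarking (the
convention of several published pipelines) trains on every subject's full
follow-up and landmarks only the test data — convenient, but it leaks
post-landmark information into the training model.

Fold plans encode the prescribed ordering: with strict landmarking the data is
landmarked first and then split into folds; with relaxed landmarking the split
comes first and only the test fold is landmarked at evaluation time.
"""

from __future__ import annotations

from dataclasses import dataclass

import numpy as np
import pandas as pd

from .dataset import LongitudinalDataset

__all__ = ["strict_landmark", "relaxed_landmark_views", "make_fold_plan", "FoldPlan"]


def strict_landmark(data: LongitudinalDataset, t_lm: float) -> LongitudinalDataset:
    """Subjects with T* > t_LM, longitudinal history truncated at t_LM.

    Subjects whose observed time equals t_LM exactly are removed; visits at
    exactly t_LM are kept.  Survival outcomes of retained subjects are left
    untouched.
    """
    if t_lm < 0:
        raise ValueError("landmark time must be nonnegative")
    keep = data.baseline["time_observed"].to_numpy() > t_lm
    if not keep.any():
        raise ValueError(f"no subject survives the landmark time {t_lm}")
    return data.subset(data.baseline.index[keep]).truncate_visits(t_lm)


def relaxed_landmark_views(
    train: LongitudinalDataset, test: LongitudinalDataset, t_lm: float
) -> tuple[LongitudinalDataset, LongitudinalDataset]:
    """(untouched training data, strictly landmarked test data)."""
    overlap = train.baseline.index.intersection(test.baseline.index)
    if len(overlap):
        raise ValueError(f"train and test subject sets overlap: {list(overlap)[:5]}")
    return train, strict_landmark(test, t_lm)


@dataclass
class FoldPlan:
    """Repeated k-fold assignments honouring the landmark-mode ordering."""

    mode: str  # "strict" or "relaxed"
    landmark_time: float
    k: int
    repeats: int
    subject_ids: np.ndarray
    assignments: np.ndarray  # (repeats, n_subjects) fold labels in 0..k-1
    seed: int

    def fold_ids(self, repeat: int, fold: int) -> tuple[np.ndarray, np.ndarray]:
        """(train subject ids, test subject ids) for one repeat/fold."""
        labels = self.assignments[repeat]
        return self.subject_ids[labels != fold], self.subject_ids[labels == fold]


def make_fold_plan(
    data: LongitudinalDataset,
    mode: str,
    t_lm: float,
    k: int,
    repeats: int,
    seed: int,
) -> FoldPlan:
    """Reproducible repeated k-fold plan.

    Strict mode draws folds from the landmark survivors only (the data is
    landmarked before splitting); relaxed mode draws folds from all subjects
    and defers landmarking to the test fold.  Fold sizes within a repeat
    differ by at most one.
    """
    if mode not in ("strict", "relaxed"):
        raise ValueError(f"unknown landmark mode {mode!r}")
    if k < 2:
        raise ValueError("at least 2 folds are required")
    if mode == "strict":
        survivors = data.baseline["time_observed"].to_numpy() > t_lm
        ids = data.baseline.index[survivors].to_numpy()
        if ids.size < k:
            raise ValueError(
                f"only {ids.size} subjects survive the landmark time; need at least k={k}"
            )
    else:
        ids = data.baseline.index.to_numpy()
    rng = np.random.default_rng(seed)
    assignments = np.empty((repeats, ids.size), dtype=int)
    base = np.arange(ids.size) % k
    for r in range(repeats):
        assignments[r] = base[rng.permutation(ids.size)]
    return FoldPlan(
        mode=mode,
        landmark_time=t_lm,
        k=k,
        repeats=repeats,
        subject_ids=ids,
        assignments=assignments,
        seed=seed,
    )
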