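"""In-memory container for longitudinal + survival study data.

The canonical layout is *long* (tidy): one row per (subject, variable, visit)
with possibly missing values, alongside a per-subject baseline table carrying
covariates (including age at entry), the observed event/censoring time and the
event indicator.  Visits live on a planned regular grid; irregular real-world
times are snapped to the nearest planned time on ingestion.
"""

from __future__ import annotations

import logging
from dataclasses import dataclass, field, replace

import numpy as np
import pandas as pd

logger = logging.getLogger(__name__)

__all__ = ["LongitudinalDataset", "snap_to_grid"]

#: required baseline-table columns
BASELINE_COLUMNS = ("age", "time_observed", "event")
#: required long-table columns
LONG_COLUMNS = ("subject_id", "variable", "time", "value")


def snap_to_grid(times: np.ndarray, grid: np.ndarray) -> np.ndarray:
    """Snap each time to the nearest planned grid time, ties to the earlier one."""
    grid = np.asarray(grid, dtype=float)
    times = np.asarray(times, dtype=float)
    idx = np.searchsorted(grid, times)
    idx = np.clip(idx, 1, len(grid) - 1)
    left, right = grid[idx - 1], grid[idx]
    # strict inequality: equidistant points snap to the earlier grid time
    snapped = np.where(right - times < times - left, right, left)
    return np.where(times <= grid[0], grid[0], snapped)


@dataclass
class LongitudinalDataset:
    """Longitudinal measurements, baseline covariates and survival outcomes.

    Attributes
    ----------
    baseline:
        DataFrame indexed by subject id with at least columns ``age``,
        ``time_observed`` (years) and ``event`` (1 = event, 0 = censored),
        plus any additional baseline covariates.
    long:
        Tidy DataFrame with columns ``subject_id``, ``variable``, ``time``,
        ``value`` (NaN marks a missing measurement).
    grid:
        Planned visit times in years, strictly increasing, starting at 0.
    variables:
        Names of the longitudinal variables.
    covariates:
        Baseline covariate columns to be used in the survival model (may be
        empty; ``age`` is always available for age-based centring regardless).
    """

    baseline: pd.DataFrame
    long: pd.DataFrame
    grid: np.ndarray
    variables: list[str]
    covariates: list[str] = field(default_factory=list)

    def __post_init__(self) -> None:
        self.grid = np.asarray(self.grid, dtype=float)
        if self.grid.ndim != 1 or len(self.grid) == 0:
            raise ValueError("grid must be a nonempty 1-d array")
        if np.any(np.diff(self.grid) <= 0):
            raise ValueError("grid must be strictly increasing")
        for col in BASELINE_COLUMNS:
            if col not in self.baseline.columns:
                raise ValueError(f"baseline table is missing mandatory column {col!r}")
        for col in LONG_COLUMNS:
            if col not in self.long.columns:
                raise ValueError(f"long table is missing mandatory column {col!r}")
        ev = self.baseline["event"].to_numpy()
        if not np.isin(ev, [0, 1]).all():
            raise ValueError("event indicator must be 0 or 1")
        if not (self.baseline["time_observed"].to_numpy() > 0).all():
            raise ValueError("observed times must be positive")
        if len(self.long):
            dup = self.long.duplicated(subset=["subject_id", "variable", "time"])
            if dup.any():
                raise ValueError("duplicate (subject, variable, time) rows in long table")

    # -- basic accessors ---------------------------------------------------
    @property
    def subject_ids(self) -> np.ndarray:
        return self.baseline.index.to_numpy()

    @property
    def n_subjects(self) -> int:
        return len(self.baseline)

    @property
    def time_observed(self) -> np.ndarray:
        return self.baseline["time_observed"].to_numpy(dtype=float)

    @property
    def event(self) -> np.ndarray:
        return self.baseline["event"].to_numpy(dtype=int)

    @property
    def ages(self) -> pd.Series:
        return self.baseline["age"]

    def wide(self, variable: str) -> pd.DataFrame:
        """Subjects x planned-grid matrix for one variable (NaN = unobserved)."""
        if variable not in self.variables:
            raise KeyError(f"unknown variable {variable!r}")
        sub = self.long[self.long["variable"] == variable]
        mat = sub.pivot(index="subject_id", columns="time", values="value")
        mat = mat.reindex(index=self.baseline.index, columns=self.grid)
        mat.columns = self.grid
        return mat

    # -- views -------------------------------------------------------------
    def subset(self, subject_ids) -> "LongitudinalDataset":
        ids = pd.Index(subject_ids)
        missing = ids.difference(self.baseline.index)
        if len(missing):
            raise KeyError(f"unknown subject ids: {list(missing)[:5]}")
        return replace(
            self,
            baseline=self.baseline.loc[ids].copy(),
            long=self.long[self.long["subject_id"].isin(ids)].copy(),
        )

    def truncate_visits(self, t_max: float) -> "LongitudinalDataset":
        """Drop visits after ``t_max`` (visits at exactly ``t_max`` are kept)."""
        return replace(
            self,
            long=self.long[self.long["time"] <= t_max].copy(),
            grid=self.grid[self.grid <= t_max],
        )

    def equals(self, other: "LongitudinalDataset") -> bool:
        return (
            np.array_equal(self.grid, other.grid)
            and self.variables == other.variables
            and self.baseline.equals(other.baseline)
            and self.long.reset_index(drop=True).equals(other.long.reset_index(drop=True))
        )
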