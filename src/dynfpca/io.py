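"""Delimited-text input/output for datasets, models and results.

All artifacts are plain text: tidy long-format measurement tables, baseline
tables, JSON model files and tidy result tables — enough to re-score unseen
subjects exactly and to reproduce a run from its configuration echo.
"""

from __future__ import annotations

import json
import logging
from pathlib import Path

import numpy as np
import pandas as pd

from .dataset import LONG_COLUMNS, LongitudinalDataset, snap_to_grid
from .simulate import SimulatedStudy

logger = logging.getLogger(__name__)

__all__ = [
    "read_long_table",
    "write_dataset",
    "write_study",
    "read_model",
    "write_model",
    "write_results",
]

_BASELINE_REQUIRED = ("subject_id", "age", "time_observed", "event")


def read_long_table(
    long_path,
    baseline_path,
    grid=None,
    delimiter: str = ",",
    covariates: list[str] | None = None,
) -> LongitudinalDataset:
    """Read a long-format measurement table plus its baseline companion.

    The long table needs columns ``subject_id, variable, time, value``; the
    baseline table needs ``subject_id`` plus covariates including ``age``,
    ``time_observed`` and ``event``.  Off-grid visit times are snapped to the
    nearest planned grid time (ties to the earlier point); unparseable values
    become missing with a logged count.  Duplicate (subject, variable, time)
    rows raise an error.
    """
    long = pd.read_csv(long_path, sep=delimiter, float_precision="round_trip")
    for col in LONG_COLUMNS:
        if col not in long.columns:
            raise ValueError(f"long table is missing mandatory column {col!r}")
    baseline = pd.read_csv(baseline_path, sep=delimiter, float_precision="round_trip")
    for col in _BASELINE_REQUIRED:
        if col not in baseline.columns:
            raise ValueError(f"baseline table is missing mandatory column {col!r}")
    baseline = baseline.set_index("subject_id")

    values = pd.to_numeric(long["value"], errors="coerce")
    n_bad = int((values.isna() & long["value"].notna()).sum())
    if n_bad:
        logger.warning("long table: %d unparseable value(s) recorded as missing", n_bad)
    long = long.assign(value=values)
    long["time"] = pd.to_numeric(long["time"], errors="raise")

    if grid is None:
        grid = np.unique(long["time"].to_numpy(dtype=float))
    else:
        grid = np.asarray(grid, dtype=float)
        long["time"] = snap_to_grid(long["time"].to_numpy(dtype=float), grid)
    if long.duplicated(subset=["subject_id", "variable", "time"]).any():
        raise ValueError("duplicate (subject, variable, time) rows after grid snapping")
    variables = sorted(long["variable"].unique())
    covariates = covariates or []
    return LongitudinalDataset(
        baseline=baseline,
        long=long[list(LONG_COLUMNS)].reset_index(drop=True),
        grid=grid,
        variables=variables,
        covariates=covariates,
    )


def write_dataset(data: LongitudinalDataset, outdir, delimiter: str = ",") -> dict[str, Path]:
    outdir = Path(outdir)
    outdir.mkdir(parents=True, exist_ok=True)
    paths = {
        "long": outdir / "longitudinal.csv",
        "baseline": outdir / "baseline.csv",
        "grid": outdir / "grid.csv",
    }
    data.long.to_csv(paths["long"], sep=delimiter, index=False, float_format="%.17g")
    data.baseline.to_csv(
        paths["baseline"], sep=delimiter, index=True, index_label="subject_id",
        float_format="%.17g",
    )
    pd.DataFrame({"time": data.grid}).to_csv(
        paths["grid"], sep=delimiter, index=False, float_format="%.17g"
    )
    return paths


def write_study(study: SimulatedStudy, outdir, delimiter: str = ",") -> dict[str, Path]:
    """Write a simulated study: data tables plus the truth-oracle files."""
    outdir = Path(outdir)
    paths = write_dataset(study.dataset, outdir, delimiter=delimiter)
    ids = study.dataset.baseline.index.to_numpy()
    m = study.true_scores.shape[1]
    scores = pd.DataFrame(
        study.true_scores, columns=[f"score{j + 1}" for j in range(m)]
    )
    scores.insert(0, "subject_id", ids)
    paths["true_scores"] = outdir / "true_scores.csv"
    scores.to_csv(paths["true_scores"], sep=delimiter, index=False, float_format="%.17g")

    # per-subject cumulative hazard on a coarsened oracle grid (text-friendly)
    stride = max(1, len(study.oracle.times) // 301)
    times = study.oracle.times[::stride]
    lam = study.oracle.cumhaz[:, ::stride]
    oracle = pd.DataFrame(lam, columns=[f"{t:.4f}" for t in times])
    oracle.insert(0, "subject_id", ids)
    paths["cumulative_hazard"] = outdir / "cumulative_hazard.csv"
    oracle.to_csv(paths["cumulative_hazard"], sep=delimiter, index=False)

    basis = study.basis.values  # (M, Q, G)
    rows = []
    for comp in range(basis.shape[0]):
        for q in range(basis.shape[1]):
            for g, t in enumerate(study.dataset.grid):
                rows.append(
                    {
                        "component": comp + 1,
                        "variable": study.dataset.variables[q],
                        "time": t,
                        "value": basis[comp, q, g],
                    }
                )
    paths["basis"] = outdir / "true_basis.csv"
    pd.DataFrame(rows).to_csv(paths["basis"], sep=delimiter, index=False)
    return paths


def write_model(model, path) -> Path:
    """Serialize a fitted model (FPCA or Cox) to a JSON text file."""
    path = Path(path)
    path.parent.mkdir(parents=True, exist_ok=True)
    payload = {"class": type(model).__name__, "model": model.to_dict()}
    path.write_text(json.dumps(payload))
    return path


def read_model(path):
    from .cox import DynamicCoxModel
    from .fpca import UnivariateFPCA
    from .mfpca import MultivariateFPCA

    classes = {c.__name__: c for c in (UnivariateFPCA, MultivariateFPCA, DynamicCoxModel)}
    payload = json.loads(Path(path).read_text())
    cls = classes[payload["class"]]
    return cls.from_dict(payload["model"])


def write_results(result, outdir, config: dict | None = None, delimiter: str = ",") -> dict:
    """Write an ExperimentResult as tidy tables plus a config echo."""
    outdir = Path(outdir)
    outdir.mkdir(parents=True, exist_ok=True)
    paths = {
        "results": outdir / "results.csv",
        "aggregated": outdir / "aggregated.csv",
        "config": outdir / "run_config.json",
    }
    result.results.to_csv(paths["results"], sep=delimiter, index=False, float_format="%.17g")
    result.aggregated.to_csv(
        paths["aggregated"], sep=delimiter, index=False, float_format="%.17g"
    )
    echo = dict(result.config)
    if config:
        echo.update(config)
    paths["config"].write_text(json.dumps(echo, indent=2))
    return paths
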