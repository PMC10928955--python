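import numpy as np
import pandas as pd
import pytest

import dynfpca as dp


def make_dataset(values, grid, ages=None, time_observed=None, event=None, variables=None):
    """Hand-built dataset from a dict {variable: (n, G) array with NaN gaps}."""
    variables = variables or list(values)
    n = next(iter(values.values())).shape[0]
    ids = pd.Index(np.arange(1, n + 1), name="subject_id")
    baseline = pd.DataFrame(
        {
            "age": 60.0 if ages is None else np.asarray(ages, dtype=float),
            "time_observed": grid[-1] + 1.0 if time_observed is None else time_observed,
            "event": 1 if event is None else event,
        },
        index=ids,
    )
    frames = []
    for var in variables:
        mat = np.asarray(values[var], dtype=float)
        frames.append(
            pd.DataFrame(
                {
                    "subject_id": np.repeat(ids, len(grid)),
                    "variable": var,
                    "time": np.tile(grid, n),
                    "value": mat.ravel(),
                }
            )
        )
    long = pd.concat(frames, ignore_index=True)
    long = long[np.isfinite(long["value"])].reset_index(drop=True)
    return dp.LongitudinalDataset(baseline, long, grid, variables, [])


@pytest.fixture(scope="session")
def quarter_grid():
    return np.round(np.arange(0, 61) * 0.25, 10)


@pytest.fixture(scope="session")
def study_median():
    """Time-on-study scenario with median censoring, n=400."""
    return dp.simulate_scenario(dp.scenario_config(2, n_subjects=400, seed=7))


@pytest.fixture(scope="session")
def study_dense_noiseless():
    """Dense noiseless uncensored study for exact-recovery oracles."""
    cfg = dp.SimConfig(n_subjects=300, noise_sd=0.0, censoring="none", seed=5)
    return dp.simulate_scenario(cfg)


@pytest.fixture(scope="session")
def study_dense_lownoise():
    """Dense low-noise study (sd 0.01) for score-recovery checks."""
    cfg = dp.SimConfig(n_subjects=400, noise_sd=0.01, censoring="none", seed=11)
    return dp.simulate_scenario(cfg)
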