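import warnings

import numpy as np
import pandas as pd
import pytest

from ideas import CellData, SimConfig, default_param_model, simulate_dataset


@pytest.fixture(autouse=True)
def _quiet_fit_warnings():
    """Regression fits on small simulated genes emit convergence chatter."""
    with warnings.catch_warnings():
        warnings.simplefilter("ignore")
        yield


@pytest.fixture
def toy_data() -> CellData:
    """3 genes x 4 cells, 2 individuals; counts chosen for hand-checkable sums."""
    counts = np.array(
        [
            [1, 0, 2, 3],
            [0, 4, 0, 1],
            [5, 1, 1, 0],
        ]
    )
    cell_meta = pd.DataFrame(
        {"individual": ["a", "a", "b", "b"]}, index=["c1", "c2", "c3", "c4"]
    )
    indiv_meta = pd.DataFrame({"status": [1, 0]}, index=["a", "b"])
    return CellData(counts, ["g1", "g2", "g3"], ["c1", "c2", "c3", "c4"], cell_meta, indiv_meta)


@pytest.fixture(scope="session")
def small_sim():
    """A small simulated cohort reused by integration-style tests."""
    with warnings.catch_warnings():
        warnings.simplefilter("ignore")
        bank = default_param_model(3, n_models=12)
        cfg = SimConfig(
            n_cases=3,
            n_controls=3,
            cells_per_individual=40,
            n_meanDE=2,
            n_varDE=2,
            n_EE=8,
            seed=3,
        )
        data, truth = simulate_dataset(bank, cfg)
    return data, truth
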