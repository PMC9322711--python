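import numpy as np
import pandas as pd
import pytest

import survite as sv
from survite.data import Dataset


@pytest.fixture(scope="session")
def actg_kb():
    return sv.builtin_knowledge_bases()["actg_semi_synthetic"]


@pytest.fixture(scope="session")
def small_cohort(actg_kb):
    """A small simulated cohort with ground truth, shared across tests."""
    ds, truth = sv.generate_semi_synthetic(600, sv.default_parameters(seed=11),
                                           actg_kb)
    return ds, truth


@pytest.fixture
def tiny_dataset():
    """Six hand-written records covering both arms and both event states."""
    rng = np.random.default_rng(3)
    return Dataset(ids=np.arange(6),
                   covariates=rng.normal(size=(6, 3)),
                   covariate_names=["a", "b", "c"],
                   treatment=np.array([1, 0, 1, 0, 1, 0]),
                   time=np.array([10.0, 7.0, 3.0, 8.0, 12.0, 5.0]),
                   event=np.array([1, 1, 0, 1, 0, 1]))


@pytest.fixture
def table_csv(tmp_path):
    df = pd.DataFrame({
        "id": [1, 2, 3],
        "AGE": [30.0, 45.0, 60.0],
        "SEX": [0, 1, 1],
        "treatment": [1, 0, 1],
        "time": [12.5, 8.0, 30.0],
        "event": [1, 0, 1],
    })
    path = tmp_path / "cohort.csv"
    df.to_csv(path, index=False)
    return path
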