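import numpy as np
import pandas as pd
import pytest

from ewaskit import SimConfig, simulate_study


@pytest.fixture(scope="session")
def study():
    """One default-condition simulated study shared across tests."""
    return simulate_study(SimConfig(seed=0))


@pytest.fixture(scope="session")
def null_study():
    """A study with no planted effects of any kind."""
    return simulate_study(SimConfig(seed=0, n_dmc=0, n_deg=0, n_links=0, n_batches=1))


@pytest.fixture()
def rng():
    return np.random.default_rng(12345)


@pytest.fixture()
def toy_sheet():
    """Six-sample sample sheet, 3 cases vs 3 controls."""
    return pd.DataFrame({
        "sample_id": [f"s{i}" for i in range(6)],
        "group": ["case"] * 3 + ["control"] * 3,
        "age": [41.0, 55.0, 62.0, 44.0, 58.0, 50.0],
        "batch": ["B1"] * 6,
        "smoker": [False] * 6,
    })
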