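import numpy as np
import pandas as pd
import pytest

from pscea import CostEffectivenessModel, default_fixture_bundle


@pytest.fixture(scope="session")
def bundle():
    """Default synthetic study: both arms, both endpoints, life table."""
    return default_fixture_bundle(seed=11)


@pytest.fixture(scope="session")
def model():
    """Full pipeline model: simulate -> digitize -> reconstruct -> fit -> select."""
    return CostEffectivenessModel.from_synthetic(seed=1)


@pytest.fixture(scope="session")
def results(model):
    return model.fit()


@pytest.fixture()
def toy_trace():
    """Two-cycle hand trace used for ledger-style accrual checks."""
    return pd.DataFrame(
        {
            "cycle": [0, 1],
            "time_years": [0.0, 21 / 365.25],
            "age": [63.0, 63.0 + 21 / 365.25],
            "pfs": [1.0, 0.6],
            "pd": [0.0, 0.3],
            "dead": [0.0, 0.1],
        }
    )


@pytest.fixture()
def flat_life_table():
    """Life table with (near-)zero background mortality except terminal age."""
    ages = np.arange(0, 111)
    q = np.zeros(len(ages))
    q[-1] = 1.0
    return pd.DataFrame({"age": ages, "q_annual": q})
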