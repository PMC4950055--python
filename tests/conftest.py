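import numpy as np
import pytest

import lmsgrowth as lg


@pytest.fixture(scope="session")
def reference_lms():
    return lg.reference_lms_table()


@pytest.fixture(scope="session")
def reference_counts():
    return lg.reference_counts()


@pytest.fixture(scope="session")
def register0():
    """Default-scale synthetic register at the canonical study seed."""
    return lg.simulate_register(lg.SimulationConfig(seed=0))


@pytest.fixture(scope="session")
def fit0(register0):
    """Full fit of the canonical register, shared across test modules."""
    return lg.LMSModel.from_dataframe(register0).fit()


@pytest.fixture(scope="session")
def quarter_counts(reference_counts):
    cnt = reference_counts.copy()
    cnt["n"] = np.ceil(cnt["n"] / 4).astype(int)
    return cnt
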