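import numpy as np
import pytest

import rotoranchor as ra


@pytest.fixture(scope="session")
def epi():
    return ra.CellParams.epicardial()


@pytest.fixture(scope="session")
def paced_epi_state(epi):
    """Single-cell state paced to steady state at CL 1000 ms (shared across
    tissue tests so each test does not redo the 20-beat conditioning)."""
    return ra.paced_steady_state(epi, cl=1000.0)


@pytest.fixture()
def rng():
    return np.random.default_rng(1234)
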