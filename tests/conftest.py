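import numpy as np
import pytest

from thetaseq import SimConfig, analyze_session, simulate_session


@pytest.fixture(scope="session")
def small_config():
    """A compact session: 20 cells, 3 laps (~45 s)."""
    return SimConfig(n_cells=20, n_laps=3)


@pytest.fixture(scope="session")
def small_session(small_config):
    return simulate_session(small_config, seed=11)


@pytest.fixture(scope="session")
def small_result(small_session):
    """Full pipeline output on the small session (fixed cut phase)."""
    return analyze_session(small_session, seed=1, n_shuffles=100,
                           optimize_cut=False)


@pytest.fixture(scope="session")
def rng():
    return np.random.default_rng(20240917)
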