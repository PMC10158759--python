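import pytest

from rdes.data import load_table1
from rdes.synth import simulate_amplification, simulate_melt


@pytest.fixture(scope="session")
def table1():
    """The verbatim 12-well excerpt (NaN at the unprinted cycles 5-41)."""
    return load_table1(infilled=False)


@pytest.fixture(scope="session")
def table1_infilled():
    """Synthetic companion with complete traces."""
    return load_table1(infilled=True)


@pytest.fixture(scope="session")
def sim_plate():
    """Default-conditions simulated plate with ground truth (96 wells)."""
    return simulate_amplification(seed=11)


@pytest.fixture(scope="session")
def small_plate():
    plate, truth = simulate_amplification(samples=3, targets=2, n_cycles=40, seed=5)
    return plate, truth


@pytest.fixture(scope="session")
def melt_plate():
    return simulate_melt(samples=3, targets=2, seed=5)
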