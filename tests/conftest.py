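import numpy as np
import pytest

from dpa import LatencyTable


@pytest.fixture
def rng():
    return np.random.default_rng(12345)


@pytest.fixture
def point_mass_table():
    """Every participant: slow = {300} repeated, fast = {100} repeated."""
    cells = {}
    for i in range(4):
        pid = f"p{i}"
        cells[(pid, "slow")] = np.full(5, 300.0)
        cells[(pid, "fast")] = np.full(5, 100.0)
    return LatencyTable(cells)


@pytest.fixture
def skewed_pool_factory(rng):
    """Positively skewed latency pools, fresh per call."""

    def make(n=60, loc=200.0, scale=25.0, tail=27.0):
        return rng.normal(loc, scale, n) + rng.exponential(tail, n)

    return make
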