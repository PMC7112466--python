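import numpy as np
import pytest

from epithresh import Network, generate_rrn


@pytest.fixture
def rng():
    return np.random.default_rng(12345)


@pytest.fixture
def dyad():
    return Network.from_edges(2, [(0, 1)])


@pytest.fixture
def triangle():
    return Network.from_edges(3, [(0, 1), (1, 2), (0, 2)])


@pytest.fixture
def star5():
    """5-node star: hub 0 with degrees (4, 1, 1, 1, 1)."""
    return Network.from_edges(5, [(0, i) for i in range(1, 5)])


@pytest.fixture
def path11():
    """11-node path graph (10 edges)."""
    return Network.from_edges(11, [(i, i + 1) for i in range(10)])


@pytest.fixture(scope="session")
def rrn_small():
    """A small random regular network shared across cheap dynamic tests."""
    return generate_rrn(200, 6, rng_seed=7)
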