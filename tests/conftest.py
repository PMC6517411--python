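import numpy as np
import pytest

from ictonet.networks import Network


@pytest.fixture(scope="session")
def cycle3() -> Network:
    """Directed 3-cycle 0 -> 1 -> 2 -> 0 (all nodes equivalent)."""
    return Network(np.array([[0, 0, 1], [1, 0, 0], [0, 1, 0]], dtype=np.int8))


@pytest.fixture(scope="session")
def complete3() -> Network:
    return Network((np.ones((3, 3)) - np.eye(3)).astype(np.int8))


@pytest.fixture(scope="session")
def mutual_pair() -> Network:
    return Network(np.array([[0, 1], [1, 0]], dtype=np.int8))


@pytest.fixture(scope="session")
def chain3() -> Network:
    """0 -> 1 -> 2."""
    adj = np.zeros((3, 3), dtype=np.int8)
    adj[1, 0] = adj[2, 1] = 1
    return Network(adj)
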