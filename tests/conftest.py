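import numpy as np
import pytest

from hemilat.build import HemiNetwork
from hemilat.regions import default_node_table


@pytest.fixture(scope="session")
def node_table():
    return default_node_table()


def random_weighted_graph(
    n: int, density: float, rng: np.random.Generator, connected: bool = False
) -> np.ndarray:
    """Symmetric nonnegative weighted adjacency matrix with zero diagonal."""
    for _ in range(200):
        mask = np.triu(rng.random((n, n)) < density, k=1)
        w = np.where(mask, rng.random((n, n)), 0.0)
        w = np.triu(w, k=1)
        w = w + w.T
        if not connected:
            return w
        from scipy.sparse.csgraph import connected_components

        if connected_components(w, directed=False)[0] == 1:
            return w
    raise RuntimeError("failed to draw a connected graph")


@pytest.fixture
def hemi_pair_scaled():
    """Left = 1.1 x right, identical topology: closed-form AS fixture."""
    rng = np.random.default_rng(11)
    base = random_weighted_graph(45, 0.3, rng, connected=True)
    left = HemiNetwork(1.1 * base, "L", "sub-x", "structural")
    right = HemiNetwork(base, "R", "sub-x", "structural")
    return left, right
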