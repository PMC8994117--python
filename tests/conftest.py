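import numpy as np
import pytest

from recovnet.io import load_table2
from recovnet.synthetic import CohortConfig, make_symmetric_network


@pytest.fixture
def rng():
    return np.random.default_rng(20260920)


@pytest.fixture
def two_networks():
    """Two disjoint symmetric 3-per-hemisphere toy networks."""
    return [make_symmetric_network("alpha", 6), make_symmetric_network("beta", 6)]


@pytest.fixture
def small_config():
    return CohortConfig(
        n_controls=4, n_patients=2,
        n_nodes_per_network={"alpha": 6, "beta": 6},
        n_volumes=200, seed=11)


@pytest.fixture(scope="session")
def table2():
    return load_table2()


def random_weighted_graph(rng, n_nodes, p_edge=0.6):
    """Random symmetric weight matrix, weights in (0, 1], 0 = no edge."""
    w = np.zeros((n_nodes, n_nodes))
    for i in range(n_nodes):
        for j in range(i + 1, n_nodes):
            if rng.random() < p_edge:
                w[i, j] = w[j, i] = rng.uniform(0.05, 1.0)
    return w
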