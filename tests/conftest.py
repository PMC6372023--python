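import numpy as np
import pytest

from strucnet import SimulationConfig, generate_base_network


def graph_from_edges(n, edges):
    a = np.zeros((n, n))
    for i, j in edges:
        a[i, j] = a[j, i] = 1.0
    return a


@pytest.fixture(scope="session")
def small_cohort_config():
    """A down-scaled but otherwise default simulation configuration."""
    return SimulationConfig(n_controls=6, n_patients=6, seed=7)


@pytest.fixture(scope="session")
def base_network():
    cfg = SimulationConfig(seed=3)
    return generate_base_network(cfg, np.random.default_rng(3))


@pytest.fixture(scope="session")
def atlas_graphs():
    """All non-isomorphic connected simple graphs on 2..7 nodes."""
    import networkx as nx

    graphs = []
    for g in nx.graph_atlas_g()[2:]:
        if g.number_of_nodes() >= 2 and nx.is_connected(g):
            graphs.append(nx.to_numpy_array(g))
    return graphs
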