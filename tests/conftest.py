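import numpy as np
import pytest

from ziln import (
    CountMatrix,
    GraphTruth,
    ZiLNConfig,
    generate_counts,
    graph_to_precision,
    make_graph,
)


@pytest.fixture
def er_graph():
    return make_graph("erdos_renyi", p=20, e=20, seed=11)


@pytest.fixture
def single_edge_system():
    """A 3-variable system with one true conditional dependence (0, 1)."""
    prec = np.array([[1.0, 0.5, 0.0], [0.5, 1.0, 0.0], [0.0, 0.0, 1.0]])
    cov = np.linalg.inv(prec)
    adj = (np.abs(prec) > 0).astype(int) - np.eye(3, dtype=int)
    truth = GraphTruth(adjacency=adj, topology="erdos_renyi", edge_count=1)
    return truth, prec, cov


@pytest.fixture
def small_counts():
    """A small zero-inflated count matrix with ground truth."""
    graph = make_graph("erdos_renyi", p=10, e=10, seed=3)
    cov = graph_to_precision(graph, kappa=100.0, seed=3)
    rng = np.random.default_rng(3)
    mu = rng.uniform(0, 3, size=10)
    cfg = ZiLNConfig(mu=mu, delta=mu - 0.5, n=60, libsize_mean=1e5, seed=3)
    return graph, cov, generate_counts(graph, cov, cfg)


@pytest.fixture
def zero_free_counts():
    rng = np.random.default_rng(7)
    counts = rng.integers(1, 500, size=(40, 6))
    return CountMatrix.from_array(counts)
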