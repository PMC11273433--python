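import numpy as np
import pytest

from hemograph.graphs import RegionGraph, pad_graph


@pytest.fixture
def rng():
    return np.random.default_rng(0)


def random_adjacency(rng, n, p=0.5):
    """Random symmetric 0/1 adjacency with zero diagonal and >= 1 edge."""
    W = (rng.random((n, n)) < p).astype(float)
    W = np.triu(W, 1)
    W = W + W.T
    if W.sum() == 0:
        W[0, 1] = W[1, 0] = 1.0
    return W


def random_region_graph(rng, n, label=None, pad_to=None):
    g = RegionGraph(
        X=rng.random((n, 1)),
        W=random_adjacency(rng, n),
        label=label,
    )
    if pad_to is not None:
        g = pad_graph(g, pad_to)
    return g


@pytest.fixture
def graph_factory():
    return random_region_graph
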