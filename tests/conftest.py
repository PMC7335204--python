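import numpy as np
import pytest

from restgraph.core import WeightedGraph


@pytest.fixture
def rng():
    return np.random.default_rng(20250922)


@pytest.fixture
def chain3():
    """3-node chain A-B, B-C with weight 0.5 each, A-C absent."""
    w = np.array([[0.0, 0.5, 0.0], [0.5, 0.0, 0.5], [0.0, 0.5, 0.0]])
    return WeightedGraph(w, ["A", "B", "C"])


@pytest.fixture
def uniform_complete():
    def make(n: int, weight: float = 0.5) -> WeightedGraph:
        w = np.full((n, n), weight)
        np.fill_diagonal(w, 0.0)
        return WeightedGraph(w)

    return make


@pytest.fixture
def star_ring():
    """12-node star (center-leaf weight 1.0) plus weak leaf ring (0.1)."""
    n = 12
    w = np.zeros((n, n))
    for leaf in range(1, n):
        w[0, leaf] = w[leaf, 0] = 1.0
    leaves = list(range(1, n))
    for idx, leaf in enumerate(leaves):
        nxt = leaves[(idx + 1) % len(leaves)]
        w[leaf, nxt] = w[nxt, leaf] = 0.1
    return WeightedGraph(w)
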