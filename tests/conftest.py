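import numpy as np
import pytest

from fcgraph import BinaryGraph

from oracles import random_adjacency


@pytest.fixture
def rng():
    return np.random.default_rng(20260930)


@pytest.fixture
def small_random_graphs(rng):
    """A varied batch of small random graphs (N <= 10), some fragmented."""
    graphs = []
    for _ in range(60):
        n = int(rng.integers(3, 11))
        p = float(rng.uniform(0.1, 0.9))
        graphs.append(BinaryGraph(random_adjacency(rng, n, p)))
    return graphs
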