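import numpy as np
import pytest

from apmnet import gnn_layers
from apmnet.fixtures import make_random_molecule
from apmnet.molgraph import mol_to_graph


@pytest.fixture
def rng():
    return np.random.default_rng(1234)


def random_graph(rng, n_max=12, d=4, ensure_edges=True):
    """Small random undirected graph as (X, edge_index, n, d)."""
    n = int(rng.integers(2, n_max + 1))
    pairs = [(i, j) for i in range(n) for j in range(i + 1, n)]
    keep = [p for p in pairs if rng.random() < 0.4]
    if ensure_edges and not keep:
        keep = [pairs[0]]
    src = [p[0] for p in keep] + [p[1] for p in keep]
    dst = [p[1] for p in keep] + [p[0] for p in keep]
    edge_index = np.array([src, dst], dtype=np.int64)
    X = rng.normal(size=(n, d))
    return X, edge_index, n, d


@pytest.fixture
def small_molecule():
    return make_random_molecule(10, ("C", "N", "O"), seed=42)


@pytest.fixture
def small_graph(small_molecule):
    return mol_to_graph(small_molecule)
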