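import sys
from pathlib import Path

import networkx as nx
import numpy as np
import pytest

sys.path.insert(0, str(Path(__file__).parent))  # make oracles importable

from fosnet.regions import default_region_set


@pytest.fixture(scope="session")
def regions24():
    return default_region_set()


def _random_graph(n, p, seed):
    rng = np.random.default_rng(seed)
    G = nx.Graph()
    G.add_nodes_from(range(n))
    for i in range(n):
        for j in range(i + 1, n):
            if rng.random() < p:
                G.add_edge(i, j)
    return G


@pytest.fixture(scope="session")
def small_graphs():
    """Fixture graphs with <= 7 nodes for exhaustive oracle checks."""
    graphs = {
        "path3": nx.path_graph(3),
        "path5": nx.path_graph(5),
        "star4": nx.star_graph(3),
        "cycle5": nx.cycle_graph(5),
        "complete5": nx.complete_graph(5),
        "two_triangles": nx.Graph([(0, 1), (1, 2), (2, 0), (3, 4), (4, 5), (5, 3), (2, 3)]),
    }
    for k, seed in enumerate((11, 12, 13)):
        graphs[f"random7_{k}"] = _random_graph(7, 0.45, seed)
    return graphs


@pytest.fixture(scope="session")
def small_weighted_graphs(small_graphs):
    """Same topologies with random positive 'distance' edge weights."""
    out = {}
    rng = np.random.default_rng(7)
    for name, G in small_graphs.items():
        H = G.copy()
        for u, v in H.edges():
            H[u][v]["distance"] = float(rng.uniform(0.2, 2.0))
        out[name] = H
    return out


def random_stable_system(rng, n=None):
    """Random nonnegative adjacency, stabilized, with random states."""
    from fosnet.control import normalize_system

    if n is None:
        n = int(rng.integers(2, 6))
    A = rng.uniform(0, 1, size=(n, n)) * (rng.random((n, n)) < 0.7)
    np.fill_diagonal(A, 0.0)
    Astar = normalize_system(A)
    x0 = rng.normal(size=n)
    xf = rng.normal(size=n)
    return Astar, x0, xf
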