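"""Shared fixtures and independent oracles for the test suite.

The oracles here deliberately avoid the library's own computation paths:
brute-force Wiener sums walk the full distance matrix via networkx, and the
ARI oracle evaluates the contingency-table formula directly.
"""

from math import comb

import networkx as nx
import numpy as np
import pytest
from hypothesis import settings

from fwiener import builtin_catalog, make_special

settings.register_profile("ci", derandomize=True, max_examples=50)
settings.load_profile("ci")


@pytest.fixture(scope="session")
def catalog():
    return builtin_catalog()


@pytest.fixture()
def p4():
    return make_special("path", 4)


@pytest.fixture()
def s5():
    return make_special("star", 5)


def brute_force_wiener(g: nx.Graph, f) -> float:
    """Sum f(d(u,v)) over all unordered pairs from the full networkx
    shortest-path dict; independent of the package's BFS/count path."""
    lengths = dict(nx.all_pairs_shortest_path_length(g))
    nodes = sorted(g.nodes)
    total = 0.0
    for i, u in enumerate(nodes):
        for v in nodes[i + 1 :]:
            total += f(lengths[u][v])
    return total


def ari_oracle(a, b) -> float:
    """Adjusted Rand Index straight from the contingency-table formula."""
    a = np.asarray(a)
    b = np.asarray(b)
    ua, ai = np.unique(a, return_inverse=True)
    ub, bi = np.unique(b, return_inverse=True)
    table = np.zeros((ua.size, ub.size), dtype=int)
    for x, y in zip(ai, bi):
        table[x, y] += 1
    sum_ij = sum(comb(int(v), 2) for v in table.ravel())
    sum_a = sum(comb(int(v), 2) for v in table.sum(axis=1))
    sum_b = sum(comb(int(v), 2) for v in table.sum(axis=0))
    total = comb(a.size, 2)
    expected = sum_a * sum_b / total
    maximum = (sum_a + sum_b) / 2
    if maximum == expected:
        return 1.0 if sum_ij == maximum else 0.0
    return (sum_ij - expected) / (maximum - expected)


def random_connected_graph(rng: np.random.Generator, n: int, p: float = 0.35) -> nx.Graph:
    """Connected G(n, p) sample for oracle cross-checks."""
    iu, ju = np.triu_indices(n, k=1)
    while True:
        mask = rng.random(iu.size) < p
        g = nx.Graph()
        g.add_nodes_from(range(n))
        g.add_edges_from(zip(iu[mask].tolist(), ju[mask].tolist()))
        if n <= 1 or nx.is_connected(g):
            return g


def random_labeled_tree(rng: np.random.Generator, n: int) -> nx.Graph:
    """Uniform labeled tree via a random Prüfer sequence."""
    if n == 2:
        seq = []
    else:
        seq = rng.integers(0, n, size=n - 2).tolist()
    return nx.from_prufer_sequence(seq) if seq or n > 2 else nx.path_graph(2)
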