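"""Graph construction, validation, distance distributions and file I/O.

Graphs are plain :class:`networkx.Graph` objects with nodes labelled
``0..n-1``.  Every graph produced by this module is *simple* (no self-loops,
no parallel edges) and frozen, so downstream index computations can treat it
as immutable.  The central derived object is the :class:`DistanceSummary`:
the counts ``D_k`` of unordered node pairs at shortest-path distance exactly
``k``.  These counts are a sufficient statistic for every distance-based
index of the form ``sum f(d(u, v))`` over pairs, so they are computed once
per graph and reused.
"""

from __future__ import annotations

from dataclasses import dataclass

import networkx as nx
import numpy as np
from scipy.sparse import csr_array
from scipy.sparse.csgraph import connected_components, shortest_path

__all__ = [
    "DistanceSummary",
    "make_special",
    "distance_summary",
    "is_connected",
    "is_tree",
    "max_degree",
    "read_edge_list",
    "write_edge_list",
    "read_graphml",
    "write_graphml",
    "validate_simple",
]

SPECIAL_FAMILIES = ("path", "star", "complete", "caterpillar", "broom", "kite")


class GraphFormatError(ValueError):
    """Raised for malformed or invalid graph input files."""


@dataclass(frozen=True)
class DistanceSummary:
    """Counts of unordered node pairs by shortest-path distance.

    Attributes
    ----------
    pair_counts:
        ``pair_counts[k]`` is the number of unordered pairs ``{u, v}`` with
        ``d(u, v) == k``; keys run from 1 to the diameter with no gaps.
    node_count:
        Number of nodes in the source graph.
    """

    pair_counts: dict[int, int]
    node_count: int

    def __post_init__(self) -> None:
        n = self.node_count
        if sum(self.pair_counts.values()) != n * (n - 1) // 2:
            raise ValueError("pair counts do not cover all unordered pairs")
        if self.pair_counts and sorted(self.pair_counts) != list(
            range(1, max(self.pair_counts) + 1)
        ):
            raise ValueError("distance keys must be contiguous from 1")

    @property
    def diameter(self) -> int:
        return max(self.pair_counts, default=0)

    def as_arrays(self) -> tuple[np.ndarray, np.ndarray]:
        """Distances and counts as aligned integer arrays."""
        ks = np.arange(1, self.diameter + 1)
        cs = np.array([self.pair_counts[int(k)] for k in ks], dtype=np.int64)
        return ks, cs


def _finish(g: nx.Graph) -> nx.Graph:
    nx.freeze(g)
    return g


def validate_simple(g: nx.Graph) -> None:
    """Raise if *g* is not a simple graph on nodes ``0..n-1``."""
    n = g.number_of_nodes()
    if set(g.nodes) != set(range(n)):
        raise ValueError("nodes must be integers 0..n-1")
    if any(u == v for u, v in g.edges):
        raise ValueError("self-loops are not allowed")


def make_special(family: str, n: int, param: int | None = None) -> nx.Graph:
    """Construct one of the special families: path, star, complete,
    caterpillar, broom, kite.

    Parameters
    ----------
    family:
        Family name.  ``caterpillar`` takes ``param`` = leaves per spine node
        (t >= 1); ``broom`` takes ``param`` = pendant-leaf count
        (1 <= l <= n-2); ``kite`` takes ``param`` = clique size
        (3 <= c <= n-1).
    n:
        Total node count (>= 1).

    Notes
    -----
    The broom ``B(n, l)`` is a path spine on ``n - l`` nodes with ``l``
    pendant leaves attached to one terminal spine node, so that node has
    degree ``l + 1``; the broom with maximum degree ``D`` is ``broom(n, D-1)``.
    The caterpillar has a spine path of ``ceil(n / (t+1))`` nodes, each
    carrying ``t`` leaves except possibly the last spine node, which carries
    the remainder.
    """
    if n < 1:
        raise ValueError(f"n must be >= 1, got {n}")
    if family in ("path", "star", "complete") and param is not None:
        raise ValueError(f"{family} takes no extra parameter")

    if family == "path":
        return _finish(nx.path_graph(n))
    if family == "star":
        # star(1), star(2) degenerate to P1, P2
        g = nx.Graph()
        g.add_nodes_from(range(n))
        g.add_edges_from((0, i) for i in range(1, n))
        return _finish(g)
    if family == "complete":
        return _finish(nx.complete_graph(n))
    if family == "caterpillar":
        if param is None or param < 1:
            raise ValueError("caterpillar requires leaves-per-spine-node t >= 1")
        t = param
        s = -(-n // (t + 1))  # ceil
        g = nx.path_graph(s)
        nxt = s
        for spine in range(s):
            want = t if spine < s - 1 else n - s - (s - 1) * t
            for _ in range(want):
                g.add_edge(spine, nxt)
                nxt += 1
        assert nxt == n
        return _finish(g)
    if family == "broom":
        if param is None or not 1 <= param <= n - 2:
            raise ValueError("broom requires pendant-leaf count 1 <= l <= n-2")
        ell = param
        spine = n - ell
        g = nx.path_graph(spine)
        g.add_edges_from((spine - 1, spine + i) for i in range(ell))
        return _finish(g)
    if family == "kite":
        if param is None or not 3 <= param <= n - 1:
            raise ValueError("kite requires clique size 3 <= c <= n-1")
        c = param
        g = nx.complete_graph(c)
        g.add_edges_from((i, i + 1) for i in range(c, n - 1))
        g.add_edge(c - 1, c)  # bridge: clique node to path end
        return _finish(g)
    raise ValueError(f"unknown family {family!r}; expected one of {SPECIAL_FAMILIES}")


def _adjacency(g: nx.Graph) -> csr_array:
    n = g.number_of_nodes()
    if g.number_of_edges() == 0:
        return csr_array((n, n), dtype=np.int8)
    e = np.array(g.edges, dtype=np.int64)
    rows = np.concatenate([e[:, 0], e[:, 1]])
    cols = np.concatenate([e[:, 1], e[:, 0]])
    data = np.ones(rows.size, dtype=np.int8)
    return csr_array((data, (rows, cols)), shape=(n, n))


def is_connected(g: nx.Graph) -> bool:
    """True iff every node is reachable from node 0."""
    n = g.number_of_nodes()
    if n <= 1:
        return True
    ncomp = connected_components(_adjacency(g), directed=False, return_labels=False)
    return int(ncomp) == 1


def is_tree(g: nx.Graph) -> bool:
    return is_connected(g) and g.number_of_edges() == g.number_of_nodes() - 1


def max_degree(g: nx.Graph) -> int:
    """Maximum node degree Delta(G)."""
    return max((d for _, d in g.degree), default=0)


def distance_summary(g: nx.Graph) -> DistanceSummary:
    """All-pairs shortest-path distance distribution of a connected graph.

    Uses unweighted BFS from every node (via ``scipy.sparse.csgraph``) and
    tallies each unordered pair once.  Raises ``ValueError`` when some pair
    is unreachable.
    """
    n = g.number_of_nodes()
    if n <= 1:
        return DistanceSummary({}, n)
    dmat = shortest_path(_adjacency(g), method="D", directed=False, unweighted=True)
    iu = np.triu_indices(n, k=1)
    dists = dmat[iu]
    if np.isinf(dists).any():
        raise ValueError("graph is disconnected: some pair has no path")
    counts = np.bincount(dists.astype(np.int64))
    return DistanceSummary(
        {int(k): int(c) for k, c in enumerate(counts) if k >= 1 and c > 0}, n
    )


# ---------------------------------------------------------------------------
# File I/O


def read_edge_list(path: str) -> nx.Graph:
    """Read a whitespace/tab-separated two-column edge list.

    Lines starting with ``#`` are ignored.  Labels are arbitrary strings,
    mapped to indices 0..n-1 in order of first appearance.  Self-loops and
    duplicate edges are rejected.
    """
    index: dict[str, int] = {}
    edges: set[tuple[int, int]] = set()
    with open(path) as fh:
        for lineno, line in enumerate(fh, start=1):
            line = line.strip()
            if not line or line.startswith("#"):
                continue
            parts = line.split()
            if len(parts) != 2:
                raise GraphFormatError(
                    f"{path}:{lineno}: expected two labels, got {len(parts)}"
                )
            a, b = parts
            if a == b:
                raise GraphFormatError(f"{path}:{lineno}: self-loop on {a!r}")
            for lab in (a, b):
                if lab not in index:
                    index[lab] = len(index)
            u, v = sorted((index[a], index[b]))
            if (u, v) in edges:
                raise GraphFormatError(f"{path}:{lineno}: duplicate edge {a!r}-{b!r}")
            edges.add((u, v))
    g = nx.Graph()
    g.add_nodes_from(range(len(index)))
    g.add_edges_from(edges)
    return _finish(g)


def write_edge_list(g: nx.Graph, path: str) -> None:
    with open(path, "w") as fh:
        for u, v in sorted(tuple(sorted(e)) for e in g.edges):
            fh.write(f"{u}\t{v}\n")


def read_graphml(path: str) -> nx.Graph:
    """Read an undirected GraphML file, dropping attributes."""
    raw = nx.read_graphml(path)
    if raw.is_directed():
        raw = raw.to_undirected()
    mapping = {lab: i for i, lab in enumerate(raw.nodes)}
    g = nx.Graph()
    g.add_nodes_from(range(len(mapping)))
    g.add_edges_from(
        (mapping[u], mapping[v]) for u, v in raw.edges if mapping[u] != mapping[v]
    )
    return _finish(g)


def write_graphml(g: nx.Graph, path: str) -> None:
    plain = nx.Graph()
    plain.add_nodes_from(g.nodes)
    plain.add_edges_from(g.edges)
    nx.write_graphml(plain, path)
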