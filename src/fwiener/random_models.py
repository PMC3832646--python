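"""Random network generators conditioned on connectivity.

Three models, all fully seeded and all retried until a connected graph
appears:

* ``er_connected`` -- Erdős–Rényi G(n, p): each edge present independently
  with probability p.
* ``preferential_attachment`` -- growth model: start from a single node;
  each arriving node attaches m edges (fewer while fewer than m nodes
  exist) to distinct existing nodes chosen with probability proportional to
  degree + 1.  The +1 keeps early isolated nodes reachable and yields a
  right-skewed (scale-free-like) degree distribution.
* ``geometric3d`` -- 3-D geometric model: n points uniform in the unit
  cube; the floor(q * C(n,2)) closest pairs by Euclidean distance are
  connected (ties at the cutoff broken by pair index order).

A global seed expands into per-graph child seeds by fixed arithmetic
(:func:`child_seed`), so any single graph is reproducible in isolation.
"""

from __future__ import annotations

from dataclasses import dataclass

import networkx as nx
import numpy as np
from scipy.spatial.distance import pdist

from .graphs import is_connected

__all__ = [
    "ModelConfig",
    "child_seed",
    "er_connected",
    "preferential_attachment",
    "geometric3d",
    "generate",
]

_MAX_RETRIES = 500
_SEED_MOD = 2**31 - 1


@dataclass(frozen=True)
class ModelConfig:
    """Configuration for one random-network draw.

    model: 'er' (p = edge probability), 'sf' (m = edges per arriving node)
    or 'ge' (q = fraction of closest pairs connected).
    """

    model: str
    n: int
    p: float | None = None
    m: int | None = None
    q: float | None = None
    seed: int = 0
    max_retries: int = _MAX_RETRIES

    def __post_init__(self) -> None:
        if self.model not in ("er", "sf", "ge"):
            raise ValueError(f"unknown model {self.model!r}")
        if self.n < 1:
            raise ValueError("n must be positive")
        if self.model == "er" and not (self.p is not None and 0 < self.p <= 1):
            raise ValueError("er requires 0 < p <= 1")
        if self.model == "sf" and not (self.m is not None and 1 <= self.m < self.n):
            raise ValueError("sf requires 1 <= m < n")
        if self.model == "ge" and not (self.q is not None and 0 < self.q <= 1):
            raise ValueError("ge requires 0 < q <= 1")


def child_seed(base_seed: int, *indices: int) -> int:
    """Deterministic per-graph seed derived from a base seed and indices."""
    s = int(base_seed) % _SEED_MOD
    for idx in indices:
        s = (s * 1_000_003 + int(idx) + 1) % _SEED_MOD
    return s


def _graph_from_pairs(n: int, rows: np.ndarray, cols: np.ndarray) -> nx.Graph:
    g = nx.Graph()
    g.add_nodes_from(range(n))
    g.add_edges_from(zip(rows.tolist(), cols.tolist()))
    nx.freeze(g)
    return g


def er_connected(cfg: ModelConfig) -> nx.Graph:
    """Draw G(n, p) repeatedly until connected."""
    if cfg.model != "er":
        raise ValueError("config is not an ER config")
    rng = np.random.default_rng(cfg.seed)
    iu, ju = np.triu_indices(cfg.n, k=1)
    for _ in range(cfg.max_retries):
        mask = rng.random(iu.size) < cfg.p
        g = _graph_from_pairs(cfg.n, iu[mask], ju[mask])
        if is_connected(g):
            return g
    raise RuntimeError(f"no connected ER graph in {cfg.max_retries} tries: {cfg}")


def preferential_attachment(cfg: ModelConfig) -> nx.Graph:
    """Grow a scale-free network by degree+1 preferential attachment."""
    if cfg.model != "sf":
        raise ValueError("config is not an SF config")
    rng = np.random.default_rng(cfg.seed)
    n, m = cfg.n, cfg.m
    weights = np.zeros(n, dtype=np.float64)  # degree + 1, over existing nodes
    weights[0] = 1.0
    edges: list[tuple[int, int]] = []
    for new in range(1, n):
        k = min(m, new)
        w = weights[:new]
        targets = rng.choice(new, size=k, replace=False, p=w / w.sum())
        for t in targets:
            edges.append((int(t), new))
            weights[t] += 1.0
        weights[new] = 1.0 + k
    g = nx.Graph()
    g.add_nodes_from(range(n))
    g.add_edges_from(edges)
    nx.freeze(g)
    return g


def geometric3d(cfg: ModelConfig) -> nx.Graph:
    """3-D geometric model: connect the closest q-fraction of pairs."""
    if cfg.model != "ge":
        raise ValueError("config is not a GE config")
    n = cfg.n
    n_pairs = n * (n - 1) // 2
    n_edges = int(cfg.q * n_pairs)
    if n > 1 and n_edges < n - 1:
        raise ValueError(f"q={cfg.q} allows only {n_edges} edges < n-1; cannot connect")
    rng = np.random.default_rng(cfg.seed)
    iu, ju = np.triu_indices(n, k=1)
    for _ in range(cfg.max_retries):
        points = rng.random((n, 3))
        order = np.argsort(pdist(points), kind="stable")[:n_edges]
        g = _graph_from_pairs(n, iu[order], ju[order])
        if is_connected(g):
            return g
    raise RuntimeError(f"no connected GE graph in {cfg.max_retries} tries: {cfg}")


_DISPATCH = {
    "er": er_connected,
    "sf": preferential_attachment,
    "ge": geometric3d,
}


def generate(cfg: ModelConfig) -> nx.Graph:
    """Dispatch on ``cfg.model``."""
    return _DISPATCH[cfg.model](cfg)
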