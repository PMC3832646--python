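"""Sharp extremal values of W_f and the normalized index N_f in [0, 1].

Over all connected graphs on n nodes, a non-decreasing f is minimized by the
complete graph K_n and maximized by the path P_n; over trees, the star S_n
replaces K_n as the minimizer.  For non-increasing f the roles swap.  The
closed forms are::

    path_value(n, f)     = sum_{k=1}^{n-1} (n - k) f(k)
    star_value(n, f)     = (n - 1) f(1) + (n - 1)(n - 2)/2 * f(2)
    complete_value(n, f) = n(n - 1)/2 * f(1)

The normalized index is anchored so that the *path* maps to 0 and the
densest graph in the domain (complete graph over graphs, star over trees)
maps to 1, irrespective of f's monotonicity direction::

    N_f(G) = (W_f(G) - path_value) / (dense_value - path_value)

so N_f reads as "how far from path-like toward densest-like".  This
orientation (rather than min -> 0, max -> 1) keeps the scale comparable
across increasing and decreasing f.
"""

from __future__ import annotations

from dataclasses import dataclass

import networkx as nx

from .functions import NON_DECREASING, IndexFunction, function_by_name
from .graphs import is_tree, make_special
from .indices import f_wiener

__all__ = [
    "ExtremalPair",
    "NormalizedIndexResult",
    "path_value",
    "star_value",
    "complete_value",
    "extremes",
    "normalized_index",
    "normalized_from_value",
    "degree_constrained_max",
    "classical_bounds",
]

_CLAMP_TOL = 1e-12


@dataclass(frozen=True)
class ExtremalPair:
    min_value: float
    max_value: float
    minimizer_family: str
    maximizer_family: str
    domain: str
    n: int


@dataclass(frozen=True)
class NormalizedIndexResult:
    value: float
    function_name: str
    domain: str


def _check_domain(domain: str) -> None:
    if domain not in ("graphs", "trees"):
        raise ValueError(f"domain must be 'graphs' or 'trees', got {domain!r}")


def path_value(n: int, f: IndexFunction) -> float:
    """W_f of the path P_n: there are n-k pairs at distance k."""
    if n < 2:
        raise ValueError("n must be >= 2")
    return sum((n - k) * f(k) for k in range(1, n))


def star_value(n: int, f: IndexFunction) -> float:
    """W_f of the star S_n: n-1 spokes at distance 1, C(n-1,2) leaf pairs at 2."""
    if n < 2:
        raise ValueError("n must be >= 2")
    val = (n - 1) * f(1)
    if n > 2:
        val += (n - 1) * (n - 2) // 2 * f(2)
    return val


def complete_value(n: int, f: IndexFunction) -> float:
    """W_f of the complete graph K_n: all C(n,2) pairs at distance 1."""
    if n < 2:
        raise ValueError("n must be >= 2")
    return n * (n - 1) // 2 * f(1)


def extremes(n: int, f: IndexFunction, domain: str) -> ExtremalPair:
    """Sharp min and max of W_f over connected graphs or trees on n nodes.

    Requires n >= 3 for graphs and n >= 4 for trees; below that the extremal
    families coincide and normalization would divide by zero.
    """
    _check_domain(domain)
    min_n = 3 if domain == "graphs" else 4
    if n < min_n:
        raise ValueError(f"extremes over {domain} requires n >= {min_n}")
    pv = path_value(n, f)
    dense = complete_value(n, f) if domain == "graphs" else star_value(n, f)
    dense_family = "complete" if domain == "graphs" else "star"
    if pv == dense:
        raise ValueError(f"{f.name}: constant on 1..{n - 1}; extremes degenerate")
    if f.direction == NON_DECREASING:
        return ExtremalPair(dense, pv, dense_family, "path", domain, n)
    return ExtremalPair(pv, dense, "path", dense_family, domain, n)


def normalized_from_value(
    w: float, n: int, f: IndexFunction, domain: str
) -> NormalizedIndexResult:
    """Normalize a precomputed W_f value (see module docstring for anchoring)."""
    _check_domain(domain)
    ext = extremes(n, f, domain)  # also validates n and non-degeneracy
    a = path_value(n, f)
    b = complete_value(n, f) if domain == "graphs" else star_value(n, f)
    value = (w - a) / (b - a)
    if not -_CLAMP_TOL <= value <= 1 + _CLAMP_TOL:
        raise ValueError(
            f"W_f={w} outside extremal range [{ext.min_value}, {ext.max_value}]"
        )
    return NormalizedIndexResult(min(1.0, max(0.0, value)), f.name, domain)


def normalized_index(g: nx.Graph, f: IndexFunction, domain: str) -> NormalizedIndexResult:
    """Normalized f-Wiener index N_f(G) in [0, 1].

    ``domain='trees'`` demands that g is a tree and normalizes against the
    tree extremes (path -> 0, star -> 1); ``domain='graphs'`` normalizes
    against all connected graphs (path -> 0, complete -> 1).
    """
    _check_domain(domain)
    if domain == "trees" and not is_tree(g):
        raise ValueError("tree-domain normalization requires a tree")
    w = f_wiener(g, f)
    return normalized_from_value(w.value, w.node_count, f, domain)


def degree_constrained_max(
    n: int, delta: int, f: IndexFunction, domain: str = "trees"
) -> tuple[float, nx.Graph]:
    """Maximum of W_f over trees on n nodes with maximum degree delta.

    Attained by the broom with delta - 1 pendant leaves; for delta = 2 this
    is the path and for delta = n - 1 the star, recovering the unconstrained
    tree extremes.  Returns the value and the extremal broom.  Graph-domain
    behaviour is certified only empirically (see the enumeration module).
    """
    _check_domain(domain)
    if not 2 <= delta <= n - 1:
        raise ValueError(f"need 2 <= delta <= n-1, got delta={delta}, n={n}")
    if f.direction != NON_DECREASING:
        raise ValueError("degree-constrained maximum is stated for non-decreasing f")
    broom = make_special("broom", n, delta - 1)
    return f_wiener(broom, f).value, broom


def classical_bounds(n: int, index_name: str, domain: str) -> ExtremalPair:
    """Extremal pair for a named classical index (wiener, harary,
    hyper_wiener, generalized:alpha)."""
    return extremes(n, function_by_name(index_name), domain)
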