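"""f-Wiener index computation: W_f(G) = sum_{u<v} f(d(u,v)).

Computed as ``sum_k D_k * f(k)`` from the distance distribution, so a graph
is traversed once regardless of how many indices are evaluated on it.
Integer-valued functions on integer counts accumulate exactly (Python ints)
so classical Wiener values are bit-exact.
"""

from __future__ import annotations

from dataclasses import dataclass

import networkx as nx

from .functions import IndexFunction, function_by_name
from .graphs import DistanceSummary, distance_summary

__all__ = ["IndexValue", "f_wiener", "f_wiener_from_summary", "hosoya_eval", "named_index"]


@dataclass(frozen=True)
class IndexValue:
    value: float
    function_name: str
    node_count: int


def f_wiener_from_summary(ds: DistanceSummary, f: IndexFunction) -> IndexValue:
    """Evaluate W_f from precomputed distance counts."""
    if ds.node_count < 2:
        raise ValueError("W_f requires at least 2 nodes")
    total: float = 0
    for k, c in ds.pair_counts.items():
        total += c * f(k)
    return IndexValue(total, f.name, ds.node_count)


def f_wiener(g: nx.Graph, f: IndexFunction) -> IndexValue:
    """The f-Wiener index of a connected graph g."""
    return f_wiener_from_summary(distance_summary(g), f)


def hosoya_eval(g: nx.Graph, q: float) -> float:
    """Hosoya (Wiener) polynomial H(q) = sum_k D_k q^k.

    H(1) equals the number of unordered pairs C(n,2); H'(1) is the Wiener
    index.
    """
    ds = distance_summary(g)
    return float(sum(c * q ** k for k, c in ds.pair_counts.items()))


def named_index(g: nx.Graph, name: str) -> IndexValue:
    """Compute a classical index by name: ``wiener``, ``harary``,
    ``hyper_wiener`` or ``generalized:alpha``."""
    return f_wiener(g, function_by_name(name))
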