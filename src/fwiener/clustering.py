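"""Characteristic vectors, Ward clustering and the Adjusted Rand Index.

Each graph in a collection is summarized by a vector of its seven catalog
index values -- either raw W_f values or normalized N_f values in [0, 1].
Collections of vectors are clustered by Ward's minimum-variance method on
Euclidean distances (scipy linkage), dendrograms are cut at a requested
cluster count, and partitions are scored against truth labels with the ARI.

No feature standardization is applied before Ward: the scale domination of
raw vectors by the largest index is exactly the size effect normalization
is meant to remove, so rescaling raw vectors would hide the phenomenon
under study, and normalized entries already share the [0, 1] scale.
"""

from __future__ import annotations

from dataclasses import dataclass

import networkx as nx
import numpy as np
from scipy.cluster.hierarchy import cut_tree, linkage
from sklearn.metrics import adjusted_rand_score

from .bounds import normalized_from_value
from .functions import IndexFunction
from .graphs import distance_summary
from .indices import f_wiener_from_summary

__all__ = [
    "CharacteristicVector",
    "characteristic_vector",
    "ward_linkage",
    "cut_k",
    "adjusted_rand_index",
]


@dataclass(frozen=True)
class CharacteristicVector:
    values: tuple[float, ...]
    graph_id: str
    normalized: bool


def characteristic_vector(
    g: nx.Graph,
    catalog: list[IndexFunction],
    normalized: bool,
    domain: str = "graphs",
    graph_id: str = "",
) -> CharacteristicVector:
    """Index vector of a graph in catalog order (raw W_f or normalized N_f)."""
    ds = distance_summary(g)
    vals = []
    for f in catalog:
        w = f_wiener_from_summary(ds, f)
        if normalized:
            vals.append(normalized_from_value(w.value, w.node_count, f, domain).value)
        else:
            vals.append(w.value)
    return CharacteristicVector(tuple(vals), graph_id, normalized)


def _as_matrix(vectors: list[CharacteristicVector] | np.ndarray) -> np.ndarray:
    if isinstance(vectors, np.ndarray):
        x = np.asarray(vectors, dtype=np.float64)
    else:
        x = np.array([v.values for v in vectors], dtype=np.float64)
    if x.ndim != 2:
        raise ValueError("expected a 2-D collection of equal-length vectors")
    return x


def ward_linkage(vectors: list[CharacteristicVector] | np.ndarray) -> np.ndarray:
    """Ward minimum-variance linkage on Euclidean distances.

    Returns the standard (n-1, 4) merge matrix: cluster ids, merge height,
    merged size.  Deterministic given the input order.
    """
    x = _as_matrix(vectors)
    if x.shape[0] < 2:
        raise ValueError("need at least 2 vectors")
    return linkage(x, method="ward")


def cut_k(tree: np.ndarray, k: int) -> np.ndarray:
    """Labels from cutting a linkage tree into exactly k clusters.

    Labels are renumbered to 0..k-1 in order of first appearance.
    """
    n = tree.shape[0] + 1
    if not 1 <= k <= n:
        raise ValueError(f"k must be in 1..{n}, got {k}")
    raw = cut_tree(tree, n_clusters=k).ravel()
    _, labels = np.unique(raw, return_index=False, return_inverse=True)
    order = {}
    out = np.empty_like(labels)
    for i, lab in enumerate(labels):
        out[i] = order.setdefault(int(lab), len(order))
    return out


def adjusted_rand_index(a, b) -> float:
    """Chance-corrected pair-counting agreement between two partitions.

    1 for identical partitions, expectation 0 under independent random
    labelling.  Degenerate case (both partitions trivial, zero denominator):
    returns 1.0 if the partitions are identical up to relabeling, else 0.0.
    """
    a = np.asarray(a)
    b = np.asarray(b)
    if a.shape != b.shape or a.ndim != 1:
        raise ValueError("label arrays must be 1-D and of equal length")
    if a.size < 2:
        raise ValueError("need at least 2 items")
    a_trivial = len(np.unique(a)) in (1, a.size)
    b_trivial = len(np.unique(b)) in (1, b.size)
    if a_trivial and b_trivial:
        same = len(np.unique(a)) == len(np.unique(b))
        return 1.0 if same else 0.0
    return float(adjusted_rand_score(a, b))
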