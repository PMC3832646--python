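"""Exhaustive small-graph enumeration certifying the extremal results.

Labeled trees on n nodes are enumerated through the Prüfer bijection
(n^(n-2) trees, practical up to n = 9); connected graphs are enumerated as
edge subsets of K_n (2^C(n,2) candidates, practical up to n = 6).
:func:`verify_extremal` scans an entire class, compares the empirical
extremes of W_f with the closed forms, and checks that every empirical
extremizer matches the predicted family (path / star / complete / broom) by
a degree-sequence + eccentricity fingerprint -- sufficient to separate
these families without a general isomorphism test.

Enumeration is labeled, not isomorphism-free: extremal-value certification
does not need canonical forms, and uniqueness is decided by the family
fingerprint.  Uniqueness assertions require strictly monotone f; weakly
monotone f create ties the characterizations presume away.
"""

from __future__ import annotations

import itertools
from collections import deque
from dataclasses import dataclass
from typing import Iterator

import networkx as nx

from .bounds import complete_value, path_value, star_value
from .functions import NON_DECREASING, IndexFunction
from .graphs import make_special

__all__ = [
    "VerificationReport",
    "enumerate_labeled_trees",
    "enumerate_connected_graphs",
    "verify_extremal",
    "certify_catalog",
]

_MAX_TREE_N = 9
_MAX_GRAPH_N = 6
_REL_TOL = 1e-9

Edges = tuple[tuple[int, int], ...]


@dataclass(frozen=True)
class VerificationReport:
    n: int
    domain: str
    function_name: str
    checked_count: int
    max_holds: bool
    min_holds: bool
    extremizer_unique: bool
    counterexamples: tuple[Edges, ...] = ()

    @property
    def ok(self) -> bool:
        return self.max_holds and self.min_holds and self.extremizer_unique

    def __post_init__(self) -> None:
        assert (len(self.counterexamples) == 0) == self.ok


def _prufer_to_edges(seq: tuple[int, ...], n: int) -> Edges:
    # classic decode: repeatedly join the smallest current leaf to the next
    # sequence entry; used leaves get degree 0 so they are never revisited
    degree = [1] * n
    for x in seq:
        degree[x] += 1
    edges = []
    ptr = 0
    leaf = -1
    for x in seq:
        if leaf == -1:
            while degree[ptr] != 1:
                ptr += 1
            leaf = ptr
        edges.append((leaf, x))
        degree[leaf] = 0
        degree[x] -= 1
        if degree[x] == 1 and x < ptr:
            leaf = x
        else:
            leaf = -1
    rest = [v for v in range(n) if degree[v] == 1]
    edges.append((rest[0], rest[1]))
    return tuple(edges)


def _tree_edges_iter(n: int) -> Iterator[Edges]:
    if not 2 <= n <= _MAX_TREE_N:
        raise ValueError(f"tree enumeration supports 2 <= n <= {_MAX_TREE_N}")
    if n == 2:
        yield ((0, 1),)
        return
    for seq in itertools.product(range(n), repeat=n - 2):
        yield _prufer_to_edges(seq, n)


def enumerate_labeled_trees(n: int) -> Iterator[nx.Graph]:
    """All n^(n-2) labeled trees on n nodes, one per Prüfer sequence."""
    for edges in _tree_edges_iter(n):
        g = nx.Graph()
        g.add_nodes_from(range(n))
        g.add_edges_from(edges)
        yield g


def _connected(n: int, adj: list[list[int]]) -> bool:
    seen = [False] * n
    seen[0] = True
    stack = [0]
    count = 1
    while stack:
        u = stack.pop()
        for v in adj[u]:
            if not seen[v]:
                seen[v] = True
                count += 1
                stack.append(v)
    return count == n


def _graph_edges_iter(n: int) -> Iterator[Edges]:
    if not 2 <= n <= _MAX_GRAPH_N:
        raise ValueError(f"graph enumeration supports 2 <= n <= {_MAX_GRAPH_N}")
    all_pairs = list(itertools.combinations(range(n), 2))
    for bits in range(1 << len(all_pairs)):
        edges = tuple(all_pairs[i] for i in range(len(all_pairs)) if bits >> i & 1)
        if len(edges) < n - 1:
            continue
        adj: list[list[int]] = [[] for _ in range(n)]
        for u, v in edges:
            adj[u].append(v)
            adj[v].append(u)
        if _connected(n, adj):
            yield edges


def enumerate_connected_graphs(n: int) -> Iterator[nx.Graph]:
    """All connected labeled simple graphs on n nodes (edge subsets of K_n)."""
    for edges in _graph_edges_iter(n):
        g = nx.Graph()
        g.add_nodes_from(range(n))
        g.add_edges_from(edges)
        yield g


def _distance_profile(n: int, edges: Edges) -> tuple[list[int], list[int]]:
    """(distance counts indexed by k-1, eccentricities) via BFS per source."""
    adj: list[list[int]] = [[] for _ in range(n)]
    for u, v in edges:
        adj[u].append(v)
        adj[v].append(u)
    counts = [0] * n
    ecc = [0] * n
    for src in range(n):
        dist = [-1] * n
        dist[src] = 0
        q = deque([src])
        while q:
            u = q.popleft()
            for v in adj[u]:
                if dist[v] < 0:
                    dist[v] = dist[u] + 1
                    q.append(v)
        ecc[src] = max(dist)
        for v in range(src + 1, n):
            counts[dist[v] - 1] += 1
    while counts and counts[-1] == 0:
        counts.pop()
    return counts, ecc


def _fingerprint(n: int, edges: Edges) -> tuple:
    deg = [0] * n
    for u, v in edges:
        deg[u] += 1
        deg[v] += 1
    _, ecc = _distance_profile(n, edges)
    return tuple(sorted(deg)), tuple(sorted(ecc))


def _family_fingerprint(family: str, n: int, param: int | None = None) -> tuple:
    g = make_special(family, n, param)
    return _fingerprint(n, tuple(g.edges))


def _is_strict(f: IndexFunction, upto: int) -> bool:
    vals = [f(k) for k in range(1, upto + 2)]
    return all(a != b for a, b in zip(vals, vals[1:]))


def verify_extremal(
    n: int, f: IndexFunction, domain: str, delta: int | None = None
) -> VerificationReport:
    """Certify the extremal characterization of W_f over an exhaustive class.

    ``domain='graphs'``: min at K_n, max at P_n.  ``domain='trees'``: min at
    S_n, max at P_n (roles swap for non-increasing f).  With ``delta`` set
    (trees only, non-decreasing f) the class is trees with maximum degree
    exactly delta, and the predicted unique maximizer is the broom with
    delta - 1 pendant leaves; the minimum clause is not certified there.
    """
    if domain not in ("graphs", "trees"):
        raise ValueError("domain must be 'graphs' or 'trees'")
    nondec = f.direction == NON_DECREASING
    if delta is not None:
        if domain != "trees":
            raise ValueError("degree-constrained certification is for trees")
        if not nondec:
            raise ValueError("degree-constrained maximum requires non-decreasing f")
        if not 2 <= delta <= n - 1:
            raise ValueError("need 2 <= delta <= n-1")

    if domain == "trees":
        iterator = _tree_edges_iter(n)
        lo_fam, hi_fam = ("star", "path") if nondec else ("path", "star")
        lo_pred = star_value(n, f) if nondec else path_value(n, f)
        hi_pred = path_value(n, f) if nondec else star_value(n, f)
    else:
        iterator = _graph_edges_iter(n)
        lo_fam, hi_fam = ("complete", "path") if nondec else ("path", "complete")
        lo_pred = complete_value(n, f) if nondec else path_value(n, f)
        hi_pred = path_value(n, f) if nondec else complete_value(n, f)

    lo_param = hi_param = None
    if delta is not None:
        hi_fam, hi_param = "broom", delta - 1
        hi_pred = None  # computed by construction, not a closed form

    best_lo = best_hi = None
    argmins: list[Edges] = []
    argmaxs: list[Edges] = []
    checked = 0
    for edges in iterator:
        if delta is not None:
            deg = [0] * n
            for u, v in edges:
                deg[u] += 1
                deg[v] += 1
            if max(deg) != delta:
                continue
        checked += 1
        counts, _ = _distance_profile(n, edges)
        w = sum(c * f(k + 1) for k, c in enumerate(counts))
        if best_lo is None or w < best_lo - abs(best_lo) * _REL_TOL:
            best_lo, argmins = w, [edges]
        elif abs(w - best_lo) <= abs(best_lo) * _REL_TOL + _REL_TOL:
            argmins.append(edges)
        if best_hi is None or w > best_hi + abs(best_hi) * _REL_TOL:
            best_hi, argmaxs = w, [edges]
        elif abs(w - best_hi) <= abs(best_hi) * _REL_TOL + _REL_TOL:
            argmaxs.append(edges)

    def close(a: float, b: float) -> bool:
        return abs(a - b) <= _REL_TOL * max(1.0, abs(a), abs(b))

    if hi_pred is None:
        hi_pred = sum(
            c * f(k + 1)
            for k, c in enumerate(
                _distance_profile(
                    n, tuple(make_special("broom", n, hi_param).edges)
                )[0]
            )
        )
    max_holds = best_hi is not None and close(best_hi, hi_pred)
    min_holds = True if delta is not None else (best_lo is not None and close(best_lo, lo_pred))

    unique = True
    counterexamples: list[Edges] = []
    if _is_strict(f, n):
        hi_fp = _family_fingerprint(hi_fam, n, hi_param)
        for e in argmaxs:
            if _fingerprint(n, e) != hi_fp:
                unique = False
                counterexamples.append(e)
        if delta is None:
            lo_fp = _family_fingerprint(lo_fam, n, lo_param)
            for e in argmins:
                if _fingerprint(n, e) != lo_fp:
                    unique = False
                    counterexamples.append(e)
    if not max_holds and argmaxs:
        counterexamples.extend(argmaxs[:3])
    if not min_holds and argmins:
        counterexamples.extend(argmins[:3])

    return VerificationReport(
        n=n,
        domain=domain,
        function_name=f.name,
        checked_count=checked,
        max_holds=max_holds,
        min_holds=min_holds,
        extremizer_unique=unique,
        counterexamples=tuple(counterexamples),
    )


class _Tracker:
    """Running extreme over one (function, constraint) cell of a scan."""

    __slots__ = ("lo", "hi", "lo_ok", "hi_ok", "lo_bad", "hi_bad")

    def __init__(self) -> None:
        self.lo = self.hi = None
        self.lo_ok = self.hi_ok = True
        self.lo_bad: list[Edges] = []
        self.hi_bad: list[Edges] = []

    def update(self, w: float, fp_lo_ok: bool, fp_hi_ok: bool, edges: Edges) -> None:
        tol = _REL_TOL * max(1.0, abs(w))
        if self.lo is None or w < self.lo - tol:
            self.lo, self.lo_ok, self.lo_bad = w, fp_lo_ok, [] if fp_lo_ok else [edges]
        elif abs(w - self.lo) <= tol:
            if not fp_lo_ok:
                self.lo_ok = False
                self.lo_bad.append(edges)
        if self.hi is None or w > self.hi + tol:
            self.hi, self.hi_ok, self.hi_bad = w, fp_hi_ok, [] if fp_hi_ok else [edges]
        elif abs(w - self.hi) <= tol:
            if not fp_hi_ok:
                self.hi_ok = False
                self.hi_bad.append(edges)


def certify_catalog(
    n: int,
    domain: str,
    catalog: list[IndexFunction],
    include_degree_constrained: bool = True,
) -> list[VerificationReport]:
    """Certify extremal characterizations for a whole function catalog in
    one exhaustive pass over the class.

    Equivalent to calling :func:`verify_extremal` for every function (and,
    over trees, every maximum-degree constraint for the non-decreasing
    functions), but enumerating the class only once.  Degree-constrained
    reports carry ``domain`` strings of the form ``"trees:delta=D"``.
    """
    if domain not in ("graphs", "trees"):
        raise ValueError("domain must be 'graphs' or 'trees'")
    strict = [_is_strict(f, n) for f in catalog]
    dense_fam = "star" if domain == "trees" else "complete"
    fp_path = _family_fingerprint("path", n)
    fp_dense = _family_fingerprint(dense_fam, n)
    pv = [path_value(n, f) for f in catalog]
    dv = [
        star_value(n, f) if domain == "trees" else complete_value(n, f)
        for f in catalog
    ]

    deltas: list[int] = []
    broom_fp: dict[int, tuple] = {}
    broom_val: dict[int, list[float]] = {}
    if include_degree_constrained and domain == "trees":
        deltas = list(range(2, n))
        for d in deltas:
            broom = make_special("broom", n, d - 1)
            edges = tuple(broom.edges)
            broom_fp[d] = _fingerprint(n, edges)
            counts, _ = _distance_profile(n, edges)
            broom_val[d] = [
                sum(c * f(k + 1) for k, c in enumerate(counts)) for f in catalog
            ]

    free = [_Tracker() for _ in catalog]
    constrained = {d: [_Tracker() for _ in catalog] for d in deltas}
    checked = 0
    iterator = _tree_edges_iter(n) if domain == "trees" else _graph_edges_iter(n)
    for edges in iterator:
        checked += 1
        deg = [0] * n
        for u, v in edges:
            deg[u] += 1
            deg[v] += 1
        counts, ecc = _distance_profile(n, edges)
        fp = (tuple(sorted(deg)), tuple(sorted(ecc)))
        is_path = fp == fp_path
        is_dense = fp == fp_dense
        dmax = max(deg)
        for i, f in enumerate(catalog):
            w = sum(c * f(k + 1) for k, c in enumerate(counts))
            if f.direction == NON_DECREASING:
                free[i].update(w, is_dense, is_path, edges)
            else:
                free[i].update(w, is_path, is_dense, edges)
            if dmax in constrained and f.direction == NON_DECREASING:
                constrained[dmax][i].update(w, True, fp == broom_fp[dmax], edges)

    def close(a: float, b: float) -> bool:
        return abs(a - b) <= _REL_TOL * max(1.0, abs(a), abs(b))

    reports: list[VerificationReport] = []
    for i, f in enumerate(catalog):
        tr = free[i]
        nondec = f.direction == NON_DECREASING
        lo_pred, hi_pred = (dv[i], pv[i]) if nondec else (pv[i], dv[i])
        unique = (tr.lo_ok and tr.hi_ok) if strict[i] else True
        reports.append(
            VerificationReport(
                n=n,
                domain=domain,
                function_name=f.name,
                checked_count=checked,
                max_holds=tr.hi is not None and close(tr.hi, hi_pred),
                min_holds=tr.lo is not None and close(tr.lo, lo_pred),
                extremizer_unique=unique,
                counterexamples=tuple(tr.lo_bad + tr.hi_bad) if strict[i] else (),
            )
        )
    for d in deltas:
        for i, f in enumerate(catalog):
            if f.direction != NON_DECREASING:
                continue
            tr = constrained[d][i]
            reports.append(
                VerificationReport(
                    n=n,
                    domain=f"trees:delta={d}",
                    function_name=f.name,
                    checked_count=checked,
                    max_holds=tr.hi is not None and close(tr.hi, broom_val[d][i]),
                    min_holds=True,
                    extremizer_unique=tr.hi_ok if strict[i] else True,
                    counterexamples=tuple(tr.hi_bad) if strict[i] else (),
                )
            )
    return reports
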