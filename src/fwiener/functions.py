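"""Catalog of monotone functions f defining f-Wiener indices.

An f-Wiener index is ``W_f(G) = sum over unordered pairs of f(d(u, v))`` for
a monotone function f on positive integers.  Classical special cases: the
Wiener index (f(k) = k), the Harary index (f(k) = 1/k), the hyper-Wiener
index (f(k) = (k^2 + k)/2), the generalized Wiener index (f(k) = k^alpha)
and the Hosoya (Wiener) polynomial evaluated at a fixed base q (f(k) = q^k).
"""

from __future__ import annotations

from dataclasses import dataclass
from typing import Callable

__all__ = [
    "IndexFunction",
    "builtin_catalog",
    "power_function",
    "geometric_function",
    "function_by_name",
    "parse_function_list",
]

NON_DECREASING = "non-decreasing"
NON_INCREASING = "non-increasing"

_MONOTONE_CHECK_UPTO = 1000


@dataclass(frozen=True)
class IndexFunction:
    """A named monotone function on positive integers.

    ``direction`` declares the monotonicity ("non-decreasing" or
    "non-increasing"); it is checked by sampling k = 1..1000 on construction.
    """

    name: str
    direction: str
    evaluate: Callable[[int], float]
    params: tuple[float, ...] = ()

    def __post_init__(self) -> None:
        if self.direction not in (NON_DECREASING, NON_INCREASING):
            raise ValueError(f"bad direction {self.direction!r}")
        vals = [self.evaluate(k) for k in range(1, _MONOTONE_CHECK_UPTO + 1)]
        diffs = (b - a for a, b in zip(vals, vals[1:]))
        ok = (
            all(d >= 0 for d in diffs)
            if self.direction == NON_DECREASING
            else all(d <= 0 for d in diffs)
        )
        if not ok:
            raise ValueError(f"{self.name}: declared direction does not hold")

    def __call__(self, k: int) -> float:
        return self.evaluate(k)


def power_function(alpha: float) -> IndexFunction:
    """Generalized-Wiener power function f(k) = k**alpha (alpha != 0)."""
    if alpha == 0:
        raise ValueError("alpha = 0 gives a constant function; normalization degenerates")
    direction = NON_DECREASING if alpha > 0 else NON_INCREASING
    return IndexFunction(f"power:{alpha:g}", direction, lambda k: float(k) ** alpha, (alpha,))


def geometric_function(q: float) -> IndexFunction:
    """Hosoya-polynomial term f(k) = q**k for fixed base q > 0, q != 1."""
    if q <= 0 or q == 1:
        raise ValueError("q must be positive and != 1")
    direction = NON_DECREASING if q > 1 else NON_INCREASING
    return IndexFunction(f"geom:{q:g}", direction, lambda k: q ** k, (q,))


def builtin_catalog() -> list[IndexFunction]:
    """The seven-function catalog used by the clustering experiments.

    In order: Wiener (k), hyper-Wiener ((k^2+k)/2), generalized Wiener with
    alpha = 2 (k^2) and alpha = 1/2 (sqrt k) -- all non-decreasing; Harary
    (1/k), generalized Wiener alpha = -2 (1/k^2), and the Hosoya polynomial
    at q = 1/2 ((1/2)^k) -- all non-increasing.  Every entry stays bounded
    for distances up to ~1000, so vectors on large sparse graphs do not
    overflow.
    """
    return [
        IndexFunction("wiener", NON_DECREASING, float),
        IndexFunction("hyper_wiener", NON_DECREASING, lambda k: (k * k + k) / 2.0),
        power_function(2.0),
        power_function(0.5),
        IndexFunction("harary", NON_INCREASING, lambda k: 1.0 / k),
        power_function(-2.0),
        geometric_function(0.5),
    ]


def function_by_name(name: str) -> IndexFunction:
    """Resolve a function spec string: ``wiener``, ``harary``,
    ``hyper_wiener``, ``power:A`` / ``generalized:A``, ``geom:Q``.
    """
    base, _, arg = name.partition(":")
    if base == "wiener":
        return IndexFunction("wiener", NON_DECREASING, float)
    if base == "harary":
        return IndexFunction("harary", NON_INCREASING, lambda k: 1.0 / k)
    if base == "hyper_wiener":
        return IndexFunction("hyper_wiener", NON_DECREASING, lambda k: (k * k + k) / 2.0)
    if base in ("power", "generalized"):
        if not arg:
            raise ValueError(f"{base} requires an exponent, e.g. {base}:2")
        return power_function(float(arg))
    if base == "geom":
        if not arg:
            raise ValueError("geom requires a base, e.g. geom:0.5")
        return geometric_function(float(arg))
    raise ValueError(f"unknown index function {name!r}")


def parse_function_list(spec: str) -> list[IndexFunction]:
    """Parse a comma-separated list of function spec strings."""
    return [function_by_name(tok.strip()) for tok in spec.split(",") if tok.strip()]
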