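"""Closed-form extremal values and the normalized index."""

import numpy as np
import pytest

from fwiener import (
    IndexFunction,
    complete_value,
    classical_bounds,
    degree_constrained_max,
    extremes,
    f_wiener,
    function_by_name,
    make_special,
    max_degree,
    normalized_index,
    path_value,
    star_value,
)
from fwiener.enumeration import enumerate_labeled_trees
from fwiener.functions import NON_DECREASING, NON_INCREASING

from conftest import random_connected_graph, random_labeled_tree

WIENER = function_by_name("wiener")
HARARY = function_by_name("harary")


class TestClosedForms:
    def test_worked_examples(self):
        assert path_value(5, WIENER) == 20
        assert complete_value(5, WIENER) == 10
        assert star_value(5, WIENER) == 16

    @pytest.mark.parametrize("n", [2, 3, 5, 11, 30])
    def test_formulas_match_constructed_graphs(self, catalog, n):
        for f in catalog:
            assert path_value(n, f) == pytest.approx(
                f_wiener(make_special("path", n), f).value
            )
            assert star_value(n, f) == pytest.approx(
                f_wiener(make_special("star", n), f).value
            )
            assert complete_value(n, f) == pytest.approx(
                f_wiener(make_special("complete", n), f).value
            )

    def test_wiener_closed_form_polynomials(self):
        # sum (n-k) k = n(n+1)(n-1)/6 for the path
        for n in range(2, 101):
            assert path_value(n, WIENER) == n * (n + 1) * (n - 1) // 6
            assert complete_value(n, WIENER) == n * (n - 1) // 2


class TestExtremes:
    def test_wiener_graphs_and_trees(self):
        g = extremes(5, WIENER, "graphs")
        assert (g.min_value, g.max_value) == (10, 20)
        assert (g.minimizer_family, g.maximizer_family) == ("complete", "path")
        t = extremes(5, WIENER, "trees")
        assert (t.min_value, t.max_value) == (16, 20)
        assert (t.minimizer_family, t.maximizer_family) == ("star", "path")

    def test_harary_n4_roles_swapped(self):
        e = extremes(4, HARARY, "graphs")
        assert e.min_value == pytest.approx(13 / 3)
        assert e.max_value == pytest.approx(6)
        assert (e.minimizer_family, e.maximizer_family) == ("path", "complete")

    def test_classical_bounds_delegate(self):
        c = classical_bounds(5, "wiener", "graphs")
        assert (c.min_value, c.max_value) == (10, 20)
        h = classical_bounds(4, "harary", "graphs")
        assert h.min_value == pytest.approx(13 / 3)

    def test_monotonicity_swap_symmetry(self, catalog):
        # extremes with non-increasing f == extremes with -f, swapped and negated
        for f in catalog:
            neg_dir = NON_INCREASING if f.direction == NON_DECREASING else NON_DECREASING
            neg = IndexFunction(f"neg_{f.name}", neg_dir, lambda k, f=f: -f(k))
            for domain, n in (("graphs", 9), ("trees", 9)):
                a = extremes(n, f, domain)
                b = extremes(n, neg, domain)
                assert a.min_value == pytest.approx(-b.max_value)
                assert a.max_value == pytest.approx(-b.min_value)

    def test_preconditions(self):
        with pytest.raises(ValueError):
            extremes(2, WIENER, "graphs")
        with pytest.raises(ValueError):
            extremes(3, WIENER, "trees")
        const = IndexFunction("const", NON_DECREASING, lambda k: 1.0)
        with pytest.raises(ValueError, match="constant"):
            extremes(6, const, "trees")

    def test_sandwich_random_graphs(self, catalog):
        rng = np.random.default_rng(17)
        for _ in range(150):
            n = int(rng.integers(4, 41))
            g = random_connected_graph(rng, n)
            for f in catalog:
                e = extremes(n, f, "graphs")
                assert e.min_value - 1e-9 <= f_wiener(g, f).value <= e.max_value + 1e-9

    def test_sandwich_random_trees(self, catalog):
        rng = np.random.default_rng(23)
        for _ in range(150):
            n = int(rng.integers(4, 41))
            t = random_labeled_tree(rng, n)
            for f in catalog:
                e = extremes(n, f, "trees")
                assert e.min_value - 1e-9 <= f_wiener(t, f).value <= e.max_value + 1e-9


class TestNormalizedIndex:
    def test_orientation_anchors(self):
        assert normalized_index(make_special("path", 5), WIENER, "trees").value == 0
        assert normalized_index(make_special("star", 5), WIENER, "trees").value == 1
        assert normalized_index(make_special("complete", 7), WIENER, "graphs").value == 1
        assert normalized_index(make_special("path", 7), WIENER, "graphs").value == 0

    def test_star_closed_form_over_graphs(self):
        # N(S_n) = (n-3)/n under graph normalization of the Wiener index
        for n in range(4, 51):
            v = normalized_index(make_special("star", n), WIENER, "graphs").value
            assert v == pytest.approx((n - 3) / n)

    def test_anchors_hold_for_every_catalog_function(self, catalog):
        for f in catalog:
            assert normalized_index(make_special("path", 20), f, "trees").value == pytest.approx(0)
            assert normalized_index(make_special("star", 20), f, "trees").value == pytest.approx(1)
            assert normalized_index(make_special("complete", 20), f, "graphs").value == pytest.approx(1)

    def test_range_and_extremizer_characterization_exhaustive_trees(self, catalog):
        # over all labeled trees on 7 nodes: N in [0,1]; 0 iff path, 1 iff star
        from fwiener.bounds import normalized_from_value
        from fwiener.graphs import distance_summary
        from fwiener.indices import f_wiener_from_summary

        for t in enumerate_labeled_trees(7):
            is_path = sorted(d for _, d in t.degree) == [1, 1, 2, 2, 2, 2, 2]
            is_star = max_degree(t) == 6
            ds = distance_summary(t)
            for f in catalog:
                w = f_wiener_from_summary(ds, f).value
                v = normalized_from_value(w, 7, f, "trees").value
                assert 0 <= v <= 1
                assert (v == pytest.approx(0, abs=1e-12)) == is_path
                assert (v == pytest.approx(1, abs=1e-12)) == is_star

    def test_non_tree_rejected_in_tree_domain(self):
        with pytest.raises(ValueError, match="tree"):
            normalized_index(make_special("complete", 5), WIENER, "trees")


class TestDegreeConstrainedMax:
    def test_endpoints(self):
        val, g = degree_constrained_max(8, 2, WIENER)
        assert val == path_value(8, WIENER)
        val, g = degree_constrained_max(5, 4, WIENER)
        assert val == 16
        assert max_degree(g) == 4

    def test_matches_exhaustive_prufer_maximum(self, catalog):
        # brute-force max over all labeled trees on 6/7 nodes per max degree
        from fwiener.graphs import distance_summary
        from fwiener.indices import f_wiener_from_summary

        for n in (6, 7):
            profiles = [
                (max_degree(t), distance_summary(t)) for t in enumerate_labeled_trees(n)
            ]
            for f in catalog[:4]:  # the non-decreasing catalog entries
                for delta in range(2, n):
                    best = max(
                        f_wiener_from_summary(ds, f).value
                        for dmax, ds in profiles
                        if dmax == delta
                    )
                    val, broom = degree_constrained_max(n, delta, f)
                    assert val == pytest.approx(best)
                    assert max_degree(broom) == delta

    def test_rejects_bad_delta_and_decreasing_f(self):
        with pytest.raises(ValueError):
            degree_constrained_max(5, 1, WIENER)
        with pytest.raises(ValueError):
            degree_constrained_max(5, 5, WIENER)
        with pytest.raises(ValueError):
            degree_constrained_max(6, 3, HARARY)
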