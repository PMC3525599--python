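"""Exact quasi-clique membership predicates and structural properties."""

import math
from fractions import Fraction

import numpy as np
import pytest
from hypothesis import given, settings, strategies as st

from qclique import (Graph, QuasiCliqueSpec, edge_density,
                     is_gamma_quasi_clique, is_lambda_gamma_quasi_clique,
                     required_edges, sample_gnp, subset_diameter)
from conftest import complete_graph


class TestRequiredEdges:
    @pytest.mark.parametrize("k,gamma,expected", [
        (4, "0.85", 6),   # ceil(5.1)
        (5, "0.85", 9),   # ceil(8.5)
        (3, "0.9", 3),    # ceil(2.7)
        (1, "0.5", 0),
        (2, "0.01", 1),
    ])
    def test_ceiling_values(self, k, gamma, expected):
        assert required_edges(k, gamma) == expected

    def test_invalid_gamma(self):
        with pytest.raises(ValueError):
            required_edges(4, "0")
        with pytest.raises(ValueError):
            required_edges(4, "1.2")

    @settings(derandomize=True, max_examples=100, deadline=None)
    @given(k=st.integers(2, 1000),
           num=st.integers(1, 99))
    def test_exact_rational_ceiling(self, k, num):
        # decimal-string gamma, compared against Fraction arithmetic
        gamma = f"0.{num:02d}"
        got = required_edges(k, gamma)
        frac = Fraction(num, 100) * k * (k - 1) / 2
        assert got - 1 < frac <= got


class TestEdgeDensity:
    def test_triangle_is_one(self, triangle):
        assert edge_density(triangle, ["a", "b", "c"]) == 1

    def test_nonadjacent_pair_is_zero(self, five_cycle):
        assert edge_density(five_cycle, ["a", "c"]) == 0

    def test_five_of_six_pairs(self, k4_minus_edge):
        assert edge_density(k4_minus_edge, list("wxyz")) == Fraction(5, 6)

    def test_singleton_convention(self, triangle):
        assert edge_density(triangle, ["a"]) == 1

    def test_empty_subset_error(self, triangle):
        with pytest.raises(ValueError):
            edge_density(triangle, [])

    def test_unknown_vertex_error(self, triangle):
        with pytest.raises(KeyError):
            edge_density(triangle, ["a", "zz"])


class TestGammaQuasiClique:
    def test_triangle_at_085(self, triangle):
        assert is_gamma_quasi_clique(triangle, "abc", QuasiCliqueSpec("0.85"))

    def test_k4_minus_edge_fails_085(self, k4_minus_edge):
        # 5 edges < ceil(0.85*6) = 6
        assert not is_gamma_quasi_clique(k4_minus_edge, "wxyz",
                                         QuasiCliqueSpec("0.85"))

    def test_boundary_nine_of_ten(self):
        # 5 vertices, exactly 9 edges: meets ceil(0.85*10) = 9 ("at least")
        g = Graph(list("abcde"),
                  [(i, j) for i in range(5) for j in range(i + 1, 5)
                   if (i, j) != (3, 4)])
        assert is_gamma_quasi_clique(g, "abcde", QuasiCliqueSpec("0.85"))

    def test_boundary_eight_of_ten_fails(self):
        g = Graph(list("abcde"),
                  [(i, j) for i in range(5) for j in range(i + 1, 5)
                   if (i, j) not in {(3, 4), (2, 4)}])
        assert not is_gamma_quasi_clique(g, "abcde", QuasiCliqueSpec("0.85"))

    def test_disconnected_passes_unless_connectivity_required(self):
        # two disjoint triangles: density 6/15 = 0.4
        g = Graph(list("abcdef"),
                  [(0, 1), (1, 2), (0, 2), (3, 4), (4, 5), (3, 5)])
        assert is_gamma_quasi_clique(g, "abcdef", QuasiCliqueSpec("0.4"))
        assert not is_gamma_quasi_clique(
            g, "abcdef", QuasiCliqueSpec("0.4", require_connected=True))

    def test_any_clique_passes_every_gamma(self):
        g = complete_graph(6)
        for gamma in ("0.1", "0.5", "0.99", 1):
            assert is_gamma_quasi_clique(g, g.labels, QuasiCliqueSpec(gamma))


class TestLambdaGammaQuasiClique:
    def test_k5_passes(self):
        g = complete_graph(5)
        spec = QuasiCliqueSpec(gamma="0.9", lam="0.9")
        assert is_lambda_gamma_quasi_clique(g, g.labels, spec)

    def test_five_cycle_at_half(self, five_cycle):
        spec = QuasiCliqueSpec(gamma="0.5", lam="0.5")
        assert is_lambda_gamma_quasi_clique(five_cycle, "abcde", spec)

    def test_star_leaf_degree_too_low(self):
        g = Graph(list("cabde"), [(0, 1), (0, 2), (0, 3), (0, 4)])
        spec = QuasiCliqueSpec(gamma="0.4", lam="0.5")
        assert not is_lambda_gamma_quasi_clique(g, "cabde", spec)

    def test_lambda_pass_implies_gamma_pass(self):
        rng = np.random.default_rng(9)
        spec_lg = QuasiCliqueSpec(gamma="0.6", lam="0.6")
        spec_g = QuasiCliqueSpec(gamma="0.6")
        hits = 0
        for seed in range(30):
            g = sample_gnp(12, 0.7, seed)
            sub = [g.label_of(int(v))
                   for v in rng.choice(12, size=6, replace=False)]
            if is_lambda_gamma_quasi_clique(g, sub, spec_lg):
                hits += 1
                assert is_gamma_quasi_clique(g, sub, spec_g)
        assert hits > 0  # the implication was actually exercised


class TestSubsetDiameter:
    def test_complete_graph_diameter_one(self):
        g = complete_graph(4)
        assert subset_diameter(g, g.labels) == 1

    def test_path_diameter_two(self):
        g = Graph(list("abc"), [(0, 1), (1, 2)])
        assert subset_diameter(g, "abc") == 2

    def test_disconnected_is_infinite(self):
        g = Graph(list("abcd"), [(0, 1), (2, 3)])
        assert subset_diameter(g, "abcd") == math.inf

    def test_lambda_core_with_lam_at_least_half_has_diameter_le_2(self):
        # degree >= ceil(lam (k-1)) with lam >= 1/2 forces any two members
        # to share a neighbour; check on randomly generated passing subsets
        rng = np.random.default_rng(4)
        spec = QuasiCliqueSpec(gamma="0.5", lam="0.5")
        checked = 0
        for seed in range(120):
            g = sample_gnp(14, 0.6, seed)
            k = int(rng.integers(4, 9))
            sub = [g.label_of(int(v))
                   for v in rng.choice(14, size=k, replace=False)]
            if is_lambda_gamma_quasi_clique(g, sub, spec):
                checked += 1
                assert subset_diameter(g, sub) <= 2
        assert checked >= 10
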