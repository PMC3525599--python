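"""First-moment analytics: KL divergence, size bounds, tails, k*."""

import math
from fractions import Fraction

import numpy as np
import pytest

from qclique import (binom_tail_exact, bound_report, chernoff_tail_bound,
                     critical_size_k_star, expected_quasi_clique_count,
                     kl_bernoulli, log_expected_quasi_clique_count,
                     normal_tail_approx, quasi_clique_size_bounds)


class TestKlBernoulli:
    def test_clique_limit_is_log_inverse_p(self):
        assert kl_bernoulli(1, 0.5) == pytest.approx(math.log(2), abs=1e-12)

    def test_zero_at_equal_distributions(self):
        assert kl_bernoulli(0.3, 0.3) == pytest.approx(0.0, abs=1e-12)

    def test_sparse_value(self):
        assert kl_bernoulli("0.85", 0.05) == pytest.approx(2.1313, abs=1e-3)

    def test_degenerate_p_rejected(self):
        with pytest.raises(ValueError):
            kl_bernoulli(0.5, 0.0)
        with pytest.raises(ValueError):
            kl_bernoulli(0.5, 1.0)


class TestSizeBounds:
    @pytest.mark.parametrize("p,gamma,lo,hi", [
        (0.05, "0.85", 3.07, 4.32),
        (0.15, "0.9", 4.85, 6.59),
        (0.09, "0.85", 3.82, 5.62),
    ])
    def test_small_graph_bound_intervals(self, p, gamma, lo, hi):
        a, b = quasi_clique_size_bounds(100, p, gamma)
        assert round(a, 2) == lo
        assert round(b, 2) == hi

    def test_clique_case_bounds_coincide(self):
        a, b = quasi_clique_size_bounds(100, 0.05, 1)
        assert a == pytest.approx(b, rel=1e-12)

    def test_dense_phase_rejected(self):
        with pytest.raises(ValueError):
            quasi_clique_size_bounds(100, 0.9, "0.85")

    def test_lower_le_upper_everywhere(self):
        for p in np.linspace(0.05, 0.8, 12):
            for g in ("0.85", "0.9", "0.95", 1):
                if p >= float(Fraction(str(g))):
                    continue
                a, b = quasi_clique_size_bounds(200, float(p), g)
                assert a <= b + 1e-12


class TestBinomTail:
    def test_all_successes(self):
        assert binom_tail_exact(6, 0.2, 6) == pytest.approx(0.2**6, rel=1e-12)

    def test_k_zero_is_one_and_k_above_m_is_zero(self):
        assert binom_tail_exact(12, 0.4, 0) == 1.0
        assert binom_tail_exact(12, 0.4, 13) == 0.0

    def test_exact_rational_mode(self):
        assert binom_tail_exact(10, "0.5", 5, exact=True) == Fraction(319, 512)
        assert binom_tail_exact(10, 0.5, 5) == pytest.approx(0.623046875,
                                                             rel=1e-12)

    def test_float_path_matches_rational_oracle(self):
        for m, p, k in [(20, "0.3", 9), (64, "0.85", 60), (30, "0.07", 6)]:
            exact = float(binom_tail_exact(m, p, k, exact=True))
            assert binom_tail_exact(m, float(Fraction(p)), k) == pytest.approx(
                exact, rel=1e-9)


class TestExpectedCount:
    def test_pairs_expectation(self):
        # k=2 needs one edge: E = C(10,2) * p
        assert expected_quasi_clique_count(10, 0.1, "0.5", 2) == pytest.approx(
            4.5, rel=1e-9)

    def test_requires_six_of_six_edges(self):
        # required_edges(4, 0.85) = 6 => E = C(20,4) * p^6
        assert expected_quasi_clique_count(20, 0.2, "0.85", 4) == pytest.approx(
            4845 * 0.2**6, rel=1e-9)

    def test_monotone_in_p(self):
        vals = [expected_quasi_clique_count(30, p, "0.8", 6)
                for p in (0.2, 0.4, 0.6)]
        assert vals[0] < vals[1] < vals[2]


class TestCriticalSize:
    def test_clique_k_star_in_gnp_half(self):
        assert critical_size_k_star(100, 0.5, 1) == 9

    def test_crossing_brackets_one(self):
        ks = critical_size_k_star(100, 0.5, 1)
        assert log_expected_quasi_clique_count(100, 0.5, 1, ks) >= 0
        assert log_expected_quasi_clique_count(100, 0.5, 1, ks + 1) < 0

    def test_at_least_two_when_an_edge_is_expected(self):
        assert critical_size_k_star(50, 0.1, "0.9") >= 2

    def test_converges_to_asymptotic_main_term(self):
        # k* = (2 ln n / D)(1 + o(1)); the o(1) term is a -ln k correction
        # that decays slowly, so convergence is monotone and only reaches
        # 15% agreement around n ~ 1e12
        p, gamma = 0.5, "0.9"
        ratios = []
        for n in (10**4, 10**6, 10**9, 10**12):
            ks = critical_size_k_star(n, p, gamma)
            main = 2 * math.log(n) / kl_bernoulli(gamma, p)
            ratios.append(abs(ks / main - 1))
        assert ratios == sorted(ratios, reverse=True)
        assert ratios[-1] < 0.15


class TestChernoff:
    def test_coincides_with_exact_at_gamma_one(self):
        assert chernoff_tail_bound(6, 0.2, 1) == pytest.approx(0.2**6,
                                                               rel=1e-12)

    def test_vacuous_when_gamma_le_p(self):
        assert chernoff_tail_bound(50, 0.4, 0.4) == 1.0
        assert chernoff_tail_bound(50, 0.4, 0.3) == 1.0

    def test_dominates_exact_tail_on_small_grid(self):
        from qclique import required_edges
        for m in range(1, 31):
            for p10 in range(1, 10):
                p = p10 / 10
                for g10 in range(p10 + 1, 11):
                    gamma = Fraction(g10, 10)
                    k = math.ceil(gamma * m)
                    bound = chernoff_tail_bound(m, p, gamma)
                    exact = float(binom_tail_exact(m, Fraction(p10, 10), k,
                                                   exact=True))
                    assert bound >= exact - 1e-15


class TestNormalTailApprox:
    def test_within_ten_percent_at_m_100(self):
        exact = binom_tail_exact(100, 0.3, 45)
        approx = normal_tail_approx(100, 0.3, 45)
        assert abs(approx - exact) / exact < 0.10

    def test_within_five_percent_at_m_400(self):
        exact = binom_tail_exact(400, 0.3, 150)
        approx = normal_tail_approx(400, 0.3, 150)
        assert abs(approx - exact) / exact < 0.05

    def test_error_shrinks_with_m_at_fixed_deviation(self):
        errs = []
        for m in (100, 400, 1600):
            sd = math.sqrt(m * 0.3 * 0.7)
            k = math.ceil(m * 0.3 + 3 * sd)
            exact = binom_tail_exact(m, 0.3, k)
            errs.append(abs(normal_tail_approx(m, 0.3, k) - exact) / exact)
        assert errs[0] > errs[1] > errs[2]

    def test_regime_violation_rejected(self):
        with pytest.raises(ValueError):
            normal_tail_approx(100, 0.5, 40)


class TestBoundReport:
    def test_report_is_internally_consistent(self):
        rep = bound_report(100, 0.05, "0.85")
        assert rep.lower <= rep.upper
        assert rep.e_counts[rep.k_star] >= 1 > rep.e_counts[rep.k_star + 1]
        d = rep.to_dict()
        assert d["gamma"] == "17/20"
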