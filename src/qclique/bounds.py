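"""First-moment analytics for dense subsets of G(n, p).

The central object is the expected number of γ-quasi-cliques of size k,

    E[Y_k] = C(n, k) · P[Bin(k(k−1)/2, p) ≥ ⌈γ·k(k−1)/2⌉],

whose crossing point E[Y_{k*}] ≥ 1 > E[Y_{k*+1}] (the critical size k*)
controls the size of the largest γ-dense subset in the sparse phase p < γ.
Asymptotically k* ~ 2 ln n / D(γ‖p), where D(γ‖p) is the Kullback–Leibler
divergence between Bernoulli(γ) and Bernoulli(p); at γ = 1 this collapses to
the classical 2 ln n / ln(1/p) maximum-clique size, which also serves as the
lower bound.  All combinatorial factors are evaluated in log space.
"""

from __future__ import annotations

import math
from dataclasses import dataclass, field
from fractions import Fraction

import numpy as np
from scipy import special, stats

from .density import required_edges, to_fraction

__all__ = [
    "kl_bernoulli",
    "quasi_clique_size_bounds",
    "binom_tail_exact",
    "expected_quasi_clique_count",
    "log_expected_quasi_clique_count",
    "critical_size_k_star",
    "chernoff_tail_bound",
    "normal_tail_approx",
    "BoundReport",
    "bound_report",
]


def kl_bernoulli(gamma, p: float) -> float:
    """Kullback–Leibler divergence D(γ‖p) between Bernoulli laws.

    Returns γ·ln(γ/p) + (1−γ)·ln((1−γ)/(1−p)); the γ = 1 limit is ln(1/p).
    """
    g = float(to_fraction(gamma))
    p = float(p)
    if not (0.0 < p < 1.0):
        raise ValueError("p must lie strictly inside (0, 1)")
    if not (0.0 < g <= 1.0):
        raise ValueError("gamma must lie in (0, 1]")
    if g == 1.0:
        return math.log(1.0 / p)
    return g * math.log(g / p) + (1.0 - g) * math.log((1.0 - g) / (1.0 - p))


def quasi_clique_size_bounds(n: int, p: float, gamma) -> tuple[float, float]:
    """Asymptotic (lower, upper) bounds on the maximum γ-quasi-clique size.

    lower = 2 ln n / ln(1/p) is the maximum-clique plug-in (a clique is a
    γ-quasi-clique for every γ); upper = 2 ln n / D(γ‖p) is the first-moment
    critical size.  Only meaningful in the sparse phase p < γ; for p ≥ γ the
    whole graph is w.h.p. γ-dense and the bound does not apply.
    """
    if n < 2:
        raise ValueError("n must be >= 2")
    g = float(to_fraction(gamma))
    if not (0.0 < p < g <= 1.0):
        raise ValueError("bounds require 0 < p < gamma <= 1 (sparse phase); "
                         f"got p={p}, gamma={g}")
    lower = 2.0 * math.log(n) / math.log(1.0 / p)
    upper = 2.0 * math.log(n) / kl_bernoulli(g, p)
    return lower, upper


def binom_tail_exact(m: int, p: float, k: int, *, exact: bool = False):
    """Upper tail P[Bin(m, p) ≥ k].

    Default path uses scipy's regularized incomplete beta (stable over the
    full range); ``exact=True`` performs rational-arithmetic summation with
    ``p`` read as a decimal fraction (supported for m ≤ 64 — the internal
    oracle for the floating path).
    """
    if m < 0:
        raise ValueError("m must be >= 0")
    if k <= 0:
        return Fraction(1) if exact else 1.0
    if k > m:
        return Fraction(0) if exact else 0.0
    if exact:
        if m > 64:
            raise ValueError("exact rational mode supported for m <= 64")
        pf = to_fraction(p)
        q = 1 - pf
        total = Fraction(0)
        for j in range(k, m + 1):
            total += math.comb(m, j) * pf**j * q**(m - j)
        return total
    return float(stats.binom.sf(k - 1, m, float(p)))


def _log_binom_tail(m: int, p: float, k: int) -> float:
    """log P[Bin(m,p) ≥ k], falling back to log-space pmf summation when the
    linear-space survival function underflows."""
    if k <= 0:
        return 0.0
    if k > m:
        return -math.inf
    ls = stats.binom.logsf(k - 1, m, p)
    if np.isfinite(ls) and ls > -700:
        return float(ls)
    # deep tail: logsumexp over pmf terms k..m (the sum is dominated by the
    # first few terms; cap the range generously)
    j = np.arange(k, m + 1)
    logpmf = stats.binom.logpmf(j, m, p)
    return float(special.logsumexp(logpmf))


def log_expected_quasi_clique_count(n: int, p: float, gamma, k: int) -> float:
    """Natural log of E[Y_k] = C(n,k)·P[Bin(k(k−1)/2, p) ≥ ⌈γ·k(k−1)/2⌉]."""
    if not (2 <= k <= n):
        raise ValueError("need 2 <= k <= n")
    g = to_fraction(gamma)
    pairs = k * (k - 1) // 2
    need = required_edges(k, g)
    logc = float(special.gammaln(n + 1) - special.gammaln(k + 1)
                 - special.gammaln(n - k + 1))
    return logc + _log_binom_tail(pairs, float(p), need)


def expected_quasi_clique_count(n: int, p: float, gamma, k: int) -> float:
    """E[Y_k]; may overflow to ``inf`` for huge counts (use the log form)."""
    logv = log_expected_quasi_clique_count(n, p, gamma, k)
    if logv > 700:
        return math.inf
    return math.exp(logv)


def critical_size_k_star(n: int, p: float, gamma) -> int:
    """Largest k with E[Y_k] ≥ 1, by ascending integer scan from k = 2.

    E[Y_k] = 1 generically falls between integers; returning the last k on
    the ≥ 1 side is this package's integerization convention.  Returns 1 when
    even E[Y_2] < 1 (fewer than one expected edge-dense pair).
    """
    if n < 2:
        raise ValueError("n must be >= 2")
    g = to_fraction(gamma)
    if not (0.0 < float(p) < float(g)):
        raise ValueError("critical size is defined for the sparse phase p < gamma")
    last = 1
    for k in range(2, n + 1):
        if log_expected_quasi_clique_count(n, p, g, k) >= 0.0:
            last = k
        else:
            break
    return last


def chernoff_tail_bound(m: int, p: float, gamma) -> float:
    """Relative-entropy Chernoff bound exp(−m·D(γ‖p)) on P[Bin(m,p) ≥ γm].

    Vacuous (returns 1) when γ ≤ p.
    """
    g = float(to_fraction(gamma))
    if g <= p:
        return 1.0
    return math.exp(-m * kl_bernoulli(g, p))


def normal_tail_approx(m: int, p: float, k: int) -> float:
    """Uniform normal-based (saddlepoint-refined) estimate of P[Bin(m,p) ≥ k].

    Valid in the upper-deviation regime k > m·p.  The estimate combines the
    exact large-deviation exponent with standard-normal tail functions:

        w = sqrt(2·m·D(a‖p)),  a = k/m,
        u = (1 − e^{−t})·sqrt(m·a(1−a)),  t = ln[a(1−p)/(p(1−a))],
        P ≈ Φc(w) + φ(w)·(1/u − 1/w),

    where Φc and φ are the standard normal survival and density functions.
    It is an *estimate*, not a bound: relative error decreases roughly like
    1/m uniformly in the tail (cf. the exact-tail cross-checks in the tests).
    """
    if not (0 < k <= m):
        raise ValueError("need 0 < k <= m")
    p = float(p)
    if not (0.0 < p < 1.0):
        raise ValueError("p must lie strictly inside (0, 1)")
    if k <= m * p:
        raise ValueError("approximation regime requires k > m*p")
    if k == m:
        return p**m
    a = k / m
    D = a * math.log(a / p) + (1 - a) * math.log((1 - a) / (1 - p))
    w = math.sqrt(2.0 * m * D)
    t = math.log(a * (1 - p) / (p * (1 - a)))
    u = (1.0 - math.exp(-t)) * math.sqrt(m * a * (1 - a))
    phi = math.exp(-0.5 * w * w) / math.sqrt(2.0 * math.pi)
    tail = float(stats.norm.sf(w)) + phi * (1.0 / u - 1.0 / w)
    return max(tail, 0.0)


@dataclass(frozen=True)
class BoundReport:
    """Analytic summary for one (n, p, γ): size bounds, k*, E[Y_k] table."""

    n: int
    p: float
    gamma: Fraction
    lower: float
    upper: float
    k_star: int
    e_counts: dict[int, float] = field(default_factory=dict)

    def to_dict(self) -> dict:
        return {
            "n": self.n,
            "p": self.p,
            "gamma": str(self.gamma),
            "lower": self.lower,
            "upper": self.upper,
            "k_star": self.k_star,
            "e_counts": {str(k): v for k, v in self.e_counts.items()},
        }


def bound_report(n: int, p: float, gamma, k_max: int | None = None) -> BoundReport:
    """Assemble the :class:`BoundReport` for one parameter point (p < γ)."""
    g = to_fraction(gamma)
    lower, upper = quasi_clique_size_bounds(n, p, g)
    ks = critical_size_k_star(n, p, g)
    top = min(n, k_max if k_max is not None else ks + 3)
    counts = {k: expected_quasi_clique_count(n, p, g, k)
              for k in range(2, top + 1)}
    return BoundReport(n=n, p=float(p), gamma=g, lower=lower, upper=upper,
                       k_star=ks, e_counts=counts)
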