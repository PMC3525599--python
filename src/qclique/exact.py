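"""Provably optimal maximum γ-quasi-clique search.

Two engines live here:

* :func:`max_quasi_clique_bruteforce` — exhaustive per-size subset
  enumeration, the oracle the other engines are tested against.
* :func:`max_quasi_clique_exact` — a combinatorial branch-and-bound over
  vertex subsets, the default exact engine.

Both exploit quasi-heredity: a γ-quasi-clique of size k contains one of
every smaller size (drop a minimum-internal-degree vertex and the density
cannot fall below γ).  The set of feasible sizes is therefore an interval
{1, …, ω̂}, so the search proceeds size by size upward and stops at the
first size with no feasible subset.  Quasi-heredity holds for the plain
γ-condition only — the (λ,γ) and connected variants are not hereditary, so
brute force falls back to a full scan for those and branch-and-bound
declines them.

Adjacency is held as python-int bitmasks; partial subsets are pruned with
the optimistic completion bound

    e(S) + C(k−s, 2) + Σ top_{k−s} |N(v) ∩ S|  <  ⌈γ·k(k−1)/2⌉  ⇒  prune.
"""

from __future__ import annotations

import itertools
import logging
import time

from .density import QuasiCliqueSpec, is_feasible, required_edges
from .graph import Graph
from .result import SolveResult, make_result

__all__ = ["max_quasi_clique_bruteforce", "max_quasi_clique_exact"]

logger = logging.getLogger("qclique.exact")

_BRUTE_N_LIMIT = 22


def _popcount(x: int) -> int:
    return x.bit_count()


def max_quasi_clique_bruteforce(graph: Graph, spec: QuasiCliqueSpec,
                                k_cap: int | None = None) -> SolveResult:
    """Exhaustive maximum quasi-clique search (test oracle, n ≤ 22).

    Subsets of each size are enumerated in lexicographic label order, so the
    witness returned for the optimal size is the lexicographically smallest
    label set.  For the plain γ-condition the scan stops at the first size
    with no feasible subset (quasi-heredity); for (λ,γ) or connected variants
    every size up to ``k_cap`` (default n) is scanned.
    """
    n = graph.n
    if n > _BRUTE_N_LIMIT and k_cap is None:
        raise ValueError(
            f"brute force on n={n} > {_BRUTE_N_LIMIT} vertices is intractable; "
            "pass k_cap to cap the subset size, or use max_quasi_clique_exact")
    hereditary = spec.lam is None and not spec.require_connected
    order = sorted(range(n), key=graph.label_of)  # lexicographic by label
    masks = graph.neighbor_masks()
    k_max = min(n, k_cap) if k_cap is not None else n

    best: tuple[int, ...] | None = (order[0],)  # singletons are always feasible
    for k in range(2, k_max + 1):
        found = None
        if hereditary:
            need = required_edges(k, spec.gamma)
            for combo in itertools.combinations(order, k):
                smask = 0
                e = 0
                for v in combo:
                    e += _popcount(masks[v] & smask)
                    smask |= 1 << v
                if e >= need:
                    found = combo
                    break
        else:
            for combo in itertools.combinations(order, k):
                if is_feasible(graph, [graph.label_of(v) for v in combo], spec):
                    found = combo
                    break
        if found is not None:
            best = found
        elif hereditary:
            break  # no feasible size-k set => none larger (quasi-heredity)
    return make_result(graph, best, spec, engine="brute", is_optimal=True)


class _Timeout(Exception):
    pass


class _SizeKSearch:
    """DFS feasibility search: is there a γ-dense subset of exactly k vertices?

    Vertices are visited in descending-degree order (dense candidates first).
    """

    def __init__(self, masks: list[int], n: int, k: int, need: int,
                 deadline: float | None):
        self.masks = masks
        self.n = n
        self.k = k
        self.need = need
        self.deadline = deadline
        self.nodes = 0

    def run(self) -> list[int] | None:
        full = (1 << self.n) - 1
        return self._dfs([], 0, 0, full)

    def _dfs(self, chosen: list[int], smask: int, e: int, cand: int
             ) -> list[int] | None:
        self.nodes += 1
        if self.deadline is not None and self.nodes % 4096 == 0:
            if time.monotonic() > self.deadline:
                raise _Timeout
        s = len(chosen)
        if s == self.k:
            return chosen if e >= self.need else None
        r = self.k - s
        # gather candidates and their connectivity into the current set
        verts: list[int] = []
        crosses: list[int] = []
        m = cand
        while m:
            b = m & -m
            j = b.bit_length() - 1
            m ^= b
            verts.append(j)
            crosses.append(_popcount(self.masks[j] & smask))
        if len(verts) < r:
            return None
        ub = e + r * (r - 1) // 2 + sum(sorted(crosses, reverse=True)[:r])
        if ub < self.need:
            return None
        for pos, j in enumerate(verts):
            rest = cand & ~((1 << (j + 1)) - 1)
            hit = self._dfs(chosen + [j], smask | (1 << j),
                            e + crosses[pos], rest)
            if hit is not None:
                return hit
        return None


def _greedy_incumbent(graph: Graph, spec: QuasiCliqueSpec) -> list[int]:
    """Cheap feasible incumbent: max-gain growth, plus peel from the whole
    graph; the larger of the two."""
    import numpy as np

    n = graph.n
    adj = graph.adjacency
    req = [required_edges(k, spec.gamma) if k >= 1 else 0 for k in range(n + 1)]

    # growth from the highest-degree vertex while feasibility is kept
    degs = graph.degrees()
    start = int(np.argmax(degs))
    in_s = {start}
    e = 0
    while True:
        best_v, best_gain = -1, -1
        for v in range(n):
            if v in in_s:
                continue
            gain = len(adj[v] & in_s)
            if gain > best_gain:
                best_v, best_gain = v, gain
        if best_v < 0 or e + best_gain < req[len(in_s) + 1]:
            break
        in_s.add(best_v)
        e += best_gain
    grown = list(in_s)

    # peel: repeatedly drop the min-internal-degree vertex until feasible
    s = set(range(n))
    e = graph.m
    deg = {v: len(adj[v]) for v in range(n)}
    while len(s) > 1 and e < req[len(s)]:
        v = min(s, key=lambda u: (deg[u], u))
        s.remove(v)
        e -= deg[v]
        for u in adj[v]:
            if u in s:
                deg[u] -= 1
    peeled = list(s) if e >= req[len(s)] else [0]

    return grown if len(grown) >= len(peeled) else peeled


def max_quasi_clique_exact(graph: Graph, spec: QuasiCliqueSpec,
                           time_limit: float | None = None,
                           k_cap: int | None = None) -> SolveResult:
    """Branch-and-bound maximum γ-quasi-clique (provably optimal).

    Seeds an incumbent greedily, then searches target sizes upward from
    ``|incumbent| + 1``; each size runs a DFS over descending-degree vertex
    orderings with the optimistic completion bound.  The first size with no
    feasible subset proves optimality of the incumbent (quasi-heredity).  If
    ``time_limit`` (seconds) runs out, the incumbent is returned with
    ``is_optimal=False`` and the unresolved size is logged.
    """
    if spec.lam is not None or spec.require_connected:
        raise NotImplementedError(
            "the exact branch-and-bound engine handles the plain γ-condition; "
            "use max_quasi_clique_bruteforce for (λ,γ)/connected variants")
    n = graph.n
    deadline = time.monotonic() + time_limit if time_limit is not None else None

    # descending-degree relabelling: DFS visits dense candidates first
    degs = graph.degrees()
    order = sorted(range(n), key=lambda v: (-int(degs[v]), v))
    pos = {v: i for i, v in enumerate(order)}
    raw = graph.neighbor_masks()
    masks = [0] * n
    for v in range(n):
        m = raw[v]
        nm = 0
        while m:
            b = m & -m
            nm |= 1 << pos[b.bit_length() - 1]
            m ^= b
        masks[pos[v]] = nm

    best = [pos[v] for v in _greedy_incumbent(graph, spec)]
    k_max = min(n, k_cap) if k_cap is not None else n
    optimal = True
    k = len(best) + 1
    try:
        while k <= k_max:
            need = required_edges(k, spec.gamma)
            hit = _SizeKSearch(masks, n, k, need, deadline).run()
            if hit is None:
                break
            best = hit
            k += 1
    except _Timeout:
        optimal = False
        logger.warning("time limit reached; incumbent size %d, size %d "
                       "unresolved (bound gap >= 1)", len(best), k)
    original = [order[i] for i in best]
    return make_result(graph, original, spec, engine="bnb", is_optimal=optimal)
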