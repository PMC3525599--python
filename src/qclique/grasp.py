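"""GRASP heuristic for maximum γ-quasi-clique search on moderate graphs.

Greedy randomized adaptive search: each start grows a set by repeatedly
adding a vertex drawn uniformly from a restricted candidate list (the
candidates whose edge count into the current set is within ``rcl_alpha`` of
the best), allowing temporarily sub-γ prefixes as long as an optimistic
completion bound says some larger feasible size is still reachable; the
final prefix is repaired by peeling minimum-internal-degree vertices until
γ-feasible, then improved by add and swap moves.  The best feasible set over
all starts is returned, never marked optimal.

Two deterministic starts complement the randomized ones: the whole vertex
set (when the graph itself is γ-dense — the supercritical phase p > γ) and a
peel from the whole graph, which is the effective strategy when the edge
probability approaches γ from below and the best feasible sets are a large
fraction of the graph, a regime where pure greedy growth does poorly.

Scales to n ~ 10^3–10^4 (dense boolean adjacency, O(n²) per start).
"""

from __future__ import annotations

import numpy as np

from .density import QuasiCliqueSpec, required_edges
from .graph import Graph
from .result import SolveResult, make_result

__all__ = ["max_quasi_clique_grasp"]

DEFAULT_ITERATIONS = 100
DEFAULT_RCL_ALPHA = 0.2


def _req_table(n: int, gamma) -> np.ndarray:
    return np.array([0, 0] + [required_edges(k, gamma) for k in range(2, n + 1)],
                    dtype=np.int64)


def _peel(adj: np.ndarray, members: np.ndarray, e: int, req: np.ndarray,
          rng: np.random.Generator | None = None
          ) -> tuple[np.ndarray, int]:
    """Drop min-internal-degree vertices (random tie-break) until feasible."""
    in_s = members.copy()
    cnt = adj[:, in_s].sum(axis=1).astype(np.int64)
    size = int(in_s.sum())
    while size > 1 and e < req[size]:
        cand = np.flatnonzero(in_s)
        local = cnt[cand]
        lows = cand[local == local.min()]
        v = int(lows[0] if rng is None else rng.choice(lows))
        in_s[v] = False
        e -= int(cnt[v])
        cnt -= adj[:, v]
        size -= 1
    return in_s, e


def _local_search(adj: np.ndarray, in_s: np.ndarray, e: int, req: np.ndarray,
                  max_passes: int = 200) -> tuple[np.ndarray, int]:
    """Add moves (grow while feasible) and density-improving swaps."""
    n = adj.shape[0]
    cnt = adj[:, in_s].sum(axis=1).astype(np.int64)
    size = int(in_s.sum())
    for _ in range(max_passes):
        if size == n:
            break
        out = ~in_s
        gains = np.where(out, cnt, -1)
        v = int(np.argmax(gains))
        if gains[v] >= 0 and e + gains[v] >= req[size + 1]:
            in_s[v] = True
            e += int(gains[v])
            cnt += adj[:, v]
            size += 1
            continue
        # swap: try the weakest members against the best outsider
        improved = False
        members = np.flatnonzero(in_s)
        order = members[np.argsort(cnt[members])][:3]
        for u in order:
            e_wo = e - int(cnt[u])
            cand_gain = cnt - adj[u, :].astype(np.int64)
            cand_gain[in_s] = -1
            cand_gain[u] = -1
            v2 = int(np.argmax(cand_gain))
            new_e = e_wo + int(cand_gain[v2])
            if cand_gain[v2] >= 0 and new_e > e and new_e >= req[size]:
                in_s[u] = False
                cnt -= adj[:, u]
                in_s[v2] = True
                cnt += adj[:, v2]
                e = new_e
                improved = True
                break
        if not improved:
            break
    return in_s, e


def _completable(e: int, size: int, sorted_out_cnt: np.ndarray,
                 req: np.ndarray) -> bool:
    """Can S possibly extend to a feasible set of some larger size?

    Optimistic bound: the r best outsiders contribute their full current
    cross-degrees plus all C(r, 2) pairs among themselves.
    """
    if sorted_out_cnt.size == 0:
        return False
    r = np.arange(1, sorted_out_cnt.size + 1)
    ub = e + r * (r - 1) // 2 + np.cumsum(sorted_out_cnt)
    return bool(np.any(ub >= req[size + r]))


def _construct(adj: np.ndarray, req: np.ndarray, degrees: np.ndarray,
               rcl_alpha: float, rng: np.random.Generator
               ) -> tuple[np.ndarray, int]:
    """One randomized greedy growth; returns the best feasible set found
    (after peel repair of the final prefix)."""
    n = adj.shape[0]
    dmax, dmin = int(degrees.max()), int(degrees.min())
    rcl0 = np.flatnonzero(degrees >= dmax - rcl_alpha * (dmax - dmin))
    v0 = int(rng.choice(rcl0))

    in_s = np.zeros(n, dtype=bool)
    in_s[v0] = True
    cnt = adj[:, v0].astype(np.int64).copy()
    e = 0
    size = 1
    best = in_s.copy()
    best_e = 0
    check_period = 8
    steps = 0
    while size < n:
        out = np.flatnonzero(~in_s)
        g = cnt[out]
        gmax, gmin = int(g.max()), int(g.min())
        rcl = out[g >= gmax - rcl_alpha * (gmax - gmin)]
        v = int(rng.choice(rcl))
        in_s[v] = True
        e += int(cnt[v])
        cnt += adj[:, v]
        size += 1
        steps += 1
        if e >= req[size]:
            if size > int(best.sum()):
                best = in_s.copy()
                best_e = e
        elif steps % check_period == 0:
            out_cnt = np.sort(cnt[~in_s])[::-1]
            if not _completable(e, size, out_cnt, req):
                break
    if e >= req[size] and size > int(best.sum()):
        best, best_e = in_s.copy(), e
    repaired, rep_e = _peel(adj, in_s, e, req, rng)
    if int(repaired.sum()) > int(best.sum()):
        best, best_e = repaired, rep_e
    return best, best_e


def max_quasi_clique_grasp(graph: Graph, spec: QuasiCliqueSpec,
                           iterations: int = DEFAULT_ITERATIONS,
                           rcl_alpha: float = DEFAULT_RCL_ALPHA,
                           seed: int | None = None) -> SolveResult:
    """Multi-start GRASP maximum γ-quasi-clique search.

    Deterministic for a fixed ``seed``; the best-so-far size is
    non-decreasing across iterations.  The returned set is re-verified with
    the exact rational density test and never flagged optimal.
    """
    if spec.lam is not None or spec.require_connected:
        raise NotImplementedError("GRASP handles the plain γ-condition only")
    if iterations < 1:
        raise ValueError("iterations must be >= 1")
    if not (0.0 <= rcl_alpha <= 1.0):
        raise ValueError("rcl_alpha must lie in [0, 1]")
    n = graph.n
    req = _req_table(n, spec.gamma)

    # supercritical shortcut: the whole graph is already γ-dense
    if graph.m >= req[n]:
        return make_result(graph, range(n), spec, engine="grasp",
                           is_optimal=False, seed=seed)

    rng = np.random.default_rng(seed)
    adj = graph.adjacency_matrix()
    degrees = graph.degrees()

    # deterministic peel start from the whole graph
    full = np.ones(n, dtype=bool)
    best, best_e = _peel(adj, full, graph.m, req)
    best, best_e = _local_search(adj, best, best_e, req)

    for _ in range(iterations):
        cand, e = _construct(adj, req, degrees, rcl_alpha, rng)
        cand, e = _local_search(adj, cand, e, req)
        if int(cand.sum()) > int(best.sum()) or (
                int(cand.sum()) == int(best.sum()) and e > best_e):
            best, best_e = cand, e
    return make_result(graph, np.flatnonzero(best).tolist(), spec,
                       engine="grasp", is_optimal=False, seed=seed)
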