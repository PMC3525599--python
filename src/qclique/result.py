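"""Common result container for all maximum-quasi-clique engines."""

from __future__ import annotations

from dataclasses import dataclass
from fractions import Fraction

from .density import QuasiCliqueSpec, edge_density, internal_edge_count, is_feasible
from .graph import Graph

__all__ = ["SolveResult", "make_result"]


@dataclass(frozen=True)
class SolveResult:
    """A (candidate) maximum γ-quasi-clique and how it was obtained.

    ``is_optimal`` is only ever set by the provably exact engines (brute
    force, branch-and-bound, MIP with an optimality-proving backend).
    """

    vertices: frozenset[str]
    size: int
    edges_within: int
    density: Fraction
    is_optimal: bool
    engine: str
    seed: int | None = None

    def to_dict(self) -> dict:
        return {
            "vertices": sorted(self.vertices),
            "size": self.size,
            "edges_within": self.edges_within,
            "density": float(self.density),
            "is_optimal": self.is_optimal,
            "engine": self.engine,
            "seed": self.seed,
        }


def make_result(graph: Graph, indices, spec: QuasiCliqueSpec, *, engine: str,
                is_optimal: bool, seed: int | None = None) -> SolveResult:
    """Build a :class:`SolveResult`, re-verifying feasibility independently.

    Every engine funnels its answer through this check, which re-evaluates
    the exact rational density test — a guard against solver tolerance and
    bookkeeping artifacts.
    """
    labels = frozenset(graph.label_of(i) if isinstance(i, int) else i
                       for i in indices)
    if not labels:
        raise ValueError("engines must return at least one vertex")
    if not is_feasible(graph, labels, spec):
        raise RuntimeError(f"engine {engine!r} returned an infeasible set "
                           f"(this is a bug): {sorted(labels)}")
    return SolveResult(
        vertices=labels,
        size=len(labels),
        edges_within=internal_edge_count(graph, labels),
        density=edge_density(graph, labels),
        is_optimal=is_optimal,
        engine=engine,
        seed=seed,
    )
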