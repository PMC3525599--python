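"""Exact verification of γ-quasi-clique and (λ,γ)-quasi-clique membership.

A vertex subset S of size k is a γ-quasi-clique when its induced edge count is
at least γ·k(k−1)/2, i.e. its edge density is at least γ.  The (λ,γ) variant
(a "γ-core" in the modularity literature) additionally requires every member
to have at least ⌈λ(k−1)⌉ neighbours inside S.  All threshold comparisons are
carried out in exact rational arithmetic — γ and λ are parsed from decimal
strings into :class:`fractions.Fraction` and the density test is the integer
comparison ``2·den·|E(S)| >= num·k(k−1)`` — so boundary cases such as
⌈0.85·10⌉ are never misclassified by floating point.

Connectivity is *not* part of the base definition (a γ-quasi-clique may be
disconnected); ``require_connected=True`` opts into the connected variant.
"""

from __future__ import annotations

import math
from dataclasses import dataclass, field
from fractions import Fraction
from typing import Iterable

import networkx as nx

from .graph import Graph

__all__ = [
    "QuasiCliqueSpec",
    "to_fraction",
    "required_edges",
    "internal_edge_count",
    "edge_density",
    "is_gamma_quasi_clique",
    "is_lambda_gamma_quasi_clique",
    "is_feasible",
    "subset_diameter",
]


def to_fraction(value) -> Fraction:
    """Parse a density threshold into an exact rational.

    Decimal strings ("0.85") and floats are interpreted through their decimal
    representation, so ``0.85`` means exactly 85/100 rather than the nearest
    binary float.
    """
    if isinstance(value, Fraction):
        return value
    if isinstance(value, int):
        return Fraction(value)
    if isinstance(value, float):
        return Fraction(repr(value))
    return Fraction(str(value))


@dataclass(frozen=True)
class QuasiCliqueSpec:
    """Density threshold γ, optional degree fraction λ, connectivity flag."""

    gamma: Fraction
    lam: Fraction | None = None
    require_connected: bool = False

    def __post_init__(self) -> None:
        object.__setattr__(self, "gamma", to_fraction(self.gamma))
        if not (0 < self.gamma <= 1):
            raise ValueError(f"gamma must lie in (0, 1], got {self.gamma}")
        if self.lam is not None:
            object.__setattr__(self, "lam", to_fraction(self.lam))
            if not (0 <= self.lam <= 1):
                raise ValueError(f"lambda must lie in [0, 1], got {self.lam}")


def required_edges(k: int, gamma) -> int:
    """Minimum internal edge count for a γ-dense subset of size k: ⌈γ·k(k−1)/2⌉."""
    if k < 1:
        raise ValueError("k must be >= 1")
    gamma = to_fraction(gamma)
    if not (0 < gamma <= 1):
        raise ValueError(f"gamma must lie in (0, 1], got {gamma}")
    if k == 1:
        return 0
    v = gamma * k * (k - 1) / 2
    return int(math.ceil(v))  # Fraction.__ceil__ is exact


def _subset_indices(graph: Graph, subset: Iterable[str | int]) -> list[int]:
    idx = []
    for v in subset:
        idx.append(v if isinstance(v, int) else graph.index_of(v))
    if not idx:
        raise ValueError("subset must be non-empty")
    n = graph.n
    for i in idx:
        if not (0 <= i < n):
            raise ValueError(f"vertex index {i} out of range")
    if len(set(idx)) != len(idx):
        raise ValueError("subset contains repeated vertices")
    return idx


def internal_edge_count(graph: Graph, subset: Iterable[str | int]) -> int:
    """Number of edges of ``graph`` with both endpoints in ``subset``."""
    idx = _subset_indices(graph, subset)
    if len(idx) == graph.n:
        return graph.m
    s = set(idx)
    adj = graph.adjacency
    return sum(len(adj[i] & s) for i in idx) // 2


def edge_density(graph: Graph, subset: Iterable[str | int]) -> Fraction:
    """Induced edge count over C(k, 2), as an exact rational; 1 for k = 1."""
    idx = _subset_indices(graph, subset)
    k = len(idx)
    if k == 1:
        return Fraction(1)
    return Fraction(internal_edge_count(graph, idx), k * (k - 1) // 2)


def _connected(graph: Graph, idx: list[int]) -> bool:
    sub = nx.Graph()
    sub.add_nodes_from(idx)
    s = set(idx)
    for i in idx:
        for j in graph.adjacency[i]:
            if j in s and i < j:
                sub.add_edge(i, j)
    return nx.is_connected(sub)


def is_gamma_quasi_clique(graph: Graph, subset: Iterable[str | int],
                          spec: QuasiCliqueSpec) -> bool:
    """True iff ``subset`` satisfies the γ-density condition of ``spec``.

    The comparison is the exact integer test against ⌈γ·k(k−1)/2⌉; with
    ``require_connected`` the induced subgraph must additionally be connected.
    """
    if spec.lam is not None:
        raise ValueError("spec.lam is set; use is_lambda_gamma_quasi_clique")
    idx = _subset_indices(graph, subset)
    k = len(idx)
    if internal_edge_count(graph, idx) < required_edges(k, spec.gamma):
        return False
    if spec.require_connected and k > 1 and not _connected(graph, idx):
        return False
    return True


def is_lambda_gamma_quasi_clique(graph: Graph, subset: Iterable[str | int],
                                 spec: QuasiCliqueSpec) -> bool:
    """True iff every member has ≥ ⌈λ(k−1)⌉ internal neighbours and the
    γ-density condition holds."""
    if spec.lam is None:
        raise ValueError("spec.lam is required for the (λ,γ) variant")
    idx = _subset_indices(graph, subset)
    k = len(idx)
    s = set(idx)
    min_deg = math.ceil(spec.lam * (k - 1))
    adj = graph.adjacency
    if any(len(adj[i] & s) < min_deg for i in idx):
        return False
    if internal_edge_count(graph, idx) < required_edges(k, spec.gamma):
        return False
    if spec.require_connected and k > 1 and not _connected(graph, idx):
        return False
    return True


def is_feasible(graph: Graph, subset: Iterable[str | int],
                spec: QuasiCliqueSpec) -> bool:
    """Dispatch to the γ or (λ,γ) membership test according to ``spec``."""
    if spec.lam is None:
        return is_gamma_quasi_clique(graph, subset, spec)
    return is_lambda_gamma_quasi_clique(graph, subset, spec)


def subset_diameter(graph: Graph, subset: Iterable[str | int]) -> int | float:
    """Diameter of the induced subgraph; ``math.inf`` if it is disconnected."""
    idx = _subset_indices(graph, subset)
    if len(idx) == 1:
        return 0
    sub = nx.Graph()
    sub.add_nodes_from(idx)
    s = set(idx)
    for i in idx:
        for j in graph.adjacency[i]:
            if j in s and i < j:
                sub.add_edge(i, j)
    if not nx.is_connected(sub):
        return math.inf
    return nx.diameter(sub)
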