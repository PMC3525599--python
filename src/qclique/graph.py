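"""Undirected simple-graph container, edge-list I/O and random-graph generators.

The graph model is deliberately minimal: opaque string node labels (gene/protein
names in interaction-network use), 0-based internal indices that never appear in
files, and a single plain-text exchange format (one edge per line, two
whitespace-separated labels, ``#`` comments).  Isolated vertices survive a
write/read round trip through a commented header listing every label, because
the vertex count ``n`` matters to relative-size statistics.

Random graphs follow the mean-field G(n, p) model: every one of the C(n, 2)
vertex pairs is linked independently with probability ``p``.  All randomness
goes through :class:`numpy.random.Generator` seeded explicitly, so every
sampled graph is reproducible from ``(n, p, seed)``.
"""

from __future__ import annotations

import io
import logging
from dataclasses import dataclass
from fractions import Fraction
from functools import cached_property
from pathlib import Path
from typing import IO, Iterable, Iterator, Sequence

import numpy as np

__all__ = [
    "Graph",
    "ERModel",
    "read_edge_list",
    "write_edge_list",
    "sample_gnp",
    "plant_dense_subset",
]

logger = logging.getLogger("qclique.graph")

_VERTEX_HEADER = "# vertices:"


class Graph:
    """An undirected simple graph with labelled vertices.

    Parameters
    ----------
    labels
        Unique, non-empty, whitespace-free vertex labels in presentation order.
    edges
        Iterable of ``(i, j)`` index pairs (0-based).  Self-loops and duplicate
        edges (in either orientation) are rejected; use :func:`read_edge_list`
        for tolerant parsing of real-world exports.
    """

    __slots__ = ("_labels", "_index", "_edges", "__dict__")

    def __init__(self, labels: Sequence[str], edges: Iterable[tuple[int, int]] = ()):
        labels = list(labels)
        for lab in labels:
            if not lab or lab.split() != [lab]:
                raise ValueError(f"invalid vertex label {lab!r}: labels must be "
                                 "non-empty and contain no whitespace")
        if len(set(labels)) != len(labels):
            raise ValueError("duplicate vertex labels")
        self._labels = labels
        self._index = {lab: i for i, lab in enumerate(labels)}
        arr = np.asarray(list(edges) if not isinstance(edges, np.ndarray) else edges,
                         dtype=np.int64)
        if arr.size == 0:
            arr = np.empty((0, 2), dtype=np.int64)
        if arr.ndim != 2 or arr.shape[1] != 2:
            raise ValueError("edges must be (i, j) pairs")
        n = len(labels)
        if arr.size and (arr.min() < 0 or arr.max() >= n):
            raise ValueError("edge endpoint index out of range")
        if np.any(arr[:, 0] == arr[:, 1]):
            raise ValueError("self-loops are not allowed in a simple graph")
        # canonical orientation (min, max) then uniqueness check
        arr = np.sort(arr, axis=1)
        if arr.shape[0]:
            uniq = np.unique(arr, axis=0)
            if uniq.shape[0] != arr.shape[0]:
                raise ValueError("duplicate edges are not allowed; "
                                 "read_edge_list deduplicates tolerantly")
            # keep canonical sorted order for determinism
            arr = uniq
        self._edges = arr

    # -- basic accessors ---------------------------------------------------

    @property
    def labels(self) -> list[str]:
        return list(self._labels)

    @property
    def n(self) -> int:
        return len(self._labels)

    @property
    def m(self) -> int:
        return int(self._edges.shape[0])

    def index_of(self, label: str) -> int:
        try:
            return self._index[label]
        except KeyError:
            raise KeyError(f"unknown vertex label {label!r}") from None

    def label_of(self, index: int) -> str:
        return self._labels[index]

    def edge_array(self) -> np.ndarray:
        """Edges as an ``(m, 2)`` int array of canonical ``(min, max)`` pairs."""
        return self._edges.copy()

    def edges(self) -> Iterator[tuple[str, str]]:
        for i, j in self._edges:
            yield self._labels[int(i)], self._labels[int(j)]

    # -- derived structure (cached) ----------------------------------------

    @cached_property
    def adjacency(self) -> list[set[int]]:
        """Per-vertex sets of neighbour indices (symmetric, no self-loops)."""
        adj: list[set[int]] = [set() for _ in range(self.n)]
        for i, j in self._edges:
            adj[int(i)].add(int(j))
            adj[int(j)].add(int(i))
        return adj

    @cached_property
    def _neighbor_masks(self) -> list[int]:
        """Adjacency as python-int bitmasks (bit j of mask[i] = edge i-j)."""
        masks = [0] * self.n
        for i, j in self._edges:
            i, j = int(i), int(j)
            masks[i] |= 1 << j
            masks[j] |= 1 << i
        return masks

    def neighbor_masks(self) -> list[int]:
        return list(self._neighbor_masks)

    def adjacency_matrix(self) -> np.ndarray:
        """Dense boolean adjacency matrix (n x n)."""
        a = np.zeros((self.n, self.n), dtype=bool)
        if self.m:
            a[self._edges[:, 0], self._edges[:, 1]] = True
            a[self._edges[:, 1], self._edges[:, 0]] = True
        return a

    def degrees(self) -> np.ndarray:
        d = np.zeros(self.n, dtype=np.int64)
        if self.m:
            d += np.bincount(self._edges[:, 0], minlength=self.n)
            d += np.bincount(self._edges[:, 1], minlength=self.n)
        return d

    def degree_sequence(self) -> list[int]:
        return sorted(int(x) for x in self.degrees())

    def has_edge(self, u: str, v: str) -> bool:
        i, j = self.index_of(u), self.index_of(v)
        return j in self.adjacency[i]

    def __repr__(self) -> str:  # pragma: no cover - cosmetic
        return f"Graph(n={self.n}, m={self.m})"


@dataclass(frozen=True)
class ERModel:
    """Parameters of a mean-field (Erdős–Rényi) random graph G(n, p).

    Every pair of the ``n`` vertices is linked independently with probability
    ``p``; ``seed`` makes the sample reproducible.
    """

    n: int
    p: float
    seed: int

    def __post_init__(self) -> None:
        if self.n < 1:
            raise ValueError("n must be >= 1")
        if not (0.0 <= float(self.p) <= 1.0):
            raise ValueError("p must lie in [0, 1]")

    def sample(self) -> Graph:
        return sample_gnp(self)


# -- I/O -------------------------------------------------------------------


def read_edge_list(source: str | Path | IO[str]) -> Graph:
    """Parse a whitespace-separated edge list into a :class:`Graph`.

    Lines beginning with ``#`` are comments; a ``# vertices:`` comment (as
    written by :func:`write_edge_list`) registers labels so isolated vertices
    round-trip.  Duplicate edges are collapsed with a logged warning; a
    self-loop is a hard error naming the offending line.
    """
    if isinstance(source, (str, Path)):
        with open(source, "r", encoding="utf-8") as fh:
            return read_edge_list(fh)

    labels: list[str] = []
    index: dict[str, int] = {}
    edges: list[tuple[int, int]] = []
    seen: set[tuple[int, int]] = set()
    n_dup = 0

    def intern(lab: str) -> int:
        if lab not in index:
            index[lab] = len(labels)
            labels.append(lab)
        return index[lab]

    for lineno, raw in enumerate(source, start=1):
        line = raw.strip()
        if not line:
            continue
        if line.startswith("#"):
            if line.startswith(_VERTEX_HEADER):
                for lab in line[len(_VERTEX_HEADER):].split():
                    intern(lab)
            continue
        tokens = line.split()
        if len(tokens) < 2:
            raise ValueError(f"line {lineno}: expected two endpoint labels, "
                             f"got {line!r}")
        a, b = tokens[0], tokens[1]
        if a == b:
            raise ValueError(f"line {lineno}: self-loop on {a!r} is not allowed")
        i, j = intern(a), intern(b)
        key = (i, j) if i < j else (j, i)
        if key in seen:
            n_dup += 1
            continue
        seen.add(key)
        edges.append(key)

    if n_dup:
        logger.warning("collapsed %d duplicate edge line(s)", n_dup)
    return Graph(labels, edges)


def write_edge_list(graph: Graph, sink: IO[str]) -> None:
    """Serialize ``graph`` as one ``label1<TAB>label2`` line per edge.

    A ``# vertices:`` header carries the full label list (in presentation
    order) so that isolated vertices and ``n`` survive a round trip.
    """
    sink.write(_VERTEX_HEADER + " " + " ".join(graph.labels) + "\n")
    for u, v in graph.edges():
        sink.write(f"{u}\t{v}\n")


def graph_to_string(graph: Graph) -> str:
    buf = io.StringIO()
    write_edge_list(graph, buf)
    return buf.getvalue()


# -- random generation -----------------------------------------------------


def _default_labels(n: int) -> list[str]:
    return [f"v{i}" for i in range(n)]


def sample_gnp(model: ERModel | int, p: float | None = None,
               seed: int | None = None) -> Graph:
    """Sample a mean-field random graph G(n, p).

    Accepts either an :class:`ERModel` or ``(n, p, seed)`` directly.  The same
    seed always yields the identical edge set.
    """
    if not isinstance(model, ERModel):
        if p is None or seed is None:
            raise TypeError("sample_gnp requires an ERModel or (n, p, seed)")
        model = ERModel(int(model), float(p), int(seed))
    n = model.n
    rng = np.random.default_rng(model.seed)
    if n < 2 or model.p == 0.0:
        return Graph(_default_labels(n))
    iu, ju = np.triu_indices(n, k=1)
    if model.p >= 1.0:
        keep = np.ones(iu.shape[0], dtype=bool)
    else:
        keep = rng.random(iu.shape[0]) < model.p
    edges = np.stack([iu[keep], ju[keep]], axis=1)
    return Graph(_default_labels(n), edges)


def plant_dense_subset(background: ERModel, k: int, gamma, seed: int
                       ) -> tuple[Graph, frozenset[str]]:
    """G(n, p) sample with a designated k-subset topped up to γ-density.

    Uniformly chosen missing pairs inside a randomly selected ``k``-subset are
    added until the subset's internal edge count reaches
    ``ceil(γ·k(k−1)/2)``, so the planted set is a feasible γ-quasi-clique by
    construction.  Returns the graph and the planted label set.
    """
    from .density import required_edges  # local import avoids a cycle

    if k > background.n:
        raise ValueError(f"k={k} exceeds n={background.n}")
    gamma = Fraction(str(gamma)) if not isinstance(gamma, Fraction) else gamma
    if not (0 < gamma <= 1):
        raise ValueError("gamma must lie in (0, 1]")

    base = sample_gnp(background)
    rng = np.random.default_rng(seed)
    members = np.sort(rng.choice(background.n, size=k, replace=False))
    member_set = {int(v) for v in members}

    edge_set = {(int(i), int(j)) for i, j in base.edge_array()}
    internal = [e for e in edge_set if e[0] in member_set and e[1] in member_set]
    need = required_edges(k, gamma)
    missing = [(int(members[a]), int(members[b]))
               for a in range(k) for b in range(a + 1, k)
               if (int(members[a]), int(members[b])) not in edge_set]
    rng.shuffle(missing)
    for e in missing[: max(0, need - len(internal))]:
        edge_set.add(e)
    graph = Graph(base.labels, sorted(edge_set))
    planted = frozenset(base.label_of(v) for v in member_set)
    return graph, planted
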