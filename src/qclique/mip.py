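"""Mixed-integer linear formulation of the maximum γ-quasi-clique problem.

The natural formulation maximizes Σ x_i over binary membership variables
subject to the nonconvex quadratic density constraint

    Σ_{(i,j)∈E} x_i x_j  ≥  γ · Σ_{i<j} x_i x_j .

Each product x_i·x_j is linearized by a continuous variable w_ij ∈ [0, 1]
tied down by four linear inequalities (w ≤ x_i, w ≤ x_j, w ≥ x_i + x_j − 1,
w ≥ 0), giving a MILP with n binary + n(n−1)/2 continuous variables and
4·n(n−1)/2 + 1 constraints.  The density constraint is cleared of the
rational γ's denominator before serialization so that boundary densities are
represented with integer coefficients — no feasibility-tolerance ambiguity.

Backends are pluggable (:class:`MilpBackend`); the default uses HiGHS through
:func:`scipy.optimize.milp`.  The combinatorial branch-and-bound engine in
:mod:`qclique.exact` works without any backend.
"""

from __future__ import annotations

from dataclasses import dataclass, field
from fractions import Fraction
from typing import Protocol, runtime_checkable

import numpy as np

from .density import QuasiCliqueSpec, to_fraction
from .graph import Graph
from .result import SolveResult, make_result

__all__ = ["MIPModel", "build_mip", "solve_mip", "MilpBackend", "ScipyHighsBackend"]


@dataclass(frozen=True)
class Constraint:
    """Σ coeffs·vars  (sense)  rhs, with sense in {"<=", ">="}."""

    name: str
    coeffs: tuple[tuple[str, int], ...]
    sense: str
    rhs: int


@dataclass
class MIPModel:
    """The linearized maximum γ-quasi-clique MILP for one graph."""

    graph: Graph
    gamma: Fraction
    binary_vars: list[str]
    continuous_vars: list[str]
    constraints: list[Constraint]
    objective: list[str] = field(default_factory=list)  # maximize Σ of these

    @property
    def n_variables(self) -> int:
        return len(self.binary_vars) + len(self.continuous_vars)

    @property
    def n_constraints(self) -> int:
        return len(self.constraints)

    def to_lp(self) -> str:
        """Deterministic CPLEX-LP-format text serialization."""
        lines = ["Maximize", " obj: " + " + ".join(self.objective), "Subject To"]
        for c in self.constraints:
            terms = []
            for name, coef in c.coeffs:
                if coef == 1:
                    terms.append(f"+ {name}")
                elif coef == -1:
                    terms.append(f"- {name}")
                elif coef >= 0:
                    terms.append(f"+ {coef} {name}")
                else:
                    terms.append(f"- {-coef} {name}")
            lines.append(f" {c.name}: " + " ".join(terms) + f" {c.sense} {c.rhs}")
        lines.append("Bounds")
        for w in self.continuous_vars:
            lines.append(f" 0 <= {w} <= 1")
        lines.append("Binary")
        lines.append(" " + " ".join(self.binary_vars))
        lines.append("End")
        return "\n".join(lines) + "\n"


def build_mip(graph: Graph, gamma) -> MIPModel:
    """Construct the linearized MILP (stable variable naming, sorted labels)."""
    g = to_fraction(gamma)
    if not (0 < g <= 1):
        raise ValueError("gamma must lie in (0, 1]")
    labels = sorted(graph.labels)
    x = {lab: f"x_{lab}" for lab in labels}
    pairs = [(labels[a], labels[b])
             for a in range(len(labels)) for b in range(a + 1, len(labels))]
    w = {pr: f"w_{pr[0]}_{pr[1]}" for pr in pairs}

    cons: list[Constraint] = []
    for idx, (u, v) in enumerate(pairs):
        wn = w[(u, v)]
        cons.append(Constraint(f"lin{idx}a", ((wn, 1), (x[u], -1)), "<=", 0))
        cons.append(Constraint(f"lin{idx}b", ((wn, 1), (x[v], -1)), "<=", 0))
        cons.append(Constraint(f"lin{idx}c", ((wn, 1), (x[u], -1), (x[v], -1)),
                               ">=", -1))
        cons.append(Constraint(f"lin{idx}d", ((wn, 1),), ">=", 0))

    num, den = g.numerator, g.denominator
    dens_terms = []
    for (u, v) in pairs:
        coef = (den - num) if graph.has_edge(u, v) else -num
        if coef != 0:
            dens_terms.append((w[(u, v)], coef))
    cons.append(Constraint("density", tuple(dens_terms), ">=", 0))

    return MIPModel(
        graph=graph,
        gamma=g,
        binary_vars=[x[lab] for lab in labels],
        continuous_vars=[w[pr] for pr in pairs],
        constraints=cons,
        objective=[x[lab] for lab in labels],
    )


@runtime_checkable
class MilpBackend(Protocol):
    """Solve contract: prove optimality and return variable values."""

    name: str

    def solve(self, model: MIPModel, time_limit: float | None = None
              ) -> tuple[str, dict[str, float]]:
        """Return ``(status, values)`` with status "optimal" only when the
        solver proved optimality; ``values`` maps variable name to value."""
        ...


class ScipyHighsBackend:
    """HiGHS via :func:`scipy.optimize.milp`."""

    name = "scipy-highs"

    def solve(self, model: MIPModel, time_limit: float | None = None
              ) -> tuple[str, dict[str, float]]:
        from scipy import optimize, sparse

        names = model.binary_vars + model.continuous_vars
        col = {nm: i for i, nm in enumerate(names)}
        nvar = len(names)
        rows, cols, vals, lo, hi = [], [], [], [], []
        for r, c in enumerate(model.constraints):
            for nm, coef in c.coeffs:
                rows.append(r)
                cols.append(col[nm])
                vals.append(float(coef))
            if c.sense == "<=":
                lo.append(-np.inf)
                hi.append(float(c.rhs))
            else:
                lo.append(float(c.rhs))
                hi.append(np.inf)
        A = sparse.csr_matrix((vals, (rows, cols)),
                              shape=(len(model.constraints), nvar))
        cvec = np.zeros(nvar)
        for nm in model.objective:
            cvec[col[nm]] = -1.0  # scipy minimizes
        integrality = np.zeros(nvar)
        integrality[: len(model.binary_vars)] = 1
        bounds = optimize.Bounds(np.zeros(nvar), np.ones(nvar))
        options = {}
        if time_limit is not None:
            options["time_limit"] = float(time_limit)
        res = optimize.milp(c=cvec,
                            constraints=optimize.LinearConstraint(A, lo, hi),
                            integrality=integrality, bounds=bounds,
                            options=options)
        if res.status == 0:
            status = "optimal"
        elif res.x is not None:
            status = "feasible"
        else:
            status = "failed"
        values = {nm: float(res.x[col[nm]]) for nm in names} if res.x is not None else {}
        return status, values


def solve_mip(model: MIPModel, backend: MilpBackend | None = None,
              time_limit: float | None = None) -> SolveResult:
    """Solve the model and return a re-verified :class:`SolveResult`.

    Binaries are rounded at 0.5 and the selected set is re-checked through
    the exact rational density test before anything is returned.
    """
    if backend is None:
        backend = ScipyHighsBackend()
    if not isinstance(backend, MilpBackend):
        raise TypeError("backend does not satisfy the MilpBackend solve contract")
    status, values = backend.solve(model, time_limit=time_limit)
    if status == "failed" or not values:
        raise RuntimeError(f"MILP backend {backend.name!r} failed to produce "
                           "a solution")
    chosen = [nm[len("x_"):] for nm in model.binary_vars if values[nm] >= 0.5]
    if not chosen:  # degenerate all-zero optimum; a singleton is always feasible
        chosen = [sorted(model.graph.labels)[0]]
    spec = QuasiCliqueSpec(gamma=model.gamma)
    return make_result(model.graph, chosen, spec, engine="mip",
                       is_optimal=(status == "optimal"))
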