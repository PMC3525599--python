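"""Dense-percolation sweep experiments over G(n, p).

The pipeline samples replicate random graphs along a grid of edge
probabilities at fixed density threshold γ, solves each for the maximum
γ-quasi-clique with a chosen engine, and aggregates sizes.  As p crosses γ
the mean relative size jumps from O(log n / n) to 1 — the first-order dense
percolation transition; :func:`step_function_reference` provides the
theoretical limiting curve to overlay.

Replication of the small-graph benchmark table (exact sizes in G(100, p),
p = 0.05 … 0.15, 100 replicates per cell, with the analytic bound interval
alongside) is :func:`replicate_table1`.  All sweeps are reproducible: the
replicate with index i uses seed ``seed_base + i``, and p-grid values are
carried as decimal strings so output keys never suffer float drift.
"""

from __future__ import annotations

from dataclasses import dataclass
from fractions import Fraction
from typing import Callable, Iterable, Sequence

import numpy as np
import pandas as pd

from . import bounds as _bounds
from .density import QuasiCliqueSpec, to_fraction
from .exact import max_quasi_clique_bruteforce, max_quasi_clique_exact
from .graph import ERModel, sample_gnp
from .grasp import max_quasi_clique_grasp
from .result import SolveResult

__all__ = [
    "SweepRecord",
    "sweep_density",
    "step_function_reference",
    "replicate_table1",
    "sweep_relative_curve",
    "records_to_dataframe",
    "EXACT_N_LIMIT",
]

EXACT_N_LIMIT = 150


@dataclass(frozen=True)
class SweepRecord:
    """Aggregated maximum-quasi-clique sizes for one (n, p, γ) cell."""

    n: int
    p: str  # decimal string, exactly as given in the grid
    gamma: Fraction
    reps: int
    mean_size: float
    min_size: int
    max_size: int
    mean_relative: float
    engine: str
    seed_base: int

    def to_dict(self) -> dict:
        return {
            "n": self.n, "p": self.p, "gamma": str(self.gamma),
            "reps": self.reps, "mean_size": self.mean_size,
            "min_size": self.min_size, "max_size": self.max_size,
            "mean_relative": self.mean_relative, "engine": self.engine,
            "seed_base": self.seed_base,
        }


def _p_label(p) -> str:
    return p if isinstance(p, str) else repr(float(p))


def _make_solver(engine: str, n: int, grasp_iterations: int,
                 grasp_alpha: float) -> Callable[[object, QuasiCliqueSpec, int], SolveResult]:
    if engine == "exact":
        if n > EXACT_N_LIMIT:
            raise ValueError(
                f"exact engine is limited to n <= {EXACT_N_LIMIT} "
                f"(got n={n}); use engine='grasp' for larger graphs")
        return lambda g, spec, seed: max_quasi_clique_exact(g, spec)
    if engine == "brute":
        return lambda g, spec, seed: max_quasi_clique_bruteforce(g, spec)
    if engine == "grasp":
        return lambda g, spec, seed: max_quasi_clique_grasp(
            g, spec, iterations=grasp_iterations, rcl_alpha=grasp_alpha,
            seed=seed)
    raise ValueError(f"unknown engine {engine!r}")


def sweep_density(n: int, p_grid: Sequence, gamma, reps: int,
                  engine: str = "exact", seed_base: int = 0,
                  grasp_iterations: int = 10, grasp_alpha: float = 0.2
                  ) -> list[SweepRecord]:
    """Sample ``reps`` graphs per grid point and solve each for ω_γ.

    Replicate i at every p uses seed ``seed_base + i`` (common random
    numbers across the grid), so an identical call reproduces identical
    records byte for byte.
    """
    if reps < 1:
        raise ValueError("reps must be >= 1")
    g = to_fraction(gamma)
    spec = QuasiCliqueSpec(gamma=g)
    solver = _make_solver(engine, n, grasp_iterations, grasp_alpha)
    records = []
    for p in p_grid:
        pf = float(p)
        sizes = []
        for i in range(reps):
            graph = sample_gnp(ERModel(n, pf, seed_base + i))
            sizes.append(solver(graph, spec, seed_base + i).size)
        arr = np.array(sizes)
        records.append(SweepRecord(
            n=n, p=_p_label(p), gamma=g, reps=reps,
            mean_size=float(arr.mean()), min_size=int(arr.min()),
            max_size=int(arr.max()), mean_relative=float(arr.mean()) / n,
            engine=engine, seed_base=seed_base))
    return records


def step_function_reference(gamma, p_grid: Sequence) -> list[tuple[str, float]]:
    """Theoretical n → ∞ relative size of the largest γ-dense cluster.

    0 for p < γ and 1 for p > γ (the first-order step).  The boundary point
    p = γ is emitted as 1: the whole graph's density concentrates at p, so at
    p = γ it is γ-dense with asymptotic probability 1/2 — the limit value at
    the jump itself is a convention, documented here as such.
    """
    g = to_fraction(gamma)
    out = []
    for p in p_grid:
        val = 1.0 if to_fraction(p) >= g else 0.0
        out.append((_p_label(p), val))
    return out


def replicate_table1(gammas: Iterable, p_grid: Sequence, n: int = 100,
                     reps: int = 100, seed_base: int = 0,
                     engine: str = "exact") -> pd.DataFrame:
    """Analytic bound intervals next to empirical exact sizes, per (γ, p).

    Columns: gamma, p, bound_lo, bound_hi, mean, min, max.
    """
    rows = []
    for gamma in gammas:
        g = to_fraction(gamma)
        recs = sweep_density(n, p_grid, g, reps, engine=engine,
                             seed_base=seed_base)
        for p, rec in zip(p_grid, recs):
            lo, hi = _bounds.quasi_clique_size_bounds(n, float(p), g)
            rows.append({
                "gamma": str(g), "p": _p_label(p),
                "bound_lo": round(lo, 2), "bound_hi": round(hi, 2),
                "mean": rec.mean_size, "min": rec.min_size,
                "max": rec.max_size,
            })
    return pd.DataFrame(rows, columns=["gamma", "p", "bound_lo", "bound_hi",
                                       "mean", "min", "max"])


def sweep_relative_curve(n_list: Sequence[int], gamma, p_grid: Sequence,
                         reps: int = 3, seed_base: int = 0,
                         grasp_iterations: int = 10, grasp_alpha: float = 0.2
                         ) -> pd.DataFrame:
    """Mean relative maximum-quasi-clique size per (n, p), GRASP engine.

    Suitable to overlay against :func:`step_function_reference`; use a
    refined p step (0.01) where p approaches γ from below to resolve the
    finite-size rounding of the step.
    """
    rows = []
    for n in n_list:
        recs = sweep_density(n, p_grid, gamma, reps, engine="grasp",
                             seed_base=seed_base,
                             grasp_iterations=grasp_iterations,
                             grasp_alpha=grasp_alpha)
        for rec in recs:
            rows.append({"n": n, "p": rec.p,
                         "mean_relative": rec.mean_relative,
                         "mean_size": rec.mean_size, "reps": rec.reps})
    return pd.DataFrame(rows, columns=["n", "p", "mean_relative",
                                       "mean_size", "reps"])


def records_to_dataframe(records: Iterable[SweepRecord]) -> pd.DataFrame:
    return pd.DataFrame([r.to_dict() for r in records])


def plot_relative_curves(df: pd.DataFrame, gamma, path: str) -> None:
    """Convenience overlay plot of sweep curves vs the theoretical step.

    Requires matplotlib (optional extra); not part of the analysis surface.
    """
    import matplotlib
    matplotlib.use("Agg")
    import matplotlib.pyplot as plt

    fig, ax = plt.subplots(figsize=(6, 4))
    for n, sub in df.groupby("n"):
        ps = sub["p"].astype(float)
        ax.plot(ps, sub["mean_relative"], marker="o", label=f"n={n}")
    g = float(to_fraction(gamma))
    ax.step([df["p"].astype(float).min(), g, g, df["p"].astype(float).max()],
            [0, 0, 1, 1], where="post", color="k", ls="--", label="n→∞ step")
    ax.set_xlabel("edge probability p")
    ax.set_ylabel("relative size of max γ-quasi-clique")
    ax.legend()
    fig.tight_layout()
    fig.savefig(path, dpi=150)
    plt.close(fig)
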