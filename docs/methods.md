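# Methods

## Model and definitions

A γ-quasi-clique in a simple undirected graph is a vertex subset S, |S| = k,
with |E(S)| ≥ ⌈γ·k(k−1)/2⌉ for a fixed density threshold γ ∈ (0, 1].
Conventions adopted here, chosen so that quasi-heredity (see below) holds all
the way down to singletons:

* |S| = 1 has density 1 and is always feasible;
* |S| = 2 requires an edge whenever γ > 0;
* "at least γ" with integer edge counts forces the ceiling: when γ·C(k,2) is
  an integer, exactly that many edges pass (ties pass).

Connectivity is **not** required by default: the base definition admits
disconnected subsets, and the size bounds below are unaffected because the
largest connected quasi-clique is sandwiched between the maximum clique and
the largest unconstrained quasi-clique. A `require_connected` flag enables
the connected variant for users who want modules in the literal sense.

The (λ,γ) variant ("γ-core") additionally requires every member to have at
least ⌈λ(k−1)⌉ neighbours inside S. With λ ≥ 1/2 any two members share a
neighbour, so such cores have diameter ≤ 2 — a robustness property checked
by a property test on randomly generated passing subsets.

### Exact rational thresholds

γ and λ are parsed from decimal strings into `fractions.Fraction`; every
feasibility decision reduces to an integer comparison after clearing
denominators. This matters at boundaries: required_edges(5, 0.85) = ⌈8.5⌉ = 9
would be misclassified by a naive `0.85 * 10 <= 9` float test in either
direction depending on rounding. The same cleared-integer coefficients go
into the MIP density constraint, so MILP feasibility tolerances cannot flip
boundary densities either.

## First-moment analytics

For G(n, p), the expected number of γ-quasi-cliques of size k is

    E[Y_k] = C(n, k) · P[Bin(k(k−1)/2, p) ≥ ⌈γ·k(k−1)/2⌉].

Everything is evaluated in log space (log-gamma for the binomial
coefficient, `binom.logsf` with a logsumexp fallback for deep tails), so
E[Y_k] at n = 10¹² is representable. An exact rational tail mode (m ≤ 64)
serves as the internal oracle for the floating path.

* **Critical size k\***: the largest k with E[Y_k] ≥ 1, located by an
  ascending integer scan from k = 2. E[Y_k] = 1 generically falls between
  integers; "last k on the ≥ 1 side" is this package's integerization. The
  asymptotic main term is k* ≈ 2 ln n / D(γ‖p); note the next-order
  correction is −(2/D) ln k, which still contributes ~20% at n = 10⁶ — the
  tests assert monotone convergence to the main term rather than closeness
  at small n.
* **Size bounds**: lower bound 2 ln n / ln(1/p) (maximum-clique plug-in —
  a clique is a γ-quasi-clique for every γ), upper bound 2 ln n / D(γ‖p).
  Only the leading term is implemented; the tabulated reference intervals at
  n = 100 reproduce from it at two decimals, confirming the leading term is
  what such tables report. Bounds are defined for the sparse phase
  0 < p < γ only; for p ≥ γ the whole graph is w.h.p. feasible and the
  question dissolves.
* **Chernoff bound**: the relative-entropy form exp(−m·D(γ‖p)) on
  P[Bin(m,p) ≥ γm], vacuous (=1) for γ ≤ p. It dominates the exact tail on
  the exhaustive m ≤ 30 grid (tested) and coincides with it at γ = 1.
* **Normal tail estimate** (`normal_tail_approx`): the uniform
  saddlepoint-refined normal estimate Φc(w) + φ(w)(1/u − 1/w) with
  w = √(2m·D(a‖p)), a = k/m, and lattice-adjusted u = (1−e^(−t))·√(m·a(1−a)),
  t = ln[a(1−p)/(p(1−a))]. Unlike a plain (or continuity-corrected) normal
  approximation, it keeps the exact large-deviation exponent, which is what
  makes it usable in the regime k ≈ γm ≫ mp where quasi-clique counting
  lives; plain normal forms err by 25–50% there. It is an estimate, not a
  bound; relative error decays roughly like 1/m (cross-checked against exact
  tails in the tests).

## Exact solvers

**Quasi-heredity.** Removing a minimum-internal-degree vertex from a
γ-quasi-clique leaves a γ-quasi-clique: the removed vertex carries at most
the average degree, and the density of the remainder cannot drop below γ.
Feasible sizes therefore form an interval {1, …, ω_γ}, and both exact
engines search sizes upward, stopping at the first size with no feasible
subset. Heredity fails for the (λ,γ) and connected variants, so
branch-and-bound declines them and brute force falls back to a full scan.

**Branch-and-bound.** Adjacency is stored as machine-integer bitmasks;
vertices are visited in descending-degree order. A partial set S (s
vertices, e internal edges) aiming at size k is pruned when

    e + C(k−s, 2) + Σ top_{k−s} |N(v) ∩ S| over candidates v < ⌈γ·k(k−1)/2⌉.

On sparse benchmark instances (n = 100, p ≤ 0.1, γ = 0.85) a solve takes
~0.1 s, so the 100-replicate benchmark table is reproduced exactly in under
half a minute. The brute-force engine (n ≤ 22) enumerates subsets per size
in lexicographic label order and is the oracle in the cross-engine tests;
its witness is the lexicographically smallest optimal label set, while the
other engines return an arbitrary optimum (tests compare sizes).

**MIP.** maximize Σx_i with w_ij linearizing x_i·x_j through w ≤ x_i,
w ≤ x_j, w ≥ x_i + x_j − 1, w ≥ 0, and the single density constraint
Σ_E w ≥ γ·Σ w with γ cleared to integer coefficients: n binary +
C(n,2) continuous variables, 4·C(n,2) + 1 constraints. Backends are
pluggable via a small solve contract; the default is HiGHS through
`scipy.optimize.milp`. Solutions are rounded at 0.5 and re-verified through
the exact rational density test before being returned — as is every result
from every engine — so solver tolerance artifacts cannot surface as
infeasible "optima".

## GRASP heuristic

The multi-start heuristic (defaults: iterations = 100, rcl_alpha = 0.2,
seed mandatory in the API, defaulted and logged in the CLI) combines:

1. **Randomized greedy growth**: add a vertex drawn uniformly from the
   restricted candidate list (candidates whose edge count into S is within
   `rcl_alpha`·(range) of the best). Temporarily sub-γ prefixes are allowed
   while an optimistic completability bound (the same bound as in B&B,
   maximized over target sizes) still admits some feasible larger size;
   always-feasible growth was rejected because γ-quasi-cliques are not
   hereditary *upward* — the best sets often pass through infeasible
   prefixes.
2. **Peel repair**: the final prefix is peeled (drop min-internal-degree,
   random tie-break) until feasible.
3. **Local search**: add moves while feasibility permits, then
   density-improving single swaps, repeated to a fixed pass budget.
4. Two deterministic starts: the whole vertex set (supercritical shortcut —
   for p > γ the graph itself is feasible and the answer is n) and a peel
   from the whole graph. The peel start is what makes the p ↑ γ regime
   work: there the best feasible sets contain a large fraction of all
   vertices (at n = 1000, γ = 0.9, p = 0.88 more than half the graph), and
   growth-style construction essentially never assembles them.

The best feasible set across starts is returned, re-verified, never flagged
optimal. Fixed seed ⇒ bit-identical output; best-so-far size is
non-decreasing in the iteration count.

## Experiment pipelines and scaled-down design

`sweep_density` samples `reps` graphs per grid point (replicate i uses seed
`seed_base + i`, common random numbers across p), solves each with the
chosen engine and aggregates mean/min/max and relative sizes; identical
invocations give byte-identical TSV. `replicate_table1` pairs the empirical
aggregates with the analytic interval per (γ, p). `step_function_reference`
emits the proven n → ∞ limit: 0 below γ, 1 above; at p = γ exactly the
whole-graph density concentrates at γ and feasibility tends to probability
1/2 — the reference emits 1 there as a documented convention, since the
limit at the jump point is not determined by the two one-sided results.

Problem sizes are the package's own desk-scale choices: exact engines serve
the n = 100 benchmark replication (full 100 replicates per cell, as in the
reference table); transition sweeps run GRASP at n ∈ {500, 1000, 2000} with
small iteration counts, rather than the n up to 20,000 used in large-scale
studies. The transition is already unambiguous at these sizes: relative
size < 0.05 at p = 0.5 vs exactly 1 at p = 0.92 (γ = 0.9, n = 1000), with
the maximum curve slope increasing monotonically in n.

## What the synthetic generators do and do not show

All test inputs are generated: G(n, p) samples and planted fixtures
(`plant_dense_subset` tops up a random k-subset with uniformly chosen
missing internal pairs until it is γ-feasible, giving solver tests a known
feasible witness). These match the mean-field model the analytics assume —
independent, homogeneous edges. Real interaction networks are heavy-tailed,
locally clustered and noisy; passing tests here validate the algorithms and
the mean-field theory, not any claim that biological networks are
mean-field. The detection machinery (solvers, verification, I/O) is
model-agnostic and applies to arbitrary edge lists.

## Numerical choices and degenerate inputs

* Ceiling arithmetic through `Fraction`; float γ inputs are interpreted via
  their shortest decimal representation (`0.85` means 85/100).
* Deep binomial tails: `logsf` with logsumexp-over-logpmf fallback below
  exp(−700).
* Ties in brute force: lexicographic label order. Peel ties: random under
  the iteration RNG (deterministic given seed), index order in the
  deterministic peel.
* Edgeless graphs: optimum size 1 (singleton convention). p = 0 and p = 1
  short-circuit the sampler. Empty subsets and unknown labels raise.
* Timeouts: B&B returns the incumbent with `is_optimal=False` and logs the
  unresolved size; the default is no limit.

## Known limitations

* Exact engines are practical to n ≈ 100–150 (sparse); the sweep guard
  refuses exact runs beyond n = 150 and suggests GRASP.
* GRASP carries no approximation guarantee; its regression tests are
  package-internal quality gates (e.g. ≥ 90% optimality on tiny instances),
  not claims about the cited original implementations.
* Only the leading asymptotic term of the size bounds is implemented;
  finite-n corrections of order ln ln n are visible at n ≤ 10⁶ (see the k*
  convergence test).
* Graphs are undirected, unweighted, in-memory; the sampler materializes all
  C(n, 2) pairs and is comfortable to n ≈ 5000.
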