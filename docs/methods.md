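# Methods

## Model

The solver targets the one-dimensional fuzzy time-fractional tumor model

    ∂^α u/∂t^α = u_xx − k(x, t) u,   0 < α ≤ 1,  (x, t) ∈ [0, L] × [0, T],

where u is the tumor-cell concentration (dimensionless), k is the net
cell-killing rate (inverse time; the therapy-driven removal of cells), and
the time derivative is a Caputo derivative of order α. α < 1 models
subdiffusive, history-dependent dynamics; α = 1 recovers the classical
model. Uncertainty enters multiplicatively: the killing rate is
k = τ̃₁ s₁(x, t) and the initial condition u(x, 0) = τ̃₂ s₂(x), with τ̃₁,
τ̃₂ fuzzy convex numbers, and the Dirichlet boundary values are
fuzzy-valued functions of time.

### Fuzzy representation

Fuzzy quantities are carried **only** through their r-cut endpoints
(single-parametric form): at confidence level r ∈ [0, 1] a fuzzy number is
the interval [lower(r), upper(r)] with nondecreasing lower, nonincreasing
upper, and nested cuts. Triangular numbers (left, peak, right), whose
cuts are linear in r, are the default family; any endpoint pair can be
supplied through `ParametricFuzzyNumber`. At fixed r the fuzzy problem
decomposes into two decoupled crisp problems — the lower branch built from
all lower endpoints, the upper branch from all upper endpoints. This
decomposition is exact for the problems treated here because the PDE is
linear and its solution operator preserves order in the data; since that
monotonicity is assumed rather than proven for arbitrary inputs, every
fuzzy solve re-checks the envelope property (lower ≤ upper at every grid
node) a posteriori and **warns** rather than errors on violation. No
general fuzzy arithmetic, and no Hukuhara case analysis, is implemented:
the branch decomposition *is* the semantics.

## Discretization

Uniform grid x_i = i Δx (0 ≤ i ≤ M, M Δx = L), t_n = n Δt (0 ≤ n ≤ N,
N Δt = T), both commensurabilities enforced to 1e−9 relative — a
non-tiling step fails fast with a suggested adjustment instead of silently
re-meshing.

* **Time**: Caputo L1 formula with weights b_j = (j+1)^{1−α} − j^{1−α}.
  The weights satisfy 0 < b_j ≤ 1, decrease strictly, and telescope
  (Σ_{j=1}^{n−1}(b_{j+1}−b_j) = b_n − b_1); at α = 1 they are computed as
  exactly zero (integer short-circuit avoids 0^0-style float noise), so
  the march degenerates to backward Euler bit-for-bit. Weights are cached
  per (α, n).
* **Space**: central second difference at the *new* level n+1.
* **Killing term**: lagged, −k(x_i, t_n) u_i^n, entering the right-hand
  side as (1 − Γ(2−α) Δt^α k) u^n.
* **Memory term**: Σ_{j=1}^{n} b_j (u^{n+1−j} − u^{n−j}) taken verbatim;
  at j = n it touches the initial row, so the full history is retained
  (O(N·M) memory, trivial at the scales used). The first step (n = 0) has
  an empty sum.
* **Linear solve**: per step and branch, the tridiagonal system
  −τ u_{i−1}^{n+1} + (1+2τ) u_i^{n+1} − τ u_{i+1}^{n+1} = RHS with
  τ = Γ(2−α) Δt^α / Δx². The dominance margin is exactly 1 for every τ,
  so the hand-written Thomas elimination cannot hit a zero pivot.
  Dirichlet values are imposed at level n+1 (implicit-consistent) and fold
  into the RHS as +τ·boundary.

The normalization τ = Γ(2−α) Δt^α / Δx² (with the matching killing factor
Γ(2−α) Δt^α k) is fixed by dimensional consistency: it is the unique
scaling under which the tridiagonal update follows from the L1 formula.

## Stability

Von Neumann analysis of the error equation gives the scalar recursion (per
Fourier phase θ)

    λ^{n+1} = [(1 − κ − b₁) λⁿ + Σ_{j=1}^{n−1} (b_j − b_{j+1}) λ^{n−j} + b_n λ⁰]
              / (1 + 4τ sin²(θ/2)),

with κ = Γ(2−α) Δt^α k ≥ 0 and first step λ¹ = (1−κ) λ⁰ / (1 + 4τ sin²(θ/2)).
Because the numerator coefficients are nonnegative and sum to 1 − κ
whenever κ ≤ 1 − b₁, induction yields |λⁿ| ≤ |λ⁰| for *every* mesh ratio:
unconditional stability. The `stability` module makes this executable
three ways: (i) brute-force iteration of the recursion over grids of
(θ, τ, α, n); (ii) the weight-inequality suite (positivity, boundedness,
strict decrease, and the telescoping identity in its algebraically true
form b_n − b_1; the companion convention b₀ = 1 turns it into 1 − b_n,
which is how stability write-ups often state it); (iii) perturbation
experiments on actual solves — base and IC-perturbed runs, with the
discrete norm ‖εⁿ‖ = √(Σᵢ h εᵢ²) over interior nodes — including a
deliberately coarse mesh (Δt = 0.5, Δx = 0.1, τ ≈ 63) where the bundled
minimal explicit comparator amplifies a seeded perturbation by ~10⁴ while
the implicit scheme damps it. The coarse-mesh window is kept short enough
(T = 1) that the lagged killing factor κ stays below 1 − b₁; outside that
regime the non-growth hypothesis of the proof itself no longer holds, and
no claim is made.

## Benchmark and its oracle

The benchmark instance has k(t) = t² (killing depends on time only),
u(x, 0) = s̃(r) e^{kx} with triangular s̃ = (0.75, 1.0, 1.25), mesh
Δt = 0.01, Δx = 0.5, report point (x = 4, t = 0.05), α ∈ {0.2, …, 1},
r ∈ {0, 0.3, 0.7}. Conventions this package fixes where the source
material is silent, all configurable:

* **Initial-profile exponent k.** Recovered by `calibrate_ic_exponent`:
  a scan over small integers accepts the unique candidate (k = −1) whose
  analytical value at the report point matches the reference table's
  numerical-plus-error to 1e−3; every other candidate is off by orders of
  magnitude. The decision trace is logged.
* **Domain L = 5** — the smallest length making x = 4 an interior node of
  the Δx = 0.5 grid with a reasonable far-field margin.
* **Dirichlet boundaries sampled from the analytical solution** per
  branch at x = 0 and x = L — the standard manufactured-benchmark
  convention; at t = 0.05 and τ ≈ 0.04 the boundary choice perturbs the
  report point well below the reported error scale.
* **Analytical oracle.** The closed form consistent with the reference
  values is u = s̃(r) e^{kx} E_α(k² t^α) with E_α the one-parameter
  Mittag-Leffler function: the reference's implied exact values
  (numerical + error) reproduce this expression to ~1e−8 in all 30 cells,
  including the exact 5/3 upper/lower ratio at r = 0. This is the default
  (`form="mittag-leffler"`). A three-term truncation with the fuzzy
  factor on the leading term only is also provided (`form="truncated"`)
  for comparison; at t = 0.05 the two differ by up to ~5e−3 at α = 0.2
  and ~2e−4 at α = 1. E_α is evaluated by its power series with
  term-ratio truncation — adequate for the |z| ≲ 1 arguments arising
  here, not a general-purpose scaled-ML implementation. The killing term
  contributes only O(t³) ≈ 4e−5 relative over the benchmark window, below
  the reported error scale, which is why the diffusion-only closed form
  serves as the oracle.

With these conventions the implicit march tracks the oracle to 1e−5–3e−4
across all (α, r) — the numerical error at this mesh is dominated by the
α-independent spatial truncation (the e^{−x} profile's curvature on the
Δx = 0.5 grid), so it does *not* decrease monotonically in α; the
r-direction trends (lower-branch error grows with r, upper-branch error
shrinks, both ∝ the endpoint magnitude) do hold and are asserted in the
tests. Published values for this benchmark whose method error greatly
exceeds these levels cannot be matched cell-for-cell by a consistent
implementation of the scheme; the reproduction tests therefore compare
at the 2e−4 scale where the α = 1 rows agree and report deviations
transparently elsewhere.

## Numerical choices and degenerate inputs

* Mesh-ratio and weight computations validate 0 < α ≤ 1, positive steps;
  r outside [0, 1] is a domain error everywhere.
* Envelope slack 1e−12 (relative to the solution magnitude) before a
  violation is flagged; corner compatibility (IC vs BC at t = 0) is
  checked to 1e−8 relative and only warns.
* Crisp (degenerate) fuzzy factors make both branches identical at every
  r; r = 1 collapses triangular envelopes exactly.
* CSV export writes shortest-round-trip floats (17 significant digits),
  so grid → CSV → grid is bitwise; solver runs are fully deterministic,
  and the only randomness in the package (the default perturbation
  sampler) flows through a single seeded generator recorded in the
  result.

## Problem sizes

The benchmark marches 5 time steps on 11 nodes per branch (30 solves for
the full table); stability sweeps iterate the scalar recursion 100 steps
over 50 × 4 × 4 parameter combinations; the weight suite checks n = 1000
weights for 100 random orders. Everything — tests, examples, and the
acceptance script — runs in seconds on one CPU.

## Limitations

* 1D, Dirichlet-only boundaries; no adaptive stepping, no short-memory
  truncation of the Caputo sum, no 2D/3D domains.
* The branch decomposition assumes order-preservation of the solution
  operator; strongly non-monotone couplings would need the full extension
  principle, which is out of scope (the runtime envelope check is the
  guard).
* The synthetic benchmark exercises a smooth, rapidly decaying profile
  with small killing over a short window; it does not probe steep fronts,
  long-time memory accumulation, or large κ regimes, so passing tests
  certify scheme correctness and stability, not clinical fidelity of the
  tumor model itself.
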