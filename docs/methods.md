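# Methods

## Problem model

The package minimizes `f(x)` over a box `l ≤ x ≤ u` in ℝⁿ, optionally
subject to inequality constraints `g_j(x) ≤ 0`, j = 1..m.  For the bundled
parameter-estimation fixtures, `f` is the sum-of-squares error between a
model's predictions at spatial/time coordinates (s, t) and observations
y_exp(s, t).  Constraint violation is aggregated as
`φ(x) = Σ_j max(0, g_j(x))²`; an individual is feasible when
`φ ≤ feasibility_tolerance` (default 0; configurable because simulator-based
constraints can be numerically noisy).  The combined score
`ψ = f + Σ_j r_j max(0, g_j)²` with user-supplied penalty coefficients r is
computed for reporting only — selection never uses it.  Instead, ranking
works directly on the (f, φ) pair via stochastic ranking, which sidesteps
the classic under-/over-penalization dilemma of fixed penalty weights.

Objective evaluations that raise or return a non-finite value (a stiff ODE
blowing up, an overflow) are assigned a sentinel worst value and ranked
last rather than aborting the run; a global search must survive bad regions
of parameter space.  Only if the entire initial population fails does the
run abort with a diagnostic, since that indicates a broken problem
definition rather than a hard region.

## Stochastic ranking

A bubble-sort-like pass over adjacent pairs: when both individuals are
feasible they are compared by f; otherwise by f with probability p_f
(default 0.45) and by φ otherwise.  Up to λ sweeps are performed, stopping
early when a sweep makes no swap.  Ties never swap, so equal individuals
keep their input order under any seed; an exact φ tie in a penalty
comparison falls back to f, which makes the deterministic p_f = 0 limit
exactly the lexicographic (φ, f) sort and the p_f = 1 limit exactly the
stable ascending sort by f.  The ranking draws all its uniforms from a
dedicated substream up front, so the number of variates consumed does not
depend on early termination and toggling other operators never perturbs
ranking decisions.

## The evolution strategy

(μ, λ) comma selection: parents are discarded every generation, the best
individual ever seen is tracked separately and never reinserted (no
elitism).  Defaults λ = 150, μ = 20; μ defaults to the value that brings
the recombination/mutation offspring ratio (μ−1)/(λ−μ+1) closest to 1/7,
which balances the success probability of the two offspring routes.

* **Recombination** (μ − 1 offspring): offspring i = x_i + γ(x_1 − x_i),
  γ = 0.85 — a partial step from each parent toward the top-ranked parent.
  Offspring keep their own parent's step sizes η unchanged.  We originally
  blended η toward the top parent's with the same γ, but that collapses the
  elite's step-size diversity onto a single (self-reinforcing) η vector and
  measurably stalls self-adaptation: on the constrained toy problem the
  median error after 300 generations is ~30× worse with blending.
  Positions may converge; step sizes must remain heritable and diverse for
  the log-normal adaptation below to see selection pressure.
* **Mutation** (λ − μ + 1 offspring, parents repeated rank-wise): step
  sizes update log-normally, η′_j = η_j exp(τ′ N + τ N_j), with one shared
  N(0,1) per individual and independent N_j per coordinate;
  τ′ = φ/√(2n), τ = φ/√(2√n), expected convergence rate φ = 1.  The
  position then takes x′_j = x_j + η′_j N_j with fresh draws.  Offspring
  store the exponentially smoothed η ← η + α(η′ − η), α = 0.2, which damps
  step-size oscillation between generations.  Initial η = (u − l)/√n.
* **Bounds repair**: a violating coordinate is redrawn from a Gaussian
  centered on its parent with sd η_j (10 retries), then reflected across
  the violated bound, then clamped.  In-bounds coordinates are never
  touched, so the box boundary itself is reachable.

## The landscape operators (ISRES+)

Every evaluated individual is appended to an archive (unbounded by default;
a ring buffer is configurable).  Around the incumbent best, the k nearest
distinct feasible archive points form the cluster; distances are Euclidean
in box-normalized coordinates `(x − l)/(u − l)` so parameters spanning many
decades contribute comparably, while the cluster diameter d_cluster used
for stepping is measured in raw parameter units.  Infeasible records are
never used.  Exact duplicate coordinate vectors are dropped before fitting
(they would make the design matrix exactly rank-deficient).

* **Linstep**: with k = n members plus the center, fit f ≈ a₀ + aᵀx by
  least squares; v = a approximates the steepest-ascent direction.  The
  n_lin fittest cluster points (the incumbent first) are translated by
  `−β_lin · d_cluster · v/‖v‖`.  The gradient is unit-normalized so that
  β_lin (default 2, constrained ≥ 1) directly expresses the step length as
  a multiple of the cluster-bubble diameter.  The operator skips when the
  predicted objective change `d_cluster · ‖v‖` is below 64 machine epsilons
  of the cluster's f scale — a slope that small is indistinguishable from
  rounding noise.
* **Newton step**: with k = n + n(n+1)/2 members beyond the center (the
  minimum determining a symmetric quadric in difference form
  f − f_best ≈ gᵀΔ + ½ΔᵀHΔ), fit by least squares and take
  `x_best − β·s` where `H s = g` is solved directly (never inverting H, and
  rejecting solves whose back-substituted relative residual exceeds 1e−6).
  A single contribution (the default n_newt = 1) takes the full step β = 1;
  additional contributions draw β uniformly from (0, 1], since all full
  steps from members of the same quadric fit land on the same stationary
  point (the fixed-point property, asserted in the tests).  No
  positive-definiteness repair is applied: the step uses whatever H the
  local fit yields.

Numerical safeguards shared by both fits: coordinates are centered on the
incumbent and scaled by the cluster diameter, and design-matrix columns are
equilibrated, so the reported condition number reflects cluster geometry
rather than parameter scale.  A fit is rejected when the design matrix is
rank-deficient, its condition number exceeds 1e10, or the relative solve
residual exceeds 1e−6; the cluster is then enlarged by 25% increments (at
minimum cluster sizes the systems are square interpolations with ~zero
residual on any objective, so the residual gate effectively applies to
enlarged, overdetermined fits).  When no acceptable fit exists, when the
incumbent is infeasible, or when there are too few distinct feasible
records, the operator's population slots silently revert to ordinary
mutation offspring.

Operator offspring occupy the slots of the lowest-ranked parents' mutation
offspring — Newton just before Linstep at the tail of the population — so
the population size is exactly λ and the composition is deterministic
given the configuration.  Offspring inherit η from their source point.
Because mutation offspring for those slots are generated (and their random
draws consumed) before being replaced, the baseline and ISRES+ variants
share every draw outside the operator slots: under paired seeds the two
population streams are identical until the first operator offspring
appears, and the first divergence is confined to the designated slots.
Operator windows default to starting at generation 2, once a full
post-initialization generation has been archived.

**Stagnation silencing**: when the normalized cluster diameter shrinks
below 1e−6 without the incumbent improving, both operators are silenced —
they would otherwise keep re-fitting a degenerate bubble of their own
offspring.  Any improvement of the incumbent re-activates them
immediately.

**Cost accounting**: neither operator evaluates the objective to build its
model; the only new evaluations are the operator offspring themselves,
which replace (not augment) mutation offspring.  Total evaluations are
exactly λ·(G+1) for G generations, asserted in the tests.

## Randomness and reproducibility

A single seed spawns four named PCG64 substreams (initialization, ranking,
mutation+repair, operators).  Evaluation order within a generation is
fixed slot order.  Runs are bit-reproducible given the configuration, and
the multi-run harness gives run i the seed `base_seed + i`, so ISRES and
ISRES+ comparisons are paired by construction.

## Synthetic fixtures: what they emulate and what they do not

The decay fixture (y = A e^(−kt), A = 2, k = 0.5, 20 samples over t ∈
[0, 10]) and the 3-species linear cascade (production k₀, transfers k₁,
k₂, decay k₃; all three species observed; fixed-step RK4 at
h = min(Δt)/10, with a stability guard that flags stiff parameter draws as
failed evaluations) emulate the target problem class — kinetic parameters
of unknown magnitude estimated from time series by SSE — at toy scale.
Noise is additive homoscedastic Gaussian.  Rate constants are searched on
a log₁₀ scale over [10⁻⁴, 10⁴] (the box becomes [−4, 4] per parameter):
the engine itself applies no transformation, but the fixture, as the
caller, pre-transforms, which is standard practice when a parameter's
order of magnitude is unknown — on the raw scale almost the entire box is
an information-free plateau for the decay model and no optimizer in this
family converges reliably.  Passing tests on these fixtures demonstrate
the machinery (constraint handling, operator correctness, recovery at the
noise floor) but not performance on stiff, multi-modal, or
partially-identifiable models with hundreds of state variables, which is
where full-scale applications live.

Benchmark problems (sphere, Rosenbrock, and the constrained toy
min x₁²+x₂² s.t. x₁ ≥ 1 with optimum f = 1 at (1, 0)) verify their
declared optima by evaluation at registration time.

## Problem sizes used in tests and the acceptance script

Multi-run statistics use λ = 60 with 150–300 generations and 10–20
independent runs per configuration — large enough for the qualitative
paired comparison (ISRES+ no worse than ISRES on the noisy fixture) and
the recovery-rate checks, small enough that the whole suite runs on one
core in a few minutes.  The recommended full-scale settings (λ = 150,
thousands of generations, ≥ 50 runs) are configurable through the same
interfaces.

## Known limitations

* No covariance-matrix adaptation, restarts, or parallel evaluation.
* Linstep's hyperplane can average across a valley and produce a poor
  direction when the cluster straddles a minimum (the operator-skip and
  silencing guards bound, but do not eliminate, the wasted offspring).
* The quadric fit needs O(n²) distinct feasible neighbors; in high
  dimension the Newton operator activates late and skips often.
* An indefinite fitted H can send the Newton offspring toward a saddle;
  the offspring then simply ranks poorly and is discarded.
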