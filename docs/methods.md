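# Methods

## Model and assumptions

A life history is the triple (growth SDE, mortality hazard, fertility rule)
on one state space.  Growth is an Itô diffusion in the individual state
(here 1-D body size; the simulator accepts any dimension), controlled by a
vector u in a box — the application needs only the scalar utilization
frequency u ∈ [0, 1].  Mortality μ(x, u, a) ≥ 0 acts through the
survivorship S(a) = exp(−∫₀ᵃ μ dt).  Semelparous fertility is a point mass
q at the first hitting time of the mature boundary (after which the
individual is removed); iteroparous fertility is a rate b(x, a) active up to
the maximum lifespan ω, with ω = ∞ recovering the accident-only survivorship.
There is no density dependence, no interaction between individuals, and no
environmental (year-to-year) stochasticity; all randomness is internal to
each life course.

The demographic layer rests on two standard facts: the net reproduction
function F(τ) (called ERS throughout the package) determines the population
growth rate λ as the unique root of ∫ e^{−λτ} F(τ) dτ = 1, because φ is
strictly decreasing; and log φ is the cumulant generating function of
breeding age in the stable population, so the breeding-age density is
ψ(a) ∝ e^{−λa} F(a) and its cumulants are signed derivatives of log φ at
the root.

## Parameters of the two-resource application

| parameter | meaning | unit | reference value |
|---|---|---|---|
| m1, m2 | mean growth from R1 / R2 | 1/time | 1.0, 0.4 |
| s1, s2 | noise intensity from R1 / R2 | 1/√time | 1.2, 0.4 |
| mu0 | baseline mortality (control-free) | 1/time | 0.05 |
| x0, xm | initial and mature size | size | 1, 5 |
| q | semelparous burst fertility | offspring | (xm/x0)^n |
| b0, α | allometric fertility b0·x^α | offspring/time | 0.3, 0.4 |
| ω | iteroparous maximum lifespan | time | 15 |

All ages and rates share one arbitrary time unit; nothing is ever converted.
The reference values are the package's fixed study conditions, chosen once
so that m1 > m2 and s1 > s2 (the defining risk/return ordering), the
generalist window (0, 1 − (m1−m2)/s1²) = (0, 0.583) is wide enough to show
both regimes, mid-range indices are persistent (λ* > 0), and the mean age at
maturity (≈ 3.6 time units) keeps Monte-Carlo horizons short.  The index n
is swept by varying q at fixed sizes, except where a claim concerns the size
ratio itself (the mature-age density does not depend on q, so Fig.-style
"maturity shifts younger as n grows" sweeps vary xm at fixed q).

## Closed forms and transcription discipline

Every closed form is defined exactly once in `two_resource.py` and verified
structurally in the test suite against its defining equation (sympy):
the first-passage exponent θ(λ) against its characteristic quadratic, the
fitness λ(n) = g·n + ½σ²n(n−1) − μ0 as the inversion θ(λ) = n, the power-law
ansatz V = C·x^γ against the stationary HJB with the interior optimal u, and
the iteroparous value
V(a,x) = b0 x^α (1 − e^{−(λ−K)(ω−a)})/(λ−K) against the backward PDE, where
K is the semelparous-fitness function evaluated at index α.  A transcription
slip therefore breaks an algebraic identity, not merely a numeric tolerance.
The iteroparous Euler–Lotka equation is transcendental; its root is always
computed numerically.  The closed-form root K + b0·x0^α of the
infinite-lifespan objective bounds the finite-ω fitness from above and
tightens as the initial-state contribution b0·x0^α becomes small; it is
exposed as `iteroparous_fitness_bound`.

## Numerical choices

**Monte Carlo.**  Euler–Maruyama with multiplicative (GBM-like) models
stepped in log-state, where constant-coefficient increments are exact in
distribution.  Survivorship is carried as a multiplicative weight
(continuous weighting) rather than by killing paths — lower variance; a
killing mode samples actual deaths and is used where *observed* maturity
ages are needed (KS tests).  Discrete-time threshold checks miss within-step
crossings (an O(√dt) first-passage bias); the optional Brownian-bridge
correction accepts a within-step crossing with probability
exp(−2(y*−y_k)(y*−y_{k+1})/(σ²dt)) and assigns the midpoint age, reducing
the bias to O(dt).  It is off by default and switched on wherever an
estimate is compared against a first-passage closed form.  Randomness:
one seed spawns an independent Philox substream per fixed 8192-path chunk,
and every per-step draw is chunk-width, so enlarging n_paths extends the
ensemble without reshuffling existing paths.  Age integrals are trapezoids;
semelparous atoms are summed exactly.

**Euler–Lotka root.**  Bracket expansion by outward doubling (objective
values past the abscissa of convergence are treated as +∞), then a bracketed
Brent solve; residual tolerance 1e−10 on φ − 1.  Cumulants use central
finite differences of log φ with a step-halving stability check, so
Monte-Carlo-estimated objectives are admissible; the order-4 stencil is the
first to feel roundoff and warns rather than fails.

**Fokker–Planck / kernel.**  Conservative finite volumes with upwinded
interface advection and central diffusion of (D·p), implicit Euler (θ = 1),
on a log-uniform grid for multiplicative models (constant coefficients,
better conditioning).  The Dirac initial condition is a Gaussian of width
two grid cells (one cell for the matrix model's restarts).  The mature
boundary is absorbing with the flux recorded per age; the semelparous ERS is
q times that flux.  Kernel mass equals survivorship — checked against the
Monte-Carlo alive mass.

**Age–size matrix model.**  Size classes are midpoint-indexed (geometric
midpoints on log grids), ages half-open [aΔa, (a+1)Δa).  The size block is
the one-step kernel restarted from each class midpoint; the absorbed flux is
integrated *within* the step on a resolved time grid — sampling it only at
the step endpoints biases the near-boundary classes and was the single
largest error source found during development.  The dominant eigenvalue
comes from power iteration with the growth factor read off as a windowed
geometric mean of norm ratios, the window a whole number of age periods, so
strictly periodic (single-fertile-age Leslie) spectra converge exactly;
a persistent period-2 structure triggers one shift-and-retry.  Reference
resolution Δa = 0.25, 160 size classes; halving/doubling these moves the
fitness toward the closed form (observed gap 7e−3 → 3e−4).

**HJB.**  Implicit upwind finite differences (monotone, consistent, stable —
the standard route to the viscosity solution; no smoothness assumed).
Semelparous: Howard policy iteration with damping 0.5 on policy updates
(undamped grid-mode iteration can cycle), Dirichlet V(x*) = q at the mature
boundary.  The degenerate lower boundary (x → 0 for GBM) carries a
homogeneous Dirichlet value at the truncation; its influence decays like the
negative characteristic exponent and is negligible on [x0, x*] (tested).
Iteroparous: backward implicit sweep from V(ω, ·) = 0 with the policy
extracted from the previous age surface.  The top of a *growing* domain
must not use Dirichlet 0: the package closes it with the full PDE row using
one-sided (backward) differences, fully implicit via a (2,1)-band solve, and
sizes the domain so that the truncation sits beyond drift·ω + 2·noise·√ω
log-units of the evaluation region (`suggested_grid`).  Pointwise control
optimization exploits that the Hamiltonian is an exact quadratic in u: three
evaluations fix the parabola, the clamped vertex or the better endpoint wins,
and ties break toward the smaller u.  A grid scan over u is available as a
fallback and as the oracle for the analytic mode.  The outer fitness loop
brackets λ on V_λ(x0) = 1 with warm-started policies; values below the
abscissa of convergence read as +∞.

## What the synthetic conditions do and do not show

The generator *is* the model: GBM growth, constant hazard, burst or
allometric fertility.  Passing tests therefore demonstrate the internal
consistency of the formulations and the correctness of the closed forms
under exactly these assumptions; they do not validate GBM growth, constant
mortality, or control-free hazards as descriptions of any real organism, and
say nothing about density dependence, environmental stochasticity, or
measurement error in real demographic data.

## Known limitations

PDE/HJB solving is 1-D (the application's scope); higher-dimensional states
are simulation-only.  Control sets are boxes; mortality control is admitted
by the Hamiltonian interface but unused (the application's hazard is
control-free, which is also why maximizing the ERS alone and the full
λ-coupled solve extract the same policy).  The matrix model's midpoint
collapse makes its fitness the least accurate of the four routes at coarse
resolution.  The renewal diagnostic needs the transient to decay
(horizon ≳ 30 mean breeding ages for the reference model).  Upwind HJB
schemes are first-order in the grid spacing; the reported sub-percent value
errors are at the documented 800-node reference grid.
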