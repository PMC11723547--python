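# Methods

## Model

Five compartments track a treated breast-cancer population: X
(hospitalized, stages 1–2), B (stages 3A/3B), C (stage 4), R
(disease-free after chemotherapy), E (chemotherapy-induced
cardiotoxicity). The drift is affine, `f(x) = A·x + c`, with inflows
ω1–ω3 (persons·time⁻¹) and first-order rates (time⁻¹) for stage
progression (μ2: X→B, μ1: B→C), transfer into remission (γ1–γ3),
relapse (α1: R→B, α2: R→C), cardiotoxic transfer into E (ϕ1–ϕ3) and
mortality of B, C, E (σ1–σ3). States are real-valued (mean-field);
no integer rounding. The X equation is decoupled, giving the
closed form X(t) = X\* + (X0 − X\*)e^{−(γ1+μ2)t}, X\* = ω1/(γ1+μ2) —
used as an analytic oracle in the tests.

The shipped baseline values are a published table using symbols
Λ, β, ψ, μ; the reconciliation to the model's ω, μ, α, σ is a data
table (`TABLE1_NAME_MAP`), not hard-coded: Λᵢ→ωᵢ, β1→μ1, β2→μ2,
table-μ1..3 (the three 0.0256 mortalities)→σ1..3, ψ1→α1, ψ2→α2. Each
table description matches exactly one flow with that meaning; the
mapping is replaceable wholesale for other parameterisations.

## The CPC operator and its discretisation

The hybrid Caputo-proportional-constant operator of order θ ∈ (0, 1],

    D^θ_CPC x = V1(θ)·I^{1−θ}_RL x + V0(θ)·D^θ_C x,
    V0(θ) = θ·Q^{1−θ},  V1(θ) = (1−θ)·Q^θ,  Q > 0,

interpolates between a pure Riemann–Liouville integral action (θ→0)
and the classical derivative (θ=1, where V0=1, V1=0 for Q=1). An
optional prefactor λ rescales the equation as (1/λ^{1−θ})·D^θ_CPC x = f,
i.e. the drift enters as λ^{1−θ}·f; λ and Q both default to 1.

Both operator parts are discretised with Grünwald–Letnikov weights on a
uniform grid, with the raw step Δt replaced by a denominator function
Π(Δt) = Δt + O(Δt²) (the nonstandard-finite-difference device; `plain`
Π=Δt for Δt<1 is the default, `expm1` Π=1−e^{−Δt} the alternative):

* ϖ₀=1, ϖᵢ=(1−θ/i)ϖᵢ₋₁ — the all-positive binomial weights of the
  order-(1−θ) integral; `Π^{1−θ}·(x_{n+1} + Σϖᵢx_{n+1−i})` ≈ I^{1−θ}x.
* κ₁=θ, κᵢ₊₁=κᵢ(i−θ)/(i+1) and rᵢ=i^{−θ}/Γ(1−θ);
  `Π^{−θ}·(x_{n+1} − Σκᵢx_{n+1−i} − r_{n+1}x₀)` ≈ D^θ_C x.

Collecting terms gives a scalar linear update per component,

    [V1·Π^{1−θ} + V0·Π^{−θ}]·x_{n+1}
      = λ^{1−θ}·f − V1·Π^{1−θ}·Σϖᵢx_{n+1−i}
        + V0·Π^{−θ}·(Σκᵢx_{n+1−i} + r_{n+1}·x₀),

whose pivot is strictly positive for θ∈(0,1], Q>0, Π∈(0,1). The
exponent placement (Π^{1−θ} with V1, Π^{−θ} with V0) is the only
dimensionally consistent choice: it makes each term a genuine GL
approximation of its operator part, and at θ=1, Q=1, Π=Δt the update
collapses algebraically to explicit Euler (all ϖᵢ vanish for i≥1,
κ₁=1 is the only surviving history weight, and the r-term is absent —
Γ(0) has a pole, so the classical limit bypasses it). The θ=1 path is
implemented as that exact reduction so the equivalence holds
bit-for-bit, not merely to rounding.

Exactness of the weights is pinned by a gamma-function oracle
(ϖᵢ = Γ(i+1−θ)/(Γ(1−θ)Γ(i+1)), κᵢ = θ·Γ(i−θ)/(Γ(1−θ)Γ(i+1)) via
log-gamma), and correctness of the whole scheme by an independent
exact-solution oracle: the scalar relaxation D^θ_CPC x = νx has Laplace
transform X(s) = V0·s^{θ−1}x₀/(V1·s^{θ−1} + V0·s^θ − ν), inverted
numerically with a Talbot contour (mpmath); both drift modes (below)
converge to it at θ = 0.5 and 0.9.

### Drift evaluation and stiffness at small orders

The history sums make a length-N solve O(N²); no short-memory
truncation is applied (full history always, N ≈ 3·10³ per regime at the
default Δt = 0.01, a fraction of a second).

The drift can be taken at tₙ (explicit, the default for the
constant-order solver) or at t_{n+1} (implicit; since the model is
linear this is one 5×5 solve per step). The distinction matters
because of a structural property of the operator at small θ: with
θ ≈ 0.01 the equation is dominated by its integral part
(V1 ≈ 0.99) and becomes a singularly perturbed Volterra equation. Its
exact solution has an initial layer far below any practical grid — the
state drops by orders of magnitude essentially instantaneously, then
decays on an O(1) timescale. For such configurations the explicit
scheme's drift amplification |ν|/pivot is *independent of Δt* (the
pivot tends to V1·Δt^{1−θ}+V0·Δt^{−θ} ≈ 0.02 for any feasible step) and
exceeds 1 for the baseline rates, so explicit stepping oscillates and
overflows regardless of refinement; this is a property of the
continuous problem's stiffness, not of implementation. The
variable-order solver therefore defaults to the implicit drift, which
is unconditionally bounded here, reduces to backward Euler at θ=1, and
agrees with the Talbot oracle at moderate θ. The explicit mode remains
available (`drift_mode="explicit"`) and is exercised by a test that
documents the divergence.

Accuracy caveat: within the θ ≈ 0.01 regime the exact solution's layer
is sub-grid, and any smooth GL quadrature overweights the initial state
at Δt = 0.01; the computed trajectories there are qualitatively right
(fast collapse, bounded small-amplitude behaviour, decaying
oscillation) but not quantitatively converged. Negative transient
values produced in this regime are reported, not clipped (a warning
logs the first offending time and component); an optional
clip-at-zero mode exists for the stochastic phase only.

### Variable order

For θ(t), the per-step kernels V0, V1 and the pivot exponent use
θ(t_{n+1}); the weight recurrences substitute θ(tᵢ) per history index
(ϖᵢ = (1−θ(tᵢ)/i)ϖᵢ₋₁, κᵢ = κᵢ₋₁·((i−1)−θ(tᵢ))/i, rᵢ from θ(tᵢ)),
chaining across indices. With a constant order function the
constant-order tables are reproduced bit-for-bit, and the solve equals
the constant-order solver exactly (matched drift mode). Orders are
validated to lie in (0,1) at every grid point, with the offending time
named on failure. The shipped order function family is
θ(t) = a − b·cos t with a = 0.01, b = 0.001.

## Stochastic phase

Each compartment carries multiplicative noise ς·x·dM^{H\*} from its own
fractional Brownian motion; the five drivers are independent, seeded by
splitting one master seed, since no cross-correlation is specified.
The update is

    x_{n+1} = x_n + f_n·Π(Δt) + ς·x_n·ΔB_n + correction,

with three correction conventions:

* `unscaled` (default): 0.5·x_n·Π^{2H\*} — no ς factor, so it acts
  as a deterministic exponential inflation at rate ≈ 0.5·Δt^{2H\*−1}
  (≈ 0.079 per unit time at Δt = 0.01, H\* = 0.7) regardless of noise;
* `sigma-squared`: 0.5·ς²·x_n·Π^{2H\*} — the Itô-type variant; with it,
  ς ≡ 0 reduces the path exactly to explicit Euler, and at H = 0.5 the
  corrected scheme converges strongly (order ≈ ½, measured on the
  geometric SDE against its exact solution x₀e^{νt+ςW});
* `off`: no correction (plain Euler–Maruyama).

H\* must exceed 0.5 for model runs (the correction is stated under that
condition); H = 0.5 stays reachable through the increment generator for
classical-Brownian oracles. H\* is not fixed by the source material;
the package default is 0.7 — mid-range of the admissible interval,
persistent increments — chosen once and not tuned. Default noise
intensities are ς = 0.1 on all five channels.

fGn increments are generated with exact covariance
γ(k) = ½(|k+1|^{2H} − 2|k|^{2H} + |k−1|^{2H}), scaled by Δt^H: the
Davies–Harte circulant embedding (FFT, O(n log n)) by default, the
Hosking recursion (O(n²)) as fallback and as an independent
cross-check. Sampling-variance note: for H close to 1 the usual
variance estimators have slowly decaying Monte-Carlo error
(sd ∝ n^{2H−2} per stream from long-range dependence), so the
statistical tests average a known-mean second-moment estimator over
independent streams, with the stream count sized per H so the standard
error sits well inside the asserted band; the bands themselves are not
widened.

## Certificates

* Lipschitz matrix Θ: the 5×5 componentwise bound of the drift,
  implemented verbatim from its published form — including its
  (1,1) entry γ1+μ1 and row-4 diagonal α1+α2+σ3, which differ from the
  drift's γ1+μ2 and α1+α2+ϕ3. The certificate keeps the published
  entries; the dynamics always use the drift equations. The
  discrepancy is deliberate and flagged here.
* Contraction factor: ρ(λ^{1−θ}·Ψmax·Φmax·|Γ(θ−1)|/|V0(θ)|·Θ), a
  uniqueness certificate when < 1. Γ(θ−1) is negative for θ∈(0,1); its
  absolute value is used so the factor is a nonnegative scale, and the
  convention is printed in the report. Ψmax and Φmax are bound
  constants with no closed definition; they are exposed as
  configuration scalars defaulting to 1, with that caveat in the
  report. The spectral radius is cross-checked against a
  power-iteration oracle and against characteristic-polynomial roots.
* Lyapunov bound V̄ = Σ(all 16 rate parameters) + ½Σς²: as published
  the noise sum covers the first four channels only; a five-term
  variant sits behind a flag. V̄ is state-independent and ≥ 0.

## Piecewise orchestration

Breakpoints 0 < T1 < T2 < Tf partition the horizon (baseline
30/60/100, Δt = 0.01); each must be an integer multiple of Δt, enforced
by snapping to the grid with a warning when a breakpoint moves more
than Δt/2. Regimes follow the half-open convention — [0,T1) constant
order, [T1,T2) variable order, [T2,Tf] stochastic — so the grid point
at a breakpoint carries the *next* regime's label. Each regime starts
from the final state of the previous one (exact array equality,
asserted when stitching), and the GL history restarts at each boundary
(the handoff state is the new x₀), mirroring the regime-wise initial
conditions of the piecewise operator. Scenario configurations
round-trip through YAML; every CLI run writes an effective-config echo
next to its output. The deterministic regimes are bit-reproducible;
the stochastic regime is a deterministic function of (config, seed).

Scenario presets: the baseline run (θ = 0.99), the order-variation
runs (θ = 0.9, swept externally), and a short-horizon structural run
([0,12] split 3/5, θ = 0.9 — the grid shape of an annual 2004–2016
incidence comparison; the registry series itself is not published and
is out of scope, so only the run structure is reproduced).

## What the scenarios emulate — and what they do not

The shipped configurations are the study conditions themselves
(printed parameter table, initial census, horizon partition, noise
level), not fits to data: passing tests demonstrate that the schemes
reproduce the analytic limits, the exact scalar solutions, the stated
weight identities and the qualitative regime behaviour under those
conditions. They do not validate the model against incidence data, and
no parameter inference, identifiability analysis or higher-order
stochastic scheme (Milstein, rough paths) is included.

Two direction claims attached to the parameter-influence studies do
not follow from the rate equations themselves, and the package's runs
(confirmed by an independent classical-ODE solve) move the opposite
way: raising the R→E transfer ϕ3 *lowers* the disease-free pool R
(ϕ3 is an outflow of R), and raising the B→R transfer γ2 *raises* the
stage-4 pool C (the relapse inflow α2·R into C, with α2 = 0.3,
dominates the weakened μ1·B inflow, μ1 = 0.01). The corresponding
acceptance checks assert the claims as stated and are expected to
fail; the model-consistent directions (ϕ1 lowering B, ϕ3 lowering B,
γ2 raising E, X's invariance to ϕ1) hold pointwise on the smooth
constant-order window t ∈ [1, 30) — the first time unit is excluded
because cross-compartment effects need to propagate (the γ2→E
difference, for instance, changes sign at t ≈ 0.41), and the
variable-order window is excluded because its collapse dynamics
oscillate around zero, where pointwise ordering is not meaningful.

## Problem sizes and tolerances

Default test/acceptance sizes: 3·10³ steps per deterministic regime
and 4·10³ stochastic steps (Δt = 0.01); 10⁵-increment fGn streams
(10/25/120 streams at H = 0.6/0.75/0.9); 500 paths across
Δt = 2⁻⁴…2⁻⁹ for the strong-order estimate; 100 noise realisations for
the cardiotoxic trend slope. Weight-oracle agreement is asserted at
1e−10 (observed ≈ 1e−14), certificate cross-checks at 1e−9,
reduction identities at 1e−12 or exact bits, and the Talbot oracle at
5e−3 for Δt = 5e−3 (discretisation, not roundoff, dominates there).
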