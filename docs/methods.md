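# Methods

## Model

The ribosome flow model (RFM) is the dynamic mean-field approximation of
the open-boundary totally asymmetric simple exclusion process (TASEP). A
transcript is coarse-grained into `n` sites with occupancy densities
`x_i ∈ [0, 1]`; the rate vector `λ = (λ₀, …, λ_n)`, units 1/time, holds the
initiation rate, `n − 1` elongation rates and the termination rate. Flow
between neighbouring sites is `λ_i x_i (1 − x_{i+1})` — occupancy times
free space downstream, a soft version of the exclusion constraint. The
model has a unique, globally attracting equilibrium `e` in the open unit
cube; the steady-state translation rate is `R = λ_n e_n`, and at
equilibrium all `n + 1` bond fluxes equal `R`.

Assumptions inherited from the RFM: ribosomes are point particles (no
extended footprint), no drop-off or internal initiation, rates constant in
time, and mean-field decoupling of neighbour correlations. The last is the
essential approximation; the TASEP machinery in this package exists to
quantify where it holds (everywhere except near the TASEP phase
transition, see below).

## Steady-state routes

Three independent routes compute `R`; their mutual agreement is the
package's core self-check.

1. **Spectral** (`translation_rate_spectral`). `A` is the
   `(n+2) × (n+2)` symmetric tridiagonal matrix with zero diagonal and
   off-diagonals `λ_i^{−1/2}`; then `R = ζ⁻²` with `ζ` the Perron root.
   Eigenpairs come from LAPACK's symmetric-tridiagonal solver
   (`scipy.linalg.eigh_tridiagonal`, top index only), then two O(n)
   inverse-iteration + Rayleigh-quotient refinement steps. Refinement
   matters for long chains: the raw LAPACK eigenvector carries ~1e−12
   entrywise relative error in its smallest components at `n = 1000`,
   which the polish drives to a few ulps (the closed-form comparisons
   below hold to 1e−12 because of it).
2. **Continued fraction** (`steady_state_cf`). Eliminating densities
   through the backward recursion `e_n = R/λ_n`,
   `e_i = R/(λ_i(1 − e_{i+1}))` leaves one scalar equation
   `λ₀(1 − e₁(R)) = R` on `(0, min λ_i)`. Bisection with an infeasibility
   convention (a trial `R` pushing any density to 1 or beyond counts as
   overshoot) contracts onto the unique feasible root; default relative
   tolerance 4e−16, i.e. machine precision, ~60 iterations of O(n) work.
   The tight default exists because this solver is the finite-difference
   oracle: with a looser root, FD noise at step 1e−6 would swamp the
   comparison against the spectral derivative.
3. **ODE integration** (`steady_state_ode`). LSODA (stiff-capable, from
   `scipy.integrate.solve_ivp`) in geometrically growing time chunks from
   the half-full state until `‖dx/dt‖∞ < 1e−9`, giving `R` to roughly
   1e−7 relative — the coarsest route, kept as the only one that also
   verifies dynamics (global convergence from arbitrary starts).

**Density recovery.** The backward recursion, though exact in real
arithmetic, is exponentially unstable in floating point whenever densities
sit near 1 (per-site error amplification `e_i/(1 − e_{i+1}) > 1`); on
log-uniform random profiles it routinely loses all precision by mid-chain.
The spectral route therefore recovers densities from Perron-vector ratios,
`e_i = ζ⁻¹ λ_i^{−1/2} v_{i+2}/v_{i+1}`, which is stable, and validates
them against the flux-balance relations (every bond flux must equal `R`).
The CF route, which has no eigenvector, uses the recursion only to seed a
Newton solve of the full steady-state system (`scipy.optimize.root`,
analytic tridiagonal Jacobian), with a brief ODE relaxation as fallback
seed; the same flux-balance validation gates the result.

## Sensitivities

With the unit-norm positive Perron vector `v`, first-order eigenvalue
perturbation theory gives `∂ζ/∂λ_i = −λ_i^{−3/2} v_{i+1} v_{i+2}` and

    s_i = ∂R/∂λ_i = 2 ζ⁻³ λ_i^{−3/2} v_{i+1} v_{i+2}.

Fixing `‖v‖₂ = 1` absorbs the usual `vᵀv` denominator. All `s_i` are
positive; a Weyl-inequality argument combined with `R ≤ λ_i` bounds each
by 1. Because `λ ↦ R` is homogeneous of degree one, `Σ λ_i s_i = R`
(Euler identity) — asserted everywhere as a conservation check.

The finite-difference oracle (`sensitivities_fd`) central-differences the
CF solver at relative step 1e−6. Comparisons against it are normalized by
the largest sensitivity of the profile: on wide log-uniform profiles
individual sensitivities reach 1e−30 and below, far beneath what any
double-precision difference of `R` can resolve, so a pointwise relative
comparison at such entries is meaningless for any implementation.
Entrywise agreement (≲1e−5) is asserted separately on
moderate-dynamic-range profiles where FD can resolve every entry.

## Closed forms

*THRFM* (all rates `λ_c`): `A` is `λ_c^{−1/2}` times the zero-diagonal
Toeplitz matrix, whose Perron pair is `2cos θ`, `v_j = sin(jθ)`,
`θ = π/(n+3)`; with `Σ_j sin²(jθ) = (n+3)/2` the sensitivity formula
reduces to `s_i = sin((i+1)θ)sin((i+2)θ)/(2(n+3)cos³θ)`, independent of
`λ_c`. The edge-effect ratio `Δ(n) = s_{⌊n/2⌋}/s₀` uses the center index
`⌊n/2⌋`; for odd `n` the two central sites tie exactly, so the floor
choice is immaterial (asserted in tests).

*HSRFM* (interior rates `λ_c`, boundaries `λ₀ = αλ_c`,
`λ_n = (1−α)λ_c`): the scaled matrix has the analytic Perron pair
`ρ = (α(1−α))^{−1/2}`, `v₁ = √α·μ`, `v_j = μ^j`,
`v_{n+2} = √(1−α)·μ^{n+2}` with `μ = √(α/(1−α))` — verified row by row at
construction time (`‖Av − ζv‖∞ < 1e−12` or the constructor raises), so a
transcription error cannot pass silently. Hence `R = λ_c α(1−α)`,
independent of `n`. Interior sensitivities follow by applying the
eigenvector formula to the analytic pair; their consecutive ratio is
exactly `α/(1−α)`, so `ln s_i` is linear inside the chain. The boundary
entries honour the `λ₀ + λ_n = λ_c` coupling (raising initiation lowers
termination): by the chain rule `s₀ = s₀ᵘⁿᶜ − s_nᵘⁿᶜ = 1 − 2α` and
`s_n = −s₀`; `coupled=False` returns the unconstrained derivatives
instead. At `α = 1/2` the boundaries are stationary and the interior is
flat at `1/(4(n+1))`.

## TASEP references

*Kinetic Monte Carlo* (`simulate_tasep`): event-driven continuous-time
Gillespie simulation — entry, hop and exit events with exponential waiting
times — rather than a discrete-time scan, because the event-driven chain
has the identical stationary law with no time-discretization bias. Starts
from an empty lattice; default budget 1e6 events per replicate with a
1e5-event burn-in (chosen so that, at `N ≈ 10`, the current estimate's
standard error is ~5e−4, tight enough for 3-sigma comparisons against
exact values while a full 8-replicate run stays in seconds; the inner loop
is numba-compiled). The current estimator is exits per unit post-burn-in
time. Seeding: a `SeedSequence` spawns one integer seed per replicate, so
a fixed configuration reproduces bit-identically.

*Master equation* (`master_equation_current`): the exact stationary
distribution of the `2^N`-state generator (sparse LU with the
normalization row), capped at `N = 12`. This is the ground truth for small
lattices and the oracle for the closed-form current.

*Closed-form homogeneous current* (`exact_current_homogeneous`):
`J = Z(N−1)/Z(N)` with the standard open-boundary partition function
`Z_N = Σ_p [p(2N−1−p)!/(N!(N−p)!)]·(β^{−p−1} − α^{−p−1})/(β^{−1} − α^{−1})`.
Each term is evaluated in the log domain (`gammaln` + `logsumexp`) with
the boundary quotient expanded as the geometric sum
`Σ_k α^{−(p−k)} β^{−k}`, which is positive termwise and passes smoothly
through the `α = β` limit — no branch, no precision loss, stable to
`N ≥ 200`.

*Monte-Carlo sensitivities* (`tasep_sensitivity_fd`) use paired
simulations with common random numbers; even so the estimate is
noise-dominated for small perturbations — the induced change in `J` is
easily masked by the process's inherent stochasticity — which is why the
deterministic `exact_current_sensitivity` (central difference of the
closed-form current in `α`) is the preferred reference.

## Mean-field vs TASEP across the phase transition

For `N = n = 30`, `β = 0.3`, the RFM initiation sensitivity `∂R/∂λ₀`
tracks the exact TASEP `dJ/dα` closely on both sides of `α = β` and
deviates most at the transition. Two facts shape how this comparison is
measured: above the transition *both* sensitivities collapse toward zero,
but the RFM's collapses much faster (~1e−11 vs ~1e−3 at `α = 0.5` — the
mean-field transition is sharper), so a pointwise ratio of two
near-zero numbers is uninformative. Gaps are therefore normalized by the
dynamic range of the curves (the sensitivity scale at the smallest `α`,
~0.9). Under that measure the off-transition gaps are below 0.2% and the
transition gap (~0.34%) is strictly the largest.

## Synthetic profiles

`make_profile` generates the study conditions: homogeneous chains with
optional distinct boundary rates; the HSRFM boundary pattern; slow-codon
clusters (a contiguous block of `width` rates set to `q` mid-chain,
defaults `n = 1000`, `q` on a grid up to 1, widths 1–3); and random
log-uniform profiles on `[0.1, 10]` — a two-decade spread covering the
realistic range from strongly rate-limited to fast codons. These profiles
probe the mathematics of the model; they do not emulate features of real
transcripts such as correlated codon usage along the ORF, 5'-end ramp
structure, or rates estimated from ribosome profiling, so passing tests
validate the solvers and formulas, not any claim about a particular
genome.

## Problem sizes and tolerances used in validation

Cross-route agreement runs on 100 random profiles with `n ∈ 1…50`
(spectral vs CF at 1e−8, vs ODE at 1e−6); sensitivity oracles on 20
profiles `n ≤ 30` at 1e−4 normalized; the `0 < s_i < 1` bound on 1000
profiles `n ≤ 40`; closed forms vs numeric spectral at 1e−12 up to
`n = 1000`; the partition-function current vs the master equation at
1e−10 for `N ≤ 8`; Monte-Carlo currents at `N = 10` with 1e6 events × 8
replicates against a 3-sigma band. These sizes keep the full suite around
half a minute on one core while exercising every regime (short chains,
long homogeneous chains, wide random rate spreads, both TASEP phases).

## Known limitations

- Ribosome footprint, drop-off, and time-varying rates are out of model.
- Monte-Carlo TASEP sensitivities carry large error bars by nature; use
  the exact current for quantitative boundary-sensitivity statements.
- The master equation is capped at `N = 12` (state space `2^N`).
- The inhomogeneous TASEP has no closed-form current here
  (matrix-product-ansatz densities are not implemented); validation of
  inhomogeneous chains relies on the master equation and Monte Carlo.
- Near the TASEP phase transition the mean-field sensitivity is not a
  quantitative estimate of the stochastic one — that disagreement is a
  property of the approximation, reproduced (not fixed) by this package.
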