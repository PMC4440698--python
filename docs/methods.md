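# Methods

## The model

`fprsim` simulates solutions of reacting Brownian particles at
single-particle resolution. Each particle diffuses with an isotropic
diffusion constant `D` (nm²/μs); a reactant pair `A–B` is characterized by a
contact (binding) radius `σ` (nm), an intrinsic association rate at contact
`k_a` (nm³/μs, `∞` for a perfectly absorbing contact) and an intrinsic
dissociation rate `k_b` (1/μs internally; configuration files accept s⁻¹).
The two-body problem — the pair diffusion equation with a radiation boundary
condition at `r = σ` — has closed-form solutions for the propagator
`p_irr(r, t | r₀)`, the survival probability `S(t | r₀)` and the association
probability `p_assoc(t | r₀) = 1 − S`, built on the derived constants
`k_D = 4πσD` (the diffusion-limited rate) and `α = (√D/σ)(1 + k_a/k_D)`.
All of these are implemented in `fprsim.greens` with `exp(x²)·erfc(x)`
products evaluated through `scipy.special.erfcx`, so the expressions remain
finite for arbitrarily large reactivity or time.

## Free-propagator reweighting (FPR)

Sampling particle positions from the exact pair propagator requires
per-parameter-set lookup tables and is the expensive part of Green's-function
based schemes. FPR instead moves every particle with the *free* propagator —
independent Gaussian displacements of per-coordinate variance `2DΔt`, with
jointly rejected redraws of both partners whenever a trial separation falls
below `σ` — and corrects the *association probabilities* instead of the
positions. Inside a reaction zone `r < R_max = σ + 3√(6 D_AB Δt)` each pair
carries an accumulated ratio

    w = Π_steps  p_irr(r_t, Δt | r_{t−Δt}) / p_free*(r_t, Δt | r_{t−Δt}),

where `p_free*` is the free propagator renormalized to the excluded-volume
domain `[σ, ∞)` (closed-form erf/exp mass, `free_norm_constant`) and rescaled
by the stored survival of the previous step, `S = 1 − w·p_assoc` — the
*reweighted* survival, not the closed-form one. The association probability
applied against the uniform random number each step is `w·p_assoc(Δt | r)`.
The ratio is initialized to one on zone entry and reset to one on exit; its
ensemble mean at exit equals one by construction, which both keeps the
scheme efficient and provides a diagnostic: a mean exit ratio below one
signals trajectory undersampling (long in-zone paths at small `DΔt/σ²` and
large `k_a`), which depresses association. Two mitigations are exposed: a
reduced reweighting radius `R_rewgt < R_max` (association is still attempted
out to `R_max` but with the ratio held at one beyond `R_rewgt`), and an
explicit intrinsic-rate override in the configuration; neither is automated
because the appropriate size is system-specific.

Association places the complex at the diffusion-weighted point
`r_A + (D_A/D_AB)(r_B − r_A)`; dissociation is a Poisson process with
per-step probability `1 − exp(−k_b Δt)` that places the pair at exact
contact separation along a uniformly random direction, split by the same
diffusion fractions, so placement and complex formation are exact inverses.
A freshly dissociated pair does not attempt to re-associate within the step
in which it dissociated, and its next attempt is an unreweighted zone entry
(no free-propagation step has occurred from which to form a ratio).

The ensemble engines (`association_curve`, `exit_ratios`) propagate the
*relative* coordinate only: under jointly-rejected free moves the relative
coordinate is itself a free diffusion with `D = D_A + D_B` restricted to
`r ≥ σ`, so pair statistics are identical to moving both particles, at half
the cost. The explicit two-position stepper `step_pair` implements the same
case logic particle by particle and is cross-checked against the ensemble
engines in the tests.

## Many-body stepping

`step_system` advances all particles with a fixed time step in four phases:
(1) dissociation tests for every bound complex; (2) neighbor search
(`scipy.spatial.cKDTree`, periodic `boxsize` and minimum image) and
evaluation of reweighted association probabilities for every reactive pair
inside its zone; (3) association attempts — a particle with several in-zone
partners sums their probabilities, one uniform random number decides both
whether and with whom (by cumulative-interval lookup), each pair is tested
at most once per step, and everything that did not react takes its free (or
drifted) move; (4) sequential overlap resolution in which an overlapping
pair is redrawn jointly unless one member has already settled, in which case
only the other moves — each particle makes exactly one accepted displacement
per step. The time step should satisfy
`Δt < min_A (Σ_B 12π σ_AB² √(6 D_AB) ρ_B)⁻²` (at most one reactive partner
per step on average); `suggest_timestep` computes the bound and the
configuration parser enforces it unless explicitly overridden.

Choices the pair model does not fix: the diffusion constant of a complex
defaults to `min(D_A, D_B)` (configurable per reaction); particle iteration
order is randomized every step to avoid index-order bias; products do not
exclude reactants by default (adequate for dilute systems, flag available);
the summed multi-partner probability is clamped at one with a warning.

## Interaction potentials

A radially symmetric Coulomb potential `βV(r) = r_c/r` (inverse temperature
absorbed; `r_c > 0` repulsive) adds a drift `D·βF·Δt`, `βF = r_c/r²`, to the
moves. The pair Green's function under the potential is tabulated
numerically: fine-step radial Brownian dynamics (Itô drift `2D/r + D·βF`,
specular reflection at `σ`) with a thin reactive shell `[σ, σ+ε)`,
`ε = f·D·4πσ²/k_a`, inner step `δt = f·ε²/2D` and per-inner-step reaction
probability `k_a·δt / V_shell` with the exact shell volume
`V_shell = 4π(σ²ε + σε² + ε³/3)` — using the flat-boundary volume `4πσ²ε`
instead over-reacts by the shell Jacobian, `O(ε/σ)`, which is ~13% at the
shell factors the tests can afford and was caught by the `V = 0` oracle.
The construction converges to the radiation boundary condition as `f → 0`
and is validated against the closed-form Green's function at `V = 0` rather
than asserted; the one residual finite-`f` artifact is a deficit at the
contact node itself (starts inside the shell), which is why nodes with
`r₀ < σ + ε` are excluded from the survival fit. Survival versus `r₀` is
smoothed by fitting the closed-form radiation-boundary expression with an
effective `k_a` free and `D` held at the known input (the drift and
diffusion of the tabulating dynamics are exact; freeing `D` as well leaves a
degenerate parameter valley that reduced repetition counts cannot
constrain), weighted by add-one-smoothed binomial errors. Each endpoint
density is additionally fitted over its inner and outer halves separately to
whichever of two three-parameter templates (scaled radiation-boundary
propagator, or scaled drift-shifted free propagator) fits better; these
smooth fits are stored and exposed for interpolation and inspection. The
*engines*, however, use the raw endpoint histograms: the FPR reweighting
numerator, because neither template can represent the Boltzmann pileup of
an attractive potential at contact and a biased numerator shifts
association rates (histogram noise, by contrast, is mean-preserving in the
weight), and the baseline "exact-GF" pair propagation, which inverts the
empirical conditional CDFs directly.

For many-body systems with long-range forces two strategies are provided
and kept as a configuration switch: (A) every particle's drift sums all
pairwise minimum-image forces (best density profiles, O(N²) per step), or
(B) forces act only inside the reaction zone and the entry value of the
reweighting ratio is `exp(−βV(R_max))` instead of one, correcting the entry
density (much cheaper). A guard warns when the drift displacement exceeds
10% of the rms diffusive displacement anywhere in the zone.

## Reference theory and baselines

`fprsim.reference_theory` holds everything the engines are validated
against: the time-dependent Smoluchowski rates `k(t)` for absorbing and
radiation boundaries, their closed-form time integrals and the resulting
annihilation solutions `A(t) = [1/A₀ + ∫₀ᵗ k]⁻¹`; the equilibrium bound
probability `K_eq B₀/(1 + K_eq B₀)` of a target in a uniform bath; the
composed rates `k_on = ((1/k_a)+(1/k_D))⁻¹` and `k_off = k_b k_D/(k_a+k_D)`
(the unique choice with `k_on/k_off = K_eq` exactly); a hand-written
Gillespie SSA for the two supported reaction sets (no installed package
exposes a plain SSA); and an exact pair sampler that propagates radial
separations by inverse-CDF sampling of `p_irr` conditioned on survival.

Two numerical details of the inverse-CDF tables matter and are worth
recording: the inversion grid of each `r₀` node is restricted to the
propagator's support (a grid reaching down to `σ` smears the first quantile
bin of far-from-contact nodes across the empty region), and the quantile
grid is geometrically refined toward 0 and 1 (a uniform grid under-resolves
the strongly convex inverse CDF in the thin near-contact tail, which biases
the sampled bath density at contact upward by tens of percent over a few
dozen steps). Both effects were diagnosed by propagating a non-reactive
uniform bath, which the exact reflecting propagator must leave exactly
uniform. The `r₀` grid spacing defaults to
`min(0.05 nm, 0.3·√(4DΔt))` for the same reason.

## The accelerated target-equilibrium estimator

The equilibrium bound fraction of a reversible target is measured at
dissociation rates as small as 1 s⁻¹ with a 0.1 μs step — a naive run needs
~10¹⁰ steps per binding cycle. `TargetEquilibriumEstimator` makes this
reachable with two distribution-preserving accelerations: bound intervals
are collapsed (the per-step Bernoulli dissociation is sampled directly as a
geometric step count; the untouched bath partners are redrawn from their
exact uniform stationary distribution, valid because bound intervals far
exceed the box mixing time `L²/6D` — violations are counted and warned
about — while the released partner is placed at contact as always), and
out-of-zone free diffusion is fast-forwarded with aggregated Gaussian steps
whose horizon stays 4 rms displacements short of the zone (crossing
probability ~10⁻¹¹ per jump). The bound fraction is the renewal estimator
over completed bound-plus-unbound cycles with a *count-based* stopping rule —
each replica contributes a fixed number of cycles. A fixed-time window
would truncate precisely the long diffusive searches and bias the estimate
upward (observed as a factor-of-several error before the rule was adopted);
stopping on cycle counts is independent of cycle length. Standard errors
come from a jackknife over replicas, and the estimator is cross-validated
against the plain engine at fast parameters in the tests.

## Synthetic data and what passing tests show

There are no external datasets: every input is generated by the package at
the physical conditions of the validation protocols (binding radius 1 nm,
diffusion constants 1–200 nm²/μs, intrinsic rates 0.01–∞ nm³/μs and
dissociation rates 1–10⁶ s⁻¹, concentrations from μM to tens of mM, time
steps 1 ns–0.5 μs). Initial placements are uniform with reactive pairs
non-overlapping; the target problem centers one static particle among
non-interacting partners. These conditions probe the rate-limited through
diffusion-limited regimes, but they do not emulate crowding beyond reactive
exclusion, hydrodynamic coupling, orientation-dependent binding or
polydisperse mixtures — agreement here shows the integrator solves the
stated reaction–diffusion model, not that the model captures any particular
cell.

Problem sizes are deliberately modest so the whole suite runs in minutes:
10⁵ trajectories per pair condition (reference-grade curves need 10⁵–10⁷),
500-particle boxes with 5–8 replicates for the annihilation relaxations,
tens of replicas × a few cycles for the equilibrium estimator, and
shell factors `f = 0.01–0.02` with ~10³–10⁴ repetitions per `r₀` node for
the GF tabulations (the reference tabulations use `f = 0.001` and ~6×10⁵
repetitions; `f` remains the package default there). Every stochastic
tolerance is tied to the realized Monte-Carlo standard error (3 s.e.), so
the reduced sizes widen confidence bands rather than weaken the checks.

## Numerical choices and degenerate inputs

* Stored survivals are floored at 1e-12 before entering the `p_free*`
  denominator; reweighted probabilities above one are clamped with a
  warning (they are probabilities compared against a uniform draw).
* Overlap rejection is capped at 10⁶ attempts, after which the simulation
  errors out naming the offending pair instead of hanging.
* `k_a = ∞` uses the analytic absorbing limits of the propagator and
  association probability (a large finite `k_a` would overflow `exp(α²t)`),
  and `k_a = 0` the reflecting forms; the two branches are checked for
  continuity at `k_a = 10⁸` in the tests.
* Quadratures over `[σ, ∞)` are truncated where the Gaussian factor falls
  below ~1e-12 of the integral and evaluated adaptively.
* Uniform random numbers are drawn on `[0, 1)`; an event fires when the
  probability exceeds the draw. Every simulation uses one seeded
  `numpy.random.Generator`, and the seed is recorded in all outputs.

## Known limitations

The integrator is approximate in the particle *positions* near contact (the
free propagator replaces the exact one there); association kinetics are
exact up to sampling, but near-contact pair correlations are not, which is
visible only in very dense, slowly diffusing systems. Undersampling of
reweighted trajectories leaves a small one-sided association deficit in the
slow-diffusion absorbing regime (about −1% of the cumulative at
`D_AB = 1 nm²/μs`, `Δt = 0.1 μs`, `k_a = ∞`), visible as a mean exit ratio
below one; the same mechanism depresses the undersampled-regime exit-ratio
diagnostic to ≈0.98. One-dimensional and
two-dimensional geometries, anisotropic diffusion, lattice electrostatics,
screened potentials, hydrodynamic interactions and rotational degrees of
freedom are out of scope. The Gillespie baseline supports the two reaction
sets used for validation (`A+A→0`, `A+B⇌C`), not arbitrary networks.
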