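# Methods

This note documents the model implemented by `devoxel`, its assumptions,
the numerical choices behind the physics core, and what the test suite's
demonstration-scale experiments do and do not show.

## Ballistic development

Every developing parameter changes linearly from its genetic start value to
its genetic final value over the lifetime τ and is unaffected by the
environment: development is open-loop ("ballistic"), predetermined,
monotone and irreversible. Setting final = start recovers the static
phenotype exactly — in this code, bit-exactly in floating point, which the
suite exploits to verify that the Evo treatment and "development removed"
genomes are literally the degenerate case of the developmental model rather
than a separate code path.

Actuation is a global sinusoid (amplitude A = 0.14 cm, frequency f = 4 Hz)
phase-shifted per voxel. Voxels below 1 cm resting length have their
actuation damped linearly, ξ(x) = min{1, (4x − 1)/3}, reaching zero at the
0.25 cm lower bound; this is a stability device of the original model and
is applied to the *developing* resting length, i.e. inside the composition
ψ_k(t) = A sin(2πft + B_φ(t)) ξ(B_ℓ(t)).

## Genome and mutation

Morphology is bilaterally symmetric: only the lefthand half of the resting
lengths is heritable and the righthand half mirrors it. The mirror axis is
x (nx columns); travel is along y, z is up. For even nx the lefthand half
is nx/2 columns (24 independent sites at the 4×4×3 reference); odd nx is
supported by letting the center column mirror onto itself, which is what
makes the 3×3×2 demonstration body legal. Controllers are unconstrained.

Mutation is a two-stage draw. First, each applicable parameter type
(φ, φ*, ℓ, ℓ* for Evo-Devo; φ, ℓ for Evo) is independently selected with
probability 0.5, redrawn until at least one type is chosen. Second, for
each selected type, every independent site mutates with that voxel's own
probability λ_k. Perturbations are Gaussian (σ_ℓ = 0.75 cm, σ_φ = π/2) and
clipped to the hard bounds; a draw that would leave the child identical to
the parent is resampled (after a bounded number of redraws one site is
forced to change), so every child differs from its parent. Where the
scheme was genuinely open we chose: uniform initialization over each legal
interval (maximally uninformative within the stated bounds), λ_k
initialized to 1/48 (one voxel mutated on average), and per-voxel rates
self-adapted on every copy by a multiplicative log-normal step
λ_k ← clip(λ_k·exp(0.1·N(0,1)), 1/480, 1) — the standard self-adaptation
scheme, which keeps rates positive and drifts them "slightly" per copy. A
`fixed_rate` setting disables self-adaptation for the fixed-mutation-rate
variant of the experiment. Clipping (rather than reflecting or resampling)
handles out-of-bounds draws; tests assert this convention.

`expected_mutation_impact` gives the closed-form expected fraction of
genome parameters modified by one mutation under this scheme (conditioned
on at least one change), validated against a 10⁵-draw Monte Carlo and
against the operator itself.

## Physics

The body is simulated in the spirit of particle/beam voxel engines: one
point mass per voxel on the grid, beams between axis-adjacent particles,
per-beam resting length equal to the average of the two incident voxels'
instantaneous lengths L_k(t), refreshed every step. No canonical material
constants exist for this class of model, so the constants here are this
package's own calibration and absolute speeds are not expected to transfer
quantitatively; the package's claims are therefore structural and
qualitative (see "What the demonstrations show" below).

Numerical choices:

- **Integrator**: semi-implicit (symplectic) Euler, the standard stable
  choice for stiff mass-spring systems. The hot loop is JIT-compiled
  (numba) and validated against closed forms: damped free fall (first-order
  convergent, < 1 % error at dt = 1 ms) and the two-particle oscillator
  (frequency within 0.02 % of √(2k/m)/2π at the default dt).
- **Rotational stiffness**: approximated by straightening springs across
  each collinear beam pair (second-neighbor springs with resting length
  equal to the sum of the two constituent beams'). These resist bending and
  buckling with central, momentum-conserving forces at a fraction of the
  complexity of quaternion beam elements.
- **Contact**: one-sided penalty spring (stiffness `ground_k`) with viscous
  normal damping, normal force clamped non-negative; kinetic Coulomb
  friction capped by μ|N| with a small regularization velocity (0.1 cm/s)
  to avoid stick-slip chatter at rest.
- **Units and defaults**: cm/g/s, gravity 981 cm/s², particle mass 1 g,
  beam stiffness 4·10⁴ g/s² (lattice eigenfrequencies well above the 4 Hz
  drive: quasi-static actuation), dt = 10⁻⁴ s. Config validation enforces
  dt ≤ 0.1 √(m/k_max). Static ground penetration at these defaults is
  ≈ 0.02 cm, well below the 0.05 cm contact threshold used for rollover
  detection (5 % of the voxel size; the threshold is exposed in config).
- **Divergence**: non-finite or runaway positions raise an instability
  error naming the offending dt/stiffness; during evolution such genomes
  score fitness 0 rather than aborting the trial, so search can traverse
  degenerate regions.
- **Fitness**: net horizontal center-of-mass displacement divided by the
  undeformed body length. "Distance traveled" could also mean path length;
  net displacement is the default because falling without advancing should
  not score, and path length is available behind a flag.
- **Initial condition**: particles are placed with spacings equal to the
  averaged instantaneous voxel lengths at t = 0, chains centered on the
  midsagittal/midcoronal planes, bottom resting on the ground plane,
  velocities zero. For heterogeneous bodies this leaves small initial beam
  stresses that relax within a few steps (damping removes the energy).

Energy accounting (kinetic + gravitational + elastic beam/straightening +
ground penalty) is non-increasing between samples for a passive damped
robot, which the suite asserts with a 10⁻⁶ relative slack for integrator
bookkeeping.

## Evolution

AFPO per generation: double by mutation (children keep the parent's
lineage age), increment every individual's age, inject one random age-0
individual — pool = 2·pop + 1, i.e. 61 at the reference population of 30 —
evaluate the new genomes, and reduce back to pop by repeated random
pairwise dominance tournaments (delete the dominated member of a sampled
pair). Injection happens before selection. Two
details are deliberately pinned down here because the canonical algorithm
leaves them open:

- **Stall guard**: after pop² consecutive dominance-free draws (a mutually
  non-dominated pool larger than capacity), a random member of the
  largest-age cohort is deleted — excluding the current fittest
  individual, so the elitism property "the globally best individual always
  survives selection" holds unconditionally.
- **Age convention**: age tracks lineage, not individual; children inherit
  the parent's (incremented) age, injected robots enter at age 0.

The selection reduction is verified against an exact enumeration of its
Markov chain (state = surviving set + stall counter) on pools of ≤ 8:
the empirical survivor-set distribution over 10³ seeded reductions matches
the enumerated distribution within 3 standard errors, including the stall
path. Fitness evaluations are cached by genome content, so survivors are
never re-simulated.

## Analyses

Developmental windows W_L and W_Φ normalize the total lifetime change of a
subsystem by its maximum (48 voxels × 1.5 cm, resp. 48 × π), so both lie in
[0, 1]. Lineages are traced through logged parent links from the run
champion (highest fitness at termination) back to a generation-0 or
injected founder; the "most distant ancestor" is the first chain entry
regardless of origin. Robustness walks apply cumulative mutations
restricted to one subsystem (φ-parameters for control walks, ℓ-parameters
for morphology walks) with per-voxel rates frozen, re-evaluating fitness
each step, so they probe the phenotype landscape rather than the rate
landscape. Rollover onset is the first recorded sample at which any
initially-top-layer particle is within the contact threshold of the
ground. The Mann-Whitney U test enumerates all group assignments exactly
for samples of ≤ 8 per group (ties handled by construction) and otherwise
uses the tie-corrected normal approximation.

## Demonstration scale and what it shows

Full-scale runs (30 trials × 10,000 generations × 48 voxels × 10 s
lifetimes) are supported through the library and CLI but are not test
artifacts. The suite and `scripts/acceptance.py` use a demonstration
scale chosen once: a 3×3×2 body, 5 actuation cycles (τ = 1.25 s), softer
constants (`PhysicsConfig.toy()`: k = 2·10⁴, dt = 3·10⁻⁴ s), populations
of 10 for 200 generations, 5 trials per treatment. At this scale one
evolutionary trial is a few seconds and the whole acceptance battery a few
minutes.

These demonstrations establish that the machinery behaves as specified:
selection improves on the initial population in every trial of both
treatments; development removal preserves the birth phenotype bit-exactly
and most of champion fitness; champions remain more robust to control
walks than to morphology walks. They do *not* reproduce the full-scale
quantitative findings (multi-body-length speeds, 25/30 vs 6/30 discovery
rates, the complete rise-and-fall canalization signature), which require
full-scale physics constants and orders of magnitude more search. The
synthetic robots also idealize real soft robots: homogeneous material, no
self-collision, flat rigid terrain, noise-free actuation — so passing
tests speak to the model, not to physical hardware.
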