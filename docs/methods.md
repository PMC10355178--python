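# Methods

This note records the model assumptions, the numerical choices and the
design decisions behind `defsym`, in the spirit of a model-description
appendix.

## Model and assumptions

A well-mixed host population co-circulates two horizontally transmitted
microbes: an obligate parasite and a defensive symbiont conferring
*mortality tolerance* (reduced disease-induced death in coinfected
hosts). Hosts are born microbe-free (no vertical transmission), acquire
each microbe independently (no cotransmission; a host carries at most
one strain of each microbe), and carry no lasting immunity. Ecology is
deterministic (ODEs); evolutionary stochasticity enters only through the
order and direction of mutations in the trait-substitution simulations.

Trait structure:

- Parasite transmission β_P with virulence α_P(β_P) = α̂_P(1 + β_P^d),
  d > 1 (diminishing returns, so a finite optimum can exist).
- Symbiont tolerance y ∈ [0, 1], costing transmission
  β_D(y) = β̂_D(1 − c(y)) with the exponential cost
  c(y) = c1(1 − e^{c2 y})/(1 − e^{c2}); the linear branch c1·y is used
  when |c2| < 1e−8 to avoid the 0/0 limit (continuity at the switch is
  tested to < 1e−6 uniformly in y).

**Coinfection virulence.** Only the constraints
α_B(y, β_P) ≤ α_D + α_P(β_P), α_B(0) = α_D + α_P and α_B(1) = α_D
(complete negation of parasite-induced mortality at full tolerance, with
the symbiont's own burden retained) pin down the coinfection mortality;
within them we adopt the linear interpolation

    α_B(y, β_P) = α_D + (1 − y) α_P(β_P).

This is a genuine modelling degree of freedom. Under the linear form all
parasite-side phenomena reproduce robustly (see *Known limitations* for
the symbiont-side consequences).

Default parameters: a = 1.0, q = 0.25, b = 0.25, β̂_D = 2, γ_D = 0.05,
α_D = 0.1, α̂_P = 0.1, d = 2, γ_P = 0.05, c1 = 0.25, c2 = 2 (all rates
per unit time; densities in arbitrary host units). The disease-free host
density is (a − b)/q = 3 and the symbiont-free CSS transmission is
β̃_P* = 2.

## Equilibria

Endemic equilibria are found by relaxing the ODEs (LSODA, rtol 1e−10,
atol 1e−12 — invasion-fitness derivatives amplify equilibrium error)
over windows of doubling length starting at 400 time units, capped at
1e6. After each window a Newton polish of the algebraic steady state is
attempted on the currently occupied compartments (extinct strains held
at zero) and accepted only if it is non-negative, lies close to the
integrated state (within 5% of its scale, so the polish cannot jump
between attractors) and drives the residual max|RHS| below the tolerance
(default 1e−9). Negative round-off densities are clamped to zero; the
clamp is never used to remove strains. Non-convergence is flagged, and
invasion-fitness evaluations refuse unconverged equilibria.

## Invasion analysis

Invasion fitness is the next-generation reproduction ratio of the
two-compartment rare-mutant subsystem (singly infected + coinfected with
the resident partner) at the resident equilibrium; it exceeds one iff
the dominant eigenvalue of that subsystem's Jacobian is positive, which
is used as an independent oracle in the tests. Neutrality of a
resident-identical mutant (w = 1) holds to machine precision at polished
equilibria and is the joint transcription/equilibrium check.

Selection gradients use central finite differences in the mutant trait
with relative step 1e−4·max(|trait|, 0.1) (one-sided at trait
boundaries); second derivatives (E, and the mixed partial C_P) use the
coarser 1e−2 step because the equilibrium residual (~1e−9) sets a noise
floor. Singular strategies are Brent roots of the gradient after a sign
scan over the bracket; when no sign change exists a boundary/runaway
report carries the gradient sign instead. Classification follows the
standard taxonomy: evolutionary stability from E < 0; convergence
stability from the slope of the gradient in the resident trait,
dF/dtrait < 0 at the root (equivalent, via the neutrality identity, to
E < −C). The mixed partial C is computed and reported but not used as
the convergence test, because the slope criterion — unlike a direct
comparison of E against C — correctly classifies the full-tolerance
branching point (E = +0.0043, C = −0.042, slope < 0: convergent and
invadable, i.e. branching).

For coevolution, the joint singular point is a 2-D root of (F_D, F_P);
strong convergence stability is assessed, under the model's
equal-mutation-rate assumption, by negative definiteness of the
symmetric part of the Jacobian of the selection-gradient vector at the
root (the isotropic specialization of the usual multi-trait convergence
criterion).

Pairwise invasion plots share one resident equilibrium per column;
columns whose resident equilibrium lacks the focal microbe are marked
undefined. Entries with |w − 1| ≤ 1e−6 are stored as neutral (0), which
covers the diagonal.

## Trait-substitution simulations

Each evolutionary step integrates the strain-structured ecology for
T_eco = 100 time units (LSODA, rtol 1e−8, atol 1e−10), prunes phenotypes
below a relative frequency of ε = 1e−4, and introduces one mutant. In
coevolution mode the microbe to mutate is chosen with equal probability;
the parent strain is chosen proportional to its frequency within its
microbe; the mutant trait is one lattice site up or down with equal
probability (steps off the lattice ends are discarded). All draws come
from one generator seeded once, in the documented order (microbe,
parent, direction), so runs are bit-reproducible. Simulations start from
the symbiont-free endemic equilibrium at the initial parasite trait
(defaulting to β̃_P*), with a small symbiont inoculum (0.01 density
units) transferred from the microbe-free class.

Design decisions where the procedure is under-determined:

- **Pruning frequency** is computed within each microbe (parasite
  strains relative to all parasite-bearing hosts, symbiont strains
  likewise), keeping the threshold comparable when prevalences differ.
  A pruned strain's coinfected hosts are reassigned to the partner's
  single-microbe class — deleting them would kill hosts spuriously;
  only the pruned strain's own singly infected mass leaves the system.
- **Mutant seeding**: 1% of the parent strain's singly infected density,
  transferred (not created), so total host density is conserved.
- **Trait lattices**: y on [0, 1] with spacing 0.05; β_P on [0, 6] with
  spacing 0.15. The spacing controls the speed of the substitution
  process twice over (sweeps per unit trait distance ~1/ε, selection
  coefficient per sweep ~ε), and these spacings let the full-tolerance
  parasite walk reach its singular point within a few hundred steps and
  express branching within the T_evo = 2000 budget, while still
  resolving the dimorphic gap (~1.2 trait units ≫ the split rule below)
  by an order of magnitude.
- **Branch detection**: phenotypes persisting through a trailing window
  (default 10% of T_evo) are clustered; a gap of at least two empty
  lattice sites splits clusters, separating true dimorphism from the
  transient mutation cloud. Cluster masses and the coinfected fraction
  of each cluster are read from the final state.

## Regime classification and impact measures

The coevolutionary outcome at a cost pair (c1, c2) is classified by
deterministic gradient flow dy/dτ = F_D, dβ_P/dτ = F_P (equal mutation
rates), started from low (0.05) and high (0.95) initial protection with
the parasite at β̃_P*. The flow uses normalized Euler steps capped at
0.02 trait units, halving the step whenever a gradient component flips
sign (oscillation around an attracting point), with warm-started
equilibrium solves along the path; components pinned at a trait boundary
with an outward gradient exert no further selection. Endpoints within
0.02 of a boundary count as boundary outcomes; endpoints differing by
more than 0.05 in y between the two starts signal a repeller. The
stochastic simulation provides a cross-check of the classification
(both agree at the four cost-plane crosses exercised in the tests).

Q1 and Q2 are pure arithmetic on equilibrium quantities; the
symbiont-free baseline (Ñ*, r̃*) is computed once per parameter set at
β̃_P* and cached. For simulation endpoints the final polymorphic state
is relaxed to equilibrium before measuring.

## Problem sizes used in the tests

The acceptance-style checks use: 20 random draws for the neutrality
identity; 100+ (resident, mutant) pairs for the eigenvalue oracle;
T_evo = 1500 with 3 seeds per cost strength for the branching runs
(branching establishes by ~step 1200 under these lattices; the full
study length is T_evo = 2000); and T_evo = 500 with 3 seeds per cross
for the coevolution impact runs, whose endpoints agree with the
gradient-flow singular points to within lattice resolution.

## What the simulations do and do not show

The trait-substitution process emulates mutation-limited evolution on a
finite trait lattice with overlapping ecological relaxation — not
demographic stochasticity (no individual-based noise), not standing
genetic variation, and not within-host dynamics (the coinfection
interaction is phenomenological). Passing tests therefore validate the
eco-evolutionary feedback logic of the model, not quantitative
predictions for any real host–microbe system.

## Known limitations

- The linear α_B interpolation is one admissible choice. The
  parasite-side predictions (escalation of virulence with protection;
  the runaway → branching → CSS progression in the cost strength at full
  tolerance) are insensitive to it in our exploration, but the
  *position* of the symbiont-side regime boundaries in the (c1, c2)
  plane is not: under the linear form the repeller region sits at
  moderate decelerating costs (e.g. c1 = 0.4, c2 = −2), while at strong
  decelerating costs (c1 = 0.9, c2 = −2) protection is selected against
  from any starting level (and the symbiont cannot persist above
  y ≈ 0.8 because its transmission falls below the persistence
  threshold); likewise the strong-accelerating co-CSS sits at moderate
  protection (y* ≈ 0.38 at c1 = 0.9, c2 = 2) where the net mortality
  effect Q2 is negative. A coinfection virulence that is concave in
  (1 − y) would strengthen selection for protection at high y and shift
  these boundaries toward stronger costs. The package exposes α_B in
  one place (`model_core.coinfection_virulence`) to make such variants
  easy to explore.
- Gradient-flow classification assumes the endemic equilibrium is
  unique and stable along the path; no fold/bistability tracking is
  attempted.
- Runaway (boundary) outcomes are reported as such rather than being
  assigned a finite singular value.
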