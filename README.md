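# defsym

Eco-evolutionary dynamics of a **tolerance-conferring defensive symbiont**
co-circulating with an obligate parasite in a well-mixed host population.

Defensive symbionts are candidate biocontrol agents: they can reduce the
harm a parasite does to its host (mortality tolerance) without blocking
infection or transmission. But protection is an evolvable trait, and so is
parasite virulence. This package implements a coinfection model to ask
what happens after such a symbiont is introduced: does the parasite evolve
higher virulence, can it diversify, how does protection itself evolve, and
is the host population better or worse off in the long run?

It is intended for theoretical ecologists and evolutionary
epidemiologists who want to regenerate, probe or extend these results:
the ecological ODE system, evolutionary invasion analysis (invasion
fitness, selection gradients, singular strategies, pairwise invasion
plots), stochastic trait-substitution simulations with branching
detection, and net host-impact measures.

## Model

Hosts occupy four classes — microbe-free `H`, symbiont-only `D`,
parasite-only `P`, coinfected `B` — with births ν(N) = N(a − qN) into `H`,
background mortality `b`, density-dependent transmission and clearance
rates γ_D, γ_P:

```
dH/dt = ν(N) − [b + β_D(y)(D+B) + β_P(P+B)] H + γ_D D + γ_P P
dD/dt = β_D(y) H (D+B) − [b + γ_D + α_D + β_P(P+B)] D + γ_P B
dP/dt = β_P H (P+B) − [b + γ_P + α_P(β_P) + β_D(y)(D+B)] P + γ_D B
dB/dt = β_D(y) P (D+B) + β_P D (P+B) − [b + α_B(y,β_P) + γ_D + γ_P] B
```

The parasite pays a power-law transmission–virulence trade-off
α_P(β_P) = α̂_P (1 + β_P^d), d > 1. The symbiont confers tolerance
y ∈ [0, 1] to coinfected hosts, α_B(y, β_P) = α_D + (1 − y) α_P(β_P),
at a cost to its own transmission, β_D(y) = β̂_D (1 − c(y)) with
c(y) = c1 (1 − e^{c2 y})/(1 − e^{c2}) (accelerating for c2 > 0,
decelerating for c2 < 0).

Invasion fitness of rare mutants (w_D for the symbiont, w_P for the
parasite) is the next-generation reproduction ratio of the two-compartment
rare-mutant subsystem at the resident endemic equilibrium; selection
gradients, singular strategies and their stability (CSS, branching point,
repeller) follow the standard adaptive-dynamics toolbox. In the absence
of the symbiont the parasite's continuously stable strategy has the
closed form β̃_P* = ((b + γ_P + α̂_P)/(α̂_P (d − 1)))^{1/d}.

Net host impact is measured against the symbiont-free baseline at β̃_P*:
Q1 = 100 (N*/Ñ* − 1) (percentage change in host density) and
Q2 = 100 (1 − r*/r̃*) (percentage reduction in the average
disease-associated mortality rate r).

## Worked example

With default parameters the symbiont-free parasite CSS is β = 2:

```
$ defsym css
2
```

Introduce a half-protective symbiont (y = 0.5) against that parasite and
the short-term, ecology-only effect is positive:

```
$ defsym impact --y 0.5 --beta 2.0
N*=1.77256 N~=1.5247 r*=0.306859 r~=0.368826 Q1=16.2570% Q2=16.8012%
```

Host density rises 16.3% and average disease mortality falls 16.8%
relative to the symbiont-free system — the symbiont initially looks like
a good biocontrol agent. But the parasite now evolves: at full tolerance
(y = 1) with protection cost strength c1 = 0.5 the parasite's singular
transmission strategy is

```
$ defsym singular --which parasite --other 1.0 -s c1=0.5 --lo 2 --hi 8
trait=4.665934785275878 class=branching E=0.004298161397713344 C=-0.042115386835900104 convergent=True |F|=2.86e-12
```

an *evolutionary branching point* far above the symbiont-free CSS:
virulence escalates (from β = 2 toward β ≈ 4.67) and the parasite then
diversifies into a low-virulence strain living mainly in unprotected
hosts and a high-virulence strain living mainly in coinfected hosts.
The same escalation from a trait-substitution simulation:

```
$ defsym evolve --mode parasite-only --y0 1.0 -s c1=0.5 -s T_evo=1500 --seed 1 --out run/
```

writes the full trajectory (long CSV + JSON manifest) and reports the
persistent phenotype clusters. Coevolutionary regime maps over the cost
plane (c1, c2) come from `defsym map`, and `defsym pip` exports pairwise
invasion plots.

## Layout

- `src/defsym/model_core.py` — rates, ODEs (mono- and polymorphic), equilibria
- `src/defsym/invasion_analysis.py` — fitness, gradients, singular strategies, PIPs
- `src/defsym/evolution_sim.py` — trait-substitution simulation, branching detection
- `src/defsym/outcome_metrics.py` — Q1/Q2, gradient-flow regime classification
- `src/defsym/io.py`, `src/defsym/cli.py` — config, manifests, CSV output, CLI
- `docs/methods.md` — modelling and numerical choices in detail
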