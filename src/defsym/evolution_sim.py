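"""Stochastic trait-substitution simulations on a discretized trait space.

Evolution proceeds as a sequence of evolutionary steps: the strain-
structured ecology is integrated for a fixed window T_eco, phenotypes
below a relative frequency threshold are pruned, and a rare mutant one
lattice site away from a randomly chosen parent strain is introduced.
Unlike the separated-timescale invasion analysis, mutants may arise
before the ecology has relaxed and mutations have small but finite
effect, so branching and runaway dynamics emerge naturally.
"""

from __future__ import annotations

import logging
from dataclasses import dataclass, field, fields, replace
from typing import List, Optional, Tuple

import numpy as np
from scipy.integrate import odeint

from .invasion_analysis import resident_equilibrium, symbiont_free_css
from .model_core import MonomorphicState, PolymorphicState, _PolyRates, _clamp
from .params import ModelParameters, ResidentTraits

__all__ = [
    "SimulationSettings",
    "StepRecord",
    "EvolutionaryTrajectory",
    "BranchReport",
    "run_trait_substitution",
    "prune_extinct",
    "introduce_mutant",
    "detect_branches",
]

logger = logging.getLogger(__name__)

MODES = ("parasite-only", "symbiont-only", "coevolution")


@dataclass(frozen=True)
class SimulationSettings:
    """Knobs of the trait-substitution algorithm.

    ``T_eco`` is the ecological window per evolutionary step, ``T_evo``
    the number of evolutionary steps, ``epsilon`` the within-microbe
    relative frequency below which a phenotype is removed.  Traits live
    on lattices with spacings ``eps_D`` (tolerance, on [0, 1]) and
    ``eps_P`` (parasite transmission, on [0, beta_max]).  Mutants are
    seeded with a fraction ``mutant_fraction`` of the parent strain's
    singly infected density, transferred so hosts are conserved.
    """

    T_eco: float = 100.0
    T_evo: int = 2000
    epsilon: float = 1e-4
    eps_D: float = 0.05
    eps_P: float = 0.15
    beta_max: float = 6.0
    mutant_fraction: float = 0.01
    seed: int = 0
    mode: str = "coevolution"
    rtol: float = 1e-8
    atol: float = 1e-10

    def __post_init__(self) -> None:
        if self.T_eco <= 0:
            raise ValueError("T_eco must be > 0")
        if self.T_evo < 1:
            raise ValueError("T_evo must be >= 1")
        if not 0.0 < self.epsilon < 1.0:
            raise ValueError("epsilon must lie in (0, 1)")
        if self.eps_D <= 0 or self.eps_P <= 0:
            raise ValueError("lattice spacings must be > 0")
        if not 0.0 < self.mutant_fraction < 1.0:
            raise ValueError("mutant_fraction must lie in (0, 1)")
        if self.mode not in MODES:
            raise ValueError(f"mode must be one of {MODES}, got {self.mode!r}")

    def with_updates(self, **kwargs) -> "SimulationSettings":
        return replace(self, **kwargs)

    def to_dict(self) -> dict:
        return {f.name: getattr(self, f.name) for f in fields(self)}

    @classmethod
    def from_mapping(cls, mapping) -> "SimulationSettings":
        known = {f.name for f in fields(cls)}
        unknown = sorted(set(mapping) - known)
        if unknown:
            raise ValueError(f"unknown settings keys: {', '.join(unknown)}")
        clean = dict(mapping)
        for key in ("T_evo", "seed"):  # tolerate float-typed config values
            if key in clean:
                clean[key] = int(clean[key])
        return cls(**clean)


def _snap(value: float, spacing: float, upper: float) -> float:
    """Round a trait onto its lattice (and into bounds)."""
    k = round(value / spacing)
    return float(np.clip(round(k * spacing, 12), 0.0, upper))


@dataclass
class StepRecord:
    """State snapshot after one evolutionary step."""

    step: int
    y_strains: np.ndarray
    beta_strains: np.ndarray
    H: float
    D: np.ndarray
    P: np.ndarray
    B: np.ndarray
    N: float


@dataclass
class EvolutionaryTrajectory:
    steps: List[StepRecord]
    settings: SimulationSettings
    params: ModelParameters

    @property
    def final_state(self) -> PolymorphicState:
        r = self.steps[-1]
        return PolymorphicState(r.y_strains.copy(), r.beta_strains.copy(),
                                r.H, r.D.copy(), r.P.copy(), r.B.copy())


@dataclass
class BranchReport:
    """Phenotype clusters of one microbe over a trailing window."""

    n_clusters: int
    cluster_means: List[float]
    cluster_masses: List[float]
    cluster_coinfected_fraction: List[float]


# --------------------------------------------------------------------------
# elementary moves


def prune_extinct(state: PolymorphicState, epsilon: float) -> PolymorphicState:
    """Remove phenotypes below relative frequency ``epsilon``.

    Frequencies are computed within each microbe: parasite strain i has
    frequency (P_i + sum_j B_ij) over all parasite-bearing hosts, and
    symmetrically for symbiont strains.  A removed strain's coinfected
    hosts are reassigned to the surviving partner's single-microbe class
    so that no partner hosts are spuriously killed; only the removed
    strain's own singly infected mass leaves the system.
    """
    st = state.copy()
    # parasite side
    if st.n_parasite > 0:
        totals = st.parasite_totals()
        grand = totals.sum()
        if grand > 0:
            keep = totals / grand >= epsilon
            if not keep.all():
                st.D = st.D + st.B[~keep].sum(axis=0)
                st.beta_strains = st.beta_strains[keep]
                st.P = st.P[keep]
                st.B = st.B[keep]
    # symbiont side
    if st.n_symbiont > 0:
        totals = st.symbiont_totals()
        grand = totals.sum()
        if grand > 0:
            keep = totals / grand >= epsilon
            if not keep.all():
                st.P = st.P + st.B[:, ~keep].sum(axis=1)
                st.y_strains = st.y_strains[keep]
                st.D = st.D[keep]
                st.B = st.B[:, keep]
    return st


def _insert_strain(traits: np.ndarray, value: float) -> Tuple[np.ndarray, int, bool]:
    """Insert a trait into a sorted list; returns (list, index, existed)."""
    idx = int(np.searchsorted(traits, value))
    if idx < len(traits) and abs(traits[idx] - value) < 1e-12:
        return traits, idx, True
    return np.insert(traits, idx, value), idx, False


def introduce_mutant(state: PolymorphicState, microbe: str, parent_index: int,
                     direction: int,
                     settings: SimulationSettings) -> Tuple[PolymorphicState, bool]:
    """Seed a mutant one lattice site from its parent strain.

    The mutant receives ``mutant_fraction`` of the parent's singly
    infected density, deducted from the parent so total host density is
    conserved.  Steps outside the trait bounds are no-ops (returned flag
    False); if the target site is already occupied its strain simply
    gains the transferred mass.
    """
    if microbe not in ("symbiont", "parasite"):
        raise ValueError(f"microbe must be 'symbiont' or 'parasite', got {microbe!r}")
    st = state.copy()
    if microbe == "parasite":
        spacing, upper = settings.eps_P, settings.beta_max
        traits = st.beta_strains
    else:
        spacing, upper = settings.eps_D, 1.0
        traits = st.y_strains
    parent_trait = traits[parent_index]
    target = round(parent_trait + direction * spacing, 12)
    if target < -1e-12 or target > upper + 1e-12:
        return st, False
    target = float(np.clip(target, 0.0, upper))

    if microbe == "parasite":
        seed = settings.mutant_fraction * st.P[parent_index]
        st.P = st.P.copy()
        st.P[parent_index] -= seed
        new_traits, idx, existed = _insert_strain(st.beta_strains, target)
        if existed:
            st.P[idx] += seed
        else:
            st.beta_strains = new_traits
            st.P = np.insert(st.P, idx, seed)
            st.B = np.insert(st.B, idx, 0.0, axis=0)
    else:
        seed = settings.mutant_fraction * st.D[parent_index]
        st.D = st.D.copy()
        st.D[parent_index] -= seed
        new_traits, idx, existed = _insert_strain(st.y_strains, target)
        if existed:
            st.D[idx] += seed
        else:
            st.y_strains = new_traits
            st.D = np.insert(st.D, idx, seed)
            st.B = np.insert(st.B, idx, 0.0, axis=1)
    return st, True


# --------------------------------------------------------------------------
# main loop


def _integrate_window(state: PolymorphicState, params: ModelParameters,
                      settings: SimulationSettings) -> PolymorphicState:
    rates = _PolyRates(state.y_strains, state.beta_strains, params)
    x0 = state.pack()
    sol = odeint(rates.rhs, x0, [0.0, settings.T_eco],
                 rtol=settings.rtol, atol=settings.atol, mxstep=100000)
    return state.unpack(_clamp(sol[-1]))


def _initial_state(params: ModelParameters, settings: SimulationSettings,
                   init: ResidentTraits,
                   symbiont_intro_density: float) -> PolymorphicState:
    """Symbiont introduced into the established host-parasite system:
    symbiont-free endemic equilibrium at the initial parasite trait, with
    a small symbiont inoculum transferred from the microbe-free class."""
    beta0 = _snap(init.beta_P, settings.eps_P, settings.beta_max)
    base = resident_equilibrium(ResidentTraits(y=None, beta_P=beta0), params)
    mono = base.state
    if init.y is None:
        return PolymorphicState(np.empty(0), np.array([beta0]), mono.H,
                                np.empty(0), np.array([mono.P]),
                                np.zeros((1, 0)))
    y0 = _snap(init.y, settings.eps_D, 1.0)
    intro = min(symbiont_intro_density, 0.5 * mono.H)
    return PolymorphicState(np.array([y0]), np.array([beta0]),
                            mono.H - intro, np.array([intro]),
                            np.array([mono.P]), np.zeros((1, 1)))


def run_trait_substitution(params: ModelParameters,
                           settings: SimulationSettings,
                           init: Optional[ResidentTraits] = None,
                           mutate: bool = True,
                           symbiont_intro_density: float = 0.01,
                           record_every: int = 1) -> EvolutionaryTrajectory:
    """Run the trait-substitution sequence.

    ``init`` supplies the initial resident traits; a missing parasite
    trait (or ``init=None`` in parasite-only mode without symbiont)
    defaults to the symbiont-free CSS transmission value.  Each of the
    ``T_evo`` steps integrates the ecology for ``T_eco``, prunes rare
    phenotypes and (unless ``mutate`` is False) introduces one mutant.
    All stochastic choices come from a single generator seeded with
    ``settings.seed``: microbe (coevolution mode only), then parent
    strain, then step direction.
    """
    if init is None:
        init = ResidentTraits(y=None, beta_P=symbiont_free_css(params))
    if init.beta_P is None:
        init = ResidentTraits(y=init.y, beta_P=symbiont_free_css(params))
    if settings.mode == "symbiont-only" and init.y is None:
        raise ValueError("symbiont-only mode requires an initial tolerance")

    rng = np.random.default_rng(settings.seed)
    state = _initial_state(params, settings, init, symbiont_intro_density)
    records: List[StepRecord] = []

    for step in range(1, settings.T_evo + 1):
        state = _integrate_window(state, params, settings)
        if state.N < 1e-6:
            raise RuntimeError(
                f"host population went extinct at evolutionary step {step}")
        state = prune_extinct(state, settings.epsilon)

        if mutate:
            if settings.mode == "coevolution":
                microbe = "symbiont" if rng.random() < 0.5 else "parasite"
            elif settings.mode == "parasite-only":
                microbe = "parasite"
            else:
                microbe = "symbiont"
            totals = (state.symbiont_totals() if microbe == "symbiont"
                      else state.parasite_totals())
            if totals.size > 0 and totals.sum() > 0:
                freqs = totals / totals.sum()
                parent = int(rng.choice(len(freqs), p=freqs))
                direction = 1 if rng.random() < 0.5 else -1
                state, ok = introduce_mutant(state, microbe, parent,
                                             direction, settings)
                if not ok:
                    logger.debug("step %d: %s mutation off-lattice (no-op)",
                                 step, microbe)
            else:
                logger.debug("step %d: %s extinct, no mutation", step, microbe)

        if step % record_every == 0 or step == settings.T_evo:
            records.append(StepRecord(
                step=step, y_strains=state.y_strains.copy(),
                beta_strains=state.beta_strains.copy(), H=float(state.H),
                D=state.D.copy(), P=state.P.copy(), B=state.B.copy(),
                N=state.N))
    return EvolutionaryTrajectory(steps=records, settings=settings,
                                  params=params)


# --------------------------------------------------------------------------
# branching detection


def detect_branches(trajectory: EvolutionaryTrajectory,
                    window: Optional[int] = None,
                    microbe: str = "parasite") -> BranchReport:
    """Cluster the phenotypes that persist through a trailing window.

    Strains present in every recorded step of the window are grouped into
    lattice-contiguous clusters; a gap of at least two empty lattice
    sites splits clusters, which separates true dimorphism from the
    transient mutation cloud around a single peak.
    """
    settings = trajectory.settings
    if window is None:
        window = max(1, settings.T_evo // 10)
    steps = trajectory.steps[-window:]
    if not steps:
        return BranchReport(0, [], [], [])
    spacing = settings.eps_P if microbe == "parasite" else settings.eps_D

    def traits_of(rec: StepRecord) -> np.ndarray:
        return rec.beta_strains if microbe == "parasite" else rec.y_strains

    persistent = set(np.round(traits_of(steps[0]), 9))
    for rec in steps[1:]:
        persistent &= set(np.round(traits_of(rec), 9))
    if not persistent:
        return BranchReport(0, [], [], [])

    sites = np.array(sorted(persistent))
    # split where >= 2 empty lattice sites separate occupied runs
    breaks = np.where(np.diff(sites) > 2.5 * spacing)[0]
    clusters = np.split(sites, breaks + 1)

    final = trajectory.final_state
    if microbe == "parasite":
        traits, singly, coinf = (final.beta_strains, final.P,
                                 final.B.sum(axis=1))
    else:
        traits, singly, coinf = (final.y_strains, final.D,
                                 final.B.sum(axis=0))
    means, masses, coinf_fracs = [], [], []
    for cluster in clusters:
        mask = np.isin(np.round(traits, 9), np.round(cluster, 9))
        mass_single = singly[mask].sum()
        mass_co = coinf[mask].sum()
        mass = mass_single + mass_co
        if mass <= 0:
            continue
        means.append(float(np.average(traits[mask],
                                      weights=(singly + coinf)[mask])))
        masses.append(float(mass))
        coinf_fracs.append(float(mass_co / mass))
    return BranchReport(n_clusters=len(means), cluster_means=means,
                        cluster_masses=masses,
                        cluster_coinfected_fraction=coinf_fracs)
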