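"""Ecological core: trait-dependent rates, coinfection ODEs, equilibria.

Hosts occupy four classes: microbe-free (H), symbiont-only (D),
parasite-only (P) and coinfected (B).  The monomorphic system tracks one
strain of each microbe; the polymorphic system structures D, P and B by
strain and is the substrate for trait-substitution simulations.

Key functional forms
--------------------
* protection cost  c(y) = c1 (1 - exp(c2 y)) / (1 - exp(c2))  (linear
  branch c1*y as c2 -> 0),
* symbiont transmission  beta_D(y) = beta_hat_D (1 - c(y)),
* parasite virulence  alpha_P(beta) = alpha_hat_P (1 + beta**d),
* coinfection virulence  alpha_B(y, beta) = alpha_D + (1 - y) alpha_P(beta),
  a linear interpolation between the additive case (y = 0) and complete
  negation of parasite-induced mortality at full tolerance (y = 1); it
  respects the bound alpha_B <= alpha_D + alpha_P everywhere.
"""

from __future__ import annotations

import math
from dataclasses import dataclass, field
from typing import Optional, Sequence, Tuple, Union

import numpy as np
from scipy.integrate import odeint
from scipy.optimize import root as _scipy_root

from .params import ModelParameters, ResidentTraits

__all__ = [
    "protection_cost",
    "symbiont_transmission",
    "parasite_virulence",
    "coinfection_virulence",
    "birth_rate",
    "MonomorphicState",
    "PolymorphicState",
    "EquilibriumResult",
    "ode_rhs_monomorphic",
    "ode_rhs_polymorphic",
    "solve_equilibrium",
]

#: below this magnitude of c2 the cost function switches to its linear limit
_C2_LINEAR_SWITCH = 1e-8


def protection_cost(y: float, c1: float, c2: float) -> float:
    """Fractional transmission cost c(y) paid by a symbiont conferring
    tolerance ``y``.

    Increasing in ``y`` from 0 to ``c1``; accelerating for ``c2 > 0``,
    decelerating for ``c2 < 0``, linear in the ``c2 -> 0`` limit.
    """
    if not 0.0 <= y <= 1.0:
        raise ValueError(f"tolerance y must lie in [0, 1], got {y}")
    if not 0.0 <= c1 <= 1.0:
        raise ValueError(f"c1 must lie in [0, 1], got {c1}")
    if abs(c2) < _C2_LINEAR_SWITCH:
        return c1 * y
    return c1 * (1.0 - math.exp(c2 * y)) / (1.0 - math.exp(c2))


def symbiont_transmission(y: float, params: ModelParameters) -> float:
    """Transmission coefficient beta_D(y) of a symbiont with tolerance y."""
    return params.beta_hat_D * (1.0 - protection_cost(y, params.c1, params.c2))


def parasite_virulence(beta_P, params: ModelParameters):
    """Virulence alpha_P(beta_P) on the power-law trade-off (vectorized)."""
    beta = np.asarray(beta_P, dtype=float)
    if np.any(beta < 0):
        raise ValueError("beta_P must be >= 0")
    out = params.alpha_hat_P * (1.0 + beta ** params.d)
    return float(out) if np.isscalar(beta_P) else out


def coinfection_virulence(y: float, beta_P, params: ModelParameters):
    """Disease-induced mortality alpha_B(y, beta_P) of coinfected hosts.

    Equals alpha_D + alpha_P at y = 0 (additive harms) and alpha_D at
    y = 1 (parasite-induced mortality completely negated).
    """
    if not 0.0 <= y <= 1.0:
        raise ValueError(f"tolerance y must lie in [0, 1], got {y}")
    return params.alpha_D + (1.0 - y) * parasite_virulence(beta_P, params)


def birth_rate(N: float, params: ModelParameters) -> float:
    """Population birth rate nu(N) = N (a - q N), clamped at zero.

    The clamp keeps nu a pure birth process above the crowding density
    a/q; equilibria of interest sit below a/q so it never binds there.
    """
    if N < 0:
        raise ValueError(f"total density N must be >= 0, got {N}")
    return max(0.0, N * (params.a - params.q * N))


# --------------------------------------------------------------------------
# state containers


@dataclass
class MonomorphicState:
    """Densities of the four host classes for single resident strains."""

    H: float
    D: float
    P: float
    B: float

    @property
    def N(self) -> float:
        return self.H + self.D + self.P + self.B

    def as_array(self) -> np.ndarray:
        return np.array([self.H, self.D, self.P, self.B], dtype=float)


@dataclass
class PolymorphicState:
    """Host densities structured by resident strain combinations.

    ``D`` is indexed by symbiont strain j, ``P`` by parasite strain i and
    the coinfected matrix ``B`` by (parasite i, symbiont j).  Strain trait
    lists are kept strictly sorted ascending.
    """

    y_strains: np.ndarray
    beta_strains: np.ndarray
    H: float
    D: np.ndarray
    P: np.ndarray
    B: np.ndarray

    def __post_init__(self) -> None:
        self.y_strains = np.atleast_1d(np.asarray(self.y_strains, dtype=float))
        self.beta_strains = np.atleast_1d(np.asarray(self.beta_strains, dtype=float))
        self.D = np.atleast_1d(np.asarray(self.D, dtype=float))
        self.P = np.atleast_1d(np.asarray(self.P, dtype=float))
        self.B = np.asarray(self.B, dtype=float).reshape(len(self.beta_strains),
                                                         len(self.y_strains))
        if len(self.D) != len(self.y_strains):
            raise ValueError("D must have one entry per symbiont strain")
        if len(self.P) != len(self.beta_strains):
            raise ValueError("P must have one entry per parasite strain")
        for name, arr in (("y_strains", self.y_strains),
                          ("beta_strains", self.beta_strains)):
            if len(arr) > 1 and np.any(np.diff(arr) <= 0):
                raise ValueError(f"{name} must be strictly sorted ascending")

    # -- derived quantities -------------------------------------------------

    @property
    def n_symbiont(self) -> int:
        return len(self.y_strains)

    @property
    def n_parasite(self) -> int:
        return len(self.beta_strains)

    @property
    def N(self) -> float:
        return float(self.H + self.D.sum() + self.P.sum() + self.B.sum())

    def symbiont_totals(self) -> np.ndarray:
        """Hosts carrying symbiont strain j: D_j + sum_i B_ij."""
        return self.D + self.B.sum(axis=0)

    def parasite_totals(self) -> np.ndarray:
        """Hosts carrying parasite strain i: P_i + sum_j B_ij."""
        return self.P + self.B.sum(axis=1)

    def copy(self) -> "PolymorphicState":
        return PolymorphicState(self.y_strains.copy(), self.beta_strains.copy(),
                                float(self.H), self.D.copy(), self.P.copy(),
                                self.B.copy())

    def to_monomorphic(self) -> MonomorphicState:
        if self.n_symbiont != 1 or self.n_parasite != 1:
            raise ValueError("only single-strain states reduce to monomorphic")
        return MonomorphicState(float(self.H), float(self.D[0]),
                                float(self.P[0]), float(self.B[0, 0]))

    @classmethod
    def from_monomorphic(cls, state: MonomorphicState,
                         traits: ResidentTraits) -> "PolymorphicState":
        y = 0.0 if traits.y is None else traits.y
        return cls(np.array([y]), np.array([traits.beta_P]), state.H,
                   np.array([state.D]), np.array([state.P]),
                   np.array([[state.B]]))

    # -- flat packing for the integrator ------------------------------------

    def pack(self) -> np.ndarray:
        return np.concatenate(([self.H], self.D, self.P, self.B.ravel()))

    def unpack(self, x: np.ndarray) -> "PolymorphicState":
        nD, nP = self.n_symbiont, self.n_parasite
        return PolymorphicState(self.y_strains, self.beta_strains,
                                float(x[0]), x[1:1 + nD].copy(),
                                x[1 + nD:1 + nD + nP].copy(),
                                x[1 + nD + nP:].reshape(nP, nD).copy())


@dataclass
class EquilibriumResult:
    """Terminal state of an equilibrium search with its residual."""

    state: Union[MonomorphicState, PolymorphicState]
    residual: float
    converged: bool
    t_elapsed: float


# --------------------------------------------------------------------------
# right-hand sides


def ode_rhs_monomorphic(state: MonomorphicState, traits: ResidentTraits,
                        params: ModelParameters) -> np.ndarray:
    """Time derivatives (dH, dD, dP, dB) of the single-strain system."""
    H, D, P, B = state.H, state.D, state.P, state.B
    N = H + D + P + B
    y = 0.0 if traits.y is None else traits.y
    bD = symbiont_transmission(y, params)
    bP = traits.beta_P
    aP = parasite_virulence(bP, params)
    aB = coinfection_virulence(y, bP, params)
    p = params
    lamD = bD * (D + B)
    lamP = bP * (P + B)
    dH = birth_rate(N, p) - (p.b + lamD + lamP) * H + p.gamma_D * D + p.gamma_P * P
    dD = lamD * H - (p.b + p.gamma_D + p.alpha_D + lamP) * D + p.gamma_P * B
    dP = lamP * H - (p.b + p.gamma_P + aP + lamD) * P + p.gamma_D * B
    dB = lamD * P + lamP * D - (p.b + aB + p.gamma_D + p.gamma_P) * B
    return np.array([dH, dD, dP, dB])


class _PolyRates:
    """Pre-computed per-strain rates for a fixed strain configuration."""

    def __init__(self, y_strains: np.ndarray, beta_strains: np.ndarray,
                 params: ModelParameters):
        self.params = params
        self.nD = len(y_strains)
        self.nP = len(beta_strains)
        self.beta_D = np.array([symbiont_transmission(y, params)
                                for y in y_strains])
        self.beta_P = np.asarray(beta_strains, dtype=float)
        self.alpha_P = parasite_virulence(self.beta_P, params) \
            if self.nP else np.empty(0)
        # alpha_B[i, j] for parasite strain i in a host with symbiont strain j
        self.alpha_B = (params.alpha_D
                        + np.outer(self.alpha_P, 1.0 - np.asarray(y_strains)))

    def rhs(self, x: np.ndarray, t: float = 0.0) -> np.ndarray:
        p = self.params
        nD, nP = self.nD, self.nP
        H = x[0]
        D = x[1:1 + nD]
        P = x[1 + nD:1 + nD + nP]
        B = x[1 + nD + nP:].reshape(nP, nD)
        N = H + D.sum() + P.sum() + B.sum()
        lamD = self.beta_D * (D + B.sum(axis=0))     # per symbiont strain j
        lamP = self.beta_P * (P + B.sum(axis=1))     # per parasite strain i
        LD, LP = lamD.sum(), lamP.sum()
        nu = max(0.0, N * (p.a - p.q * N))
        dH = (nu - (p.b + LD + LP) * H + p.gamma_D * D.sum()
              + p.gamma_P * P.sum())
        dD = (lamD * H - (p.b + p.gamma_D + p.alpha_D + LP) * D
              + p.gamma_P * B.sum(axis=0))
        dP = (lamP * H - (p.b + p.gamma_P + self.alpha_P + LD) * P
              + p.gamma_D * B.sum(axis=1))
        dB = (np.outer(P, lamD) + np.outer(lamP, D)
              - (p.b + self.alpha_B + p.gamma_D + p.gamma_P) * B)
        return np.concatenate(([dH], dD, dP, dB.ravel()))


def ode_rhs_polymorphic(state: PolymorphicState,
                        params: ModelParameters) -> PolymorphicState:
    """Strain-structured time derivatives, returned in state layout.

    Each symbiont strain j infects H and every P_i host at force
    beta_D(y_j) (D_j + sum_i B_ij); each parasite strain i infects H and
    every D_j host at force beta_i (P_i + sum_j B_ij); a host carries at
    most one strain of each microbe.  Reduces exactly to the monomorphic
    system for singleton strain lists.
    """
    rates = _PolyRates(state.y_strains, state.beta_strains, params)
    dx = rates.rhs(state.pack())
    return state.unpack(dx)


# --------------------------------------------------------------------------
# equilibrium search


def _clamp(x: np.ndarray) -> np.ndarray:
    return np.where(x < 0.0, 0.0, x)


def solve_equilibrium(initial: Union[PolymorphicState, MonomorphicState],
                      params: ModelParameters,
                      traits: Optional[ResidentTraits] = None,
                      horizon: float = 400.0,
                      tol: float = 1e-9,
                      max_horizon: float = 1e6,
                      rtol: float = 1e-10,
                      atol: float = 1e-12) -> EquilibriumResult:
    """Relax the ecological ODEs to their stable endemic equilibrium.

    Integrates from ``initial`` over windows of doubling length; after
    each window a Newton polish of the algebraic steady-state system is
    attempted on the currently occupied compartments (extinct strains are
    held at zero), and accepted only if it stays non-negative, lands close
    to the integrated state and drives the residual below ``tol``.
    Non-convergence within ``max_horizon`` is flagged, never silent.

    A ``MonomorphicState`` input requires ``traits`` and returns a
    monomorphic state; a ``PolymorphicState`` carries its own traits.
    """
    mono = isinstance(initial, MonomorphicState)
    if mono:
        if traits is None:
            raise ValueError("monomorphic input requires resident traits")
        poly = PolymorphicState.from_monomorphic(initial, traits)
    else:
        poly = initial.copy()

    rates = _PolyRates(poly.y_strains, poly.beta_strains, params)
    x = _clamp(poly.pack())
    t_total = 0.0
    window = float(horizon)
    residual = float(np.max(np.abs(rates.rhs(x))))
    converged = residual <= tol

    while not converged and t_total < max_horizon:
        window = min(window, max_horizon - t_total)
        sol = odeint(rates.rhs, x, [0.0, window], rtol=rtol, atol=atol,
                     mxstep=100000)
        x = _clamp(sol[-1])
        t_total += window
        residual = float(np.max(np.abs(rates.rhs(x))))
        if residual <= tol:
            converged = True
            break
        # Newton polish restricted to the occupied support
        support = x > 0.0
        if support.any():
            def masked(z: np.ndarray) -> np.ndarray:
                full = np.zeros_like(x)
                full[support] = z
                return rates.rhs(full)[support]

            res = _scipy_root(masked, x[support], method="hybr", tol=1e-13)
            if res.success:
                cand = np.zeros_like(x)
                cand[support] = res.x
                near = np.max(np.abs(cand - x)) <= 0.05 * (1.0 + np.max(np.abs(x)))
                cand = _clamp(cand)
                cand_res = float(np.max(np.abs(rates.rhs(cand))))
                if near and cand_res <= tol:
                    x, residual, converged = cand, cand_res, True
                    break
        window *= 2.0

    out = poly.unpack(x)
    state: Union[MonomorphicState, PolymorphicState]
    state = out.to_monomorphic() if mono else out
    return EquilibriumResult(state=state, residual=residual,
                             converged=converged, t_elapsed=t_total)
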