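"""Evolutionary invasion analysis: fitness, gradients, singular strategies.

Invasion fitness of a rare mutant microbe is its reproduction ratio in
the resident population at its endemic equilibrium, obtained by the
next-generation method applied to the two-compartment rare-mutant
subsystem (singly infected + coinfected with the resident partner).  The
mutant invades when the fitness exceeds one.  Selection gradients are
computed by central finite differences of the fitness in the mutant
trait; singular strategies are their roots, classified by the standard
adaptive-dynamics taxonomy (CSS, branching point, repeller,
garden-of-eden, or boundary/runaway when no interior root exists).
"""

from __future__ import annotations

import math
from dataclasses import dataclass
from typing import Optional, Sequence, Tuple

import numpy as np
from scipy.optimize import brentq, root as _scipy_root

from .model_core import (
    EquilibriumResult,
    MonomorphicState,
    PolymorphicState,
    coinfection_virulence,
    parasite_virulence,
    solve_equilibrium,
    symbiont_transmission,
)
from .params import ModelParameters, ResidentTraits

__all__ = [
    "SingularStrategy",
    "PIPGrid",
    "resident_equilibrium",
    "invasion_fitness_symbiont",
    "invasion_fitness_parasite",
    "fitness_gradient",
    "find_singular_strategy",
    "symbiont_free_css",
    "coevolutionary_singular_point",
    "compute_pip",
    "mutant_jacobian",
]

# finite-difference steps, relative to max(|trait|, 0.1); the second-
# derivative step is coarser because the equilibrium residual (~1e-9)
# sets a noise floor
_H_GRAD = 1e-4
_H_CURV = 1e-2

Y_BOUNDS = (0.0, 1.0)


@dataclass
class SingularStrategy:
    """A singular trait value with stability classification.

    ``trait`` is y* or beta_P* (or the (y*, beta_P*) pair for
    coevolution); ``E`` is the second derivative of invasion fitness in
    the mutant trait (evolutionary stability when negative); ``C`` is the
    mixed mutant-resident second derivative used in the parasite
    convergence criterion; ``classification`` is one of ``css``,
    ``branching``, ``repeller``, ``garden_of_eden``, ``boundary_low``,
    ``boundary_high`` (runaway toward a bracket end).
    """

    trait: object
    gradient_residual: float
    E: Optional[float]
    C: Optional[float]
    classification: str
    convergence_stable: Optional[bool] = None


@dataclass
class PIPGrid:
    """Sign map of invasion fitness over (resident, mutant) trait pairs."""

    resident_axis: np.ndarray
    mutant_axis: np.ndarray
    sign_matrix: np.ndarray  # mutant rows x resident columns; 0 = neutral
    undefined_columns: list


# --------------------------------------------------------------------------
# resident equilibria


def resident_equilibrium(traits: ResidentTraits, params: ModelParameters,
                         symbiont: Optional[bool] = None,
                         parasite: bool = True,
                         initial: Optional[MonomorphicState] = None,
                         tol: float = 1e-9) -> EquilibriumResult:
    """Endemic equilibrium of the monomorphic resident system.

    The symbiont is included when ``traits.y`` is not None (override with
    ``symbiont``); seeding densities are immaterial because the endemic
    equilibrium is unique and locally stable.
    """
    if symbiont is None:
        symbiont = traits.symbiont_present
    if initial is None:
        H0 = 0.5 * (params.a - params.b) / params.q
        D0 = 0.1 if symbiont else 0.0
        P0 = 0.1 if parasite else 0.0
        B0 = 0.01 if (symbiont and parasite) else 0.0
        initial = MonomorphicState(H=H0, D=D0, P=P0, B=B0)
    return solve_equilibrium(initial, params, traits=traits, tol=tol)


def _eq_densities(eq: EquilibriumResult) -> Tuple[float, float, float, float]:
    s = eq.state
    if isinstance(s, PolymorphicState):
        s = s.to_monomorphic()
    return s.H, s.D, s.P, s.B


def _require_converged(eq: EquilibriumResult) -> None:
    if not eq.converged:
        raise RuntimeError(
            "resident equilibrium did not converge "
            f"(residual={eq.residual:.3e} after t={eq.t_elapsed:.0f}); "
            "refusing to evaluate invasion fitness on it")


# --------------------------------------------------------------------------
# invasion fitness


def invasion_fitness_symbiont(y_m: float, resident: ResidentTraits,
                              eq: EquilibriumResult,
                              params: ModelParameters) -> float:
    """Reproduction ratio of a rare symbiont mutant with tolerance y_m."""
    _require_converged(eq)
    H, _D, P, B = _eq_densities(eq)
    p = params
    lamP = resident.beta_P * (P + B)
    bD_m = symbiont_transmission(y_m, p)
    aB_m = coinfection_virulence(y_m, resident.beta_P, p)
    num = bD_m * (H * (p.b + p.gamma_D + p.gamma_P + aB_m + lamP)
                  + P * (p.b + p.gamma_D + p.gamma_P + p.alpha_D + lamP))
    den = ((p.b + p.gamma_D + p.alpha_D + lamP)
           * (p.b + aB_m + p.gamma_D + p.gamma_P)
           - p.gamma_P * lamP)
    return num / den


def invasion_fitness_parasite(beta_m: float, resident: ResidentTraits,
                              eq: EquilibriumResult,
                              params: ModelParameters) -> float:
    """Reproduction ratio of a rare parasite mutant with transmission beta_m."""
    _require_converged(eq)
    H, D, _P, B = _eq_densities(eq)
    p = params
    y_r = 0.0 if resident.y is None else resident.y
    lamD = symbiont_transmission(y_r, p) * (D + B)
    aP_m = parasite_virulence(beta_m, p)
    aB_m = coinfection_virulence(y_r, beta_m, p)
    num = beta_m * (H * (p.b + p.gamma_D + p.gamma_P + aB_m + lamD)
                    + D * (p.b + p.gamma_D + p.gamma_P + aP_m + lamD))
    den = ((p.b + p.gamma_P + aP_m + lamD)
           * (p.b + aB_m + p.gamma_D + p.gamma_P)
           - p.gamma_D * lamD)
    return num / den


def mutant_jacobian(which: str, mutant_trait: float, resident: ResidentTraits,
                    eq: EquilibriumResult, params: ModelParameters) -> np.ndarray:
    """2x2 Jacobian of the rare-mutant (singly infected, coinfected)
    subsystem linearized at the resident equilibrium.

    Serves as the independent oracle for the invasion-fitness sign: the
    mutant invades iff the dominant eigenvalue is positive.
    """
    _require_converged(eq)
    H, D, P, B = _eq_densities(eq)
    p = params
    y_r = 0.0 if resident.y is None else resident.y
    if which == "symbiont":
        lam = resident.beta_P * (P + B)
        bD_m = symbiont_transmission(mutant_trait, p)
        aB_m = coinfection_virulence(mutant_trait, resident.beta_P, p)
        return np.array([
            [bD_m * H - (p.b + p.gamma_D + p.alpha_D + lam),
             bD_m * H + p.gamma_P],
            [bD_m * P + lam,
             bD_m * P - (p.b + aB_m + p.gamma_D + p.gamma_P)],
        ])
    if which == "parasite":
        lam = symbiont_transmission(y_r, p) * (D + B)
        aP_m = parasite_virulence(mutant_trait, p)
        aB_m = coinfection_virulence(y_r, mutant_trait, p)
        return np.array([
            [mutant_trait * H - (p.b + p.gamma_P + aP_m + lam),
             mutant_trait * H + p.gamma_D],
            [mutant_trait * D + lam,
             mutant_trait * D - (p.b + aB_m + p.gamma_D + p.gamma_P)],
        ])
    raise ValueError(f"which must be 'symbiont' or 'parasite', got {which!r}")


# --------------------------------------------------------------------------
# gradients and singular strategies


def _fitness_fn(which: str, resident: ResidentTraits, eq: EquilibriumResult,
                params: ModelParameters):
    if which == "symbiont":
        return lambda t: invasion_fitness_symbiont(t, resident, eq, params)
    if which == "parasite":
        return lambda t: invasion_fitness_parasite(t, resident, eq, params)
    raise ValueError(f"which must be 'symbiont' or 'parasite', got {which!r}")


def _trait_bounds(which: str) -> Tuple[float, Optional[float]]:
    return (0.0, 1.0) if which == "symbiont" else (0.0, None)


def fitness_gradient(which: str, resident: ResidentTraits,
                     params: ModelParameters,
                     eq: Optional[EquilibriumResult] = None) -> float:
    """Selection gradient: d(invasion fitness)/d(mutant trait) at the
    resident trait value.  Central differences in the interior, one-sided
    at trait boundaries.  A pre-computed resident equilibrium may be
    supplied to avoid re-solving."""
    if eq is None:
        eq = resident_equilibrium(resident, params)
    trait = resident.y if which == "symbiont" else resident.beta_P
    if trait is None:
        raise ValueError("symbiont gradient requires a resident tolerance")
    w = _fitness_fn(which, resident, eq, params)
    lo, hi = _trait_bounds(which)
    h = _H_GRAD * max(abs(trait), 0.1)
    if trait - h < lo:
        return (w(trait + h) - w(trait)) / h
    if hi is not None and trait + h > hi:
        return (w(trait) - w(trait - h)) / h
    return (w(trait + h) - w(trait - h)) / (2.0 * h)


def _curvature_E(which: str, trait: float, resident: ResidentTraits,
                 eq: EquilibriumResult, params: ModelParameters) -> float:
    """Second derivative of fitness in the mutant trait (ES criterion)."""
    w = _fitness_fn(which, resident, eq, params)
    lo, hi = _trait_bounds(which)
    h = _H_CURV * max(abs(trait), 0.1)
    if trait - h < lo:
        trait = lo + h
    if hi is not None and trait + h > hi:
        trait = hi - h
    return (w(trait + h) - 2.0 * w(trait) + w(trait - h)) / h ** 2


def _with_trait(resident: ResidentTraits, which: str, value: float) -> ResidentTraits:
    if which == "symbiont":
        return ResidentTraits(y=value, beta_P=resident.beta_P)
    return ResidentTraits(y=resident.y, beta_P=value)


def _cross_C(which: str, trait: float, resident: ResidentTraits,
             params: ModelParameters) -> float:
    """Mixed partial d2 w / d(mutant trait) d(resident trait), by a 2x2
    stencil of full equilibrium solves."""
    h = _H_CURV * max(abs(trait), 0.1)
    vals = np.empty((2, 2))
    for k, sr in enumerate((+1.0, -1.0)):
        res_r = _with_trait(resident, which, trait + sr * h)
        eq_r = resident_equilibrium(res_r, params)
        w = _fitness_fn(which, res_r, eq_r, params)
        for l, sm in enumerate((+1.0, -1.0)):
            vals[k, l] = w(trait + sm * h)
    return (vals[0, 0] - vals[0, 1] - vals[1, 0] + vals[1, 1]) / (4.0 * h ** 2)


def _gradient_slope(which: str, trait: float, resident: ResidentTraits,
                    params: ModelParameters) -> float:
    """dF/d(resident trait) at the singular point (convergence check)."""
    h = _H_CURV * max(abs(trait), 0.1)
    lo, hi = _trait_bounds(which)
    t_hi = trait + h if (hi is None or trait + h <= hi) else hi
    t_lo = trait - h if trait - h >= lo else lo
    g_hi = fitness_gradient(which, _with_trait(resident, which, t_hi), params)
    g_lo = fitness_gradient(which, _with_trait(resident, which, t_lo), params)
    return (g_hi - g_lo) / (t_hi - t_lo)


def _classify(E: float, convergent: bool) -> str:
    if convergent:
        return "css" if E < 0 else "branching"
    return "garden_of_eden" if E < 0 else "repeller"


def find_singular_strategy(which: str, bracket: Tuple[float, float],
                           resident_other: Optional[float],
                           params: ModelParameters,
                           xtol: float = 1e-8,
                           n_scan: int = 8) -> SingularStrategy:
    """Root of the selection gradient within ``bracket``, with stability.

    ``resident_other`` fixes the non-focal trait (the tolerance y when
    solving for the parasite, the parasite transmission when solving for
    the symbiont; None means the other microbe is absent).  When the
    gradient has no sign change on the bracket a boundary/runaway report
    is returned carrying the gradient sign instead of a root.
    """

    def make_resident(t: float) -> ResidentTraits:
        if which == "parasite":
            return ResidentTraits(y=resident_other, beta_P=t)
        if resident_other is None:
            raise ValueError("symbiont singular strategy requires a parasite trait")
        return ResidentTraits(y=t, beta_P=resident_other)

    def grad(t: float) -> float:
        return fitness_gradient(which, make_resident(t), params)

    lo, hi = bracket
    ts = np.linspace(lo, hi, n_scan + 1)
    gs = [grad(t) for t in ts]
    idx = next((k for k in range(len(ts) - 1)
                if gs[k] == 0.0 or np.sign(gs[k]) != np.sign(gs[k + 1])), None)
    if idx is None:
        side = "boundary_high" if gs[-1] > 0 else "boundary_low"
        return SingularStrategy(trait=hi if gs[-1] > 0 else lo,
                                gradient_residual=float(min(abs(g) for g in gs)),
                                E=None, C=None, classification=side,
                                convergence_stable=None)
    t_star = brentq(grad, ts[idx], ts[idx + 1], xtol=xtol)
    res = make_resident(t_star)
    eq = resident_equilibrium(res, params)
    E = _curvature_E(which, t_star, res, eq, params)
    if which == "parasite":
        C = _cross_C(which, t_star, res, params)
    else:
        C = None
    convergent = _gradient_slope(which, t_star, res, params) < 0.0
    return SingularStrategy(trait=float(t_star),
                            gradient_residual=abs(grad(t_star)),
                            E=float(E), C=None if C is None else float(C),
                            classification=_classify(E, convergent),
                            convergence_stable=convergent)


def symbiont_free_css(params: ModelParameters) -> float:
    """Closed-form continuously stable parasite transmission in the
    absence of the defensive symbiont:
    ((b + gamma_P + alpha_hat_P) / (alpha_hat_P (d - 1)))**(1/d)."""
    if params.d <= 1.0:
        raise ValueError("closed-form CSS requires d > 1")
    return ((params.b + params.gamma_P + params.alpha_hat_P)
            / (params.alpha_hat_P * (params.d - 1.0))) ** (1.0 / params.d)


def coevolutionary_singular_point(params: ModelParameters,
                                  start: ResidentTraits,
                                  beta_max: float = 10.0,
                                  gtol: float = 1e-8) -> SingularStrategy:
    """Joint root of (F_D, F_P) with strong convergence stability.

    Strong convergence stability is assessed, under equal mutation rates
    in the two microbes, by requiring the symmetric part of the Jacobian
    of the selection-gradient vector at the singular point to be negative
    definite.  Evolutionary stability of each trait is checked by the
    corresponding second derivative of the invasion fitness.
    """
    if start.y is None:
        raise ValueError("coevolution requires a symbiont tolerance start value")

    def gvec(z: np.ndarray) -> np.ndarray:
        y = float(np.clip(z[0], 0.0, 1.0))
        beta = float(np.clip(z[1], 1e-6, beta_max))
        res = ResidentTraits(y=y, beta_P=beta)
        eq = resident_equilibrium(res, params)
        return np.array([fitness_gradient("symbiont", res, params, eq),
                         fitness_gradient("parasite", res, params, eq)])

    sol = _scipy_root(gvec, np.array([start.y, start.beta_P]), method="hybr",
                      tol=1e-11)
    z = sol.x
    gres = gvec(z)
    interior = (sol.success and 1e-3 < z[0] < 1.0 - 1e-3 and
                0.0 < z[1] < beta_max and np.max(np.abs(gres)) <= gtol)
    if not interior:
        return SingularStrategy(trait=(float(z[0]), float(z[1])),
                                gradient_residual=float(np.max(np.abs(gres))),
                                E=None, C=None, classification="boundary_or_runaway",
                                convergence_stable=None)
    y_s, b_s = float(z[0]), float(z[1])
    # Jacobian of the gradient vector in the resident traits
    J = np.empty((2, 2))
    for col, (dy, db) in enumerate(((1.0, 0.0), (0.0, 1.0))):
        h = _H_CURV * max(abs(y_s if col == 0 else b_s), 0.1)
        gp = gvec(np.array([y_s + dy * h, b_s + db * h]))
        gm = gvec(np.array([y_s - dy * h, b_s - db * h]))
        J[:, col] = (gp - gm) / (2.0 * h)
    sym_eigs = np.linalg.eigvalsh(0.5 * (J + J.T))
    strong = bool(np.all(sym_eigs < 0.0))
    res = ResidentTraits(y=y_s, beta_P=b_s)
    eq = resident_equilibrium(res, params)
    E_D = _curvature_E("symbiont", y_s, res, eq, params)
    E_P = _curvature_E("parasite", b_s, res, eq, params)
    E = max(E_D, E_P)  # evolutionarily stable only if both are negative
    classification = _classify(E, strong)
    out = SingularStrategy(trait=(y_s, b_s),
                           gradient_residual=float(np.max(np.abs(gres))),
                           E=float(E), C=None, classification=classification,
                           convergence_stable=strong)
    return out


# --------------------------------------------------------------------------
# pairwise invasion plots


def compute_pip(which: str, resident_grid: Sequence[float],
                mutant_grid: Sequence[float], other_trait: Optional[float],
                params: ModelParameters,
                neutral_tol: float = 1e-6) -> PIPGrid:
    """Sign matrix of (invasion fitness - 1) over a trait grid.

    One resident equilibrium solve is shared by all mutants in a column.
    Columns whose resident equilibrium lacks the focal microbe are
    recorded as undefined (entries 0).
    """
    residents = np.asarray(resident_grid, dtype=float)
    mutants = np.asarray(mutant_grid, dtype=float)
    sign = np.zeros((len(mutants), len(residents)), dtype=int)
    undefined = []
    for j, r in enumerate(residents):
        if which == "parasite":
            res = ResidentTraits(y=other_trait, beta_P=float(r))
        else:
            if other_trait is None:
                raise ValueError("symbiont PIP requires the parasite trait")
            res = ResidentTraits(y=float(r), beta_P=other_trait)
        eq = resident_equilibrium(res, params)
        H, D, P, B = _eq_densities(eq)
        focal_mass = (P + B) if which == "parasite" else (D + B)
        if focal_mass < 1e-8:
            undefined.append(j)
            continue
        w = _fitness_fn(which, res, eq, params)
        for i, m in enumerate(mutants):
            val = w(float(m)) - 1.0
            sign[i, j] = 0 if abs(val) <= neutral_tol else (1 if val > 0 else -1)
    return PIPGrid(resident_axis=residents, mutant_axis=mutants,
                   sign_matrix=sign, undefined_columns=undefined)
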