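"""Net host-impact measures and classification of coevolutionary regimes.

The impact of introducing the defensive symbiont is measured against the
symbiont-free baseline, evaluated once per parameter set at the
parasite's symbiont-free CSS: Q1 is the percentage change in equilibrium
host density, Q2 the percentage reduction in the average
disease-associated mortality rate.  Coevolutionary outcomes over the
cost plane (c1, c2) are classified by deterministic gradient-flow
integration of the two selection gradients under equal mutation rates,
with the stochastic trait-substitution simulation available as a
cross-check.
"""

from __future__ import annotations

from dataclasses import dataclass
from typing import Dict, Optional, Sequence, Tuple, Union

import numpy as np
import pandas as pd

from .invasion_analysis import (
    fitness_gradient,
    resident_equilibrium,
    symbiont_free_css,
)
from .model_core import (
    MonomorphicState,
    PolymorphicState,
    coinfection_virulence,
    parasite_virulence,
    solve_equilibrium,
)
from .params import ModelParameters, ResidentTraits

__all__ = [
    "OutcomeMeasures",
    "RegimeLabel",
    "average_mortality",
    "symbiont_free_baseline",
    "impact_measures",
    "gradient_flow",
    "classify_regime",
    "regime_map",
]


@dataclass
class OutcomeMeasures:
    """Host-impact summary relative to the symbiont-free baseline."""

    N_star: float
    N_tilde: float
    r_star: float
    r_tilde: float
    Q1: float  # percentage change in host population size
    Q2: float  # percentage reduction in disease-associated mortality


@dataclass
class RegimeLabel:
    """Coevolutionary outcome at one (c1, c2) cell.

    ``label`` is one of ``maximization``, ``minimization``, ``repeller``
    or ``interior_css``; ``evidence`` holds the endpoint (y, beta_P)
    pairs reached from the low and high initial protection levels.
    """

    label: str
    evidence: Dict[str, Tuple[float, float]]


def average_mortality(state: Union[MonomorphicState, PolymorphicState],
                      params: ModelParameters,
                      traits: Optional[ResidentTraits] = None) -> float:
    """Average disease-associated mortality rate of the population.

    r = (alpha_D * sum_j D_j + sum_i alpha_P(beta_i) P_i
         + sum_ij alpha_B(y_j, beta_i) B_ij) / N.
    A monomorphic state requires the resident traits to evaluate the
    trait-dependent virulences.
    """
    if isinstance(state, MonomorphicState):
        if traits is None:
            raise ValueError("monomorphic state requires resident traits")
        state = PolymorphicState.from_monomorphic(state, traits)
    N = state.N
    if N <= 0:
        raise ValueError("average mortality undefined for an empty population")
    aP = parasite_virulence(state.beta_strains, params) \
        if state.n_parasite else np.empty(0)
    aB = (params.alpha_D
          + np.outer(aP, 1.0 - state.y_strains)) if state.B.size else 0.0
    total = (params.alpha_D * state.D.sum()
             + float(np.dot(aP, state.P))
             + float(np.sum(aB * state.B)))
    return total / N


_baseline_cache: Dict[tuple, Tuple[float, float, float]] = {}


def symbiont_free_baseline(params: ModelParameters) -> Tuple[float, float, float]:
    """Baseline (N_tilde, r_tilde, beta_tilde) at the symbiont-free CSS.

    Cached per parameter set; raises if the parasite cannot persist
    there (the baseline is then undefined).
    """
    key = tuple(sorted(params.to_dict().items()))
    if key not in _baseline_cache:
        beta = symbiont_free_css(params)
        traits = ResidentTraits(y=None, beta_P=beta)
        eq = resident_equilibrium(traits, params)
        if not eq.converged:
            raise RuntimeError("symbiont-free baseline equilibrium did not converge")
        st = eq.state
        if st.P + st.B < 1e-8:
            raise ValueError("parasite extinct in the symbiont-free baseline; "
                             "impact measures are undefined")
        _baseline_cache[key] = (st.N, average_mortality(st, params, traits), beta)
    return _baseline_cache[key]


def impact_measures(target: Union[ResidentTraits, PolymorphicState],
                    params: ModelParameters,
                    relax: bool = True) -> OutcomeMeasures:
    """Q1/Q2 host-impact measures for a trait pair or an endpoint state.

    Q1 = 100 (N*/N_tilde - 1): percentage increase in host density.
    Q2 = 100 (1 - r*/r_tilde): percentage decrease in the average
    disease-associated mortality rate.
    """
    N_tilde, r_tilde, _ = symbiont_free_baseline(params)
    if isinstance(target, ResidentTraits):
        eq = resident_equilibrium(target, params)
        if not eq.converged:
            raise RuntimeError("resident equilibrium did not converge")
        N_star = eq.state.N
        r_star = average_mortality(eq.state, params, target)
    else:
        state = target
        if relax:
            eq = solve_equilibrium(state, params)
            state = eq.state
        N_star = state.N
        r_star = average_mortality(state, params)
    return OutcomeMeasures(N_star=N_star, N_tilde=N_tilde, r_star=r_star,
                           r_tilde=r_tilde,
                           Q1=100.0 * (N_star / N_tilde - 1.0),
                           Q2=100.0 * (1.0 - r_star / r_tilde))


# --------------------------------------------------------------------------
# gradient-flow classification


def gradient_flow(params: ModelParameters, y0: float, beta0: float,
                  max_steps: int = 600, trait_step: float = 0.02,
                  gtol: float = 1e-5, beta_max: float = 10.0,
                  ) -> Tuple[float, float, bool]:
    """Integrate dy/dtau = F_D, dbeta/dtau = F_P (equal mutation rates).

    Uses normalized Euler steps capped at ``trait_step`` trait units, so
    only the endpoint is meaningful (the flow's time parametrization is
    not); the step is halved whenever a gradient component flips sign
    (oscillation around an attracting singular point).  Traits are
    clipped to their domains; a component pinned at a boundary with an
    outward gradient exerts no further selection.  Returns
    (y_end, beta_end, converged).
    """
    y, beta = float(y0), float(beta0)
    eq = None
    step = float(trait_step)
    prev = (0.0, 0.0)
    for _ in range(max_steps):
        res = ResidentTraits(y=y, beta_P=beta)
        init = eq.state if eq is not None and eq.converged else None
        eq = resident_equilibrium(res, params, initial=init)
        F_D = fitness_gradient("symbiont", res, params, eq)
        F_P = fitness_gradient("parasite", res, params, eq)
        # boundary-pinned components exert no further selection
        eff_D = 0.0 if ((y <= 0.0 and F_D < 0) or (y >= 1.0 and F_D > 0)) else F_D
        eff_P = 0.0 if ((beta <= 0.0 and F_P < 0)
                        or (beta >= beta_max and F_P > 0)) else F_P
        norm = max(abs(eff_D), abs(eff_P))
        if norm < gtol:
            return y, beta, True
        if eff_D * prev[0] < 0 or eff_P * prev[1] < 0:
            step *= 0.5
            if step < 1e-3 * trait_step:
                # endpoint resolved to well below one step of the flow
                return y, beta, True
        prev = (eff_D, eff_P)
        dt = step / norm
        y = float(np.clip(y + dt * eff_D, 0.0, 1.0))
        beta = float(np.clip(beta + dt * eff_P, 0.0, beta_max))
    return y, beta, False


def classify_regime(c1: float, c2: float, params: ModelParameters,
                    low_start: float = 0.05, high_start: float = 0.95,
                    boundary_band: float = 0.02,
                    divergence_tol: float = 0.05,
                    **flow_kwargs) -> RegimeLabel:
    """Classify the symbiont's coevolutionary outcome at one cost pair.

    Two gradient flows start from low and high initial protection, both
    with the parasite at its symbiont-free CSS.  Endpoints within
    ``boundary_band`` of 0 or 1 count as boundary outcomes.
    """
    if low_start >= high_start:
        raise ValueError("low_start must be below high_start")
    p = params.with_updates(c1=c1, c2=c2)
    beta0 = symbiont_free_css(p)
    y_lo, b_lo, ok_lo = gradient_flow(p, low_start, beta0, **flow_kwargs)
    y_hi, b_hi, ok_hi = gradient_flow(p, high_start, beta0, **flow_kwargs)
    evidence = {"low_start": (y_lo, b_lo), "high_start": (y_hi, b_hi),
                "converged": (ok_lo, ok_hi)}
    if abs(y_lo - y_hi) > divergence_tol:
        label = "repeller"
    elif 0.5 * (y_lo + y_hi) >= 1.0 - boundary_band:
        label = "maximization"
    elif 0.5 * (y_lo + y_hi) <= boundary_band:
        label = "minimization"
    else:
        label = "interior_css"
    return RegimeLabel(label=label, evidence=evidence)


def regime_map(c1_grid: Sequence[float], c2_grid: Sequence[float],
               params: ModelParameters, **kwargs) -> pd.DataFrame:
    """Classify every (c1, c2) cell; failures are recorded, not raised.

    Returns a long-format frame with one row per cell: the label, the
    endpoint (y, beta_P) from each start, and Q1/Q2 at the low-start
    endpoint.  The parasite always tends to a CSS (or runs away), so no
    separate parasite column is reported beyond its endpoint value.
    """
    rows = []
    for c1 in c1_grid:
        for c2 in c2_grid:
            row = {"c1": c1, "c2": c2}
            try:
                lab = classify_regime(c1, c2, params, **kwargs)
                y_lo, b_lo = lab.evidence["low_start"]
                y_hi, b_hi = lab.evidence["high_start"]
                p = params.with_updates(c1=c1, c2=c2)
                m = impact_measures(ResidentTraits(y=y_lo, beta_P=b_lo), p)
                row.update(label=lab.label, endpoint_y_low=y_lo,
                           endpoint_beta_low=b_lo, endpoint_y_high=y_hi,
                           endpoint_beta_high=b_hi, Q1=m.Q1, Q2=m.Q2)
            except Exception as exc:  # pragma: no cover - defensive
                row.update(label=f"error: {exc}", endpoint_y_low=np.nan,
                           endpoint_beta_low=np.nan, endpoint_y_high=np.nan,
                           endpoint_beta_high=np.nan, Q1=np.nan, Q2=np.nan)
            rows.append(row)
    return pd.DataFrame(rows)
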