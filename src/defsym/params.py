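"""Model parameters and resident trait containers.

The model describes a well-mixed host population co-circulating two
horizontally transmitted microbes: an obligate parasite that raises host
mortality, and a defensive symbiont that can confer *mortality tolerance*
(a reduction of disease-induced death) to coinfected hosts at a cost to
its own transmissibility.  All rates are per unit time; densities are in
arbitrary host-density units.
"""

from __future__ import annotations

from dataclasses import dataclass, field, fields, replace
from typing import Mapping, Optional

__all__ = ["ModelParameters", "ResidentTraits", "DEFAULT_PARAMETERS"]


@dataclass(frozen=True)
class ModelParameters:
    """Rate constants and trade-off parameters of the coinfection model.

    Attributes
    ----------
    a : float
        Maximum per-capita host birth rate.
    q : float
        Strength of density-dependent competition on host reproduction;
        births occur at rate ``N (a - q N)``.
    b : float
        Natural (background) host mortality rate.
    beta_hat_D : float
        Transmission coefficient of a defensive symbiont conferring no
        protection (zero cost).
    gamma_D : float
        Host clearance (recovery) rate for the defensive symbiont.
    alpha_D : float
        Additional host mortality induced by carrying the symbiont.
    alpha_hat_P : float
        Virulence of a parasite that cannot transmit (trade-off intercept).
    d : float
        Exponent of the power-law transmission-virulence trade-off,
        ``alpha_P(beta) = alpha_hat_P (1 + beta**d)``; requires ``d > 1``
        for diminishing returns.
    gamma_P : float
        Host clearance rate for the parasite.
    c1 : float
        Strength of the symbiont's protection cost, in ``[0, 1]``: the
        fractional reduction in symbiont transmissibility at full
        tolerance ``y = 1``.
    c2 : float
        Shape of the protection cost: positive values give accelerating
        costs, negative values decelerating costs, zero is linear.
    """

    a: float = 1.0
    q: float = 0.25
    b: float = 0.25
    beta_hat_D: float = 2.0
    gamma_D: float = 0.05
    alpha_D: float = 0.1
    alpha_hat_P: float = 0.1
    d: float = 2.0
    gamma_P: float = 0.05
    c1: float = 0.25
    c2: float = 2.0

    def __post_init__(self) -> None:
        for name in ("a", "q", "b", "beta_hat_D", "gamma_D", "alpha_D",
                     "alpha_hat_P", "gamma_P"):
            if getattr(self, name) < 0:
                raise ValueError(f"parameter {name!r} must be >= 0, got "
                                 f"{getattr(self, name)}")
        if not 0.0 <= self.c1 <= 1.0:
            raise ValueError(f"c1 must lie in [0, 1], got {self.c1}")
        if self.d <= 1.0:
            raise ValueError(f"d must exceed 1 (diminishing returns), got {self.d}")
        if self.a <= self.b:
            raise ValueError(
                f"a must exceed b for a viable host population (a={self.a}, b={self.b})")

    def with_updates(self, **kwargs: float) -> "ModelParameters":
        """Return a copy with the given fields replaced (re-validated)."""
        return replace(self, **kwargs)

    def to_dict(self) -> dict:
        return {f.name: getattr(self, f.name) for f in fields(self)}

    @classmethod
    def from_mapping(cls, mapping: Mapping[str, float]) -> "ModelParameters":
        known = {f.name for f in fields(cls)}
        unknown = sorted(set(mapping) - known)
        if unknown:
            raise ValueError(f"unknown parameter keys: {', '.join(unknown)}")
        return cls(**dict(mapping))


DEFAULT_PARAMETERS = ModelParameters()


@dataclass(frozen=True)
class ResidentTraits:
    """Resident trait pair: symbiont tolerance and parasite transmission.

    ``y`` is the level of tolerance conferred to coinfected hosts
    (dimensionless, in ``[0, 1]``); ``y = None`` denotes a system in which
    the defensive symbiont is absent.  ``beta_P`` is the parasite's
    transmission coefficient (>= 0).
    """

    y: Optional[float]
    beta_P: float

    def __post_init__(self) -> None:
        if self.y is not None and not 0.0 <= self.y <= 1.0:
            raise ValueError(f"tolerance y must lie in [0, 1], got {self.y}")
        if self.beta_P < 0:
            raise ValueError(f"beta_P must be >= 0, got {self.beta_P}")

    @property
    def symbiont_present(self) -> bool:
        return self.y is not None
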