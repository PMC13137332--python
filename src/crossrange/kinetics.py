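"""Reaction and growth kinetics for a two-strain detoxifier/consumer consortium.

The consortium degrades a toxic substrate in two sequential steps: the
*detoxifier* converts the substrate S (e.g. salicylate) into an intermediate I
(e.g. catechol); the *consumer* converts I into a diffusible final product P
(e.g. pyruvate / acetyl-CoA) that supports the growth of both strains.

Both conversion reactions follow Michaelis-Menten kinetics,

    nu_S = kcat1 * S / (K1 + S)        (detoxifier, per unit biomass)
    nu_I = kcat2 * I / (K2 + I)        (consumer,   per unit biomass)

where ``kcat`` is the catalytic capacity of a cell, the product of the
specific reaction rate and the (constant) enzyme level.  Growth is Monod in
the product concentration, multiplied by a Hill-type inhibition factor that
models substrate toxicity, minus a constant maintenance rate d:

    g = kg * P / (Kg + P) * 1 / (1 + (theta * S)^n) - d

with Hill exponent n = 3 by default.  All functions here are deterministic,
pure, and accept scalars or numpy arrays; negative concentrations are
contract violations and raise ``ValueError`` rather than being clamped, so
that solver bugs surface instead of being silently masked.

Units: concentrations in C-mM (millimolar carbon), rates in 1/h, catalytic
capacities in C-mM per hour per unit biomass (voxel volume folded in).
"""

from __future__ import annotations

from dataclasses import dataclass
from enum import IntEnum

import numpy as np

__all__ = [
    "Species",
    "SpeciesParams",
    "ToxicityParams",
    "substrate_conversion_rate",
    "intermediate_conversion_rate",
    "toxicity_factor",
    "specific_growth_rate",
]


class Species(IntEnum):
    """Strain identity within the consortium."""

    DETOXIFIER = 0
    CONSUMER = 1


def _check_nonnegative(value, name: str):
    arr = np.asarray(value, dtype=float)
    if np.any(arr < 0):
        raise ValueError(f"{name} must be non-negative, got {value!r}")
    return arr


@dataclass(frozen=True)
class SpeciesParams:
    """Per-strain kinetic constants.

    Parameters
    ----------
    species_id
        Which strain these constants describe.  The detoxifier's catalytic
        capacity acts on the substrate S only; the consumer's on the
        intermediate I only.
    catalytic_capacity
        Maximum conversion rate k*E (C-mM / h per unit biomass).  Enzyme
        level E is folded in because expression is held constant.
    half_saturation_K
        Michaelis constant of the conversion reaction (C-mM).
    max_growth_kg
        Maximum specific growth rate (1/h).
    growth_half_sat_Kg
        Monod half-saturation concentration of the product P (C-mM).
    maintenance_d
        Constant specific biomass loss rate (1/h), subtracted from growth.
    yield_biomass_per_product
        Biomass produced per unit of product carbon consumed
        (biomass units per C-mM * voxel volume).
    product_per_intermediate
        Stoichiometric yield of product per intermediate converted
        (consumer only; ignored for the detoxifier).
    """

    species_id: Species
    catalytic_capacity: float
    half_saturation_K: float
    max_growth_kg: float
    growth_half_sat_Kg: float
    maintenance_d: float
    yield_biomass_per_product: float
    product_per_intermediate: float = 1.0

    def __post_init__(self):
        for name in (
            "catalytic_capacity",
            "half_saturation_K",
            "max_growth_kg",
            "growth_half_sat_Kg",
            "maintenance_d",
            "yield_biomass_per_product",
            "product_per_intermediate",
        ):
            if getattr(self, name) < 0:
                raise ValueError(f"SpeciesParams.{name} must be >= 0")
        object.__setattr__(self, "species_id", Species(self.species_id))


@dataclass(frozen=True)
class ToxicityParams:
    """Hill-type substrate toxicity: growth is multiplied by 1/(1+(theta*S)^n).

    ``theta`` (1 / C-mM) sets the substrate concentration scale at which
    growth is half-inhibited (S = 1/theta); ``hill_exponent`` sets the
    steepness (default 3).  theta = 0 disables toxicity.
    """

    theta: float = 0.0
    hill_exponent: int = 3

    def __post_init__(self):
        if self.theta < 0:
            raise ValueError("theta must be >= 0")
        if self.hill_exponent < 1:
            raise ValueError("hill_exponent must be >= 1")


def _michaelis_menten(conc, vmax: float, K: float):
    conc = np.asarray(conc, dtype=float)
    return vmax * conc / (K + conc)


def substrate_conversion_rate(S_local, detox: SpeciesParams):
    """Detoxifier substrate conversion rate nu_S = kcat1 * S / (K1 + S).

    Returns the per-unit-biomass conversion rate (C-mM / h) at local
    substrate concentration ``S_local``.
    """
    if detox.species_id is not Species.DETOXIFIER:
        raise ValueError("substrate conversion requires detoxifier parameters")
    S = _check_nonnegative(S_local, "S_local")
    out = _michaelis_menten(S, detox.catalytic_capacity, detox.half_saturation_K)
    return out if out.ndim else float(out)


def intermediate_conversion_rate(I_local, cons: SpeciesParams):
    """Consumer intermediate conversion rate nu_I = kcat2 * I / (K2 + I)."""
    if cons.species_id is not Species.CONSUMER:
        raise ValueError("intermediate conversion requires consumer parameters")
    I = _check_nonnegative(I_local, "I_local")
    out = _michaelis_menten(I, cons.catalytic_capacity, cons.half_saturation_K)
    return out if out.ndim else float(out)


def toxicity_factor(S_local, tox: ToxicityParams):
    """Hill inhibition factor 1 / (1 + (theta * S)^n), in (0, 1].

    Equals 1 when theta = 0 or S = 0 and decreases strictly with S for
    theta > 0.
    """
    S = _check_nonnegative(S_local, "S_local")
    out = 1.0 / (1.0 + (tox.theta * S) ** tox.hill_exponent)
    return out if out.ndim else float(out)


def specific_growth_rate(P_local, S_local, sp: SpeciesParams, tox: ToxicityParams):
    """Net specific growth rate g = Monod(P) * toxicity(S) - d (1/h).

    May be negative (net biomass decay) when the product is scarce, the
    substrate is toxic, or both.  With theta = 0 this reduces exactly to the
    plain Monod form minus maintenance.
    """
    P = _check_nonnegative(P_local, "P_local")
    monod = _michaelis_menten(P, sp.max_growth_kg, sp.growth_half_sat_Kg)
    out = monod * toxicity_factor(S_local, tox) - sp.maintenance_d
    return out if np.ndim(out) else float(out)
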