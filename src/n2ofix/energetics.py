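"""Reaction energetics of the three N-acquisition pathways.

Gibbs free energies per mol NH3 produced for

    N2O fixation:     0.5 N2O + 1.5 H2O -> NH3 + O2
    N2 fixation:      0.5 N2  + 1.5 H2O -> NH3 + 0.75 O2
    NO3- assimilation: NO3- + 3 H+ + 2 e- -> NH3 + 1.5 O2

computed from standard formation free energies and enthalpies (bundled
table, see ``constants.yaml`` for sources), temperature-adjusted via
Gibbs--Helmholtz (constant-enthalpy approximation) and corrected for a
freshwater activity set (dissolved gases at ambient/incubation levels,
NH3 at the analytical detection limit, pH 7, electrons referenced to the
standard hydrogen electrode).

All three reactions are endergonic as written; the percentage *saving* of
one pathway over another is defined relative to the cheaper pathway, the
only convention under which fixing N2O instead of N2 saves ~18% while
assimilating NO3- instead saves ~21%.
"""

from __future__ import annotations

import math
from dataclasses import dataclass, field
from typing import Mapping

from .gases import load_constants

__all__ = [
    "ReactionEnergetics",
    "FreshwaterMedium",
    "StoichiometryError",
    "load_reaction",
    "delta_g",
    "energy_saving",
]

T_STANDARD_K = 298.15


class StoichiometryError(ValueError):
    """Reaction is not element- or charge-balanced."""


@dataclass(frozen=True)
class ReactionEnergetics:
    """One reaction, written per mol NH3: species -> signed stoichiometric
    coefficient (reactants negative)."""

    reaction_id: str
    stoichiometry: Mapping[str, float]

    def validate_balance(self) -> None:
        """Check element and charge balance against the bundled composition
        table; electrons count only toward charge."""
        elements = load_constants()["thermo_elements"]
        totals: dict[str, float] = {}
        for species, coeff in self.stoichiometry.items():
            if species not in elements:
                raise StoichiometryError(
                    f"unknown species {species!r} in reaction {self.reaction_id}"
                )
            for el, n in elements[species].items():
                totals[el] = totals.get(el, 0.0) + coeff * n
        unbalanced = {el: v for el, v in totals.items() if abs(v) > 1e-9}
        if unbalanced:
            raise StoichiometryError(
                f"reaction {self.reaction_id} is not balanced: {unbalanced}"
            )


@dataclass
class FreshwaterMedium:
    """Temperature and activity set used for the RT ln Q correction.

    Activities are mol/L (H+ as 10^-pH); species absent from the mapping
    are taken at unit activity (water, standard states).
    """

    temperature_C: float = 10.0
    activities: dict[str, float] = field(default_factory=dict)

    @classmethod
    def default(cls) -> "FreshwaterMedium":
        block = load_constants()["freshwater_medium"]
        return cls(
            temperature_C=float(block["temperature_C"]),
            activities={k: float(v) for k, v in block["activities"].items()},
        )


def load_reaction(reaction_id: str) -> ReactionEnergetics:
    """Load one of the bundled reactions (N2O-fix, N2-fix, NO3-assim)."""
    reactions = load_constants()["reactions"]
    if reaction_id not in reactions:
        raise KeyError(
            f"unknown reaction {reaction_id!r}; available: {sorted(reactions)}"
        )
    return ReactionEnergetics(
        reaction_id=reaction_id,
        stoichiometry=dict(reactions[reaction_id]["stoichiometry"]),
    )


def delta_g(
    reaction: ReactionEnergetics,
    temperature_C: float | None = None,
    medium: FreshwaterMedium | None = None,
    *,
    standard_state: bool = False,
) -> float:
    """Gibbs free energy of the reaction, kJ per mol NH3.

    dG(T) is obtained from the 298.15 K formation values by Gibbs--Helmholtz
    with constant reaction enthalpy, then corrected by RT ln Q using the
    medium's activities (skipped entirely with ``standard_state=True``).
    """
    reaction.validate_balance()
    consts = load_constants()
    species_table = consts["thermo_species"]
    if medium is None:
        medium = FreshwaterMedium.default()
    if temperature_C is None:
        temperature_C = medium.temperature_C
    T = temperature_C + 273.15
    dg298 = 0.0
    dh = 0.0
    for species, coeff in reaction.stoichiometry.items():
        try:
            entry = species_table[species]
        except KeyError as exc:
            raise StoichiometryError(
                f"no thermodynamic data for species {species!r}"
            ) from exc
        dg298 += coeff * float(entry["dGf"])
        dh += coeff * float(entry["dHf"])
    dg_t = dh - (T / T_STANDARD_K) * (dh - dg298)
    if standard_state:
        return dg_t
    R = float(consts["gas_constant_kJ"])
    ln_q = 0.0
    for species, coeff in reaction.stoichiometry.items():
        a = medium.activities.get(species)
        if a is not None:
            if a <= 0:
                raise ValueError(f"activity of {species} must be positive")
            ln_q += coeff * math.log(a)
    return dg_t + R * T * ln_q


def energy_saving(dg_alternative: float, dg_reference: float) -> float:
    """Percentage energy saving of the alternative pathway over the reference.

    Defined relative to the *cheaper* (alternative) pathway:
    ``100 * (dG_ref - dG_alt) / dG_alt``.  Antisymmetric in sign under
    argument swap (a saving becomes a penalty).
    """
    if dg_alternative <= 0 or dg_reference <= 0:
        raise ValueError("both free energies must be positive (endergonic)")
    return 100.0 * (dg_reference - dg_alternative) / dg_alternative
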