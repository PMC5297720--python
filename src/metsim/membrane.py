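"""Current-coupled ion transport across the separation membrane.

The simplified flux model imposes charge neutrality: the total ionic charge
crossing the membrane per unit time equals the electrical current.  The
current is partitioned over the mobile ions by transport numbers computed
from their relative membrane permeabilities and solution conductivities
(concentration times limiting molar conductivity times |charge|).  Cations
are carried out of the anode, anions out of the cathode, matching the
direction of conventional current through the electrolyte.

Diffusive (non-migrative) crossover of neutral species is not modelled.
"""

from __future__ import annotations

from dataclasses import dataclass, field
from typing import Mapping

from .constants import F, SECONDS_PER_DAY
from .species import SpeciesDB

__all__ = ["MembraneSpec", "transport_numbers", "ion_fluxes"]

#: ions considered as charge carriers (those with tabulated conductivities)
DEFAULT_CARRIERS = ("h+", "oh-", "na+", "k+", "nh4+", "acetate", "butyrate",
                    "hco3-", "cl-", "clo4-", "clo3-", "clo2-", "clo-")


#: relative permeability of non-proton cations through a proton exchange
#: membrane (strong selectivity for H+/OH- over salt ions)
PEM_CO_ION_FACTOR = 1e-6


@dataclass
class MembraneSpec:
    """Ion-selective membrane: PEM, CEM, AEM or custom permeability map.

    Type rules: a CEM zeroes the permeability of all anions, an AEM of all
    cations; H+ and OH- are always permitted.  A PEM behaves as a CEM whose
    selectivity strongly favours H+/OH- over the other cations (factor
    ``PEM_CO_ION_FACTOR``).  ``permeability_overrides`` replaces the
    species-table default for individual ions.
    """

    type_name: str = "PEM"
    area: float = 1e-2        # m2 (not rate-limiting in this simplified flux)
    permeability_overrides: Mapping[str, float] = field(default_factory=dict)

    def __post_init__(self) -> None:
        if self.type_name not in ("PEM", "CEM", "AEM", "custom"):
            raise ValueError(f"unknown membrane type {self.type_name!r}")
        if any(p < 0 for p in self.permeability_overrides.values()):
            raise ValueError("permeabilities must be >= 0")

    def permeability(self, ion: str, db: SpeciesDB) -> float:
        p = self.permeability_overrides.get(ion, db[ion].membrane_permeability)
        if ion in ("h+", "oh-"):
            return p
        z = db[ion].charge
        if self.type_name in ("CEM", "PEM") and z < 0:
            return 0.0
        if self.type_name == "AEM" and z > 0:
            return 0.0
        if self.type_name == "PEM":
            return p * PEM_CO_ION_FACTOR
        return p


def transport_numbers(conc_source: Mapping[str, float], membrane: MembraneSpec,
                      db: SpeciesDB) -> dict[str, float]:
    """Fraction of the membrane current carried by each ion.

    t_i = P_i c_i lambda_i |z_i| / sum_k P_k c_k lambda_k |z_k|; the weights
    are equivalent conductances of the permeating ions at the source-side
    concentration.  Transport numbers sum to 1 exactly.
    """
    weights: dict[str, float] = {}
    for ion, c in conc_source.items():
        if ion not in db or c <= 0.0:
            continue
        sp = db[ion]
        if sp.charge == 0:
            continue
        w = membrane.permeability(ion, db) * c * sp.molar_conductivity * abs(sp.charge)
        if w > 0.0:
            weights[ion] = w
    total = sum(weights.values())
    if total <= 0.0:
        raise ValueError("no mobile charge carrier with positive conductance")
    return {ion: w / total for ion, w in weights.items()}


def ion_fluxes(I_total: float, t: Mapping[str, float],
               db: SpeciesDB) -> dict[str, float]:
    """Molar membrane fluxes, mol/day, positive anode -> cathode.

    flux_i = t_i I 86400 / (z_i F).  With conventional current flowing
    anode -> cathode through the electrolyte, cations (z > 0) move
    anode -> cathode (positive flux) and anions cathode -> anode (negative),
    and sum_i z_i F flux_i / 86400 = I exactly by construction.
    """
    if I_total == 0.0:
        return {ion: 0.0 for ion in t}
    return {ion: t_i * I_total * SECONDS_PER_DAY / (db[ion].charge * F)
            for ion, t_i in t.items()}
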