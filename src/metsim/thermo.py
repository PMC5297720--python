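"""Reaction Gibbs energies, Nernst potentials and thermodynamic rate gating.

Fermentative kinetics are multiplied by a feasibility factor that smoothly
switches a reaction off as its in-situ Gibbs energy approaches zero; electrode
half-reaction potentials come from the same Gibbs energies of formation, so
the whole thermodynamic layer runs off the packaged species table.
"""

from __future__ import annotations

import math
from dataclasses import dataclass, field
from fractions import Fraction
from typing import Mapping

from .constants import F, R, T_REF
from .species import ChemSpecies, SpeciesDB

__all__ = ["HalfReaction", "reaction_gibbs", "nernst_potential",
           "feasibility_factor", "CONC_FLOOR"]

#: concentration floor inside logarithms, mol/L (avoids -inf at washout)
CONC_FLOOR = 1e-12


def _activity(sp: ChemSpecies, conc: Mapping[str, float]) -> float:
    """Activity of a species: c/(1 mol/L) for solutes, 1 for water, biomass
    and electrons.  Gas species are passed as partial pressure in bar."""
    if sp.role in ("solvent", "biomass", "electron"):
        return 1.0
    if sp.name not in conc:
        raise KeyError(f"species {sp.name!r} missing from concentration map")
    return max(float(conc[sp.name]), CONC_FLOOR)


def reaction_gibbs(stoich: Mapping[str, float | Fraction],
                   conc: Mapping[str, float],
                   db: SpeciesDB, T: float = T_REF) -> float:
    """In-situ reaction Gibbs energy, kJ/mol of reaction extent.

    dGr = dG0r(T) + R T sum(nu_i ln a_i), products positive.  Electrons are
    assigned zero energy and unit activity (they appear in electrode columns).
    """
    dG0 = 0.0
    dH0: float | None = 0.0
    ln_q = 0.0
    for name, nu in stoich.items():
        sp = db[name]
        nu = float(nu)
        dG0 += nu * sp.dGf0
        dH0 = None if (dH0 is None or sp.dHf0 is None) else dH0 + nu * sp.dHf0
        a = _activity(sp, conc)
        if a != 1.0:
            ln_q += nu * math.log(a)
    if abs(T - T_REF) > 1e-9:
        if dH0 is None:
            raise ValueError("dHf0 required for all species when T != 298.15 K")
        dG0 = dH0 - T * (dH0 - dG0) / T_REF
    return dG0 + R * T * ln_q


@dataclass(frozen=True)
class HalfReaction:
    """An electrode half-reaction written as a reduction.

    ``stoich`` carries the solution species only (products positive); the
    ``n_electrons`` electrons consumed are implicit.  Charge balance requires
    sum(nu_i z_i) = -n_electrons.
    """

    name: str
    stoich: Mapping[str, Fraction]
    n_electrons: int
    _db: SpeciesDB = field(repr=False, hash=False, compare=False, default=None)

    def __post_init__(self) -> None:
        if self.n_electrons <= 0:
            raise ValueError(f"{self.name}: n_electrons must be > 0")
        db = self._db
        charge = sum(Fraction(nu) * db[nm].charge for nm, nu in self.stoich.items())
        if charge != -self.n_electrons:
            raise ValueError(
                f"{self.name}: charge imbalance {charge} != -{self.n_electrons}")
        for el in ("C", "H", "O", "N", "Cl", "Na", "K"):
            r = sum(Fraction(nu) * db[nm].element(el)
                    for nm, nu in self.stoich.items())
            if r != 0:
                raise ValueError(f"{self.name}: element {el} imbalance {r}")

    def standard_potential(self, T: float = T_REF) -> float:
        """E0 vs SHE at unit activities, V."""
        return nernst_potential(self, {}, self._db, T, _standard=True)


def nernst_potential(hr: HalfReaction, conc: Mapping[str, float],
                     db: SpeciesDB | None = None, T: float = T_REF,
                     _standard: bool = False) -> float:
    """Equilibrium (Nernst) potential of a half-reaction, V vs SHE.

    E = -dGr(reduction, electrons at zero energy) / (n F).
    """
    db = db if db is not None else hr._db
    if hr.n_electrons <= 0:
        raise ValueError("n_electrons must be positive")
    if _standard:
        conc = {nm: 1.0 for nm in hr.stoich}
    dG = reaction_gibbs(hr.stoich, conc, db, T)  # kJ/mol
    return -dG * 1000.0 / (hr.n_electrons * F)


def feasibility_factor(dGr: float, T: float = T_REF, dG_min: float = 0.0) -> float:
    """Thermodynamic feasibility switch in [0, 1].

    factor = max(0, 1 - exp((dGr + dG_min)/(R T))): ~1 when the reaction is
    deeply exergonic, 0 at and beyond dGr = -dG_min, smooth and monotone
    non-increasing in dGr (a hard on/off switch would make the ODE right-hand
    side discontinuous).  ``dG_min`` (kJ/mol) shifts the cut-off.
    """
    x = (dGr + dG_min) / (R * T)
    if x >= 0.0:
        return 0.0
    return min(1.0, 1.0 - math.exp(x))
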