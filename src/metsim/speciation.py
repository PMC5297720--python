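"""Acid-base speciation and pH from standard Gibbs energies only.

Every liquid phase is speciated algebraically at every instant: given the
total (analytical) concentration of each acid-base family plus the net charge
of the fully dissociated ("strong") ions, the free concentration of every
member species follows from chemical equilibrium once [H+] is known, and
[H+] itself is pinned by electroneutrality.  Because all equilibria involved
are proton exchanges, the whole problem reduces exactly to one scalar
equation in pH, which is solved by safeguarded Brent iteration and polished
by Newton steps.  Activity coefficients are unity (ideal dilute solution);
see the methods note.

Equilibrium constants are computed from standard Gibbs energies of formation
(and enthalpies of formation when T != 298.15 K, via Gibbs-Helmholtz).
"""

from __future__ import annotations

import math
from dataclasses import dataclass
from typing import Mapping, Sequence

import numpy as np
from scipy.optimize import brentq

from .constants import R, T_REF
from .species import ChemSpecies, SpeciesDB, load_species_db

__all__ = ["AcidBaseFamily", "SpeciationModel", "equilibrium_constant",
           "speciate", "SpeciationError", "default_families"]


class SpeciationError(RuntimeError):
    """Raised when the pH solve cannot be completed; carries the residual."""

    def __init__(self, message: str, residual: float | None = None):
        super().__init__(message)
        self.residual = residual


def _dG0_at_T(dG0: float, dH0: float | None, T: float, what: str) -> float:
    """Gibbs-Helmholtz correction of a standard reaction Gibbs energy."""
    if abs(T - T_REF) < 1e-9:
        return dG0
    if dH0 is None:
        raise ValueError(
            f"{what}: dHf0 required for temperature correction at T={T} K")
    return dH0 - T * (dH0 - dG0) / T_REF


def equilibrium_constant(stoich: Mapping[ChemSpecies, float], T: float = T_REF) -> float:
    """Thermodynamic equilibrium constant K = exp(-dG0r(T)/RT).

    ``stoich`` maps species to signed coefficients (products positive).
    """
    dG = 0.0
    dH: float | None = 0.0
    for sp, nu in stoich.items():
        dG += nu * sp.dGf0
        dH = None if (dH is None or sp.dHf0 is None) else dH + nu * sp.dHf0
    dG_T = _dG0_at_T(dG, dH, T, "equilibrium_constant")
    return math.exp(-dG_T / (R * T))


@dataclass(frozen=True)
class AcidBaseFamily:
    """An ordered conjugate acid-base series sharing one lumped total.

    ``members`` run from most to least protonated; consecutive members must
    differ by exactly one H and one unit of charge.  ``total_symbol`` names
    the state variable carrying the sum of all members (mol/L).
    """

    total_symbol: str
    members: tuple[ChemSpecies, ...]

    def __post_init__(self) -> None:
        if len(self.members) < 2:
            raise ValueError(f"{self.total_symbol}: need at least two members")
        for a, b in zip(self.members, self.members[1:]):
            if a.charge - b.charge != 1:
                raise ValueError(
                    f"{self.total_symbol}: {a.name}->{b.name} must lose one "
                    f"positive charge")
            self._water_coefficient(a, b)

    @staticmethod
    def _water_coefficient(a: ChemSpecies, b: ChemSpecies) -> int:
        """Waters consumed in ``a + n H2O -> b + H+`` (0 for plain acids,
        1 for hydration steps such as CO2 -> HCO3-); raises if the pair is
        not a single-proton step."""
        d = {el: b.element(el) - a.element(el)
             for el in set(a.elements) | set(b.elements)}
        d = {el: v for el, v in d.items() if v != 0}
        n_w = int(d.pop("O", 0))
        expect_h = 2 * n_w - 1
        if d.pop("H", 0) != expect_h or d:
            raise ValueError(
                f"{a.name}->{b.name} is not a one-proton (plus hydration "
                f"water) step")
        return n_w

    @property
    def reference_charge(self) -> int:
        """Charge of the fully deprotonated member."""
        return self.members[-1].charge

    def cumulative_Ka(self, proton: ChemSpecies, water: ChemSpecies,
                      T: float = T_REF) -> np.ndarray:
        """beta_i = product of the first i stepwise dissociation constants.

        Member i has free concentration proportional to beta_i / [H+]**i.
        """
        betas = [1.0]
        for acid, base in zip(self.members, self.members[1:]):
            # acid + n H2O -> base + H+ (n = 1 for hydration steps like CO2)
            n_w = self._water_coefficient(acid, base)
            stoich: dict[ChemSpecies, float] = {acid: -1.0, base: 1.0,
                                                proton: 1.0}
            if n_w:
                stoich[water] = stoich.get(water, 0.0) - n_w
            Ka = equilibrium_constant(stoich, T)
            betas.append(betas[-1] * Ka)
        return np.asarray(betas)


def default_families(db: SpeciesDB | None = None) -> list[AcidBaseFamily]:
    """The acid-base families used by both shipped case studies."""
    db = db or load_species_db()
    fam = [
        AcidBaseFamily("ac_T", (db["acetic_acid"], db["acetate"])),
        AcidBaseFamily("bu_T", (db["butyric_acid"], db["butyrate"])),
        AcidBaseFamily("ct_T", (db["co2_aq"], db["hco3-"], db["co3--"])),
        AcidBaseFamily("n_T", (db["nh4+"], db["nh3_aq"])),
        AcidBaseFamily("ocl_T", (db["hclo"], db["clo-"])),
    ]
    return fam


class SpeciationModel:
    """Compiled pH / speciation solver for a fixed set of families.

    The compiled form keeps per-family charge vectors and cumulative
    dissociation constants as arrays so a single solve costs a few dozen
    scalar function evaluations.
    """

    def __init__(self, families: Sequence[AcidBaseFamily],
                 db: SpeciesDB | None = None, T: float = T_REF):
        db = db or load_species_db()
        self.families = list(families)
        self.T = T
        self.Kw = equilibrium_constant(
            {db["h2o"]: -1.0, db["h+"]: 1.0, db["oh-"]: 1.0}, T)
        self._betas = [f.cumulative_Ka(db["h+"], db["h2o"], T)
                       for f in self.families]
        self._charges = [np.array([m.charge for m in f.members], float)
                         for f in self.families]
        self._index = {f.total_symbol: i for i, f in enumerate(self.families)}
        self._last_ph: float | None = None

    # -- core scalar function -------------------------------------------------
    def _family_alphas(self, h: float, i: int) -> np.ndarray:
        n = len(self._betas[i])
        w = self._betas[i] / h ** np.arange(n)
        return w / w.sum()

    def charge_residual(self, ph: float, totals: np.ndarray,
                        strong_charge: float) -> float:
        h = 10.0 ** (-ph)
        resid = h - self.Kw / h + strong_charge
        for i, T_i in enumerate(totals):
            if T_i != 0.0:
                resid += T_i * float(self._charges[i] @ self._family_alphas(h, i))
        return resid

    # -- public solves --------------------------------------------------------
    def solve_ph(self, totals: np.ndarray, strong_charge: float,
                 warm_start: float | None = None) -> float:
        """pH at which the liquid is electroneutral.

        ``totals`` is ordered as ``self.families``; ``strong_charge`` is the
        signed equivalents/L of all fully dissociated ions (and, in the
        reactor, the proton-inventory correction).
        """
        if np.any(totals < -1e-15):
            raise SpeciationError(f"negative family total: {totals}")
        totals = np.maximum(totals, 0.0)
        f = lambda ph: self.charge_residual(ph, totals, strong_charge)

        guess = warm_start if warm_start is not None else self._last_ph
        if guess is not None:
            # cheap local bracket around the previous solution
            lo, hi = guess - 0.05, guess + 0.05
            flo, fhi = f(lo), f(hi)
            if flo > 0.0 > fhi:
                ph = brentq(f, lo, hi, xtol=1e-13, rtol=8.9e-16)
                self._last_ph = ph
                return ph
        lo, hi = -2.0, 16.0
        flo, fhi = f(lo), f(hi)
        if not (flo > 0.0 > fhi):
            lo, hi = -6.0, 20.0
            flo, fhi = f(lo), f(hi)
            if not (flo > 0.0 > fhi):
                raise SpeciationError(
                    "charge balance has no root in pH [-6, 20]",
                    residual=min(abs(flo), abs(fhi)))
        ph = brentq(f, lo, hi, xtol=1e-13, rtol=8.9e-16)
        self._last_ph = ph
        return ph

    def free_concentrations(self, ph: float, totals: np.ndarray) -> dict[str, float]:
        """Free concentration of every family member plus H+/OH- at ``ph``."""
        h = 10.0 ** (-ph)
        out = {"h+": h, "oh-": self.Kw / h}
        for i, fam in enumerate(self.families):
            alphas = self._family_alphas(h, i)
            for m, a in zip(fam.members, alphas):
                out[m.name] = float(totals[i] * a)
        return out

    def totals_vector(self, totals: Mapping[str, float]) -> np.ndarray:
        vec = np.zeros(len(self.families))
        for sym, val in totals.items():
            if sym not in self._index:
                raise KeyError(f"unknown family total {sym!r}")
            vec[self._index[sym]] = val
        return vec


def speciate(totals: Mapping[str, float], fixed_ions: Mapping[str, float],
             T: float = T_REF, families: Sequence[AcidBaseFamily] | None = None,
             db: SpeciesDB | None = None) -> tuple[float, dict[str, float]]:
    """pH and full ionic speciation of an aqueous solution.

    Parameters
    ----------
    totals : analytical concentration per family total symbol, mol/L.
    fixed_ions : fully dissociated spectator ions (e.g. na+, cl-), mol/L.
    T : temperature, K.

    Returns ``(pH, concentrations)`` where concentrations include every
    family member, H+, OH- and the fixed ions.  The returned state satisfies
    the family equilibria and mass balances exactly (by construction) and the
    charge balance to < 1e-10 eq/L.
    """
    db = db or load_species_db()
    for sym, v in list(totals.items()) + list(fixed_ions.items()):
        if v < 0:
            raise SpeciationError(f"negative concentration for {sym}: {v}")
    model = SpeciationModel(families or default_families(db), db=db, T=T)
    strong = sum(db[name].charge * c for name, c in fixed_ions.items())
    vec = model.totals_vector(totals)
    ph = model.solve_ph(vec, strong)
    conc = model.free_concentrations(ph, vec)
    conc.update({k: float(v) for k, v in fixed_ions.items()})
    resid = model.charge_residual(ph, vec, strong)
    if abs(resid) > 1e-10:
        raise SpeciationError("charge balance not converged", residual=resid)
    return ph, conc
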