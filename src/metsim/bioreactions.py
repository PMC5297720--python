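"""Microbial functional groups, Petersen stoichiometry and kinetic rate laws.

Every reaction in the system is one column of a Petersen matrix whose rows
are the state variables of a chamber.  Columns are built and validated in
exact rational arithmetic: each one must conserve every element and charge
(counting the electron pseudo-species for electrode columns), which also
implies exact electron-equivalent (COD) bookkeeping.

Kinetics follow ADM1 conventions (Monod uptake, lower/upper pH inhibition,
first-order decay) with an additional thermodynamic feasibility factor that
switches fermentative reactions off as their in-situ Gibbs energy approaches
zero.
"""

from __future__ import annotations

from dataclasses import dataclass, field
from fractions import Fraction
from typing import Mapping, Sequence

import numpy as np

from .species import SpeciesDB, electron_equivalents
from .thermo import HalfReaction, feasibility_factor, reaction_gibbs
from .constants import T_REF

__all__ = [
    "MicrobialGroup", "ReactionSpec", "StoichiometryError", "balance_column",
    "heterotrophic_anabolism", "electrotrophic_anabolism", "ph_inhibition",
    "fermentative_rate", "decay_rate", "gas_transfer_rate", "build_matrix",
    "column_balance_residuals", "electron_balance",
]

_ELEMENTS = ("C", "H", "O", "N", "Cl", "Na", "K")

REACTION_KINDS = ("fermentative", "electrode_anodic", "electrode_cathodic",
                  "gas_transfer", "decay")


class StoichiometryError(ValueError):
    """An unbalanced Petersen column, naming the offending residuals."""


@dataclass
class MicrobialGroup:
    """One microbial functional group (ADM1-style parameters, molar basis).

    k_max   maximum specific substrate uptake, mol substrate / mol-C biomass / day
    K_S     half-saturation per substrate state symbol, mol/L
    pH_LL/pH_UL  lower/upper bounds of the ADM1 pH-inhibition window
    k_dec   first-order decay to inerts, 1/day
    f_an    fraction of substrate uptake routed to anabolism (mol basis)
    """

    name: str
    biomass_symbol: str
    k_max: float
    K_S: Mapping[str, float]
    pH_LL: float
    pH_UL: float
    k_dec: float = 0.02
    f_an: float = 0.05

    def __post_init__(self) -> None:
        if not self.pH_LL < self.pH_UL:
            raise ValueError(f"{self.name}: pH_LL must be < pH_UL")
        params = [self.k_max, self.k_dec, self.f_an, *self.K_S.values()]
        if any(p < 0 for p in params):
            raise ValueError(f"{self.name}: kinetic parameters must be >= 0")


@dataclass
class ReactionSpec:
    """One Petersen-matrix column.

    ``stoichiometry`` maps species names (database entries) to signed rational
    coefficients, normalised per mol of the primary substrate (or per mol of
    product for substrate-free columns such as H2 evolution).  Electrode
    columns include the electron pseudo-species ``e-``.
    """

    name: str
    kind: str
    stoichiometry: Mapping[str, Fraction]
    catalyst: MicrobialGroup | None = None
    substrates: Sequence[str] = ()
    half_reaction: HalfReaction | None = None
    catabolic: Mapping[str, Fraction] | None = None  # gating stoichiometry
    dG_min: float = 0.0

    def __post_init__(self) -> None:
        if self.kind not in REACTION_KINDS:
            raise ValueError(f"{self.name}: unknown reaction kind {self.kind!r}")
        if self.kind.startswith("electrode") and self.half_reaction is None:
            raise ValueError(f"{self.name}: electrode reactions need a half_reaction")

    @property
    def n_electrons(self) -> Fraction:
        """Signed electron coefficient of the column (positive = released)."""
        return Fraction(self.stoichiometry.get("e-", 0))


# ---------------------------------------------------------------------------
# exact balancing machinery
# ---------------------------------------------------------------------------

def column_balance_residuals(stoich: Mapping[str, Fraction],
                             db: SpeciesDB) -> dict[str, Fraction]:
    """Element and charge residuals of a column, exact rationals."""
    out: dict[str, Fraction] = {}
    for el in _ELEMENTS:
        r = sum((Fraction(nu) * db[nm].element(el) for nm, nu in stoich.items()),
                Fraction(0))
        if r != 0:
            out[el] = r
    zr = sum((Fraction(nu) * db[nm].charge for nm, nu in stoich.items()),
             Fraction(0))
    if zr != 0:
        out["charge"] = zr
    return out


def electron_balance(stoich: Mapping[str, Fraction], db: SpeciesDB) -> Fraction:
    """Net electron equivalents of a column (0 for any balanced column,
    since the electron pseudo-species carries 1 equivalent)."""
    return sum((Fraction(nu) * electron_equivalents(db[nm])
                for nm, nu in stoich.items()), Fraction(0))


def _solve_exact(A: list[list[Fraction]], b: list[Fraction]) -> list[Fraction]:
    """Gaussian elimination over the rationals; raises on singular or
    inconsistent systems."""
    n_eq, n_un = len(A), len(A[0])
    M = [row[:] + [b[i]] for i, row in enumerate(A)]
    piv_cols = []
    r = 0
    for c in range(n_un):
        piv = next((i for i in range(r, n_eq) if M[i][c] != 0), None)
        if piv is None:
            continue
        M[r], M[piv] = M[piv], M[r]
        M[r] = [v / M[r][c] for v in M[r]]
        for i in range(n_eq):
            if i != r and M[i][c] != 0:
                f = M[i][c]
                M[i] = [vi - f * vr for vi, vr in zip(M[i], M[r])]
        piv_cols.append(c)
        r += 1
        if r == n_eq:
            break
    for i in range(r, n_eq):
        if M[i][n_un] != 0:
            raise StoichiometryError("balance system inconsistent")
    if len(piv_cols) < n_un:
        raise StoichiometryError("balance system underdetermined")
    x = [Fraction(0)] * n_un
    for i, c in enumerate(piv_cols):
        x[c] = M[i][n_un]
    return x


def balance_column(fixed: Mapping[str, Fraction], free: Sequence[str],
                   db: SpeciesDB) -> dict[str, Fraction]:
    """Complete a column by solving exactly for the ``free`` species so that
    every element and charge balances.

    Raises :class:`StoichiometryError` if no exact completion exists.
    """
    rows: list[list[Fraction]] = []
    rhs: list[Fraction] = []
    for el in _ELEMENTS:
        rows.append([db[nm].element(el) for nm in free])
        rhs.append(-sum((Fraction(nu) * db[nm].element(el)
                         for nm, nu in fixed.items()), Fraction(0)))
    rows.append([Fraction(db[nm].charge) for nm in free])
    rhs.append(-sum((Fraction(nu) * db[nm].charge
                     for nm, nu in fixed.items()), Fraction(0)))
    # drop all-zero equations with zero rhs (elements absent everywhere)
    keep = [i for i, row in enumerate(rows) if any(v != 0 for v in row) or rhs[i] != 0]
    rows = [rows[i] for i in keep]
    rhs = [rhs[i] for i in keep]
    sol = _solve_exact(rows, rhs)
    out = {nm: Fraction(nu) for nm, nu in fixed.items()}
    for nm, nu in zip(free, sol):
        out[nm] = out.get(nm, Fraction(0)) + nu
    out = {nm: nu for nm, nu in out.items() if nu != 0}
    resid = column_balance_residuals(out, db)
    if resid:
        raise StoichiometryError(f"column does not balance: {resid}")
    return out


def heterotrophic_anabolism(substrate: str, db: SpeciesDB,
                            n_source: str = "nh4+") -> dict[str, Fraction]:
    """Biomass synthesis from one mol of an organic substrate.

    Free coefficients on the nitrogen source, biomass, CO2, water and H+
    close the balance exactly; the CO2 term shunts the redox mismatch between
    substrate and the lumped biomass composition CH1.8O0.5N0.2.
    """
    return balance_column({substrate: Fraction(-1)},
                          ["biomass", n_source, "co2_aq", "h2o", "h+"], db)


def electrotrophic_anabolism(db: SpeciesDB,
                             n_source: str = "nh4+") -> dict[str, Fraction]:
    """Biomass synthesis from CO2 with electrode electrons, per mol biomass-C."""
    return balance_column({"biomass": Fraction(1)},
                          ["co2_aq", n_source, "h2o", "h+", "e-"], db)


def combine(*parts: tuple[Fraction | int | float, Mapping[str, Fraction]]
            ) -> dict[str, Fraction]:
    """Exact linear combination of stoichiometries."""
    out: dict[str, Fraction] = {}
    for w, st in parts:
        w = Fraction(w) if not isinstance(w, Fraction) else w
        for nm, nu in st.items():
            out[nm] = out.get(nm, Fraction(0)) + w * Fraction(nu)
    return {nm: nu for nm, nu in out.items() if nu != 0}


# ---------------------------------------------------------------------------
# kinetic rate laws
# ---------------------------------------------------------------------------

def ph_inhibition(pH: float, pH_LL: float, pH_UL: float) -> float:
    """ADM1 lower/upper pH inhibition term.

    I = (1 + 2*10^(0.5 (pH_LL - pH_UL))) / (1 + 10^(pH - pH_UL) + 10^(pH_LL - pH))
    """
    num = 1.0 + 2.0 * 10.0 ** (0.5 * (pH_LL - pH_UL))
    den = 1.0 + 10.0 ** (pH - pH_UL) + 10.0 ** (pH_LL - pH)
    return num / den


def monod(S: float, K: float) -> float:
    S = max(S, 0.0)
    return S / (K + S) if K > 0 else (1.0 if S > 0 else 0.0)


def fermentative_rate(rx: ReactionSpec, totals: Mapping[str, float],
                      free: Mapping[str, float], X: float, pH: float,
                      db: SpeciesDB, T: float = T_REF) -> float:
    """Volumetric rate of a fermentative column, mol substrate / L / day.

    rate = k_max * X * prod_s Monod(S_s) * I_pH * f_thermo(dGr); the
    thermodynamic gate is evaluated on the catabolic stoichiometry at the
    in-situ free concentrations.
    """
    if rx.kind != "fermentative":
        raise ValueError(f"{rx.name} is not fermentative")
    g = rx.catalyst
    if X <= 0.0:
        return 0.0
    rate = g.k_max * X
    for s in rx.substrates:
        S = totals.get(s, free.get(s, 0.0))
        rate *= monod(S, g.K_S.get(s, 0.0))
    if rate == 0.0:
        return 0.0
    rate *= ph_inhibition(pH, g.pH_LL, g.pH_UL)
    gate_st = rx.catabolic if rx.catabolic is not None else rx.stoichiometry
    dG = reaction_gibbs(gate_st, free, db, T)
    rate *= feasibility_factor(dG, T, rx.dG_min)
    return max(rate, 0.0)


def decay_rate(group: MicrobialGroup, X: float) -> float:
    """First-order biomass decay into the inert pool, mol-C / L / day."""
    return max(group.k_dec * max(X, 0.0), 0.0)


def gas_transfer_rate(S_liq: float, p_gas: float, kla: float, K_H: float) -> float:
    """Liquid->gas transfer rate, mol / L_liq / day (positive = stripping).

    rate = kLa (S_liq - K_H p_gas), with K_H the Henry solubility in
    mol/L/bar.
    """
    return kla * (S_liq - K_H * p_gas)


# ---------------------------------------------------------------------------
# Petersen matrix assembly
# ---------------------------------------------------------------------------

def map_species_to_states(stoich: Mapping[str, Fraction], db: SpeciesDB,
                          family_of: Mapping[str, tuple[str, int]],
                          biomass_symbol: str | None,
                          ) -> dict[str, float]:
    """Project a species-level column onto chamber state variables.

    Family members collapse onto their lumped total; H+ / OH- and the bound
    protons of family members land on the proton-inventory state ``A``;
    water and electrons drop out (water is the solvent reservoir, electrons
    are booked as current).
    """
    out: dict[str, float] = {}

    def add(sym: str, v: float) -> None:
        if v != 0.0:
            out[sym] = out.get(sym, 0.0) + v

    for nm, nu in stoich.items():
        nu = float(nu)
        sp = db[nm]
        if nm == "h2o" or sp.role == "electron":
            continue
        if nm == "h+":
            add("A", nu)
            continue
        if nm == "oh-":
            add("A", -nu)
            continue
        if nm == "biomass":
            if biomass_symbol is None:
                raise StoichiometryError("biomass produced by a column with no catalyst")
            add(biomass_symbol, nu)
            continue
        if nm in family_of:
            total_symbol, z_ref = family_of[nm]
            add(total_symbol, nu)
            add("A", nu * (sp.charge - z_ref))
            continue
        add(nm, nu)
    return {k: v for k, v in out.items() if v != 0.0}


def build_matrix(reactions: Sequence[ReactionSpec], state_variables: Sequence[str],
                 db: SpeciesDB, family_of: Mapping[str, tuple[str, int]],
                 ) -> np.ndarray:
    """Assemble the m x p Petersen matrix over chamber state variables.

    Every column is validated in exact rational arithmetic before being
    projected: any element or charge residual raises a build-time error
    naming the residuals.
    """
    idx = {s: i for i, s in enumerate(state_variables)}
    M = np.zeros((len(state_variables), len(reactions)))
    for j, rx in enumerate(reactions):
        resid = column_balance_residuals(rx.stoichiometry, db)
        if resid:
            raise StoichiometryError(f"{rx.name}: unbalanced column {resid}")
        bio_sym = rx.catalyst.biomass_symbol if rx.catalyst else None
        proj = map_species_to_states(rx.stoichiometry, db, family_of, bio_sym)
        for sym, v in proj.items():
            if sym not in idx:
                raise StoichiometryError(
                    f"{rx.name}: species maps to undeclared state {sym!r}")
            M[idx[sym], j] = v
    return M
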