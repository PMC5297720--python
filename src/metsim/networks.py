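"""Reaction networks of the two shipped case studies.

Case A (MEC): anodic electroactive acetate and hydrogen oxidation compete
with butyrate fermentation and both methanogeneses; the cathode reduces
acetate and butyrate to ethanol and butanol both electroactively and
homogeneously (H2-driven), evolves hydrogen, and hosts the same fermentative
background.

Case B (MFC): anodic electroactive acetate oxidation with acetoclastic
methanogenesis; the biocathode reduces perchlorate to chloride in four
serial two-electron electrode reactions.

Every column couples an exactly balanced catabolic stoichiometry with an
exactly balanced anabolic one (fraction ``f_an`` of substrate uptake, or
``Y_ELECTROTROPHIC`` biomass-C per mol for CO2-fixing biocathode groups), so
the Petersen matrix conserves elements, charge and electron equivalents to
machine-exact rational arithmetic.
"""

from __future__ import annotations

from fractions import Fraction

from . import params
from .bioreactions import (MicrobialGroup, ReactionSpec, combine,
                           electrotrophic_anabolism, heterotrophic_anabolism)
from .electrical import ElectrodeReactionSpec
from .reactor import ChamberNetwork
from .species import SpeciesDB
from .thermo import HalfReaction

F1 = Fraction(1)


def make_group(name: str, suffix: str = "") -> MicrobialGroup:
    k_max, K_S, pH_LL, pH_UL, k_dec, f_an = params.GROUPS[name]
    full = f"{name}{suffix}"
    return MicrobialGroup(name=full, biomass_symbol=f"X_{full}", k_max=k_max,
                          K_S=dict(K_S), pH_LL=pH_LL, pH_UL=pH_UL,
                          k_dec=k_dec, f_an=f_an)


# ---------------------------------------------------------------------------
# catabolic stoichiometries (exact; validated at build time)
# ---------------------------------------------------------------------------

CATABOLIC = {
    # anode oxidations (electrons released)
    "ac_ox":   {"acetate": -F1, "h2o": -4 * F1, "hco3-": 2 * F1,
                "h+": 9 * F1, "e-": 8 * F1},
    "h2_ox":   {"h2_aq": -F1, "h+": 2 * F1, "e-": 2 * F1},
    # fermentative / methanogenic
    "bu_ferm": {"butyrate": -F1, "h2o": -2 * F1, "acetate": 2 * F1,
                "h+": F1, "h2_aq": 2 * F1},
    "ac_meth": {"acetate": -F1, "h2o": -F1, "ch4_aq": F1, "hco3-": F1},
    "h2_meth": {"h2_aq": -4 * F1, "hco3-": -F1, "h+": -F1, "ch4_aq": F1,
                "h2o": 3 * F1},
    # cathode reductions (electrons consumed)
    "ac_red":  {"acetate": -F1, "h+": -5 * F1, "e-": -4 * F1,
                "ethanol": F1, "h2o": F1},
    "bu_red":  {"butyrate": -F1, "h+": -5 * F1, "e-": -4 * F1,
                "butanol": F1, "h2o": F1},
    "h2_ev":   {"h+": -2 * F1, "e-": -2 * F1, "h2_aq": F1},
    # homogeneous hydrogenations
    "ac_h2":   {"acetate": -F1, "h2_aq": -2 * F1, "h+": -F1,
                "ethanol": F1, "h2o": F1},
    "bu_h2":   {"butyrate": -F1, "h2_aq": -2 * F1, "h+": -F1,
                "butanol": F1, "h2o": F1},
    # perchlorate chain, four serial 2-electron reductions
    "clo4_red": {"clo4-": -F1, "h+": -2 * F1, "e-": -2 * F1,
                 "clo3-": F1, "h2o": F1},
    "clo3_red": {"clo3-": -F1, "h+": -2 * F1, "e-": -2 * F1,
                 "clo2-": F1, "h2o": F1},
    "clo2_red": {"clo2-": -F1, "h+": -2 * F1, "e-": -2 * F1,
                 "clo-": F1, "h2o": F1},
    "clo_red":  {"clo-": -F1, "h+": -2 * F1, "e-": -2 * F1,
                 "cl-": F1, "h2o": F1},
}


def _half_reaction(name: str, db: SpeciesDB) -> HalfReaction:
    """Reduction-form half reaction of a catabolic electrode stoichiometry."""
    cat = CATABOLIC[name]
    n_e = cat["e-"]
    if n_e > 0:       # written as oxidation: reverse it
        stoich = {nm: -nu for nm, nu in cat.items() if nm != "e-"}
    else:
        stoich = {nm: nu for nm, nu in cat.items() if nm != "e-"}
    return HalfReaction(name=name, stoich=stoich, n_electrons=int(abs(n_e)),
                        _db=db)


def _ferm(name: str, cat_key: str, group: MicrobialGroup, substrates,
          db: SpeciesDB, gated: bool = True) -> ReactionSpec:
    cat = CATABOLIC[cat_key]
    f = Fraction(group.f_an)
    anab = heterotrophic_anabolism(substrates_species(substrates[0]), db)
    col = combine((1 - f, cat), (f, anab))
    return ReactionSpec(name=name, kind="fermentative", stoichiometry=col,
                        catalyst=group, substrates=list(substrates),
                        catabolic=cat if gated else None)


def _electrode(name: str, cat_key: str, group: MicrobialGroup, substrates,
               db: SpeciesDB, kind: str, growth: str = "hetero",
               ) -> ElectrodeReactionSpec:
    cat = CATABOLIC[cat_key]
    if growth == "hetero":
        f = Fraction(group.f_an)
        anab = heterotrophic_anabolism(substrates_species(substrates[0]), db)
        col = combine((1 - f, cat), (f, anab))
    else:  # electrotrophic: CO2 fixation with electrode electrons
        y = Fraction(params.Y_ELECTROTROPHIC)
        anab = electrotrophic_anabolism(db)
        col = combine((F1, cat), (y, anab))
    rx = ReactionSpec(name=name, kind=kind, stoichiometry=col,
                      catalyst=group, substrates=list(substrates),
                      half_reaction=_half_reaction(cat_key, db),
                      catabolic=cat)
    e = params.ELECTRODE
    kse = params.KSE_OVERRIDES.get(cat_key, e["KSE"])
    return ElectrodeReactionSpec(base=rx, KSE=kse, k_m=e["k_m"],
                                 area=e["area"], activation=e["activation"])


_SUBSTRATE_SPECIES = {"ac_T": "acetate", "bu_T": "butyrate", "h2_aq": "h2_aq",
                      "clo4-": "clo4-", "clo3-": "clo3-", "clo2-": "clo2-",
                      "ocl_T": "clo-"}


def substrates_species(total_symbol: str) -> str:
    """Free species used as the anabolic carbon/electron source for a
    substrate state symbol."""
    return _SUBSTRATE_SPECIES[total_symbol]


# ---------------------------------------------------------------------------
# chamber networks
# ---------------------------------------------------------------------------

def case_a_anode(db: SpeciesDB) -> ChamberNetwork:
    ea_ac = make_group("ea_ac_an")
    ea_h2 = make_group("ea_h2_an")
    ferm = make_group("ferm_bu", "_an")
    mac = make_group("meth_ac", "_an")
    mh2 = make_group("meth_h2", "_an")
    return ChamberNetwork(
        groups=[ea_ac, ea_h2, ferm, mac, mh2],
        fermentative=[
            _ferm("an_bu_ferm", "bu_ferm", ferm, ["bu_T"], db),
            _ferm("an_ac_meth", "ac_meth", mac, ["ac_T"], db),
            _ferm("an_h2_meth", "h2_meth", mh2, ["h2_aq"], db),
        ],
        electrode=[
            _electrode("an_ac_ox", "ac_ox", ea_ac, ["ac_T"], db,
                       "electrode_anodic"),
            _electrode("an_h2_ox", "h2_ox", ea_h2, ["h2_aq"], db,
                       "electrode_anodic"),
        ])


def case_a_cathode(db: SpeciesDB) -> ChamberNetwork:
    ea_ac = make_group("ea_ac_cat")
    ea_bu = make_group("ea_bu_cat")
    h2ev = make_group("ea_h2ev")
    rah = make_group("red_ac_h2")
    rbh = make_group("red_bu_h2")
    ferm = make_group("ferm_bu", "_cat")
    mac = make_group("meth_ac", "_cat")
    mh2 = make_group("meth_h2", "_cat")
    return ChamberNetwork(
        groups=[ea_ac, ea_bu, h2ev, rah, rbh, ferm, mac, mh2],
        fermentative=[
            _ferm("cat_ac_h2red", "ac_h2", rah, ["ac_T", "h2_aq"], db),
            _ferm("cat_bu_h2red", "bu_h2", rbh, ["bu_T", "h2_aq"], db),
            _ferm("cat_bu_ferm", "bu_ferm", ferm, ["bu_T"], db),
            _ferm("cat_ac_meth", "ac_meth", mac, ["ac_T"], db),
            _ferm("cat_h2_meth", "h2_meth", mh2, ["h2_aq"], db),
        ],
        electrode=[
            _electrode("cat_ac_red", "ac_red", ea_ac, ["ac_T"], db,
                       "electrode_cathodic"),
            _electrode("cat_bu_red", "bu_red", ea_bu, ["bu_T"], db,
                       "electrode_cathodic"),
            _electrode("cat_h2_ev", "h2_ev", h2ev, [], db,
                       "electrode_cathodic", growth="electro"),
        ])


def case_b_anode(db: SpeciesDB) -> ChamberNetwork:
    ea_ac = make_group("ea_ac_an")
    mac = make_group("meth_ac", "_an")
    return ChamberNetwork(
        groups=[ea_ac, mac],
        fermentative=[_ferm("an_ac_meth", "ac_meth", mac, ["ac_T"], db)],
        electrode=[_electrode("an_ac_ox", "ac_ox", ea_ac, ["ac_T"], db,
                              "electrode_anodic")])


def case_b_cathode(db: SpeciesDB) -> ChamberNetwork:
    prb = make_group("prb")
    steps = [("cat_clo4_red", "clo4_red", ["clo4-"]),
             ("cat_clo3_red", "clo3_red", ["clo3-"]),
             ("cat_clo2_red", "clo2_red", ["clo2-"]),
             ("cat_clo_red", "clo_red", ["ocl_T"])]
    return ChamberNetwork(
        groups=[prb],
        fermentative=[],
        electrode=[_electrode(nm, key, prb, subs, db, "electrode_cathodic",
                              growth="electro")
                   for nm, key, subs in steps])
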