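"""Petersen stoichiometry (exact balancing) and kinetic rate laws."""

from fractions import Fraction

import numpy as np
import pytest

from metsim import networks
from metsim.bioreactions import (MicrobialGroup, ReactionSpec,
                                 StoichiometryError, balance_column,
                                 build_matrix, column_balance_residuals,
                                 combine, decay_rate, electron_balance,
                                 electrotrophic_anabolism, fermentative_rate,
                                 gas_transfer_rate, heterotrophic_anabolism,
                                 map_species_to_states, monod, ph_inhibition)

F1 = Fraction(1)


# --- exact balancing -------------------------------------------------------

@pytest.mark.parametrize("key", sorted(networks.CATABOLIC))
def test_catabolic_stoichiometries_balance_exactly(db, key):
    st = networks.CATABOLIC[key]
    assert column_balance_residuals(st, db) == {}
    assert electron_balance(st, db) == 0


def test_acetoclastic_methanogenesis_element_counts(db):
    # CH3COO- + H2O -> CH4 + HCO3- balances C, H, O and charge by hand count
    st = {"acetate": -F1, "h2o": -F1, "ch4_aq": F1, "hco3-": F1}
    assert column_balance_residuals(st, db) == {}


def test_butyrate_fermentation_cod_arithmetic(db):
    """Butyrate (20 e-eq) -> 2 acetate (16) + 2 H2 (4)."""
    from metsim.species import electron_equivalents
    assert electron_equivalents(db["butyrate"]) == 20
    assert 2 * electron_equivalents(db["acetate"]) == 16
    assert 2 * electron_equivalents(db["h2_aq"]) == 4
    assert electron_balance(networks.CATABOLIC["bu_ferm"], db) == 0


def test_anabolic_columns_balance_for_every_substrate(db):
    for sp in ("acetate", "butyrate", "h2_aq"):
        col = heterotrophic_anabolism(sp, db)
        assert column_balance_residuals(col, db) == {}
        assert col["biomass"] > 0
    col = electrotrophic_anabolism(db)
    assert column_balance_residuals(col, db) == {}
    assert col["e-"] < 0  # anabolic electrons drawn from the electrode


def test_balance_column_reports_impossible_completion(db):
    # methane from acetate cannot balance with water and protons alone
    with pytest.raises(StoichiometryError):
        balance_column({"acetate": -F1, "ch4_aq": 2 * F1}, ["h2o", "h+"], db)


def test_combine_is_exact_linear_combination(db):
    cat = networks.CATABOLIC["ac_meth"]
    anab = heterotrophic_anabolism("acetate", db)
    col = combine((Fraction(19, 20), cat), (Fraction(1, 20), anab))
    assert column_balance_residuals(col, db) == {}
    assert col["acetate"] == -1


# --- Petersen matrix assembly ----------------------------------------------

def _family_of(families):
    return {m.name: (f.total_symbol, f.reference_charge)
            for f in families for m in f.members}


def test_single_reaction_matrix(db, families):
    """A -> B with r = [1] gives generation R = (-1, +1)."""
    grp = MicrobialGroup("g", "X_g", 1.0, {}, 4.0, 9.0)
    rx = ReactionSpec("dec", "decay",
                      {"biomass": -F1, "inert": F1}, catalyst=grp)
    M = build_matrix([rx], ["inert", "A", "X_g"], db, _family_of(families))
    R = M @ np.array([1.0])
    assert R[0] == 1.0 and R[2] == -1.0 and R[1] == 0.0


def test_family_protonation_conserves_proton_inventory(db, families):
    # acetate + H+ -> acetic acid: total and A both unchanged (a free
    # proton becomes a bound one)
    proj = map_species_to_states({"acetate": -F1, "h+": -F1,
                                  "acetic_acid": F1}, db,
                                 _family_of(families), None)
    assert proj == {}


def test_unbalanced_column_rejected_at_build_time(db, families):
    rx = ReactionSpec("bad", "fermentative", {"acetate": -F1, "ethanol": F1})
    with pytest.raises(StoichiometryError, match="unbalanced"):
        build_matrix([rx], ["ac_T", "ethanol", "A"], db, _family_of(families))


def test_species_mapping_collapses_families_and_protons(db, families):
    proj = map_species_to_states(networks.CATABOLIC["ac_ox"], db,
                                 _family_of(families), None)
    # acetate -> ac_T; 2 HCO3- -> ct_T with 2 bound protons; 9 free H+
    assert proj["ac_T"] == -1.0
    assert proj["ct_T"] == 2.0
    assert proj["A"] == pytest.approx(9.0 + 2.0 * 1.0)
    assert "e-" not in proj and "h2o" not in proj


@pytest.mark.parametrize("builder", [networks.case_a_anode,
                                     networks.case_a_cathode,
                                     networks.case_b_anode,
                                     networks.case_b_cathode])
def test_every_case_study_column_is_exactly_balanced(db, builder):
    """Element, charge and electron-equivalent conservation of every
    Petersen column in both case-study networks, in rational arithmetic."""
    net = builder(db)
    reactions = list(net.fermentative) + [e.base for e in net.electrode] \
        + net.decay_reactions()
    for rx in reactions:
        assert column_balance_residuals(rx.stoichiometry, db) == {}, rx.name
        assert electron_balance(rx.stoichiometry, db) == 0, rx.name


# --- rate laws -------------------------------------------------------------

def test_ph_inhibition_formula_values():
    # two-sided ADM1 form: exactly 1 at the window midpoint, symmetric decay
    assert ph_inhibition(6.0, 5.0, 7.0) == pytest.approx(1.0)
    assert ph_inhibition(5.0, 5.0, 7.0) == pytest.approx(
        (1 + 2 * 10 ** -1.0) / (1 + 10 ** -2.0 + 1.0))
    assert ph_inhibition(3.0, 5.0, 7.0) < 0.02
    assert ph_inhibition(9.0, 5.0, 7.0) < 0.02


@pytest.fixture
def ferm_group():
    return MicrobialGroup("m", "X_m", k_max=4.0, K_S={"ac_T": 1e-3},
                          pH_LL=5.0, pH_UL=9.0, k_dec=0.02, f_an=0.05)


@pytest.fixture
def ferm_rx(db, ferm_group):
    cat = networks.CATABOLIC["ac_meth"]
    return ReactionSpec("ac_meth", "fermentative", stoichiometry=cat,
                        catalyst=ferm_group, substrates=["ac_T"],
                        catabolic=cat)


def test_zero_biomass_gives_zero_rate(db, ferm_rx):
    assert fermentative_rate(ferm_rx, {"ac_T": 0.1}, {"acetate": 0.09,
                             "ch4_aq": 1e-4, "hco3-": 0.01, "h+": 1e-7},
                             0.0, 7.0, db) == 0.0


def test_saturation_limit_approaches_kmax_X(db, ferm_rx, ferm_group):
    free = {"acetate": 0.5, "ch4_aq": 1e-6, "hco3-": 1e-3, "h+": 1e-7}
    rate = fermentative_rate(ferm_rx, {"ac_T": 0.5}, free, 0.01, 7.0, db)
    assert rate == pytest.approx(ferm_group.k_max * 0.01, rel=0.05)


def test_thermodynamic_gate_stops_endergonic_reaction(db, ferm_group):
    """No positive rate when the in-situ Gibbs energy is positive: butyrate
    oxidation under high H2 pressure."""
    cat = networks.CATABOLIC["bu_ferm"]
    rx = ReactionSpec("bu_ferm", "fermentative", stoichiometry=cat,
                      catalyst=ferm_group, substrates=["bu_T"], catabolic=cat)
    free = {"butyrate": 0.01, "acetate": 0.05, "h2_aq": 1e-3, "h+": 1e-7}
    from metsim.thermo import reaction_gibbs
    assert reaction_gibbs(cat, free, db) > 0
    assert fermentative_rate(rx, {"bu_T": 0.01}, free, 0.01, 7.0, db) == 0.0
    # at low H2 the same reaction proceeds
    free["h2_aq"] = 1e-8
    assert fermentative_rate(rx, {"bu_T": 0.01}, free, 0.01, 7.0, db) > 0.0


def test_decay_rate_examples(ferm_group):
    assert decay_rate(ferm_group, 0.0) == 0.0
    assert decay_rate(ferm_group, 0.1) == pytest.approx(0.002)


def test_gas_transfer_rate_examples():
    assert gas_transfer_rate(1e-3, 0.0, 200.0, 0.0008) == pytest.approx(0.2)
    assert gas_transfer_rate(0.0008, 1.0, 200.0, 0.0008) == pytest.approx(0.0)
    assert gas_transfer_rate(0.0, 1.0, 200.0, 0.0008) < 0.0  # absorption


def test_group_parameter_validation():
    with pytest.raises(ValueError):
        MicrobialGroup("g", "X", 1.0, {}, pH_LL=8.0, pH_UL=5.0)
    with pytest.raises(ValueError):
        MicrobialGroup("g", "X", -1.0, {}, pH_LL=5.0, pH_UL=8.0)
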