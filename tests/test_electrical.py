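"""Electrode kinetics and the two-rule cell solve, including the
grid-search oracle for multi-reaction current partitioning."""

import numpy as np
import pytest

from metsim import networks
from metsim.constants import F, SECONDS_PER_DAY
from metsim.electrical import (ChamberEnv, CircuitSpec, ElectrodeReactionSpec,
                               _activation_term, reaction_current, solve_cell,
                               surface_concentration)
from metsim.species import load_species_db
from metsim.thermo import nernst_potential


@pytest.fixture(scope="module")
def family_members(families):
    return {f.total_symbol: tuple(m.name for m in f.members)
            for f in families}


def make_env(family_members, totals, free, biomass, pH=7.0, V_liq=0.2):
    return ChamberEnv(totals=totals, free=free, biomass=biomass, pH=pH,
                      V_liq=V_liq, family_members=family_members)


@pytest.fixture(scope="module")
def anodic_spec(db):
    net = networks.case_a_anode(db)
    return next(e for e in net.electrode if e.name == "an_ac_ox")


@pytest.fixture(scope="module")
def cathodic_specs(db):
    net = networks.case_a_cathode(db)
    return [e for e in net.electrode if e.name in ("cat_ac_red",
                                                   "cat_bu_red")]


ANODE_FREE = {"acetate": 0.05, "acetic_acid": 1e-4, "hco3-": 0.02,
              "co2_aq": 2e-3, "h+": 1e-7, "oh-": 1e-7, "h2_aq": 1e-7}
CATHODE_FREE = {"acetate": 0.05, "butyrate": 0.05, "ethanol": 5e-3,
                "butanol": 2e-3, "h+": 1e-5, "oh-": 1e-9, "h2_aq": 1e-7,
                "hco3-": 1e-3, "co2_aq": 5e-3}


# --- surface concentration --------------------------------------------------

def test_zero_demand_keeps_bulk_concentration():
    assert surface_concentration(0.01, lambda S: 0.0, 1.0, 0.01) == 0.01


def test_infinite_mass_transfer_removes_polarisation():
    S = surface_concentration(0.01, lambda S: 0.5 * S, 1e9, 0.01)
    assert S == pytest.approx(0.01, rel=1e-9)


def test_linear_kinetics_closed_form():
    """rate = c*S_surf gives S_surf = kmA*S_bulk/(kmA + c) exactly."""
    k_m, A, c, S_bulk = 0.3, 0.02, 4.0, 0.05
    kmA = k_m * A * 1000.0
    S = surface_concentration(S_bulk, lambda s: c * s, k_m, A)
    assert S == pytest.approx(kmA * S_bulk / (kmA + c), abs=1e-10)


# --- single-reaction currents ----------------------------------------------

def test_equilibrium_potential_gives_zero_current(db, anodic_spec,
                                                  family_members):
    env = make_env(family_members, {"ac_T": 0.05}, ANODE_FREE,
                   {anodic_spec.group.name: 0.01})
    E_n = nernst_potential(anodic_spec.base.half_reaction, env.free, db)
    I, eta, _, rate = reaction_current(anodic_spec, E_n, env, db)
    assert I == 0.0 and eta == 0.0 and rate == 0.0


def test_activation_term_half_saturation(anodic_spec):
    assert _activation_term(anodic_spec, anodic_spec.KSE, 298.15) == 0.5


def test_no_reverse_current_below_equilibrium(db, anodic_spec,
                                              family_members):
    env = make_env(family_members, {"ac_T": 0.05}, ANODE_FREE,
                   {anodic_spec.group.name: 0.01})
    E_n = nernst_potential(anodic_spec.base.half_reaction, env.free, db)
    I, eta, _, _ = reaction_current(anodic_spec, E_n - 0.3, env, db)
    assert I == 0.0 and eta == 0.0


def test_current_monotone_in_overpotential(db, anodic_spec, family_members):
    env = make_env(family_members, {"ac_T": 0.05}, ANODE_FREE,
                   {anodic_spec.group.name: 0.01})
    E_n = nernst_potential(anodic_spec.base.half_reaction, env.free, db)
    currents = [reaction_current(anodic_spec, E_n + d, env, db)[0]
                for d in np.linspace(0.0, 0.6, 25)]
    assert all(b >= a - 1e-15 for a, b in zip(currents, currents[1:]))
    assert currents[-1] > 0


def test_zero_biomass_gives_zero_current(db, anodic_spec, family_members):
    env = make_env(family_members, {"ac_T": 0.05}, ANODE_FREE, {})
    I, _, _, _ = reaction_current(anodic_spec, 1.0, env, db)
    assert I == 0.0


# --- circuit validation -----------------------------------------------------

def test_circuit_validation():
    with pytest.raises(ValueError):
        CircuitSpec("XX")
    with pytest.raises(ValueError):
        CircuitSpec("MFC", R_ext=0.0)
    with pytest.raises(ValueError):
        CircuitSpec("MEC", V_app=-0.1)


def test_electrode_spec_validation(db, anodic_spec):
    with pytest.raises(ValueError):
        ElectrodeReactionSpec(base=anodic_spec.base, KSE=0.0, k_m=1.0,
                              area=0.01)
    with pytest.raises(ValueError):
        ElectrodeReactionSpec(base=anodic_spec.base, KSE=0.1, k_m=-1.0,
                              area=0.01)


# --- cell solve -------------------------------------------------------------

def _envs(db, family_members, with_biomass=True):
    X = 0.01 if with_biomass else 0.0
    an = make_env(family_members, {"ac_T": 0.05, "h2_aq": 1e-7}, ANODE_FREE,
                  {"ea_ac_an": X, "ea_h2_an": 0.0}, pH=7.0)
    cat = make_env(family_members,
                   {"ac_T": 0.05, "bu_T": 0.05, "h2_aq": 1e-7},
                   CATHODE_FREE,
                   {"ea_ac_cat": X, "ea_bu_cat": X, "ea_h2ev": 0.0}, pH=5.0)
    return an, cat


def test_open_circuit_with_no_biomass(db, family_members):
    an_env, cat_env = _envs(db, family_members, with_biomass=False)
    anodic = networks.case_a_anode(db).electrode
    cathodic = networks.case_a_cathode(db).electrode
    circuit = CircuitSpec("MEC", V_app=0.7, R_int=100.0)
    sol = solve_cell(an_env, cat_env, anodic, cathodic, circuit, db)
    assert sol.I_total == 0.0
    assert sol.E_an - sol.E_cat == pytest.approx(0.7, abs=1e-12)


def test_cell_solution_satisfies_both_rules(db, family_members):
    an_env, cat_env = _envs(db, family_members)
    anodic = networks.case_a_anode(db).electrode
    cathodic = networks.case_a_cathode(db).electrode
    circuit = CircuitSpec("MEC", V_app=0.7, R_int=100.0)
    sol = solve_cell(an_env, cat_env, anodic, cathodic, circuit, db)
    assert sol.I_total > 0
    # rule (i): contributions sum to the total at each electrode
    names_an = [e.name for e in anodic]
    names_cat = [e.name for e in cathodic]
    assert sol.current_sum_residual(names_an, names_cat) <= 1e-9
    # circuit closure
    assert (circuit.V_app - (sol.E_an - sol.E_cat)
            - sol.I_total * circuit.R_total) == pytest.approx(0.0, abs=1e-9)
    # rule (ii): each reaction sees the single electrode potential
    for spec in anodic + list(cathodic):
        E = sol.E_an if spec.anodic else sol.E_cat
        I, eta, S, rate = reaction_current(spec, E, an_env if spec.anodic
                                           else cat_env, db)
        assert I == pytest.approx(sol.I_contrib[spec.name], abs=1e-12)
        assert eta >= 0.0


def test_two_cathodic_reactions_match_grid_search_oracle(db, family_members):
    """Current partition between two parallel cathodic reactions vs a
    brute-force grid search over (E_an, E_cat) minimising the constraint
    residuals; currents agree within 0.5%."""
    an_env, cat_env = _envs(db, family_members)
    anodic = [e for e in networks.case_a_anode(db).electrode
              if e.name == "an_ac_ox"]
    cathodic = networks.case_a_cathode(db).electrode[:2]  # ac_red, bu_red
    circuit = CircuitSpec("MEC", V_app=0.7, R_int=100.0)
    sol = solve_cell(an_env, cat_env, anodic, cathodic, circuit, db)
    assert sol.I_total > 0

    # oracle: scan E_an on a fine grid; for each, close the circuit
    # explicitly and measure the current mismatch between the electrodes
    E_grid = np.linspace(sol.E_an - 0.05, sol.E_an + 0.05, 2001)
    best = None
    for E_an in E_grid:
        I_an = sum(reaction_current(s, E_an, an_env, db)[0] for s in anodic)
        E_cat = E_an - circuit.V_app + I_an * circuit.R_total
        I_cat = sum(reaction_current(s, E_cat, cat_env, db)[0]
                    for s in cathodic)
        resid = abs(I_an - I_cat)
        if best is None or resid < best[0]:
            best = (resid, E_an, E_cat, I_an)
    _, E_an_o, E_cat_o, I_o = best
    assert sol.I_total == pytest.approx(I_o, rel=5e-3)
    for s in cathodic:
        I_ref = reaction_current(s, E_cat_o, cat_env, db)[0]
        assert sol.I_contrib[s.name] == pytest.approx(I_ref, rel=5e-3,
                                                      abs=1e-9)


def test_mfc_circuit_closure(db, family_members):
    an_env, cat_env = _envs(db, family_members)
    anodic = networks.case_b_anode(db).electrode
    prb = networks.case_b_cathode(db).electrode
    cat_env_b = make_env(family_members,
                         {"clo4-": 3e-3, "clo3-": 1e-4, "clo2-": 1e-4,
                          "ocl_T": 1e-4},
                         {"clo4-": 3e-3, "clo3-": 1e-4, "clo2-": 1e-4,
                          "clo-": 5e-5, "hclo": 5e-5, "cl-": 1e-3,
                          "h+": 1e-7, "oh-": 1e-7},
                         {"prb": 0.01}, pH=7.0)
    circuit = CircuitSpec("MFC", R_ext=419.01, R_int=100.0)
    sol = solve_cell(an_env, cat_env_b, anodic, prb, circuit, db)
    assert sol.I_total > 0
    assert sol.E_cat > sol.E_an
    assert (sol.E_cat - sol.E_an) == pytest.approx(
        sol.I_total * circuit.R_total, abs=1e-9)
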