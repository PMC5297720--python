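"""DAE assembly and integration: washout closed forms, conservation,
gas-phase invariants, steady-state detection."""

import numpy as np
import pytest

from metsim import networks
from metsim.bioreactions import MicrobialGroup, ReactionSpec
from metsim.electrical import CircuitSpec
from metsim.membrane import MembraneSpec
from metsim.reactor import (ChamberNetwork, Feed, Geometry, SimulationConfig,
                            SolverSettings, System)
from metsim.studies import CASE_A_LIQUID, case_a_config


def tracer_config(**overrides):
    """Minimal two-chamber system with no reactions: an inert tracer."""
    kw = dict(
        liquid_states=["na+", "cl-"],
        anode=ChamberNetwork(), cathode=ChamberNetwork(),
        geometry=Geometry(0.5, 0.5, 0.1, 0.1),
        membrane=MembraneSpec("PEM"),
        circuit=CircuitSpec("MEC", V_app=0.0),
        feed_an=Feed(flow=0.1, composition={"na+": 0.02, "cl-": 0.02}),
        feed_cat=Feed(flow=0.1, composition={"na+": 0.02, "cl-": 0.02}),
        SRT=100.0,
        initial_an={"na+": 0.001, "cl-": 0.001},
        initial_cat={"na+": 0.001, "cl-": 0.001},
        solver=SolverSettings(rtol=1e-10, atol=1e-14, t_end=50.0),
    )
    kw.update(overrides)
    return SimulationConfig(**kw)


def closed_case_a_config():
    """Case A chemistry with no feed and no electrode reactions: a sealed
    fermenting bottle (zero current by construction)."""
    cfg = case_a_config()
    an = ChamberNetwork(groups=cfg.anode.groups,
                        fermentative=cfg.anode.fermentative, electrode=[])
    cat = ChamberNetwork(groups=cfg.cathode.groups,
                         fermentative=cfg.cathode.fermentative, electrode=[])
    return SimulationConfig(
        liquid_states=CASE_A_LIQUID, anode=an, cathode=cat,
        geometry=cfg.geometry, membrane=cfg.membrane, circuit=cfg.circuit,
        feed_an=Feed(flow=0.0), feed_cat=Feed(flow=0.0),
        SRT=cfg.SRT, X_max=cfg.X_max, k_ret=cfg.k_ret, kla=cfg.kla,
        solver=SolverSettings(rtol=1e-8, atol=1e-12, t_end=100.0),
        initial_an=dict(cfg.initial_an), initial_cat=dict(cfg.initial_cat),
        initial_biomass=cfg.initial_biomass, db=cfg.db)


# --- washout / tracer closed forms -----------------------------------------

def test_inert_tracer_washout_matches_exponential():
    """dX/dt = D(X_in - X) with no reactions: X(t) = X_in + (X0-X_in)e^-Dt."""
    cfg = tracer_config()
    system = System(cfg)
    traj = system.integrate(t_end=30.0, cadence=5.0)
    D = 0.1 / 0.5
    i = system.index["an.na+"]
    for t, y in zip(traj.t, traj.y):
        expected = 0.02 + (0.001 - 0.02) * np.exp(-D * t)
        assert y[i] == pytest.approx(expected, rel=1e-8)


def test_zero_horizon_echoes_initial_state():
    system = System(tracer_config())
    traj = system.integrate(t_end=0.0)
    assert len(traj) == 1
    np.testing.assert_array_equal(traj.y[0], system.initial_state())


def test_output_cadence_does_not_change_solution():
    system = System(tracer_config())
    a = system.integrate(t_end=20.0, cadence=4.0)
    b = system.integrate(t_end=20.0, cadence=2.0)
    shared = np.isin(b.t, a.t)
    np.testing.assert_allclose(b.y[shared], a.y, rtol=1e-6, atol=1e-12)


def test_tracer_steady_state_is_inlet_composition():
    cfg = tracer_config(solver=SolverSettings(rtol=1e-10, atol=1e-14,
                                              t_end=400.0, ss_tol=1e-8,
                                              ss_floor=1e-9, chunk=50.0))
    system = System(cfg)
    y, alg, converged, t = system.steady_state()
    assert converged
    assert y[system.index["an.na+"]] == pytest.approx(0.02, rel=1e-6)


def test_no_feed_no_reactions_initial_state_is_steady():
    cfg = tracer_config(feed_an=Feed(flow=0.0), feed_cat=Feed(flow=0.0),
                        solver=SolverSettings(t_end=10.0, ss_tol=1e-6,
                                              chunk=5.0))
    system = System(cfg)
    y0 = system.initial_state()
    dy = system.rhs(0.0, y0)
    assert np.max(np.abs(dy)) < 1e-12


# --- chemostat closed form --------------------------------------------------

@pytest.fixture(scope="module")
def chemostat_system():
    """Single-group methanogenic chemostat run to steady state."""
    from metsim.species import load_species_db
    db = load_species_db()
    grp = networks.make_group("meth_ac", "_x")
    rx = networks._ferm("meth", "ac_meth", grp, ["ac_T"], db)
    net = ChamberNetwork(groups=[grp], fermentative=[rx])
    cfg = SimulationConfig(
        liquid_states=["ac_T", "ct_T", "n_T", "na+", "cl-", "ch4_aq",
                       "h2_aq"],
        anode=net, cathode=ChamberNetwork(),
        geometry=Geometry(0.5, 0.5, 0.1, 0.1),
        membrane=MembraneSpec("PEM"), circuit=CircuitSpec("MEC", V_app=0.0),
        feed_an=Feed(flow=0.05, composition={"ac_T": 0.05, "na+": 0.055,
                                             "n_T": 0.01, "cl-": 0.01,
                                             "ct_T": 0.01}),
        feed_cat=Feed(flow=0.0),
        SRT=20.0, X_max=0.05,
        solver=SolverSettings(t_end=600.0, ss_tol=1e-6, ss_floor=1e-8,
                              chunk=50.0),
        initial_an={"ac_T": 0.01, "na+": 0.055, "n_T": 0.01, "cl-": 0.01,
                    "ct_T": 0.01},
        initial_cat={}, initial_biomass=2e-3, db=db)
    system = System(cfg)
    y, alg, converged, t = system.steady_state()
    return system, y, alg


def test_monod_chemostat_residual_substrate(chemostat_system):
    """Single-group chemostat: at steady state the rate law must balance
    washout, giving S* from the Monod closed form with the effective
    (pH- and thermodynamics-corrected) maximum uptake."""
    system, y, alg = chemostat_system
    from metsim.species import load_species_db
    db = load_species_db()
    cfg = system.config
    grp = system.config.anode.groups[0]
    rx = system.config.anode.fermentative[0]
    env = alg["an_env"]
    S = y[system.index["an.ac_T"]]
    X = y[system.index["an.X_meth_ac_x"]]
    assert X > 1e-4  # the population established

    # independent algebraic balance: per-capita growth = washout + decay.
    # The biomass yield per mol substrate is f_an times the biomass
    # coefficient of the (exactly balanced) anabolic column.
    from metsim.bioreactions import (fermentative_rate,
                                     heterotrophic_anabolism, ph_inhibition)
    Y = grp.f_an * float(heterotrophic_anabolism("acetate", db)["biomass"])
    rate = fermentative_rate(rx, env.totals, env.free, X, env.pH, db)
    mu_eff = rate / X * Y                       # mol-C growth per mol-C day
    f_ret = 1.0 + cfg.k_ret * X / (cfg.X_max - X)
    washout = f_ret / cfg.SRT + grp.k_dec
    assert mu_eff == pytest.approx(washout, rel=0.02)

    # Monod closed form with the pH- and thermodynamics-corrected maximum
    from metsim.thermo import feasibility_factor, reaction_gibbs
    fth = feasibility_factor(reaction_gibbs(rx.catabolic, env.free, db))
    k_eff = grp.k_max * ph_inhibition(env.pH, grp.pH_LL, grp.pH_UL) * fth
    S_star = grp.K_S["ac_T"] * washout / (Y * k_eff - washout)
    assert S == pytest.approx(S_star, rel=0.05)


# --- conservation -----------------------------------------------------------

def test_closed_system_conserves_elements_and_cod():
    """Sealed, zero-current case A chemistry over 100 days: C, N, Na and
    electron equivalents conserved to 1e-6 relative."""
    system = System(closed_case_a_config())
    y0 = system.initial_state()
    traj = system.integrate(t_end=100.0, cadence=25.0)
    inv0 = system.element_inventory(y0)
    cod0 = system.cod_inventory(y0)
    alg = system.algebraic(traj.state())
    assert alg["cell"].I_total == 0.0
    for y in traj.y[1:]:
        inv = system.element_inventory(y)
        for el in ("C", "N", "Na"):
            assert inv[el] == pytest.approx(inv0[el], rel=1e-6)
        assert system.cod_inventory(y) == pytest.approx(cod0, rel=1e-6)


def test_charge_consistency_preserved_along_trajectory():
    """Electroneutrality is emergent: the tracked strong-ion charge and the
    proton inventory remain consistent through 100 simulated days."""
    system = System(closed_case_a_config())
    traj = system.integrate(t_end=100.0, cadence=50.0)
    for y in traj.y:
        res = system.charge_consistency(y)
        assert abs(res["an"]) < 1e-8
        assert abs(res["cat"]) < 1e-8


def test_headspace_pressure_constant_while_producing(chemostat_system):
    """Sum of partial pressures + water vapour stays at the total pressure
    while the liquid is a net gas producer (one-way venting can leave the
    headspace below total pressure only during net absorption)."""
    system, y, alg = chemostat_system
    p_dry = system.config.P_total - system.P_w
    p_sum = sum(y[system.gas_offset + j] for j in range(3))
    assert p_sum == pytest.approx(p_dry, abs=1e-6)
    # and never above it anywhere
    traj = system.integrate(t_end=30.0, cadence=5.0)
    for yy in traj.y:
        for k in (0, 1):
            s2 = sum(yy[system.gas_offset + 3 * k + j] for j in range(3))
            assert s2 <= p_dry + 1e-6


def test_biomass_never_exceeds_cap():
    cfg = case_a_config()
    system = System(cfg)
    traj = system.integrate(t_end=60.0, cadence=10.0)
    for tag in ("an", "cat"):
        ch = system.chambers[tag]
        off = ch["offset"]
        n_liq = len(system.liquid_states)
        for y in traj.y:
            X_sum = np.sum(np.maximum(
                y[off + n_liq: off + len(ch["local"])], 0.0))
            assert X_sum <= cfg.X_max - 1e-9


# --- config validation -------------------------------------------------------

def test_srt_must_cover_hydraulic_retention():
    with pytest.raises(ValueError, match="SRT"):
        tracer_config(SRT=1.0)


def test_unknown_feed_state_rejected():
    cfg = tracer_config(feed_an=Feed(flow=0.1, composition={"bogus": 1.0}))
    with pytest.raises(KeyError):
        System(cfg).feed_vector("an")


def test_compartment_state_snapshot():
    system = System(case_a_config())
    y0 = system.initial_state()
    cs = system.compartment_state(y0, "anode")
    assert cs.V_liq == 0.2
    assert cs.liquid["na+"] == pytest.approx(0.12)
    assert set(cs.gas) == {"co2", "ch4", "h2"}
    assert cs.D == pytest.approx(system.config.feed_an.flow / 0.2)
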