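"""Case-study configurations, experiment runners and steady-state summaries.

Shipped experiments mirror the simulation campaigns of the two case studies:
the ethanol/butanol MEC base case with applied-voltage and feed-ratio
sweeps, and the perchlorate-reducing MFC base case with a polarization curve
and feed sweeps.  Sweeps run each point to steady state, warm-starting from
the previous point (continuation), and report failed points as flagged rows
rather than dropping them.
"""

from __future__ import annotations

from dataclasses import dataclass, field, replace
from typing import Mapping, Sequence

import numpy as np
import pandas as pd

from . import networks, params
from .constants import E_AGCL_VS_SHE, F, R_BAR, SECONDS_PER_DAY
from .electrical import CircuitSpec
from .membrane import MembraneSpec
from .reactor import (Feed, GAS_SPECIES, Geometry, SimulationConfig,
                      SolverSettings, System, IntegrationError)
from .species import electron_equivalents, load_species_db

__all__ = ["ExperimentSpec", "case_a_config", "case_b_config",
           "run_case_a_base", "run_case_b_base", "run_sweep",
           "polarization_curve", "steady_summary", "electron_fate",
           "run_to_steady"]

CASE_A_LIQUID = ["ac_T", "bu_T", "ct_T", "n_T", "na+", "cl-",
                 "ethanol", "butanol", "h2_aq", "ch4_aq"]
CASE_B_LIQUID = ["ac_T", "ct_T", "n_T", "na+", "cl-",
                 "clo4-", "clo3-", "clo2-", "ocl_T", "h2_aq", "ch4_aq"]

SWEEP_VARIABLES = ("V_app", "anode_feed_fraction", "R_ext", "feed_flow",
                   "feed_concentration")


@dataclass
class ExperimentSpec:
    """A one-variable steady-state sweep over a base configuration."""

    base_config: SimulationConfig
    sweep_variable: str
    sweep_values: Sequence[float]
    outputs: Sequence[str] = ()

    def __post_init__(self) -> None:
        if self.sweep_variable not in SWEEP_VARIABLES:
            raise ValueError(f"unknown sweep variable {self.sweep_variable!r}")
        if len(self.sweep_values) == 0:
            raise ValueError("sweep_values must be non-empty")
        for v in self.sweep_values:
            if self.sweep_variable == "anode_feed_fraction" and not 0 < v < 1:
                raise ValueError("feed fractions must be in (0, 1)")
            if self.sweep_variable == "V_app" and v < 0:
                raise ValueError("V_app must be >= 0")
            if self.sweep_variable == "R_ext" and v <= 0:
                raise ValueError("R_ext must be > 0")


def _solver_defaults() -> SolverSettings:
    # production defaults for the shipped studies: tolerances tight enough
    # for the conservation audits, horizon long enough for steady state
    return SolverSettings(rtol=1e-7, atol=1e-10, t_end=400.0, cadence=0.5,
                          ss_tol=1e-3, ss_floor=1e-6, chunk=20.0)


def case_a_config(V_app: float | None = None,
                  anode_fraction: float | None = None,
                  total_feed: float | None = None,
                  solver: SolverSettings | None = None) -> SimulationConfig:
    """Ethanol/butanol MEC: one feed stream split anode:cathode."""
    p = params.CASE_A
    db = load_species_db()
    V_app = p["V_app"] if V_app is None else V_app
    frac = p["anode_fraction"] if anode_fraction is None else anode_fraction
    Q = p["total_feed"] if total_feed is None else total_feed
    return SimulationConfig(
        liquid_states=CASE_A_LIQUID,
        anode=networks.case_a_anode(db),
        cathode=networks.case_a_cathode(db),
        geometry=Geometry(p["V_liq"], p["V_liq"], p["V_gas"], p["V_gas"]),
        membrane=MembraneSpec("PEM", area=params.ELECTRODE["area"]),
        circuit=CircuitSpec("MEC", R_ext=0.0, V_app=V_app,
                            R_int=params.CIRCUIT["R_int"]),
        feed_an=Feed(flow=Q * frac, composition=dict(p["feed"])),
        feed_cat=Feed(flow=Q * (1.0 - frac), composition=dict(p["feed"])),
        SRT=p["SRT"], X_max=p["X_max"], k_ret=p["k_ret"], kla=params.KLA,
        solver=solver or _solver_defaults(),
        initial_an={**p["initial_an"], **p["inoculum_an"]},
        initial_cat={**p["initial_cat"], **p["inoculum_cat"]},
        initial_gas_an=p["initial_gas_an"],
        initial_gas_cat=p["initial_gas_cat"],
        initial_biomass=params.X_INOCULUM, db=db)


def case_b_config(R_ext: float | None = None,
                  flow_an: float | None = None, flow_cat: float | None = None,
                  conc_ac: float | None = None, conc_clo4: float | None = None,
                  solver: SolverSettings | None = None) -> SimulationConfig:
    """Perchlorate-reducing MFC."""
    p = params.CASE_B
    db = load_species_db()
    feed_an = dict(p["feed_an"])
    feed_cat = dict(p["feed_cat"])
    if conc_ac is not None:
        feed_an["na+"] = feed_an["na+"] + (conc_ac - feed_an["ac_T"])
        feed_an["ac_T"] = conc_ac
    if conc_clo4 is not None:
        feed_cat["na+"] = feed_cat["na+"] + (conc_clo4 - feed_cat["clo4-"])
        feed_cat["clo4-"] = conc_clo4
    return SimulationConfig(
        liquid_states=CASE_B_LIQUID,
        anode=networks.case_b_anode(db),
        cathode=networks.case_b_cathode(db),
        geometry=Geometry(p["V_liq"], p["V_liq"], p["V_gas"], p["V_gas"]),
        membrane=MembraneSpec("PEM", area=params.ELECTRODE["area"]),
        circuit=CircuitSpec("MFC", R_ext=p["R_ext"] if R_ext is None else R_ext,
                            R_int=params.CIRCUIT["R_int"]),
        feed_an=Feed(flow=p["flow"] if flow_an is None else flow_an,
                     composition=feed_an),
        feed_cat=Feed(flow=p["flow"] if flow_cat is None else flow_cat,
                      composition=feed_cat),
        SRT=p["SRT"], X_max=p["X_max"], k_ret=p["k_ret"], kla=params.KLA,
        solver=solver or _solver_defaults(),
        initial_an={**p["initial_an"], **p["inoculum_an"]},
        initial_cat={**p["initial_cat"], **p["inoculum_cat"]},
        initial_biomass=params.X_INOCULUM, db=db)


# ---------------------------------------------------------------------------
# steady-state summaries
# ---------------------------------------------------------------------------

def _gamma(system: System, sym: str) -> float:
    """Electron equivalents per mol of a liquid state symbol."""
    if sym in system.family_members:
        return float(electron_equivalents(
            system.db[system.family_members[sym][-1]]))
    if sym in ("inert",) or sym.startswith("X_"):
        return float(electron_equivalents(system.db["biomass"]))
    if sym in system.db:
        return float(electron_equivalents(system.db[sym]))
    return 0.0


def electron_fate(system: System, y: np.ndarray, alg: Mapping,
                  which: str) -> dict[str, float]:
    """Steady-state fate of the electron equivalents entering a chamber.

    Fractions of the total electron-equivalent input (feed, plus cathodic
    current) leaving as current (anode), liquid products, vented gas, and
    wasted solids (biomass + inerts).  Sums to ~1 at steady state.
    """
    tag = "an" if which.startswith("an") else "cat"
    cfg = system.config
    ch = system.chambers[tag]
    feed = cfg.feed_an if tag == "an" else cfg.feed_cat
    V_liq = cfg.geometry.V_liq_an if tag == "an" else cfg.geometry.V_liq_cat
    off = ch["offset"]
    local = ch["local"]
    vals = {s: float(y[off + i]) for i, s in enumerate(local)}
    I = alg["cell"].I_total
    e_current = I * SECONDS_PER_DAY / F  # mol e-/day

    e_in = feed.flow * sum(_gamma(system, s) * c
                           for s, c in feed.composition.items())
    if tag == "cat":
        e_in += e_current
    # liquid outflow
    e_liq = feed.flow * sum(_gamma(system, s) * max(vals[s], 0.0)
                            for s in local
                            if s not in ("A",) and s not in ch["bio"]
                            and s != "inert")
    # wasted solids at f/SRT
    X_sum = sum(max(vals[b], 0.0) for b in ch["bio"])
    f_ret = 1.0 + cfg.k_ret * X_sum / max(cfg.X_max - X_sum, 1e-12)
    e_solids = (X_sum * f_ret / cfg.SRT * V_liq
                * _gamma(system, "inert"))
    e_solids += feed.flow * max(vals.get("inert", 0.0), 0.0) * _gamma(system, "inert")
    # gas vent
    env = alg[f"{tag}_env"]
    k = 0 if tag == "an" else 1
    from .bioreactions import gas_transfer_rate
    q = []
    for jg, (gas, aq) in enumerate(GAS_SPECIES):
        p = max(y[system.gas_offset + 3 * k + jg], 0.0)
        q.append(gas_transfer_rate(env.free.get(aq, 0.0), p, cfg.kla,
                                   system._henry(gas)))
    qsum = sum(q)
    p_dry = cfg.P_total - system.P_w
    gamma_gas = {"co2": 0.0, "ch4": 8.0, "h2": 2.0}
    e_gas = 0.0
    if qsum > 0:
        for jg, (gas, _) in enumerate(GAS_SPECIES):
            p = max(y[system.gas_offset + 3 * k + jg], 0.0)
            e_gas += gamma_gas[gas] * (p / p_dry) * V_liq * qsum
    out = {"liquid": e_liq, "gas": e_gas, "solids": e_solids}
    if tag == "an":
        out["current"] = e_current
    denom = max(e_in, 1e-30)
    return {k2: v / denom for k2, v in out.items()}


def steady_summary(system: System, y: np.ndarray, alg: Mapping) -> dict:
    """Headline steady-state quantities of one solved configuration."""
    cell = alg["cell"]
    cfg = system.config
    out = {
        "E_an_V": cell.E_an,
        "E_cat_V": cell.E_cat,
        "E_cat_mV_AgAgCl": (cell.E_cat - E_AGCL_VS_SHE) * 1000.0,
        "I_total_A": cell.I_total,
        "delta_E_V": cell.E_an - cell.E_cat,
        "pH_an": alg["an_env"].pH,
        "pH_cat": alg["cat_env"].pH,
    }
    if cfg.circuit.mode == "MFC":
        out["V_cell_V"] = cell.I_total * cfg.circuit.R_ext
        out["P_W"] = out["V_cell_V"] * cell.I_total
    for name, I in cell.I_contrib.items():
        out[f"I_{name}_A"] = I
    for tag in ("an", "cat"):
        ch = system.chambers[tag]
        off = ch["offset"]
        for i, s in enumerate(ch["local"]):
            out[f"{tag}.{s}"] = float(y[off + i])
    # conversions of the fed substrates
    for tag, feed in (("an", cfg.feed_an), ("cat", cfg.feed_cat)):
        for s, c_in in feed.composition.items():
            if c_in > 0 and _gamma(system, s) != 0:
                c_out = out.get(f"{tag}.{s}", 0.0)
                out[f"conversion_{tag}.{s}"] = 1.0 - c_out / c_in
    for tag in ("an", "cat"):
        for k2, v in electron_fate(system, y, alg, tag).items():
            out[f"efate_{tag}.{k2}"] = v
    return out


# ---------------------------------------------------------------------------
# runners
# ---------------------------------------------------------------------------

def run_to_steady(config: SimulationConfig, y0: np.ndarray | None = None
                  ) -> tuple[System, np.ndarray, dict, bool, float]:
    system = System(config)
    y, alg, converged, t = system.steady_state(y0=y0)
    return system, y, alg, converged, t


def run_case_a_base(V_app: float | None = None, trajectory: bool = False):
    """Case A base run; returns (system, steady state, algebraic snapshot,
    summary) and optionally the full trajectory."""
    cfg = case_a_config(V_app=V_app)
    system = System(cfg)
    traj = system.integrate() if trajectory else None
    y0 = traj.state() if traj is not None else None
    y, alg, converged, t = system.steady_state(y0=y0)
    summ = steady_summary(system, y, alg)
    summ["steady_converged"] = converged
    summ["t_days"] = t
    if trajectory:
        return system, y, alg, summ, traj
    return system, y, alg, summ


def run_case_b_base(trajectory: bool = False):
    cfg = case_b_config()
    system = System(cfg)
    traj = system.integrate() if trajectory else None
    y0 = traj.state() if traj is not None else None
    y, alg, converged, t = system.steady_state(y0=y0)
    summ = steady_summary(system, y, alg)
    summ["steady_converged"] = converged
    summ["t_days"] = t
    if trajectory:
        return system, y, alg, summ, traj
    return system, y, alg, summ


def _config_for(spec: ExperimentSpec, value: float) -> SimulationConfig:
    base = spec.base_config
    var = spec.sweep_variable
    if var == "V_app":
        return replace(base, circuit=replace(base.circuit, V_app=value))
    if var == "R_ext":
        return replace(base, circuit=replace(base.circuit, R_ext=value))
    if var == "anode_feed_fraction":
        Q = base.feed_an.flow + base.feed_cat.flow
        return replace(base,
                       feed_an=replace(base.feed_an, flow=Q * value),
                       feed_cat=replace(base.feed_cat, flow=Q * (1 - value)))
    if var == "feed_flow":
        return replace(base, feed_an=replace(base.feed_an, flow=value))
    if var == "feed_concentration":
        comp = dict(base.feed_an.composition)
        comp["ac_T"] = value
        return replace(base, feed_an=replace(base.feed_an, composition=comp))
    raise ValueError(var)


def run_sweep(spec: ExperimentSpec, continuation: bool = True) -> pd.DataFrame:
    """Steady-state summary table, one row per sweep value.

    Failed or non-converged points are reported as flagged rows (``ok`` /
    ``steady_converged`` columns), never dropped.
    """
    rows = []
    y_prev = None
    for v in spec.sweep_values:
        cfg = _config_for(spec, v)
        row = {spec.sweep_variable: v}
        try:
            system = System(cfg)
            y, alg, converged, t = system.steady_state(
                y0=y_prev if continuation else None)
            summ = steady_summary(system, y, alg)
            row.update(summ)
            row["ok"] = True
            row["steady_converged"] = converged
            if continuation:
                y_prev = y
        except (IntegrationError, ValueError) as exc:
            row["ok"] = False
            row["error"] = str(exc)
        rows.append(row)
    df = pd.DataFrame(rows)
    if spec.outputs:
        keep = [spec.sweep_variable, "ok"] + [c for c in spec.outputs
                                              if c in df.columns]
        df = df[keep + [c for c in ("steady_converged",) if c in df.columns]]
    return df


def polarization_curve(r_ext_values: Sequence[float] | None = None,
                       base: SimulationConfig | None = None) -> pd.DataFrame:
    """Steady-state polarization/power curve of the MFC case study.

    Sweeps the external resistance from high to low (continuation), and
    reports cell voltage V = I R_ext and power P = V I per point.
    """
    if r_ext_values is None:
        r_ext_values = [2500, 1500, 1000, 700, 419.01, 250, 150, 100, 50]
    base = base or case_b_config()
    spec = ExperimentSpec(base_config=base, sweep_variable="R_ext",
                          sweep_values=sorted(r_ext_values, reverse=True))
    df = run_sweep(spec)
    return df
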