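"""Two-chamber reactor assembly and stiff integration of the full DAE.

State variables live in four domains: anode and cathode liquid phases
(family totals, strong ions, neutral solutes, a proton-inventory state and
per-group biomasses) and anode and cathode gas phases (partial pressures).
pH, electrode potentials, currents and membrane fluxes are *algebraic*
states, recomputed from the differential states inside the right-hand side
at every step — never integrated.

Liquid balances:   dX/dt = D (X_in - X) + (M r) + membrane/V_liq
Biomass balances:  dX/dt = (M r) - X f / SRT,  f = 1 + k SumX/(Xmax - SumX)
Gas balances:      dp/dt = R T (V_liq/V_gas) (q - p Sum q / (P - P_w))

The proton-inventory state ``A`` tracks the net dissociable-proton excess of
each liquid relative to fully deprotonated references; it is what electrode
H+ turnover and H+/OH- membrane transport act on, and it closes the charge
bookkeeping exactly (electroneutrality is then an emergent invariant that
the audit checks, not an imposed constraint).
"""

from __future__ import annotations

from dataclasses import dataclass, field, replace
from fractions import Fraction
from typing import Mapping, Sequence

import numpy as np
from scipy.integrate import solve_ivp

from .bioreactions import (MicrobialGroup, ReactionSpec, build_matrix,
                           decay_rate, fermentative_rate, gas_transfer_rate,
                           map_species_to_states)
from .constants import (F, P_TOTAL, R_BAR, SECONDS_PER_DAY, T_REF,
                        water_vapour_pressure)
from .electrical import (CellSolution, ChamberEnv, CircuitSpec,
                         ElectrodeReactionSpec, solve_cell)
from .membrane import MembraneSpec, ion_fluxes, transport_numbers, DEFAULT_CARRIERS
from .speciation import AcidBaseFamily, SpeciationModel, default_families
from .species import SpeciesDB, electron_equivalents, load_species_db

__all__ = ["ChamberNetwork", "CompartmentState", "Geometry", "Feed",
           "SolverSettings", "SimulationConfig", "System", "Trajectory",
           "IntegrationError"]

GAS_SPECIES = (("co2", "co2_aq"), ("ch4", "ch4_aq"), ("h2", "h2_aq"))


class IntegrationError(RuntimeError):
    """Integration aborted; carries the last state for diagnostics."""

    def __init__(self, message: str, t: float | None = None,
                 state: np.ndarray | None = None):
        super().__init__(message)
        self.t = t
        self.state = state


@dataclass
class ChamberNetwork:
    """Reaction network of one chamber: groups, fermentative columns and
    electrode reactions.  Decay columns are generated automatically."""

    groups: Sequence[MicrobialGroup] = ()
    fermentative: Sequence[ReactionSpec] = ()
    electrode: Sequence[ElectrodeReactionSpec] = ()

    def decay_reactions(self) -> list[ReactionSpec]:
        out = []
        for g in self.groups:
            out.append(ReactionSpec(
                name=f"decay_{g.name}", kind="decay",
                stoichiometry={"biomass": Fraction(-1), "inert": Fraction(1)},
                catalyst=g))
        return out


@dataclass
class Geometry:
    V_liq_an: float = 0.2     # L
    V_liq_cat: float = 0.2
    V_gas_an: float = 0.05
    V_gas_cat: float = 0.05


@dataclass
class Feed:
    """One chamber inflow: flow rate (L/day) and liquid-state composition.

    ``composition`` maps liquid state symbols (family totals, strong ions,
    neutrals) to mol/L; the proton inventory of the feed is derived
    automatically from electroneutrality of the stated composition.
    """

    flow: float = 0.0
    composition: Mapping[str, float] = field(default_factory=dict)


@dataclass
class SolverSettings:
    rtol: float = 1e-8
    atol: float = 1e-12
    t_end: float = 200.0            # days
    cadence: float = 0.5            # output interval, days
    ss_tol: float = 1e-6            # steady state: max |dX/dt|/scale, 1/day
    ss_floor: float = 1e-9          # scale floor, mol/L
    chunk: float = 10.0             # steady-state check interval, days
    method: str = "BDF"


@dataclass
class SimulationConfig:
    """Full system definition."""

    liquid_states: Sequence[str]
    anode: ChamberNetwork
    cathode: ChamberNetwork
    geometry: Geometry
    membrane: MembraneSpec
    circuit: CircuitSpec
    feed_an: Feed
    feed_cat: Feed
    T: float = T_REF
    P_total: float = P_TOTAL
    SRT: float = 25.0               # days
    X_max: float = 0.02             # mol-C/L
    k_ret: float = 0.2              # retention half-saturation factor
    kla: float = 200.0              # 1/day
    solver: SolverSettings = field(default_factory=SolverSettings)
    families: Sequence[AcidBaseFamily] | None = None
    db: SpeciesDB | None = None
    initial_an: Mapping[str, float] = field(default_factory=dict)
    initial_cat: Mapping[str, float] = field(default_factory=dict)
    initial_gas_an: Mapping[str, float] | None = None
    initial_gas_cat: Mapping[str, float] | None = None
    initial_biomass: float = 1e-3   # mol-C/L default inoculum per group

    def __post_init__(self) -> None:
        if self.X_max <= 0:
            raise ValueError("X_max must be > 0")
        for feed, V in ((self.feed_an, self.geometry.V_liq_an),
                        (self.feed_cat, self.geometry.V_liq_cat)):
            if feed.flow > 0 and self.SRT < V / feed.flow:
                raise ValueError("SRT must be >= hydraulic retention time")


@dataclass
class CompartmentState:
    """Read-only snapshot of one chamber at one instant."""

    liquid: dict[str, float]
    biomass: dict[str, float]
    gas: dict[str, float]
    V_liq: float
    V_gas: float
    D: float
    X_in: dict[str, float]


# ---------------------------------------------------------------------------


class System:
    """Compiled simulator for one :class:`SimulationConfig`."""

    def __init__(self, config: SimulationConfig):
        self.config = config
        self.db = config.db or load_species_db()
        self.families = list(config.families or default_families(self.db))
        self.spec_model = SpeciationModel(self.families, db=self.db, T=config.T)
        self.family_of = {m.name: (f.total_symbol, f.reference_charge)
                          for f in self.families for m in f.members}
        self.family_members = {f.total_symbol: tuple(m.name for m in f.members)
                               for f in self.families}
        self._fam_zref = {f.total_symbol: f.reference_charge
                          for f in self.families}
        self.P_w = water_vapour_pressure(config.T)

        liq = list(config.liquid_states)
        if "A" not in liq:
            liq = liq + ["A"]
        if "inert" not in liq:
            liq = liq + ["inert"]
        self.liquid_states = liq

        self._compile()
        self._warm_E_an: float | None = None
        self._ph_warm = {"an": None, "cat": None}

    # -- compilation --------------------------------------------------------
    def _compile(self) -> None:
        cfg = self.config
        self.chambers = {}
        names: list[str] = []
        for tag, net in (("an", cfg.anode), ("cat", cfg.cathode)):
            bio = [g.biomass_symbol for g in net.groups]
            local = self.liquid_states + bio
            ferm = list(net.fermentative) + list(net.decay_reactions())
            elec = [e.base for e in net.electrode]
            M_ferm = build_matrix(ferm, local, self.db, self.family_of)
            M_elec = (build_matrix(elec, local, self.db, self.family_of)
                      if elec else np.zeros((len(local), 0)))
            self.chambers[tag] = {
                "net": net, "local": local, "bio": bio,
                "ferm": ferm, "M_ferm": M_ferm, "M_elec": M_elec,
                "offset": len(names),
            }
            names.extend(f"{tag}.{s}" for s in local)
        self.gas_offset = len(names)
        for tag in ("an", "cat"):
            names.extend(f"gas_{tag}.{g}" for g, _ in GAS_SPECIES)
        # cumulative moles vented from each headspace (quadrature states,
        # used by the conservation audits and electron-fate bookkeeping)
        self.vent_offset = len(names)
        for tag in ("an", "cat"):
            names.extend(f"vent_{tag}.{g}" for g, _ in GAS_SPECIES)
        self.state_names = names
        self.index = {n: i for i, n in enumerate(names)}
        self.n_states = len(names)

        # gas-transfer projection columns (liquid side), one per gas species
        self._gas_cols = {}
        for tag in ("an", "cat"):
            local = self.chambers[tag]["local"]
            idx = {s: i for i, s in enumerate(local)}
            cols = []
            for gas, aq in GAS_SPECIES:
                proj = map_species_to_states({aq: Fraction(-1)}, self.db,
                                             self.family_of, None)
                if all(s in idx for s in proj):
                    cols.append([(idx[s], v) for s, v in proj.items()])
                else:       # volatile species not part of this system
                    cols.append(None)
            self._gas_cols[tag] = cols

        # membrane carrier projections onto local states
        self._carrier_proj = {}
        for ion in DEFAULT_CARRIERS:
            if ion not in self.db:
                continue
            proj = map_species_to_states({ion: Fraction(1)}, self.db,
                                         self.family_of, None)
            self._carrier_proj[ion] = proj

        self._fam_syms = [f.total_symbol for f in self.families]

    # -- initial condition ---------------------------------------------------
    def proton_inventory(self, composition: Mapping[str, float]) -> float:
        """Proton-inventory value A consistent with electroneutrality of a
        stated composition (family totals + strong ions)."""
        strong = 0.0
        zref_T = 0.0
        for sym, c in composition.items():
            if sym in self._fam_zref:
                zref_T += self._fam_zref[sym] * c
            elif sym in self.db and sym not in ("A",):
                strong += self.db[sym].charge * c
        return -(strong + zref_T)

    def initial_state(self) -> np.ndarray:
        cfg = self.config
        y = np.zeros(self.n_states)
        for tag, init in (("an", cfg.initial_an), ("cat", cfg.initial_cat)):
            ch = self.chambers[tag]
            off = ch["offset"]
            local = ch["local"]
            comp = dict(init)
            for sym, c in comp.items():
                if sym not in local:
                    raise KeyError(f"initial composition: unknown state {sym!r}")
                y[off + local.index(sym)] = c
            if "A" not in comp:
                y[off + local.index("A")] = self.proton_inventory(comp)
            for g in ch["net"].groups:
                sym = g.biomass_symbol
                if sym not in comp:
                    y[off + local.index(sym)] = cfg.initial_biomass
        p_dry = cfg.P_total - self.P_w
        for k, tag in enumerate(("an", "cat")):
            override = (cfg.initial_gas_an if tag == "an" else cfg.initial_gas_cat)
            if override is None:
                frac = {"co2": 0.30, "ch4": 0.69, "h2": 0.01}
            else:
                tot = sum(override.values())
                frac = {g: override.get(g, 0.0) / tot for g, _ in GAS_SPECIES}
            for j, (g, _) in enumerate(GAS_SPECIES):
                y[self.gas_offset + 3 * k + j] = frac.get(g, 0.0) * p_dry
        return y

    def feed_vector(self, tag: str) -> np.ndarray:
        """Inlet composition over local liquid states, incl. derived A."""
        cfg = self.config
        feed = cfg.feed_an if tag == "an" else cfg.feed_cat
        local = self.chambers[tag]["local"]
        x_in = np.zeros(len(local))
        for sym, c in feed.composition.items():
            if sym not in local:
                raise KeyError(f"feed composition: unknown state {sym!r}")
            x_in[local.index(sym)] = c
        x_in[local.index("A")] = self.proton_inventory(feed.composition)
        return x_in

    # -- chamber snapshot ----------------------------------------------------
    def _chamber_env(self, tag: str, y: np.ndarray) -> tuple[ChamberEnv, np.ndarray]:
        cfg = self.config
        ch = self.chambers[tag]
        off = ch["offset"]
        local = ch["local"]
        vals = y[off:off + len(local)]
        totals = {s: max(float(v), 0.0) for s, v in zip(local, vals)}
        totals["A"] = float(vals[local.index("A")])  # A may be negative

        fam_vec = np.array([totals.get(s, 0.0) for s in self._fam_syms])
        zref_T = sum(self._fam_zref[s] * totals.get(s, 0.0)
                     for s in self._fam_syms)
        strong_eff = -(totals["A"] + zref_T)
        ph = self.spec_model.solve_ph(fam_vec, strong_eff,
                                      warm_start=self._ph_warm[tag])
        self._ph_warm[tag] = ph
        free = self.spec_model.free_concentrations(ph, fam_vec)
        # neutrals and strong ions are their own free species
        for s in local:
            if s in ("A", "inert") or s in self._fam_syms or s in ch["bio"]:
                continue
            free[s] = totals[s]
        V_liq = cfg.geometry.V_liq_an if tag == "an" else cfg.geometry.V_liq_cat
        biomass = {g.name: totals[g.biomass_symbol] for g in ch["net"].groups}
        env = ChamberEnv(totals=totals, free=free, biomass=biomass, pH=ph,
                         V_liq=V_liq, T=cfg.T,
                         family_members=self.family_members)
        return env, vals

    # -- algebraic layer -----------------------------------------------------
    def algebraic(self, y: np.ndarray) -> dict:
        """pH, cell solution and membrane fluxes at a state (no derivatives)."""
        an_env, _ = self._chamber_env("an", y)
        cat_env, _ = self._chamber_env("cat", y)
        cell = solve_cell(an_env, cat_env,
                          self.chambers["an"]["net"].electrode,
                          self.chambers["cat"]["net"].electrode,
                          self.config.circuit, self.db,
                          warm_start=self._warm_E_an)
        self._warm_E_an = cell.E_an
        tn, fluxes = self._membrane_fluxes(an_env, cat_env, cell.I_total)
        return {"an_env": an_env, "cat_env": cat_env, "cell": cell,
                "transport_numbers": tn, "fluxes": fluxes}

    def _membrane_fluxes(self, an_env: ChamberEnv, cat_env: ChamberEnv,
                         I: float) -> tuple[dict, dict]:
        src = {}
        for ion in self._carrier_proj:
            z = self.db[ion].charge
            conc = (an_env.free if z > 0 else cat_env.free).get(ion, 0.0)
            if conc > 0.0:
                src[ion] = conc
        tn = transport_numbers(src, self.config.membrane, self.db)
        fluxes = ion_fluxes(I, tn, self.db) if I != 0.0 else {i: 0.0 for i in tn}
        return tn, fluxes

    # -- right-hand side -----------------------------------------------------
    def rhs(self, t: float, y: np.ndarray) -> np.ndarray:
        cfg = self.config
        if not np.all(np.isfinite(y)):
            raise IntegrationError("non-finite state encountered", t, y)
        try:
            alg = self.algebraic(y)
        except Exception as exc:  # re-raise with state dump
            raise IntegrationError(
                f"algebraic sub-solver failed at t={t:.4f} d: {exc}", t, y
                ) from exc
        dy = np.zeros_like(y)
        cell: CellSolution = alg["cell"]

        for k, tag in enumerate(("an", "cat")):
            ch = self.chambers[tag]
            env: ChamberEnv = alg[f"{tag}_env"]
            off = ch["offset"]
            local = ch["local"]
            n_loc = len(local)
            vals = y[off:off + n_loc]
            V_liq = env.V_liq
            V_gas = cfg.geometry.V_gas_an if tag == "an" else cfg.geometry.V_gas_cat
            feed = cfg.feed_an if tag == "an" else cfg.feed_cat
            D = feed.flow / V_liq if feed.flow > 0 else 0.0

            # reaction rates: fermentative + decay
            r = np.zeros(len(ch["ferm"]))
            for j, rx in enumerate(ch["ferm"]):
                if rx.kind == "decay":
                    r[j] = decay_rate(rx.catalyst,
                                      env.totals[rx.catalyst.biomass_symbol])
                else:
                    X = env.totals[rx.catalyst.biomass_symbol]
                    r[j] = fermentative_rate(rx, env.totals, env.free, X,
                                             env.pH, self.db, cfg.T)
            gen = ch["M_ferm"] @ r

            # electrode reaction rates from the cell solution
            elec = ch["net"].electrode
            if elec:
                r_e = np.array([cell.rates.get(e.name, 0.0) for e in elec])
                gen = gen + ch["M_elec"] @ r_e

            # gas transfer
            q = np.zeros(len(GAS_SPECIES))
            for jg, (gas, aq) in enumerate(GAS_SPECIES):
                col = self._gas_cols[tag][jg]
                if col is None:
                    continue
                p = max(y[self.gas_offset + 3 * k + jg], 0.0)
                S = env.free.get(aq, 0.0)
                q[jg] = gas_transfer_rate(S, p, cfg.kla, self._henry(gas))
                for (i_loc, v) in col:
                    gen[i_loc] += v * q[jg]

            # membrane term (anode loses positive flux, cathode gains)
            sgn = -1.0 if tag == "an" else 1.0
            for ion, fl in alg["fluxes"].items():
                if fl == 0.0:
                    continue
                for sym, v in self._carrier_proj[ion].items():
                    gen[local.index(sym)] += sgn * v * fl / V_liq

            # assemble liquid + biomass derivatives
            x_in = self._feed_cache(tag)
            dloc = gen.copy()
            n_liq = len(self.liquid_states)
            dloc[:n_liq] += D * (x_in[:n_liq] - vals[:n_liq])
            # SRT-governed biomass wasting: an outflow term, so it exists
            # only when the chamber actually has an outflow (D > 0)
            if D > 0.0:
                X_sum = float(np.sum(np.maximum(vals[n_liq:], 0.0)))
                f_ret = 1.0 + cfg.k_ret * X_sum / max(cfg.X_max - X_sum, 1e-12)
                for ib in range(n_liq, n_loc):
                    dloc[ib] -= max(vals[ib], 0.0) * f_ret / cfg.SRT
            dy[off:off + n_loc] = dloc

            # gas phase: constant-pressure headspace with one-way venting
            # (an overpressure valve: no back-flow when net transfer is
            # absorptive, so the vent term is clamped at zero)
            p_dry = cfg.P_total - self.P_w
            qvent = max(float(np.sum(q)), 0.0)
            coef = R_BAR * cfg.T * V_liq / V_gas
            for jg in range(len(GAS_SPECIES)):
                p = max(y[self.gas_offset + 3 * k + jg], 0.0)
                dy[self.gas_offset + 3 * k + jg] = coef * (
                    q[jg] - p * qvent / p_dry)
                # cumulative vented moles of this gas
                dy[self.vent_offset + 3 * k + jg] = (
                    (p / p_dry) * qvent * V_liq)
        return dy

    def _henry(self, gas: str) -> float:
        return _HENRY[gas]

    _feed_vectors: dict | None = None

    def _feed_cache(self, tag: str) -> np.ndarray:
        if self._feed_vectors is None:
            self._feed_vectors = {}
        if tag not in self._feed_vectors:
            self._feed_vectors[tag] = self.feed_vector(tag)
        return self._feed_vectors[tag]

    # -- integration ---------------------------------------------------------
    def integrate(self, t_end: float | None = None, y0: np.ndarray | None = None,
                  cadence: float | None = None) -> "Trajectory":
        cfg = self.config
        s = cfg.solver
        t_end = s.t_end if t_end is None else t_end
        cadence = s.cadence if cadence is None else cadence
        y0 = self.initial_state() if y0 is None else np.asarray(y0, float)
        if t_end <= 0.0:
            return Trajectory(np.array([0.0]), y0[None, :], self)
        t_eval = np.arange(0.0, t_end + 0.5 * cadence, cadence)
        sol = solve_ivp(self.rhs, (0.0, t_end), y0, method=s.method,
                        rtol=s.rtol, atol=s.atol, t_eval=t_eval)
        if not sol.success:
            raise IntegrationError(f"integrator failed: {sol.message}",
                                   sol.t[-1] if len(sol.t) else 0.0,
                                   sol.y[:, -1] if sol.y.size else y0)
        return Trajectory(sol.t, sol.y.T, self)

    def steady_state(self, y0: np.ndarray | None = None
                     ) -> tuple[np.ndarray, dict, bool, float]:
        """Integrate until max |dX/dt| / max(|X|, floor) < ss_tol or t_end.

        Returns ``(state, algebraic snapshot, converged, t_reached)``.
        """
        cfg = self.config
        s = cfg.solver
        y = self.initial_state() if y0 is None else np.asarray(y0, float)
        t = 0.0
        converged = False
        while t < s.t_end - 1e-9:
            step = min(s.chunk, s.t_end - t)
            sol = solve_ivp(self.rhs, (t, t + step), y, method=s.method,
                            rtol=s.rtol, atol=s.atol)
            if not sol.success:
                raise IntegrationError(f"integrator failed: {sol.message}",
                                       sol.t[-1], sol.y[:, -1])
            y = sol.y[:, -1]
            t += step
            dy = self.rhs(t, y)
            scale = np.maximum(np.abs(y), s.ss_floor)
            if float(np.max(np.abs(dy) / scale)) < s.ss_tol:
                converged = True
                break
        return y, self.algebraic(y), converged, t

    # -- audits --------------------------------------------------------------
    def element_inventory(self, y: np.ndarray,
                          elements: Sequence[str] = ("C", "N", "Cl", "Na", "K"),
                          ) -> dict[str, float]:
        """Moles of each element in liquid + biomass + gas, whole system.

        H and O are excluded by default: the solvent is an unmodelled
        reservoir exchanging both freely.
        """
        cfg = self.config
        inv = {el: 0.0 for el in elements}
        gas_formula = {"co2": {"C": 1}, "ch4": {"C": 1}, "h2": {}}
        for k, tag in enumerate(("an", "cat")):
            ch = self.chambers[tag]
            off = ch["offset"]
            local = ch["local"]
            V_liq = cfg.geometry.V_liq_an if tag == "an" else cfg.geometry.V_liq_cat
            V_gas = cfg.geometry.V_gas_an if tag == "an" else cfg.geometry.V_gas_cat
            for i, sym in enumerate(local):
                c = y[off + i]
                if sym == "A":
                    continue
                if sym in self._fam_syms:
                    ref = self.db[self.family_members[sym][-1]]
                    for el in elements:
                        inv[el] += float(ref.element(el)) * c * V_liq
                elif sym in ch["bio"] or sym == "inert":
                    sp = self.db["biomass"]
                    for el in elements:
                        inv[el] += float(sp.element(el)) * c * V_liq
                elif sym in self.db:
                    sp = self.db[sym]
                    for el in elements:
                        inv[el] += float(sp.element(el)) * c * V_liq
            for jg, (gas, _) in enumerate(GAS_SPECIES):
                p = y[self.gas_offset + 3 * k + jg]
                n = p * V_gas / (R_BAR * cfg.T)
                n += y[self.vent_offset + 3 * k + jg]   # vented moles
                for el, cnt in gas_formula[gas].items():
                    if el in inv:
                        inv[el] += cnt * n
        return inv

    def cod_inventory(self, y: np.ndarray) -> float:
        """Electron equivalents in liquid + biomass + gas, mol e-."""
        cfg = self.config
        total = 0.0
        gamma_gas = {"co2": 0.0, "ch4": 8.0, "h2": 2.0}
        for k, tag in enumerate(("an", "cat")):
            ch = self.chambers[tag]
            off = ch["offset"]
            local = ch["local"]
            V_liq = cfg.geometry.V_liq_an if tag == "an" else cfg.geometry.V_liq_cat
            V_gas = cfg.geometry.V_gas_an if tag == "an" else cfg.geometry.V_gas_cat
            for i, sym in enumerate(local):
                c = y[off + i]
                if sym == "A":
                    continue
                if sym in self._fam_syms:
                    g = float(electron_equivalents(
                        self.db[self.family_members[sym][-1]]))
                elif sym in ch["bio"] or sym == "inert":
                    g = float(electron_equivalents(self.db["biomass"]))
                elif sym in self.db:
                    g = float(electron_equivalents(self.db[sym]))
                else:
                    g = 0.0
                total += g * c * V_liq
            for jg, (gas, _) in enumerate(GAS_SPECIES):
                p = y[self.gas_offset + 3 * k + jg]
                n = p * V_gas / (R_BAR * cfg.T)
                n += y[self.vent_offset + 3 * k + jg]   # vented moles
                total += gamma_gas[gas] * n
        return total

    def charge_consistency(self, y: np.ndarray) -> dict[str, float]:
        """Residual between tracked strong-ion charge and the proton
        inventory's implied value, per chamber (eq/L; ~0 when charge closes)."""
        out = {}
        for tag in ("an", "cat"):
            ch = self.chambers[tag]
            off = ch["offset"]
            local = ch["local"]
            strong = 0.0
            A = 0.0
            zref_T = 0.0
            for i, sym in enumerate(local):
                c = y[off + i]
                if sym == "A":
                    A = c
                elif sym in self._fam_syms:
                    zref_T += self._fam_zref[sym] * c
                elif sym in self.db and sym not in ch["bio"] and sym != "inert":
                    strong += self.db[sym].charge * c
            out[tag] = strong + zref_T + A
        return out

    def compartment_state(self, y: np.ndarray, which: str) -> CompartmentState:
        tag = "an" if which.startswith("an") else "cat"
        k = 0 if tag == "an" else 1
        cfg = self.config
        ch = self.chambers[tag]
        off = ch["offset"]
        local = ch["local"]
        liquid = {s: float(y[off + i]) for i, s in enumerate(local)
                  if s not in ch["bio"]}
        biomass = {g.name: float(y[off + local.index(g.biomass_symbol)])
                   for g in ch["net"].groups}
        gas = {g: float(y[self.gas_offset + 3 * k + j])
               for j, (g, _) in enumerate(GAS_SPECIES)}
        V_liq = cfg.geometry.V_liq_an if tag == "an" else cfg.geometry.V_liq_cat
        V_gas = cfg.geometry.V_gas_an if tag == "an" else cfg.geometry.V_gas_cat
        feed = cfg.feed_an if tag == "an" else cfg.feed_cat
        return CompartmentState(liquid=liquid, biomass=biomass, gas=gas,
                                V_liq=V_liq, V_gas=V_gas,
                                D=feed.flow / V_liq,
                                X_in=dict(feed.composition))


_HENRY = {}


def _init_henry() -> None:
    """Henry solubilities (mol/L/bar) derived from the formation energies so
    gas-liquid equilibrium is thermodynamically consistent with speciation."""
    import math
    from .constants import R as R_KJ
    db = load_species_db()
    gas_dgf = {"co2": -394.36, "ch4": -50.79, "h2": 0.0}   # kJ/mol, 1 bar
    aq = {"co2": "co2_aq", "ch4": "ch4_aq", "h2": "h2_aq"}
    for g, dg_gas in gas_dgf.items():
        dG = db[aq[g]].dGf0 - dg_gas
        _HENRY[g] = math.exp(-dG / (R_KJ * T_REF))


_init_henry()


class Trajectory:
    """Time-indexed differential states plus on-demand algebraic states."""

    def __init__(self, t: np.ndarray, y: np.ndarray, system: System):
        self.t = t
        self.y = y
        self.system = system

    def __len__(self) -> int:
        return len(self.t)

    def state(self, i: int = -1) -> np.ndarray:
        return self.y[i]

    def value(self, name: str) -> np.ndarray:
        return self.y[:, self.system.index[name]]

    def annotate(self, stride: int = 1) -> "list[dict]":
        """Recompute the algebraic states at saved times."""
        out = []
        for i in range(0, len(self.t), stride):
            alg = self.system.algebraic(self.y[i])
            out.append({"t": self.t[i],
                        "pH_an": alg["an_env"].pH,
                        "pH_cat": alg["cat_env"].pH,
                        "cell": alg["cell"],
                        "fluxes": alg["fluxes"]})
        return out

    def to_frame(self):
        """Wide DataFrame: one row per time, one column per state."""
        import pandas as pd
        return pd.DataFrame(self.y, index=pd.Index(self.t, name="t_days"),
                            columns=self.system.state_names)

    def electrical_log(self, stride: int = 1):
        """Per-step electrical CSV log: t, potentials, total current and one
        column per reaction's current contribution."""
        import pandas as pd
        rows = []
        for rec in self.annotate(stride):
            cell: CellSolution = rec["cell"]
            row = {"t_days": rec["t"], "E_an_V": cell.E_an,
                   "E_cat_V": cell.E_cat, "I_total_A": cell.I_total}
            row.update({f"I_{k}_A": v for k, v in cell.I_contrib.items()})
            rows.append(row)
        return pd.DataFrame(rows)
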