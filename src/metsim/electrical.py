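"""Electrode kinetics and the cell-level current/potential solve.

Each electroactive reaction is described by Monod substrate terms, ADM1 pH
inhibition, and an activation term driven by the overpotential beyond its
Nernst equilibrium potential; substrate concentrations at the electrode
surface are computed from a steady diffusion-layer balance.  The cell solve
enforces the two fundamental rules of the electrical model: (i) per-reaction
current contributions sum to the total current at each electrode, and
(ii) each electrode has a single potential shared by all of its reactions.

The activation loss uses a half-saturation ("loss factor") form
eta/(KSE + eta) by default, with the Nernst-Monod exponential form
1/(1 + exp(-F eta / R T)) selectable per reaction.
"""

from __future__ import annotations

import math
from dataclasses import dataclass, field
from typing import Callable, Mapping, Sequence

from scipy.optimize import brentq

from .bioreactions import MicrobialGroup, ReactionSpec, monod, ph_inhibition
from .constants import F, R_J, SECONDS_PER_DAY, T_REF
from .species import SpeciesDB
from .thermo import CONC_FLOOR, nernst_potential


def _nernst_compiled(spec: "ElectrodeReactionSpec", conc: Mapping[str, float],
                     db: SpeciesDB, T: float) -> float:
    """Nernst potential via a per-reaction compiled term list (identical to
    :func:`metsim.thermo.nernst_potential`, hot-path form)."""
    cache = spec.__dict__.get("_nernst_cache")
    if cache is None or cache[0] != T:
        hr = spec.base.half_reaction
        terms = [(nm, float(nu)) for nm, nu in hr.stoich.items()
                 if db[nm].role == "aqueous"]
        E0 = hr.standard_potential(T)
        cache = (T, E0, terms, R_J * T / (hr.n_electrons * F))
        spec.__dict__["_nernst_cache"] = cache
    _, E0, terms, rt_nf = cache
    s = 0.0
    for nm, nu in terms:
        a = conc.get(nm, CONC_FLOOR)
        s += nu * math.log(a if a > CONC_FLOOR else CONC_FLOOR)
    return E0 - rt_nf * s

__all__ = ["ElectrodeReactionSpec", "CircuitSpec", "CellSolution",
           "ChamberEnv", "surface_concentration", "reaction_current",
           "solve_cell", "CellSolveError"]

_E_SPAN = 3.0      # bracket width above/below the zero-current potential, V
_I_FLOOR = 1e-6    # current scale floor for relative residuals, A


class CellSolveError(RuntimeError):
    """Cell solve failed; message carries bracketing diagnostics."""


@dataclass
class ElectrodeReactionSpec:
    """An electroactive reaction at one electrode.

    KSE       half-saturation constant for the activation overpotential, V
    k_m       external mass-transfer coefficient of the diffusing substrate, m/day
    area      electrode area, m2
    activation  'monod' (eta/(KSE+eta)) or 'nernst-monod'
    """

    base: ReactionSpec
    KSE: float
    k_m: float
    area: float
    activation: str = "monod"

    def __post_init__(self) -> None:
        if self.base.kind not in ("electrode_anodic", "electrode_cathodic"):
            raise ValueError(f"{self.base.name}: not an electrode reaction")
        if self.KSE <= 0:
            raise ValueError(f"{self.base.name}: KSE must be > 0")
        if self.k_m <= 0:
            raise ValueError(f"{self.base.name}: k_m must be > 0")
        if self.activation not in ("monod", "nernst-monod"):
            raise ValueError(f"{self.base.name}: unknown activation model")

    @property
    def name(self) -> str:
        return self.base.name

    @property
    def group(self) -> MicrobialGroup:
        return self.base.catalyst

    @property
    def anodic(self) -> bool:
        return self.base.kind == "electrode_anodic"

    @property
    def diffusing(self) -> str | None:
        """State symbol of the diffusion-limited (primary) substrate."""
        return self.base.substrates[0] if self.base.substrates else None


@dataclass
class CircuitSpec:
    """External circuit: MFC (load resistor) or MEC (applied voltage)."""

    mode: str                 # 'MFC' | 'MEC'
    R_ext: float = 0.0        # ohm
    V_app: float = 0.0        # V (MEC)
    R_int: float = 0.0        # ohm, lumped internal (solution+membrane+contacts)

    def __post_init__(self) -> None:
        if self.mode not in ("MFC", "MEC"):
            raise ValueError(f"circuit mode must be MFC or MEC, got {self.mode!r}")
        if self.R_ext < 0 or self.R_int < 0 or self.V_app < 0:
            raise ValueError("resistances and applied voltage must be >= 0")
        if self.mode == "MFC" and self.R_ext <= 0:
            raise ValueError("MFC requires R_ext > 0")

    @property
    def R_total(self) -> float:
        return self.R_ext + self.R_int


@dataclass
class ChamberEnv:
    """Snapshot of one chamber as seen by the electrode kinetics."""

    totals: Mapping[str, float]          # state symbol -> mol/L
    free: Mapping[str, float]            # species name -> mol/L
    biomass: Mapping[str, float]         # group name -> mol-C/L
    pH: float
    V_liq: float                         # L
    T: float = T_REF
    family_members: Mapping[str, tuple[str, ...]] = field(default_factory=dict)


@dataclass
class CellSolution:
    """Anode/cathode potentials, total current and per-reaction partition."""

    E_an: float                          # V vs SHE
    E_cat: float                         # V vs SHE
    I_total: float                       # A
    I_contrib: dict[str, float]          # reaction name -> A
    eta_act: dict[str, float]            # reaction name -> V (>= 0)
    S_surf: dict[str, float]             # reaction name -> mol/L (primary substrate)
    rates: dict[str, float]              # reaction name -> mol/L/day (volumetric)

    def current_sum_residual(self, anodic_names: Sequence[str],
                             cathodic_names: Sequence[str]) -> float:
        """max relative deviation of per-electrode current sums from I_total."""
        s_an = sum(self.I_contrib.get(n, 0.0) for n in anodic_names)
        s_cat = sum(self.I_contrib.get(n, 0.0) for n in cathodic_names)
        scale = max(abs(self.I_total), _I_FLOOR)
        return max(abs(s_an - self.I_total), abs(s_cat - self.I_total)) / scale


def surface_concentration(S_bulk: float, demand: Callable[[float], float],
                          k_m: float, area: float) -> float:
    """Steady diffusion-layer substrate concentration at the electrode.

    Solves k_m * A * 1000 * (S_bulk - S_surf) = demand(S_surf) for
    S_surf in [0, S_bulk]; ``demand`` is the consumption rate in mol/day as
    a non-decreasing function of the surface concentration.
    """
    if S_bulk <= 0.0:
        return 0.0
    supply = k_m * area * 1000.0  # L/day exchange coefficient

    def g(S: float) -> float:
        return supply * (S_bulk - S) - demand(S)

    if g(S_bulk) >= 0.0:          # kinetic demand below diffusive capacity
        return S_bulk
    return brentq(g, 0.0, S_bulk, xtol=1e-16, rtol=8.9e-16)


def _activation_term(spec: ElectrodeReactionSpec, eta: float, T: float) -> float:
    if eta <= 0.0:
        return 0.0
    if spec.activation == "monod":
        return eta / (spec.KSE + eta)
    return 1.0 / (1.0 + math.exp(-F * eta / (R_J * T)))


def reaction_current(spec: ElectrodeReactionSpec, E_electrode: float,
                     env: ChamberEnv, db: SpeciesDB,
                     ) -> tuple[float, float, float, float]:
    """Current of one electrode reaction at a given electrode potential.

    Returns ``(I in A, eta_act in V, S_surf in mol/L, rate in mol/L/day)``.
    The overpotential is truncated at zero (no reverse current: each
    direction is its own reaction), and the surface concentration is solved
    simultaneously with the rate law.
    """
    if not math.isfinite(E_electrode):
        raise ValueError("electrode potential must be finite")
    g = spec.group
    X = env.biomass.get(g.name, 0.0)
    if X <= 0.0:
        return 0.0, 0.0, _bulk_substrate(spec, env), 0.0
    sign = 1.0 if spec.anodic else -1.0
    i_ph = ph_inhibition(env.pH, g.pH_LL, g.pH_UL)
    n_e = abs(float(spec.base.n_electrons))
    S_bulk = _bulk_substrate(spec, env)

    # secondary substrates at bulk concentration
    aux = 1.0
    for s in (spec.base.substrates[1:] if spec.base.substrates else ()):
        aux *= monod(env.totals.get(s, env.free.get(s, 0.0)), g.K_S.get(s, 0.0))

    def rate_at(S_surf: float) -> tuple[float, float]:
        conc = _surface_conc_map(spec, env, S_surf, S_bulk)
        E_n = _nernst_compiled(spec, conc, db, env.T)
        eta = sign * (E_electrode - E_n)
        if eta <= 0.0:
            return 0.0, 0.0
        r = g.k_max * X * aux * i_ph * _activation_term(spec, eta, env.T)
        if spec.diffusing is not None:
            r *= monod(S_surf, g.K_S.get(spec.diffusing, 0.0))
        return r, eta

    if spec.diffusing is None or S_bulk <= 0.0:
        rate, eta = rate_at(S_bulk)
        if spec.diffusing is not None and S_bulk <= 0.0:
            rate = 0.0
        S_surf = S_bulk
    else:
        demand = lambda S: rate_at(S)[0] * env.V_liq
        S_surf = surface_concentration(S_bulk, demand, spec.k_m, spec.area)
        rate, eta = rate_at(S_surf)
    I = n_e * F * rate * env.V_liq / SECONDS_PER_DAY
    return I, eta, S_surf, rate


def _bulk_substrate(spec: ElectrodeReactionSpec, env: ChamberEnv) -> float:
    s = spec.diffusing
    if s is None:
        return 0.0
    return max(env.totals.get(s, env.free.get(s, 0.0)), 0.0)


def _surface_conc_map(spec: ElectrodeReactionSpec, env: ChamberEnv,
                      S_surf: float, S_bulk: float) -> Mapping[str, float]:
    """Free concentrations with the diffusing substrate scaled to the surface."""
    s = spec.diffusing
    if s is None or S_bulk <= 0.0 or S_surf >= S_bulk:
        return env.free
    ratio = max(S_surf / S_bulk, CONC_FLOOR)
    conc = dict(env.free)
    for member in env.family_members.get(s, (s,)):
        if member in conc:
            conc[member] *= ratio
    if s in conc:
        conc[s] = S_surf
    return conc


def _electrode_current(E: float, specs: Sequence[ElectrodeReactionSpec],
                       env: ChamberEnv, db: SpeciesDB) -> float:
    return sum(reaction_current(sp, E, env, db)[0] for sp in specs)


def _zero_current_potential(specs: Sequence[ElectrodeReactionSpec],
                            env: ChamberEnv, db: SpeciesDB,
                            anodic: bool) -> float | None:
    """Onset potential: min (anode) / max (cathode) of the Nernst potentials
    of reactions with active biomass and substrate."""
    pots = []
    for sp in specs:
        if env.biomass.get(sp.group.name, 0.0) <= 0.0:
            continue
        if sp.diffusing is not None and _bulk_substrate(sp, env) <= 0.0:
            continue
        E_n = nernst_potential(sp.base.half_reaction, env.free, db, env.T)
        pots.append(E_n)
    if not pots:
        return None
    return min(pots) if anodic else max(pots)


def solve_cell(an_env: ChamberEnv, cat_env: ChamberEnv,
               anodic: Sequence[ElectrodeReactionSpec],
               cathodic: Sequence[ElectrodeReactionSpec],
               circuit: CircuitSpec, db: SpeciesDB,
               warm_start: float | None = None) -> CellSolution:
    """Solve for the unique (E_an, E_cat, I_total) closing the circuit.

    The problem collapses to one scalar equation in the anode potential:
    given E_an, the total current is I = I_an(E_an), the cathode potential
    follows from circuit closure (MFC: E_cat = E_an + I R; MEC:
    E_cat = E_an - V_app + I R), and the residual I_cat(E_cat) - I is
    strictly decreasing in E_an.  A warm start narrows the bracket.
    """
    R_tot = circuit.R_total

    E_an0 = _zero_current_potential(anodic, an_env, db, anodic=True)
    E_cat0 = _zero_current_potential(cathodic, cat_env, db, anodic=False)

    def open_circuit() -> CellSolution:
        ea = E_an0 if E_an0 is not None else 0.0
        if circuit.mode == "MEC":
            ec = ea - circuit.V_app
        else:
            ec = E_cat0 if E_cat0 is not None else ea
        return _assemble(ea, ec, an_env, cat_env, anodic, cathodic, db)

    if E_an0 is None or E_cat0 is None:
        return open_circuit()
    driving = (circuit.V_app - (E_an0 - E_cat0) if circuit.mode == "MEC"
               else E_cat0 - E_an0)
    if driving <= 0.0:
        return open_circuit()

    def cat_potential(E_an: float, I: float) -> float:
        if circuit.mode == "MEC":
            return E_an - circuit.V_app + I * R_tot
        return E_an + I * R_tot

    def residual(E_an: float) -> float:
        I = _electrode_current(E_an, anodic, an_env, db)
        E_cat = cat_potential(E_an, I)
        return _electrode_current(E_cat, cathodic, cat_env, db) - I

    lo, hi = E_an0, E_an0 + _E_SPAN
    if warm_start is not None and lo < warm_start < hi:
        wlo, whi = max(lo, warm_start - 0.02), min(hi, warm_start + 0.02)
        try:
            rlo, rhi = residual(wlo), residual(whi)
        except (ValueError, OverflowError):
            rlo = rhi = None
        if rlo is not None and rlo >= 0.0 >= rhi:
            E_an = brentq(residual, wlo, whi, xtol=1e-12, rtol=8.9e-16)
            return _finish(E_an, cat_potential, an_env, cat_env, anodic,
                           cathodic, db)
    rlo, rhi = residual(lo), residual(hi)
    if rlo < 0.0:
        # zero-current edge: residual already negative at onset
        return open_circuit()
    if rhi > 0.0:
        raise CellSolveError(
            f"no root: residual({lo:.3f})={rlo:.3e}, residual({hi:.3f})={rhi:.3e}")
    E_an = brentq(residual, lo, hi, xtol=1e-12, rtol=8.9e-16)
    return _finish(E_an, cat_potential, an_env, cat_env, anodic, cathodic, db)


def _finish(E_an, cat_potential, an_env, cat_env, anodic, cathodic, db):
    I = _electrode_current(E_an, anodic, an_env, db)
    E_cat = cat_potential(E_an, I)
    return _assemble(E_an, E_cat, an_env, cat_env, anodic, cathodic, db)


def _assemble(E_an: float, E_cat: float, an_env: ChamberEnv,
              cat_env: ChamberEnv, anodic, cathodic, db) -> CellSolution:
    contrib: dict[str, float] = {}
    etas: dict[str, float] = {}
    surf: dict[str, float] = {}
    rates: dict[str, float] = {}
    I_an = I_cat = 0.0
    for sp in anodic:
        I, eta, S, r = reaction_current(sp, E_an, an_env, db)
        contrib[sp.name] = I
        etas[sp.name] = eta
        surf[sp.name] = S
        rates[sp.name] = r
        I_an += I
    for sp in cathodic:
        I, eta, S, r = reaction_current(sp, E_cat, cat_env, db)
        contrib[sp.name] = I
        etas[sp.name] = eta
        surf[sp.name] = S
        rates[sp.name] = r
        I_cat += I
    # rule (i): both electrode sums are the observed total current
    I_total = 0.5 * (I_an + I_cat)
    return CellSolution(E_an=E_an, E_cat=E_cat, I_total=I_total,
                        I_contrib=contrib, eta_act=etas, S_surf=surf,
                        rates=rates)
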