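"""Structured-config serialisation: reaction networks and simulation setups.

Networks round-trip losslessly through plain YAML: stoichiometric
coefficients are written as exact rational strings, kinetic parameters as
floats.  Simulation configs serialise everything except the species database
and acid-base families, which are reconstructed from the packaged tables.
"""

from __future__ import annotations

from dataclasses import asdict
from fractions import Fraction
from typing import Any

import yaml

from .bioreactions import MicrobialGroup, ReactionSpec
from .electrical import CircuitSpec, ElectrodeReactionSpec
from .membrane import MembraneSpec
from .reactor import (ChamberNetwork, Feed, Geometry, SimulationConfig,
                      SolverSettings)
from .species import SpeciesDB, load_species_db
from .thermo import HalfReaction

__all__ = ["network_to_dict", "network_from_dict", "save_network",
           "load_network", "config_to_dict", "config_from_dict",
           "save_config", "load_config"]


def _stoich_out(st) -> dict[str, str]:
    return {k: str(Fraction(v)) for k, v in st.items()}


def _stoich_in(d) -> dict[str, Fraction]:
    return {k: Fraction(v) for k, v in d.items()}


def _group_to_dict(g: MicrobialGroup) -> dict:
    return {"name": g.name, "biomass_symbol": g.biomass_symbol,
            "k_max": g.k_max, "K_S": dict(g.K_S), "pH_LL": g.pH_LL,
            "pH_UL": g.pH_UL, "k_dec": g.k_dec, "f_an": g.f_an}


def _reaction_to_dict(rx: ReactionSpec) -> dict:
    out = {"name": rx.name, "kind": rx.kind,
           "stoichiometry": _stoich_out(rx.stoichiometry),
           "catalyst": rx.catalyst.name if rx.catalyst else None,
           "substrates": list(rx.substrates), "dG_min": rx.dG_min}
    if rx.catabolic is not None:
        out["catabolic"] = _stoich_out(rx.catabolic)
    if rx.half_reaction is not None:
        hr = rx.half_reaction
        out["half_reaction"] = {"name": hr.name,
                                "stoich": _stoich_out(hr.stoich),
                                "n_electrons": hr.n_electrons}
    return out


def network_to_dict(net: ChamberNetwork) -> dict:
    return {
        "groups": [_group_to_dict(g) for g in net.groups],
        "fermentative": [_reaction_to_dict(r) for r in net.fermentative],
        "electrode": [{**_reaction_to_dict(e.base), "KSE": e.KSE,
                       "k_m": e.k_m, "area": e.area,
                       "activation": e.activation}
                      for e in net.electrode],
    }


def network_from_dict(d: dict, db: SpeciesDB | None = None) -> ChamberNetwork:
    db = db or load_species_db()
    groups = {g["name"]: MicrobialGroup(**{**g, "K_S": dict(g["K_S"])})
              for g in d["groups"]}

    def reaction(rd: dict) -> ReactionSpec:
        hr = None
        if "half_reaction" in rd:
            h = rd["half_reaction"]
            hr = HalfReaction(name=h["name"], stoich=_stoich_in(h["stoich"]),
                              n_electrons=h["n_electrons"], _db=db)
        return ReactionSpec(
            name=rd["name"], kind=rd["kind"],
            stoichiometry=_stoich_in(rd["stoichiometry"]),
            catalyst=groups[rd["catalyst"]] if rd.get("catalyst") else None,
            substrates=list(rd.get("substrates", ())),
            half_reaction=hr,
            catabolic=_stoich_in(rd["catabolic"]) if "catabolic" in rd else None,
            dG_min=rd.get("dG_min", 0.0))

    electrode = [ElectrodeReactionSpec(
        base=reaction(ed), KSE=ed["KSE"], k_m=ed["k_m"], area=ed["area"],
        activation=ed.get("activation", "monod")) for ed in d["electrode"]]
    return ChamberNetwork(groups=list(groups.values()),
                          fermentative=[reaction(r) for r in d["fermentative"]],
                          electrode=electrode)


def save_network(net: ChamberNetwork, path) -> None:
    with open(path, "w") as fh:
        yaml.safe_dump(network_to_dict(net), fh, sort_keys=False)


def load_network(path, db: SpeciesDB | None = None) -> ChamberNetwork:
    with open(path) as fh:
        return network_from_dict(yaml.safe_load(fh), db)


def config_to_dict(cfg: SimulationConfig) -> dict:
    return {
        "schema_version": 1,
        "liquid_states": list(cfg.liquid_states),
        "anode": network_to_dict(cfg.anode),
        "cathode": network_to_dict(cfg.cathode),
        "geometry": asdict(cfg.geometry),
        "membrane": {"type_name": cfg.membrane.type_name,
                     "area": cfg.membrane.area,
                     "permeability_overrides":
                         dict(cfg.membrane.permeability_overrides)},
        "circuit": asdict(cfg.circuit),
        "feed_an": {"flow": cfg.feed_an.flow,
                    "composition": dict(cfg.feed_an.composition)},
        "feed_cat": {"flow": cfg.feed_cat.flow,
                     "composition": dict(cfg.feed_cat.composition)},
        "T": cfg.T, "P_total": cfg.P_total, "SRT": cfg.SRT,
        "X_max": cfg.X_max, "k_ret": cfg.k_ret, "kla": cfg.kla,
        "solver": asdict(cfg.solver),
        "initial_an": dict(cfg.initial_an),
        "initial_cat": dict(cfg.initial_cat),
        "initial_gas_an": dict(cfg.initial_gas_an) if cfg.initial_gas_an else None,
        "initial_gas_cat": dict(cfg.initial_gas_cat) if cfg.initial_gas_cat else None,
        "initial_biomass": cfg.initial_biomass,
    }


def config_from_dict(d: dict, db: SpeciesDB | None = None) -> SimulationConfig:
    if d.get("schema_version") != 1:
        raise ValueError(f"unsupported config schema {d.get('schema_version')!r}")
    db = db or load_species_db()
    return SimulationConfig(
        liquid_states=list(d["liquid_states"]),
        anode=network_from_dict(d["anode"], db),
        cathode=network_from_dict(d["cathode"], db),
        geometry=Geometry(**d["geometry"]),
        membrane=MembraneSpec(**d["membrane"]),
        circuit=CircuitSpec(**d["circuit"]),
        feed_an=Feed(**d["feed_an"]),
        feed_cat=Feed(**d["feed_cat"]),
        T=d["T"], P_total=d["P_total"], SRT=d["SRT"], X_max=d["X_max"],
        k_ret=d["k_ret"], kla=d["kla"],
        solver=SolverSettings(**d["solver"]),
        initial_an=d["initial_an"], initial_cat=d["initial_cat"],
        initial_gas_an=d["initial_gas_an"],
        initial_gas_cat=d["initial_gas_cat"],
        initial_biomass=d["initial_biomass"], db=db)


def save_config(cfg: SimulationConfig, path) -> None:
    with open(path, "w") as fh:
        yaml.safe_dump(config_to_dict(cfg), fh, sort_keys=False)


def load_config(path, db: SpeciesDB | None = None) -> SimulationConfig:
    with open(path) as fh:
        return config_from_dict(yaml.safe_load(fh), db)
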