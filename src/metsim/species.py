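"""Chemical species: thermodynamic, charge and transport properties.

The packaged database (``data/species.tsv``) is the single source of record
for standard Gibbs energies / enthalpies of formation, limiting molar
conductivities and relative membrane permeabilities of every species used by
the shipped case studies.  Values are cited per row in the file.
"""

from __future__ import annotations

import importlib.resources
from dataclasses import dataclass, field
from fractions import Fraction
from typing import Mapping

__all__ = ["ChemSpecies", "SpeciesDB", "load_species_db", "electron_equivalents"]

_COLUMNS = ["name", "charge", "dGf0", "dHf0", "elements", "role",
            "lambda0", "perm", "source"]

_ROLES = {"solvent", "aqueous", "biomass", "electron"}


@dataclass(frozen=True)
class ChemSpecies:
    """A chemical entity with thermodynamic, charge and transport properties."""

    name: str
    charge: int
    dGf0: float                       # kJ/mol at 298.15 K
    dHf0: float | None                # kJ/mol; None if unknown
    elements: Mapping[str, Fraction] = field(default_factory=dict, hash=False)
    role: str = "aqueous"
    molar_conductivity: float = 0.0   # S*cm2/mol
    membrane_permeability: float = 0.0  # relative, dimensionless

    def __post_init__(self) -> None:
        if self.role not in _ROLES:
            raise ValueError(f"unknown phase role {self.role!r} for {self.name}")
        if self.molar_conductivity < 0:
            raise ValueError(f"{self.name}: molar conductivity must be >= 0")
        if self.membrane_permeability < 0:
            raise ValueError(f"{self.name}: membrane permeability must be >= 0")

    def element(self, symbol: str) -> Fraction:
        return self.elements.get(symbol, Fraction(0))


SpeciesDB = dict[str, ChemSpecies]


def _parse_elements(text: str) -> dict[str, Fraction]:
    out: dict[str, Fraction] = {}
    text = text.strip()
    if not text:
        return out
    for item in text.split(","):
        sym, _, count = item.partition(":")
        if not sym or not count:
            raise ValueError(f"malformed element entry {item!r}")
        out[sym.strip()] = Fraction(count.strip())
    return out


def load_species_db(path=None) -> SpeciesDB:
    """Load the species database (packaged table by default).

    The parser is strict: the header must list exactly the documented
    columns, every row must have a value for each, and unknown columns are
    rejected.
    """
    if path is None:
        source = importlib.resources.files("metsim.data").joinpath("species.tsv")
        text = source.read_text()
    else:
        with open(path) as fh:
            text = fh.read()
    lines = [ln for ln in text.splitlines() if ln.strip() and not ln.startswith("#")]
    header = lines[0].split("\t")
    if header != _COLUMNS:
        unknown = [c for c in header if c not in _COLUMNS]
        raise ValueError(
            f"species table header mismatch; unknown/unexpected columns {unknown!r},"
            f" expected {_COLUMNS!r}")
    db: SpeciesDB = {}
    for ln in lines[1:]:
        parts = ln.split("\t")
        if len(parts) != len(_COLUMNS):
            raise ValueError(f"species row has {len(parts)} fields, expected "
                             f"{len(_COLUMNS)}: {ln!r}")
        row = dict(zip(_COLUMNS, parts))
        sp = ChemSpecies(
            name=row["name"],
            charge=int(row["charge"]),
            dGf0=float(row["dGf0"]),
            dHf0=float(row["dHf0"]) if row["dHf0"].strip() else None,
            elements=_parse_elements(row["elements"]),
            role=row["role"],
            molar_conductivity=float(row["lambda0"]),
            membrane_permeability=float(row["perm"]),
        )
        if sp.name in db:
            raise ValueError(f"duplicate species {sp.name}")
        db[sp.name] = sp
    return db


def electron_equivalents(sp: ChemSpecies) -> Fraction:
    """Electron equivalents of a species relative to the reference states
    CO2 / H2O / NH4+ / Cl- (the COD bookkeeping currency).

    gamma = 4 C + H - 2 O - 3 N - Cl + Na + K - z.  Examples: acetate 8,
    H2 2, CH4 8, NH4+ 0, Na+ 0, ClO4- -8 (it *accepts* 8 electrons), e- 1.
    """
    return (4 * sp.element("C") + sp.element("H") - 2 * sp.element("O")
            - 3 * sp.element("N") - sp.element("Cl") + sp.element("Na")
            + sp.element("K") - sp.charge)
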