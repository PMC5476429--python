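"""Sample materials: stoichiometric compounds and the element-level physics
parameters consumed by the Monte Carlo engine.

A :class:`Material` is a stoichiometric formula (fractional counts allowed, so
a partially osmium-stained lipid is a first-class material) plus a mass
density.  From those two ingredients everything the scattering physics needs
is derived: formula mass, element weight fractions, per-element number
densities, and mean ionization potentials.
"""

from __future__ import annotations

import json
from dataclasses import dataclass, field
from pathlib import Path
from typing import Mapping

AVOGADRO = 6.02214076e23  # atoms/mol

#: Standard atomic weights (IUPAC 2021, conventional values), g/mol.
ATOMIC_MASS: dict[str, float] = {
    "H": 1.008,
    "He": 4.0026,
    "Li": 6.94,
    "Be": 9.0122,
    "B": 10.81,
    "C": 12.011,
    "N": 14.007,
    "O": 15.999,
    "F": 18.998,
    "Na": 22.990,
    "Mg": 24.305,
    "Al": 26.982,
    "Si": 28.085,
    "P": 30.974,
    "S": 32.06,
    "Cl": 35.45,
    "K": 39.098,
    "Ca": 40.078,
    "Fe": 55.845,
    "Cu": 63.546,
    "Zn": 65.38,
    "Ga": 69.723,
    "Os": 190.23,
    "Ir": 192.22,
    "Pt": 195.084,
    "Au": 196.967,
    "Pb": 207.2,
    "U": 238.029,
}

ATOMIC_NUMBER: dict[str, int] = {
    "H": 1, "He": 2, "Li": 3, "Be": 4, "B": 5, "C": 6, "N": 7, "O": 8,
    "F": 9, "Na": 11, "Mg": 12, "Al": 13, "Si": 14, "P": 15, "S": 16,
    "Cl": 17, "K": 19, "Ca": 20, "Fe": 26, "Cu": 29, "Zn": 30, "Ga": 31,
    "Os": 76, "Ir": 77, "Pt": 78, "Au": 79, "Pb": 82, "U": 92,
}


class InvalidMaterialError(ValueError):
    """Raised for empty/ill-formed stoichiometries or non-physical densities."""


@dataclass(frozen=True)
class ElementSpec:
    """One chemical element: symbol, atomic number Z and standard atomic mass."""

    symbol: str
    Z: int
    atomic_mass: float  # g/mol

    def __post_init__(self) -> None:
        if self.Z < 1:
            raise ValueError(f"atomic number must be >= 1, got {self.Z}")
        if self.atomic_mass <= 0:
            raise ValueError("atomic mass must be positive")


def element(symbol: str) -> ElementSpec:
    """Look up an :class:`ElementSpec` from the embedded standard tables."""
    try:
        return ElementSpec(symbol, ATOMIC_NUMBER[symbol], ATOMIC_MASS[symbol])
    except KeyError as exc:
        raise KeyError(f"element {symbol!r} is not tabulated") from exc


@dataclass(frozen=True)
class Material:
    """A compound: formula-unit stoichiometry plus bulk mass density.

    Parameters
    ----------
    name:
        Free-form label, e.g. ``"epoxy"``.
    stoichiometry:
        Element symbol -> atoms per formula unit.  Counts may be fractional
        (partial staining); they must be non-negative with at least one > 0.
    mass_density:
        Bulk density in g/cm^3.
    """

    name: str
    stoichiometry: Mapping[str, float] = field(default_factory=dict)
    mass_density: float = 1.0

    def __post_init__(self) -> None:
        stoich = {s: float(c) for s, c in self.stoichiometry.items() if c != 0}
        if not stoich or all(c <= 0 for c in stoich.values()):
            raise InvalidMaterialError(
                f"material {self.name!r} needs at least one element with count > 0"
            )
        if any(c < 0 for c in stoich.values()):
            raise InvalidMaterialError("stoichiometric counts must be >= 0")
        for sym in stoich:
            if sym not in ATOMIC_MASS:
                raise InvalidMaterialError(f"element {sym!r} is not tabulated")
        if self.mass_density <= 0:
            raise InvalidMaterialError("mass density must be positive")
        object.__setattr__(self, "stoichiometry", stoich)

    @property
    def elements(self) -> list[ElementSpec]:
        return [element(sym) for sym in self.stoichiometry]


def formula_mass(material: Material) -> float:
    """Mass of one formula unit, g/mol."""
    return sum(
        count * ATOMIC_MASS[sym] for sym, count in material.stoichiometry.items()
    )


def weight_fraction(material: Material, elem: ElementSpec | str) -> float:
    """Mass fraction of ``elem`` in ``material`` (0 if absent)."""
    sym = elem if isinstance(elem, str) else elem.symbol
    if sym not in ATOMIC_MASS:
        raise KeyError(f"element {sym!r} is not tabulated")
    count = material.stoichiometry.get(sym, 0.0)
    if count == 0.0:
        return 0.0
    return count * ATOMIC_MASS[sym] / formula_mass(material)


def number_density(material: Material, elem: ElementSpec | str) -> float:
    """Atoms of ``elem`` per cm^3 of bulk material (0 if absent)."""
    sym = elem if isinstance(elem, str) else elem.symbol
    count = material.stoichiometry.get(sym, 0.0)
    if count == 0.0:
        return 0.0
    return material.mass_density * AVOGADRO * count / formula_mass(material)


def mean_ionization_potential(Z: int) -> float:
    """Mean ionization potential J in eV (Berger-Seltzer parameterization).

    J = 11.5 Z for Z < 13, else J = 9.76 Z + 58.5 Z^(-0.19).
    """
    if Z < 1:
        raise ValueError(f"atomic number must be >= 1, got {Z}")
    if Z < 13:
        return 11.5 * Z
    return 9.76 * Z + 58.5 * Z ** (-0.19)


# ---------------------------------------------------------------------------
# Built-in registry
# ---------------------------------------------------------------------------

#: Default mass densities, g/cm^3 (user-overridable; literature-range values).
DEFAULT_DENSITIES = {
    "gold": 19.32,
    "epoxy": 1.20,
    "pt_tetrakis": 1.30,
    "lecithin": 1.05,
}

#: Lecithin, a representative membrane lipid (before any osmium stain).
LECITHIN_STOICHIOMETRY = {"C": 42.0, "H": 80.0, "N": 1.0, "O": 8.0, "P": 1.0}

#: Stained-lipid density interpolates linearly from lecithin to this at x_os=1.
STAINED_LIPID_DENSITY_AT_1 = 1.40


def make_stained_lipid(x_os: float, mass_density: float | None = None) -> Material:
    """Osmium-stained lecithin with ``x_os`` Os atoms per lipid molecule.

    ``x_os = 1`` is the fully stained membrane model (~20 wt% Os); fractional
    values model partial staining.  Unless overridden, the density
    interpolates linearly between 1.05 (unstained) and 1.40 (x_os = 1) and
    continues on the same line above 1.
    """
    if x_os < 0:
        raise ValueError(f"x_os must be >= 0, got {x_os}")
    if mass_density is None:
        rho0 = DEFAULT_DENSITIES["lecithin"]
        mass_density = rho0 + (STAINED_LIPID_DENSITY_AT_1 - rho0) * x_os
    stoich = dict(LECITHIN_STOICHIOMETRY)
    if x_os > 0:
        stoich["Os"] = float(x_os)
    return Material(f"lecithin_os{x_os:g}", stoich, mass_density)


def _registry() -> dict[str, Material]:
    return {
        "gold": Material("gold", {"Au": 1}, DEFAULT_DENSITIES["gold"]),
        "epoxy": Material(
            "epoxy", {"C": 21, "H": 25, "O": 5}, DEFAULT_DENSITIES["epoxy"]
        ),
        # Tetrakis(triphenylphosphine)platinum, Pt[(C6H5)3P]4 = C72H60P4Pt
        "pt_tetrakis": Material(
            "pt_tetrakis",
            {"C": 72, "H": 60, "P": 4, "Pt": 1},
            DEFAULT_DENSITIES["pt_tetrakis"],
        ),
        "lecithin": Material(
            "lecithin", LECITHIN_STOICHIOMETRY, DEFAULT_DENSITIES["lecithin"]
        ),
    }


REGISTRY_KEYS = ("gold", "epoxy", "pt_tetrakis", "lecithin")


def get_material(name: str) -> Material:
    """Fetch a built-in material by registry key."""
    reg = _registry()
    try:
        return reg[name]
    except KeyError as exc:
        raise KeyError(
            f"unknown material {name!r}; built-ins: {sorted(reg)}"
        ) from exc


# ---------------------------------------------------------------------------
# JSON I/O
# ---------------------------------------------------------------------------


def to_json_dict(material: Material) -> dict:
    return {
        "name": material.name,
        "formula": dict(material.stoichiometry),
        "density_g_cm3": material.mass_density,
    }


def from_json_dict(d: Mapping) -> Material:
    return Material(d["name"], d["formula"], d["density_g_cm3"])


def save_material(material: Material, path: str | Path) -> None:
    Path(path).write_text(json.dumps(to_json_dict(material), indent=2))


def load_material(path: str | Path) -> Material:
    return from_json_dict(json.loads(Path(path).read_text()))
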