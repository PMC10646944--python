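"""Periodic-table data: symbols, periods/groups, masses, unit constants.

The element table (18-column IUPAC convention, H in group 1, He in group 18)
ships as a plain-text resource so users can swap in a different group
convention if needed.
"""

from __future__ import annotations

from dataclasses import dataclass
from importlib import resources

import numpy as np

# ---------------------------------------------------------------------------
# unit policy: Angstrom, kcal/mol, elementary charge, amu, fs
COULOMB_CONSTANT = 332.0637  # kcal * Angstrom / (mol * e^2)
KBOLTZ = 0.0019872043  # kcal / (mol * K)
BOHR = 0.529177210903  # Angstrom
HARTREE = 627.509474  # kcal / mol
# (kcal/mol) / (Angstrom * amu) expressed in Angstrom / fs^2
ACC_UNIT = 4.184e-4

MASSES = {
    "H": 1.008, "He": 4.0026, "Li": 6.94, "Be": 9.0122, "B": 10.81,
    "C": 12.011, "N": 14.007, "O": 15.999, "F": 18.998, "Ne": 20.180,
    "Na": 22.990, "Mg": 24.305, "Al": 26.982, "Si": 28.085, "P": 30.974,
    "S": 32.06, "Cl": 35.45, "Ar": 39.948,
}


@dataclass(frozen=True)
class PeriodicCoords:
    """Row (period) and column (group) of an element, both 1-based."""

    row: int
    col: int


def _load_table():
    sym_by_z, coords_by_z, z_by_sym = {}, {}, {}
    text = resources.files("eqff.data").joinpath("elements.csv").read_text()
    for line in text.splitlines():
        line = line.strip()
        if not line or line.startswith("#"):
            continue
        sym, z, period, group = line.split(",")
        z = int(z)
        sym_by_z[z] = sym
        z_by_sym[sym] = z
        coords_by_z[z] = PeriodicCoords(int(period), int(group))
    return sym_by_z, coords_by_z, z_by_sym


SYMBOLS, _COORDS, ATOMIC_NUMBERS = _load_table()
Z_MAX = max(SYMBOLS)


def atomic_number(element) -> int:
    """Accept an atomic number or a symbol; return the atomic number."""
    if isinstance(element, str):
        try:
            return ATOMIC_NUMBERS[element]
        except KeyError:
            raise ValueError(f"unsupported element symbol {element!r}") from None
    z = int(element)
    if z not in SYMBOLS:
        raise ValueError(
            f"unsupported atomic number {z}: supported range is "
            f"H (1) to {SYMBOLS[Z_MAX]} ({Z_MAX})"
        )
    return z


def symbol(z: int) -> str:
    return SYMBOLS[atomic_number(z)]


def periodic_coords(element) -> PeriodicCoords:
    """Period and 18-column IUPAC group of an element (H-Xe)."""
    return _COORDS[atomic_number(element)]


def mass(element) -> float:
    sym = symbol(atomic_number(element))
    try:
        return MASSES[sym]
    except KeyError:
        raise ValueError(f"no mass tabulated for element {sym}") from None


def species_array(species) -> np.ndarray:
    """Normalize a list of symbols / atomic numbers to an int array."""
    return np.asarray([atomic_number(s) for s in species], dtype=np.intp)


def load_free_atom_table() -> dict:
    """Free-atom physics parameters converted to package units.

    Returns a dict keyed by symbol with n_valence (e), alpha_free (A^3),
    c6_free (kcal/mol * A^6), r_vdw_free (A), v_free (A^3).
    """
    import yaml

    raw = yaml.safe_load(
        resources.files("eqff.data").joinpath("free_atoms.yaml").read_text()
    )
    table = {}
    for sym, row in raw.items():
        table[sym] = {
            "n_valence": float(row["n_valence"]),
            "alpha_free": row["alpha_free"] * BOHR**3,
            "c6_free": row["c6_free"] * HARTREE * BOHR**6,
            "r_vdw_free": row["r_vdw_free"] * BOHR,
            "v_free": row["v_free"] * BOHR**3,
        }
    return table
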