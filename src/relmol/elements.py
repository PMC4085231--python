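"""Element data tables used across the package.

Covalent radii per bond order (Cordero/Pyykkoe compilations, rounded to
0.01 Angstrom), Bondi van-der-Waals radii, standard valences for implicit
hydrogen counting, atomic masses, per-element effective Born radii and GB
screening factors (mbondi-like defaults), and X-H bond lengths for hydrogen
placement.  Values cover the elements relevant to organic and biomolecular
systems; lookups fall back to documented defaults.
"""

from __future__ import annotations

__all__ = [
    "SYMBOLS",
    "atomic_number",
    "symbol",
    "mass",
    "covalent_radius",
    "vdw_radius",
    "standard_valences",
    "xh_length",
    "born_radius",
    "gb_screen",
    "guess_element_from_pdb_name",
]

SYMBOLS = [
    "X", "H", "He", "Li", "Be", "B", "C", "N", "O", "F", "Ne",
    "Na", "Mg", "Al", "Si", "P", "S", "Cl", "Ar", "K", "Ca",
    "Sc", "Ti", "V", "Cr", "Mn", "Fe", "Co", "Ni", "Cu", "Zn",
    "Ga", "Ge", "As", "Se", "Br", "Kr", "Rb", "Sr", "Y", "Zr",
    "Nb", "Mo", "Tc", "Ru", "Rh", "Pd", "Ag", "Cd", "In", "Sn",
    "Sb", "Te", "I", "Xe", "Cs", "Ba",
]

_SYMBOL_TO_Z = {s.upper(): z for z, s in enumerate(SYMBOLS) if z}

_MASSES = {
    1: 1.008, 2: 4.0026, 3: 6.94, 5: 10.81, 6: 12.011, 7: 14.007,
    8: 15.999, 9: 18.998, 11: 22.9898, 12: 24.305, 13: 26.982, 14: 28.085,
    15: 30.974, 16: 32.06, 17: 35.45, 19: 39.098, 20: 40.078, 25: 54.938,
    26: 55.845, 29: 63.546, 30: 65.38, 34: 78.971, 35: 79.904, 53: 126.904,
    55: 132.905,
}

# single/double/triple covalent radii (Angstrom)
_COV_R1 = {
    1: 0.31, 5: 0.84, 6: 0.76, 7: 0.71, 8: 0.66, 9: 0.57, 14: 1.11,
    15: 1.07, 16: 1.05, 17: 1.02, 35: 1.20, 53: 1.39, 11: 1.66, 12: 1.41,
    19: 2.03, 20: 1.76, 26: 1.32, 30: 1.22,
}
_COV_R2 = {
    5: 0.78, 6: 0.67, 7: 0.60, 8: 0.57, 14: 1.07, 15: 1.02, 16: 0.94,
}
_COV_R3 = {
    6: 0.60, 7: 0.54, 8: 0.53, 15: 0.94, 16: 0.95,
}

_VDW = {
    1: 1.20, 6: 1.70, 7: 1.55, 8: 1.52, 9: 1.47, 15: 1.80, 16: 1.80,
    17: 1.75, 35: 1.85, 53: 1.98, 11: 2.27, 12: 1.73, 19: 2.75, 20: 2.31,
}

# admissible total valences, smallest first
_VALENCES = {
    1: (1,), 5: (3,), 6: (4,), 7: (3, 5), 8: (2,), 9: (1,),
    14: (4,), 15: (3, 5), 16: (2, 4, 6), 17: (1,), 35: (1,), 53: (1,),
}

_XH = {6: 1.09, 7: 1.01, 8: 0.96, 16: 1.34, 15: 1.42, 5: 1.19, 14: 1.48}

# mbondi-like per-element effective Born radii (Angstrom)
_BORN = {
    1: 1.20, 6: 1.70, 7: 1.55, 8: 1.50, 9: 1.50, 15: 1.85, 16: 1.80,
    17: 1.70, 35: 1.85, 53: 1.98, 11: 1.87, 19: 2.66,
}

_SCREEN = {1: 0.85, 6: 0.72, 7: 0.79, 8: 0.85, 9: 0.88, 15: 0.86, 16: 0.96}


def atomic_number(sym: str) -> int:
    z = _SYMBOL_TO_Z.get(sym.strip().upper())
    if z is None:
        raise KeyError(f"unknown element symbol {sym!r}")
    return z


def symbol(z: int) -> str:
    if 0 < z < len(SYMBOLS):
        return SYMBOLS[z]
    raise KeyError(f"unknown atomic number {z}")


def mass(z: int) -> float:
    return _MASSES.get(z, 0.0)


def covalent_radius(z: int, order: int = 1) -> float:
    if order >= 3 and z in _COV_R3:
        return _COV_R3[z]
    if order >= 2 and z in _COV_R2:
        return _COV_R2[z]
    return _COV_R1.get(z, 1.50)


def vdw_radius(z: int) -> float:
    return _VDW.get(z, 1.60)


def standard_valences(z: int) -> tuple[int, ...]:
    return _VALENCES.get(z, ())


def xh_length(z: int) -> float:
    return _XH.get(z, 1.09)


def born_radius(z: int) -> float:
    return _BORN.get(z, 1.50)


def gb_screen(z: int) -> float:
    return _SCREEN.get(z, 0.80)


_TWO_LETTER = {"CL", "BR", "NA", "MG", "FE", "ZN", "CA", "MN", "CU", "SE", "SI"}


def guess_element_from_pdb_name(name: str) -> int:
    """Infer an atomic number from a PDB atom-name field.

    Follows the PDB naming convention: the element is right-justified in the
    first two columns of the name field, hydrogens may carry a leading
    digit (``1HB``), and two-letter symbols (Cl, Fe, ...) occupy both
    columns.  ``name`` should be the raw 4-character field when available.
    """
    raw = name
    stripped = raw.strip()
    if not stripped:
        raise ValueError("empty atom name")
    # leading digit => hydrogen-style name like 1HB2
    s = stripped.lstrip("0123456789")
    if not s:
        raise ValueError(f"cannot infer element from atom name {name!r}")
    two = s[:2].upper()
    # a name that fills the 2-char element columns may be a 2-letter element;
    # only trust it when the first column of the raw field is occupied
    if len(raw) >= 2 and raw[0] not in " 0123456789" and two in _TWO_LETTER:
        return atomic_number(two)
    return atomic_number(s[0])
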