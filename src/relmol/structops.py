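"""Structure repair and rigid-body geometry.

``fixbond`` assigns integer bond orders by three rules applied in sequence:
a *hard rule* (fixed-order functional-group templates: carboxylate, nitro,
guanidinium), a *length rule* (element-pair bond-length bands from the
packaged covalent-radius table), and a *conjugation rule* (alternating
single/double assignment — Kekulization — over whatever remains ambiguous).
``add_hydrogens`` completes standard valences with idealised hydrogen
geometry.  ``translate``/``transform``/``rotate`` are rigid-body moves and
``center`` returns the unweighted geometric centre of a molecule or residue
(a mass-weighted variant is ``center_of_mass``).
"""

from __future__ import annotations

import math

import numpy as np
from scipy.spatial.transform import Rotation

from . import elements
from .hashkeys import ATOM, BOND, RESD
from .model import Molecule, MoRange, ObjectHandle

__all__ = [
    "fixbond",
    "add_hydrogens",
    "translate",
    "transform",
    "rotate",
    "center",
    "center_of_mass",
    "bond_order_sum",
    "implicit_hydrogen_count",
    "BondOrderError",
]

AROMATIC_ORDER = 4  # internal code for a delocalised (MOL2 "ar") bond
AMIDE_ORDER = 5     # internal code for a MOL2 "am" bond

# slack around the length-rule band edges (Angstrom)
_BAND_SLACK_LOW = 0.04   # above the double-bond length
_BAND_SLACK_HIGH = 0.06  # below the single-bond length


class BondOrderError(ValueError):
    """Raised when no valence-consistent bond-order assignment exists."""


# ---------------------------------------------------------------------------
# helpers


def _bond_atoms(bond: ObjectHandle) -> tuple[ObjectHandle, ObjectHandle]:
    atoms = bond.related(ATOM)
    if len(atoms) != 2:
        raise ValueError(f"bond #{bond.user_id} does not relate exactly 2 atoms")
    return atoms[0], atoms[1]


def bond_order_sum(atom: ObjectHandle) -> float:
    """Sum of bond orders at an atom; aromatic counts 1.5, amide 1."""
    total = 0.0
    for b in atom.related(BOND):
        order = b.find_i("order")[1] or 0
        if order == AROMATIC_ORDER:
            total += 1.5
        elif order == AMIDE_ORDER:
            total += 1.0
        else:
            total += order
    return total


def implicit_hydrogen_count(atom: ObjectHandle) -> int:
    """Hydrogens needed to reach the smallest admissible valence.

    The valence target is charge-adjusted: a positive charge raises the
    target for lone-pair bearers (N, O, P, S), a negative charge lowers it.
    """
    z = atom.get_i("element")
    valences = elements.standard_valences(z)
    if not valences:
        return 0
    charge = atom.find_i("fcharge")[1] or 0
    used = bond_order_sum(atom)
    used_int = int(math.ceil(used - 1e-9))
    for v in valences:
        target = v
        if charge > 0 and z in (7, 8, 15, 16):
            target = v + charge
        elif charge < 0:
            target = v + charge  # lowers the target
        if target >= used_int:
            return target - used_int
    return 0


# ---------------------------------------------------------------------------
# fixbond


def _neighbors(atom: ObjectHandle) -> list[ObjectHandle]:
    return list(atom.related(ATOM))


def _apply_hard_rules(mol: Molecule) -> set[int]:
    """Fixed-order functional-group templates.  Returns decided bond indices."""
    decided: set[int] = set()
    for atom in mol.atoms:
        z = atom.get_i("element")
        nbrs = _neighbors(atom)
        bonds = list(atom.related(BOND))
        if z == 6 and len(nbrs) == 3:
            # carboxylate / guanidinium-like: C bonded to >=2 terminal O (or 3 N)
            term_o = [n for n in nbrs if n.get_i("element") == 8
                      and len(_neighbors(n)) == 1]
            if len(term_o) >= 2:
                first = True
                for b in bonds:
                    a1, a2 = _bond_atoms(b)
                    other = a2 if a1.index == atom.index else a1
                    if other in term_o:
                        b.set_i("order", 2 if first else 1)
                        first = False
                    else:
                        b.set_i("order", 1)
                    decided.add(b.index)
                continue
            amine_n = [n for n in nbrs if n.get_i("element") == 7]
            if len(amine_n) == 3:  # guanidinium carbon
                first = True
                for b in bonds:
                    b.set_i("order", 2 if first else 1)
                    decided.add(b.index)
                    first = False
                continue
        if z == 7 and len(nbrs) == 3:
            # nitro: N bonded to two terminal O
            term_o = [n for n in nbrs if n.get_i("element") == 8
                      and len(_neighbors(n)) == 1]
            if len(term_o) == 2:
                first = True
                for b in bonds:
                    a1, a2 = _bond_atoms(b)
                    other = a2 if a1.index == atom.index else a1
                    if other in term_o:
                        b.set_i("order", 2 if first else 1)
                        first = False
                    else:
                        b.set_i("order", 1)
                    decided.add(b.index)
    return decided


def _length_rule(bond: ObjectHandle) -> int | None:
    """Order from the element-pair length bands, or None when ambiguous."""
    a, b = _bond_atoms(bond)
    try:
        d = float(np.linalg.norm(a.pos - b.pos))
    except Exception:
        return 1  # no geometry: default single
    za, zb = a.get_i("element"), b.get_i("element")
    l1 = elements.covalent_radius(za, 1) + elements.covalent_radius(zb, 1)
    l2 = elements.covalent_radius(za, 2) + elements.covalent_radius(zb, 2)
    l3 = elements.covalent_radius(za, 3) + elements.covalent_radius(zb, 3)
    if l3 < l2 and d <= (l2 + l3) / 2.0:
        return 3
    if l2 < l1:
        if d <= l2 + _BAND_SLACK_LOW:
            return 2
        if d < l1 - _BAND_SLACK_HIGH:
            return None  # conjugation zone
    return 1


def _kekulize(mol: Molecule, ambiguous: list[ObjectHandle]) -> None:
    """Assign alternating orders over the ambiguous (conjugated) bonds.

    Every atom incident to an ambiguous bond receives exactly one double
    bond unless its valence is already satisfied by decided bonds; atoms
    with spare lone-pair capacity (N, O, S with full valence) may take
    zero.  Backtracking with lowest-atom-index-first ordering keeps the
    result deterministic.
    """
    if not ambiguous:
        return
    amb_idx = {b.index for b in ambiguous}
    atoms_in: set[int] = set()
    for b in ambiguous:
        a1, a2 = _bond_atoms(b)
        atoms_in.update((a1.index, a2.index))

    def needs_double(aidx: int) -> bool:
        atom = mol.handle(ATOM, aidx)
        z = atom.get_i("element")
        valences = elements.standard_valences(z)
        if not valences:
            return False
        decided_sum = 0.0
        for bb in atom.related(BOND):
            if bb.index in amb_idx:
                decided_sum += 1.0  # ambiguous bonds count single for now
            else:
                o = bb.find_i("order")[1] or 1
                decided_sum += 1.0 if o in (AROMATIC_ORDER, AMIDE_ORDER) else o
        nh = atom.find_i("nhyd")[1] or 0
        slack = valences[-1] - (decided_sum + nh)
        return slack >= 1

    need = {a: needs_double(a) for a in atoms_in}
    # adjacency over ambiguous bonds
    edges = sorted(amb_idx)
    edge_atoms = {}
    for bi in edges:
        a1, a2 = _bond_atoms(mol.handle(BOND, bi))
        edge_atoms[bi] = (min(a1.index, a2.index), max(a1.index, a2.index))
    edges.sort(key=lambda bi: edge_atoms[bi])

    assigned: dict[int, int] = {}
    has_double: dict[int, bool] = {a: False for a in atoms_in}

    def backtrack(k: int) -> bool:
        if k == len(edges):
            return all(has_double[a] or not need[a] for a in atoms_in)
        bi = edges[k]
        i, j = edge_atoms[bi]
        # try double first where both ends still need one (deterministic bias)
        options = []
        if not has_double[i] and not has_double[j] and (need[i] or need[j]):
            options.append(2)
        options.append(1)
        for order in options:
            assigned[bi] = order
            if order == 2:
                has_double[i] = has_double[j] = True
            if backtrack(k + 1):
                return True
            if order == 2:
                has_double[i] = has_double[j] = False
            del assigned[bi]
        return False

    if not backtrack(0):
        bad = sorted({a + 1 for a in atoms_in if need[a] and not has_double[a]})
        raise BondOrderError(
            f"no valence-consistent alternation exists; offending atoms {bad}")
    for bi, order in assigned.items():
        mol.handle(BOND, bi).set_i("order", order)


def fixbond(mol: Molecule) -> None:
    """Assign an integer order to every bond (hard, length, conjugation rules)."""
    decided = _apply_hard_rules(mol)
    ambiguous: list[ObjectHandle] = []
    for bond in mol.bonds:
        if bond.index in decided:
            continue
        existing = bond.find_i("order")[1]
        if existing in (1, 2, 3):
            continue
        if existing == AMIDE_ORDER:
            bond.set_i("order", 1)
            continue
        order = _length_rule(bond)
        if order is None or existing == AROMATIC_ORDER:
            ambiguous.append(bond)
        else:
            bond.set_i("order", order)
    _kekulize(mol, ambiguous)
    _check_valences(mol)


def _check_valences(mol: Molecule) -> None:
    bad = []
    for atom in mol.atoms:
        z = atom.get_i("element")
        valences = elements.standard_valences(z)
        if not valences:
            continue
        charge = atom.find_i("fcharge")[1] or 0
        if bond_order_sum(atom) > valences[-1] + max(charge, 0) + 1e-9:
            bad.append(atom.user_id)
    if bad:
        raise BondOrderError(f"valence exceeded at atoms {bad}")


# ---------------------------------------------------------------------------
# hydrogen addition

_TETRA = np.array([[1, 1, 1], [1, -1, -1], [-1, 1, -1], [-1, -1, 1]], float)
_TETRA /= np.linalg.norm(_TETRA, axis=1, keepdims=True)
_TRIG = np.array([[1.0, 0.0, 0.0],
                  [-0.5, math.sqrt(3) / 2, 0.0],
                  [-0.5, -math.sqrt(3) / 2, 0.0]])
_LINEAR = np.array([[1.0, 0.0, 0.0], [-1.0, 0.0, 0.0]])


def _ideal_set(steric: int) -> np.ndarray:
    if steric >= 4:
        return _TETRA
    if steric == 3:
        return _TRIG
    return _LINEAR


def _new_directions(existing: np.ndarray, steric: int, m: int) -> np.ndarray:
    """Directions for ``m`` new substituents given existing unit vectors."""
    ideal = _ideal_set(steric)
    k = len(existing)
    if k == 0:
        return ideal[:m]
    if k >= len(ideal):
        v = -existing.sum(axis=0)
        n = np.linalg.norm(v)
        v = v / n if n > 1e-9 else np.array([0.0, 0.0, 1.0])
        return v[None, :]
    rot, _ = Rotation.align_vectors(existing, ideal[:k])
    out = rot.apply(ideal[k : k + m])
    if k == len(ideal) - 1:
        # one slot left: the exact answer is the negated resultant
        v = -existing.sum(axis=0)
        n = np.linalg.norm(v)
        if n > 1e-9:
            out = (v / n)[None, :]
    return out


def add_hydrogens(mol: Molecule) -> None:
    """Add hydrogens until each heavy atom reaches its standard valence.

    Requires bond orders (run :func:`fixbond` first on raw connectivity).
    Hydrogens are named ``H<n>``, bonded to their heavy atom, related to its
    residue when one exists, and placed at standard X-H lengths with
    tetrahedral/trigonal/linear geometry chosen from the steric number.
    """
    heavy = [a for a in mol.atoms if a.get_i("element") != 1]
    for atom in heavy:
        z = atom.get_i("element")
        nh = implicit_hydrogen_count(atom)
        # a recorded hydrogen count overrides the valence rule, but a zero
        # only counts when it was set explicitly (bracket SMILES atoms) —
        # lazily backfilled columns default to zero for untouched atoms
        found, recorded = atom.find_i("nhyd")
        if found and (recorded > 0 or atom.find_i("explicit_h")[1]):
            nh = recorded
        if nh <= 0:
            continue
        nbrs = _neighbors(atom)
        pos = atom.pos
        dirs = []
        for n in nbrs:
            v = n.pos - pos
            norm = np.linalg.norm(v)
            if norm > 1e-9:
                dirs.append(v / norm)
        existing = np.array(dirs) if dirs else np.zeros((0, 3))
        steric = len(nbrs) + nh
        # sp2 centres (one double/aromatic bond) are trigonal even with few nbrs
        if any((b.find_i("order")[1] or 1) in (2, AROMATIC_ORDER)
               for b in atom.related(BOND)):
            steric = max(3, len(nbrs) + nh) if z != 6 else 3
        new_dirs = _new_directions(existing, steric, nh)
        length = elements.xh_length(z)
        resd = atom.related(RESD)
        for i in range(nh):
            h = mol.create(ATOM)
            h.set_i("element", 1)
            h.set_s("name", f"H{h.user_id}")
            h.pos = pos + new_dirs[i % len(new_dirs)] * length
            bond = mol.create(BOND)
            bond.relate(atom)
            bond.relate(h)
            bond.set_i("order", 1)
            atom.relate(h)
            for r in resd:
                r.relate(h)
        atom.set_i("nhyd", 0)


# ---------------------------------------------------------------------------
# rigid-body moves


def translate(mol: Molecule, v) -> None:
    pos = mol.positions()
    if pos.size == 0:
        raise ValueError("molecule has no positions")
    mol.set_positions(pos + np.asarray(v, float))


def transform(mol: Molecule, matrix, origin=None) -> None:
    """Apply a 3x3 linear map (optionally about ``origin``) to all positions."""
    m = np.asarray(matrix, float)
    if m.shape != (3, 3):
        raise ValueError("transform expects a 3x3 matrix")
    pos = mol.positions()
    if pos.size == 0:
        raise ValueError("molecule has no positions")
    o = np.zeros(3) if origin is None else np.asarray(origin, float)
    mol.set_positions((pos - o) @ m.T + o)


def rotate(mol: Molecule, axis, angle_deg: float, origin=None) -> None:
    """Rotate about ``axis`` through ``origin`` by ``angle_deg`` degrees."""
    axis = np.asarray(axis, float)
    n = np.linalg.norm(axis)
    if n < 1e-12:
        raise ValueError("rotation axis must be non-zero")
    rot = Rotation.from_rotvec(axis / n * math.radians(angle_deg))
    transform(mol, rot.as_matrix(), origin=origin)


def _target_atoms(target) -> list[ObjectHandle]:
    if isinstance(target, Molecule):
        return list(target.atoms)
    if isinstance(target, ObjectHandle):
        return list(target.related(ATOM))
    if isinstance(target, MoRange):
        return list(target)
    raise TypeError(f"cannot take the center of {target!r}")


def center(target) -> np.ndarray:
    """Unweighted geometric centre of a molecule, residue or atom range."""
    atoms = _target_atoms(target)
    if not atoms:
        raise ValueError("empty selection has no center")
    return np.mean([a.pos for a in atoms], axis=0)


def center_of_mass(target) -> np.ndarray:
    """Mass-weighted centre (uses element masses)."""
    atoms = _target_atoms(target)
    if not atoms:
        raise ValueError("empty selection has no center")
    ms = np.array([elements.mass(a.get_i("element")) for a in atoms])
    ps = np.array([a.pos for a in atoms])
    if ms.sum() <= 0:
        raise ValueError("selection has zero total mass")
    return ms @ ps / ms.sum()
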