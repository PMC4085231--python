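"""AMBER prmtop / inpcrd emission (and prmtop re-reading).

``write_amber_prmtop`` produces the two MD input files: a modern ``%FLAG``
topology with fixed-width Fortran layouts (``10I8`` / ``5E16.8`` / ``20a4``)
and an ASCII restart with coordinates six-per-line at ``%12.7f``.  The
CHARGE column holds q * sqrt(332.05) so that q_i q_j / r read straight from
the file is already kcal/mol.  Dihedral entries use coordinate-array
offsets (3 * atom index); a negative third index suppresses the 1-4 pair
(duplicate Fourier terms, ring short-circuits) and a negative fourth marks
an improper.  Where a sign is needed on atom 0 the quartet is reversed —
a dihedral angle is invariant under full reversal, so energies are
unchanged.  Excluded-atom lists count 1-2/1-3/1-4 partners; an atom with
none stores the mandatory single zero.
"""

from __future__ import annotations

import math
from dataclasses import dataclass, field

import numpy as np

from . import elements
from .energy import INVCHG2, SCEE, SCNB, exclusion_pairs
from .forcefield import ForceField
from .hashkeys import ANGL, ATOM, BOND, OOPS, TORS
from .model import Molecule

__all__ = ["TopologySnapshot", "build_snapshot", "write_amber_prmtop",
           "write_prmtop_snapshot", "read_amber_prmtop", "write_coordinates",
           "CHARGE_SCALE"]

#: prmtop charge unit: electron charges times sqrt(INVCHG2) (~18.2223)
CHARGE_SCALE = math.sqrt(INVCHG2)

_VERSION_LINE = ("%VERSION  VERSION_STAMP = V0001.000  DATE = 01/01/00  "
                 "00:00:00")


@dataclass
class TopologySnapshot:
    """Everything the prmtop stores, in write order."""

    title: str = ""
    atom_names: list = field(default_factory=list)
    charges: list = field(default_factory=list)        # scaled units
    atomic_numbers: list = field(default_factory=list)
    masses: list = field(default_factory=list)
    type_index: list = field(default_factory=list)     # 1-based
    nexcl: list = field(default_factory=list)
    ico: list = field(default_factory=list)
    res_labels: list = field(default_factory=list)
    res_pointers: list = field(default_factory=list)   # 1-based first atom
    bond_k: list = field(default_factory=list)
    bond_req: list = field(default_factory=list)
    angle_k: list = field(default_factory=list)
    angle_eq: list = field(default_factory=list)
    dih_k: list = field(default_factory=list)
    dih_per: list = field(default_factory=list)
    dih_phase: list = field(default_factory=list)
    scee: list = field(default_factory=list)
    scnb: list = field(default_factory=list)
    solty: list = field(default_factory=list)
    lj_a: list = field(default_factory=list)
    lj_b: list = field(default_factory=list)
    bonds_h: list = field(default_factory=list)        # flat triples
    bonds_nonh: list = field(default_factory=list)
    angles_h: list = field(default_factory=list)
    angles_nonh: list = field(default_factory=list)
    dih_h: list = field(default_factory=list)          # flat quintuples
    dih_nonh: list = field(default_factory=list)
    excluded: list = field(default_factory=list)
    amber_types: list = field(default_factory=list)
    radii: list = field(default_factory=list)
    screen: list = field(default_factory=list)
    radius_set: str = "modified Bondi radii (mbondi)"
    box: list | None = None                            # [beta, x, y, z]
    solvent_pointers: list | None = None
    atoms_per_molecule: list | None = None

    @property
    def natom(self) -> int:
        return len(self.atom_names)

    @property
    def ntypes(self) -> int:
        return max(self.type_index) if self.type_index else 0


# ---------------------------------------------------------------------------
# building a snapshot from a parameterised molecule


def _element_of(atom) -> int:
    return atom.find_i("element")[1] or 0


def _is_h(mol: Molecule, idx: int) -> bool:
    return _element_of(mol.handle(ATOM, idx)) == 1


def _term_indices(term) -> list[int]:
    return [a.index for a in term.related(ATOM)]


def build_snapshot(mol: Molecule, ff: ForceField) -> TopologySnapshot:
    from .energy import _atom_type  # shared type-property accessor

    natom = mol.natoms
    if natom == 0:
        raise ValueError("cannot build a topology for zero atoms")
    snap = TopologySnapshot(title=mol.name or "MOL")
    types = []
    for a in mol.atoms:
        snap.atom_names.append((a.find_s("name")[1] or "X")[:4])
        found, q = a.find_d("pchg")
        snap.charges.append((q if found else 0.0) * CHARGE_SCALE)
        z = _element_of(a)
        snap.atomic_numbers.append(z)
        t = _atom_type(a)
        types.append(t)
        snap.masses.append(ff.masses.get(t, elements.mass(z)))
        snap.amber_types.append(t[:4])
        fr, r = a.find_d("born")
        snap.radii.append(r if fr else elements.born_radius(z))
        snap.screen.append(elements.gb_screen(z))
    # vdW type indices in order of first appearance
    distinct: list[str] = []
    for t in types:
        if t not in distinct:
            distinct.append(t)
    snap.type_index = [distinct.index(t) + 1 for t in types]
    ntypes = len(distinct)
    # Lennard-Jones tables
    snap.ico = [0] * (ntypes * ntypes)
    for i in range(1, ntypes + 1):
        for j in range(1, ntypes + 1):
            a, b = max(i, j), min(i, j)
            snap.ico[ntypes * (i - 1) + j - 1] = a * (a - 1) // 2 + b
    for i in range(1, ntypes + 1):
        for j in range(1, i + 1):
            ri, ei = ff.vdw(distinct[i - 1])
            rj, ej = ff.vdw(distinct[j - 1])
            rmin = ri + rj
            eps = math.sqrt(ei * ej)
            snap.lj_a.append(eps * rmin**12)
            snap.lj_b.append(2.0 * eps * rmin**6)
    snap.solty = [0.0]
    # residues: atoms must be contiguous per residue, in residue order
    if mol.nresds == 0:
        snap.res_labels = ["MOL"]
        snap.res_pointers = [1]
    else:
        cursor = 0
        for res in mol.resds:
            members = sorted(a.index for a in res.related(ATOM))
            if not members:
                continue
            if members[0] != cursor or members != list(
                    range(members[0], members[-1] + 1)):
                raise ValueError(
                    "prmtop writing requires residue atoms to be contiguous "
                    f"and in residue order (residue {res.user_id})")
            snap.res_labels.append((res.find_s("name")[1] or "RES")[:4])
            snap.res_pointers.append(members[0] + 1)
            cursor = members[-1] + 1
        if cursor != natom:
            raise ValueError("some atoms belong to no residue; cannot write "
                             "RESIDUE_POINTER")

    # bond terms
    bond_types: dict[tuple, int] = {}
    for bond in mol.objects(BOND):
        i, j = _term_indices(bond)
        k, r0 = ff.bond(types[i], types[j])
        key = (round(k, 10), round(r0, 10))
        idx = bond_types.setdefault(key, len(bond_types) + 1)
        if idx > len(snap.bond_k):
            snap.bond_k.append(k)
            snap.bond_req.append(r0)
        entry = [3 * i, 3 * j, idx]
        (snap.bonds_h if _is_h(mol, i) or _is_h(mol, j)
         else snap.bonds_nonh).extend(entry)
    # angle terms
    angle_types: dict[tuple, int] = {}
    for angle in mol.objects(ANGL):
        i, j, k_ = _term_indices(angle)
        kf, th0 = ff.angle(types[i], types[j], types[k_])
        key = (round(kf, 10), round(th0, 12))
        idx = angle_types.setdefault(key, len(angle_types) + 1)
        if idx > len(snap.angle_k):
            snap.angle_k.append(kf)
            snap.angle_eq.append(th0)
        entry = [3 * i, 3 * j, 3 * k_, idx]
        (snap.angles_h if any(_is_h(mol, x) for x in (i, j, k_))
         else snap.angles_nonh).extend(entry)
    # dihedral terms (propers then impropers)
    dih_types: dict[tuple, int] = {}

    def dih_type_index(pk: float, per: int, phase: float) -> int:
        key = (round(pk, 10), per, round(phase, 12))
        idx = dih_types.setdefault(key, len(dih_types) + 1)
        if idx > len(snap.dih_k):
            snap.dih_k.append(pk)
            snap.dih_per.append(float(per))
            snap.dih_phase.append(phase)
            snap.scee.append(SCEE)
            snap.scnb.append(SCNB)
        return idx

    _excl, scaled = exclusion_pairs(mol)
    remaining_14 = set(scaled)
    for tors in mol.objects(TORS):
        i, j, k_, l = _term_indices(tors)
        terms = ff.torsion(types[i], types[j], types[k_], types[l])
        pair = (min(i, l), max(i, l))
        for n, term in enumerate(terms):
            idx = dih_type_index(term.pk / term.idivf, term.pn, term.phase)
            count_14 = n == 0 and pair in remaining_14
            if count_14:
                remaining_14.discard(pair)
            ii, jj, kk, ll = i, j, k_, l
            if not count_14 and kk == 0:
                ii, jj, kk, ll = ll, kk, jj, ii  # avoid a sign on atom 0
            entry = [3 * ii, 3 * jj, 3 * kk if count_14 else -3 * kk, 3 * ll,
                     idx]
            (snap.dih_h if any(_is_h(mol, x) for x in (i, j, k_, l))
             else snap.dih_nonh).extend(entry)
    for oops in mol.objects(OOPS):
        i, j, c, l = _term_indices(oops)
        terms = ff.improper(types[i], types[j], types[c], types[l])
        for term in terms:
            idx = dih_type_index(term.pk / term.idivf, term.pn, term.phase)
            ii, jj, cc, ll = i, j, c, l
            if cc == 0 or ll == 0:
                ii, jj, cc, ll = ll, cc, jj, ii
            entry = [3 * ii, 3 * jj, -3 * cc, -3 * ll, idx]
            (snap.dih_h if any(_is_h(mol, x) for x in (i, j, c, l))
             else snap.dih_nonh).extend(entry)

    # exclusion lists (1-2, 1-3, 1-4 partners with j > i)
    excl, scaled_all = exclusion_pairs(mol)
    partners: dict[int, list[int]] = {i: [] for i in range(natom)}
    for (i, j) in sorted(excl | scaled_all):
        partners[i].append(j)
    for i in range(natom):
        row = sorted(partners[i])
        if not row:
            snap.nexcl.append(1)
            snap.excluded.append(0)
        else:
            snap.nexcl.append(len(row))
            snap.excluded.extend(j + 1 for j in row)

    # box metadata
    boxv = mol.find_prop("v", "box")
    if boxv is not None:
        snap.box = [90.0, float(boxv[0]), float(boxv[1]), float(boxv[2])]
        comp = _connected_components(mol)
        snap.atoms_per_molecule = [len(c) for c in comp]
        first_solvent = len(comp) + 1
        res_names = snap.res_labels
        solvent_like = {"WAT", "HOH"}
        # first molecule whose first atom starts a solvent-named residue
        atom_res = np.searchsorted(np.array(snap.res_pointers),
                                   [c[0] + 1 for c in comp], side="right") - 1
        for m, c in enumerate(comp):
            if res_names[int(atom_res[m])] in solvent_like:
                first_solvent = m + 1
                break
        iptres = len(res_names)
        snap.solvent_pointers = [iptres, len(comp), first_solvent]
    return snap


def _connected_components(mol: Molecule) -> list[list[int]]:
    from .energy import _neighbor_map

    nbrs = _neighbor_map(mol)
    seen: set[int] = set()
    comps = []
    for i in range(mol.natoms):
        if i in seen:
            continue
        stack = [i]
        comp = []
        seen.add(i)
        while stack:
            u = stack.pop()
            comp.append(u)
            for v in nbrs[u]:
                if v not in seen:
                    seen.add(v)
                    stack.append(v)
        comps.append(sorted(comp))
    return comps


# ---------------------------------------------------------------------------
# writing


def _chunk(values, per_line, fmt):
    lines = []
    for k in range(0, len(values), per_line):
        lines.append("".join(fmt % v for v in values[k : k + per_line]))
    if not lines:
        lines = [""]
    return "\n".join(lines) + "\n"


def _section(stream, flag: str, fortran: str, values, per_line, fmt) -> None:
    stream.write(f"%FLAG {flag}\n%FORMAT({fortran})\n")
    stream.write(_chunk(values, per_line, fmt))


def write_prmtop_snapshot(snap: TopologySnapshot, stream) -> None:
    natom = snap.natom
    ntypes = snap.ntypes
    nbonh = len(snap.bonds_h) // 3
    nbona = len(snap.bonds_nonh) // 3
    ntheth = len(snap.angles_h) // 4
    ntheta = len(snap.angles_nonh) // 4
    nphih = len(snap.dih_h) // 5
    nphia = len(snap.dih_nonh) // 5
    nres = len(snap.res_labels)
    nnb = len(snap.excluded)
    ifbox = 1 if snap.box is not None else 0
    nmxrs = 0
    pointers_res = snap.res_pointers + [natom + 1]
    for k in range(nres):
        nmxrs = max(nmxrs, pointers_res[k + 1] - pointers_res[k])
    pointers = [
        natom, ntypes, nbonh, nbona, ntheth, ntheta, nphih, nphia, 0, 0,
        nnb, nres, nbona, ntheta, nphia, len(snap.bond_k), len(snap.angle_k),
        len(snap.dih_k), len(snap.solty), 0,
        0, 0, 0, 0, 0, 0, 0, ifbox, nmxrs, 0,
        0,
    ]
    stream.write(_VERSION_LINE + "\n")
    stream.write("%FLAG TITLE\n%FORMAT(20a4)\n")
    stream.write((snap.title or "MOL")[:80].rstrip() + "\n")
    _section(stream, "POINTERS", "10I8", pointers, 10, "%8d")
    _section(stream, "ATOM_NAME", "20a4", snap.atom_names, 20, "%-4s")
    _section(stream, "CHARGE", "5E16.8", snap.charges, 5, "%16.8E")
    _section(stream, "ATOMIC_NUMBER", "10I8", snap.atomic_numbers, 10, "%8d")
    _section(stream, "MASS", "5E16.8", snap.masses, 5, "%16.8E")
    _section(stream, "ATOM_TYPE_INDEX", "10I8", snap.type_index, 10, "%8d")
    _section(stream, "NUMBER_EXCLUDED_ATOMS", "10I8", snap.nexcl, 10, "%8d")
    _section(stream, "NONBONDED_PARM_INDEX", "10I8", snap.ico, 10, "%8d")
    _section(stream, "RESIDUE_LABEL", "20a4", snap.res_labels, 20, "%-4s")
    _section(stream, "RESIDUE_POINTER", "10I8", snap.res_pointers, 10, "%8d")
    _section(stream, "BOND_FORCE_CONSTANT", "5E16.8", snap.bond_k, 5, "%16.8E")
    _section(stream, "BOND_EQUIL_VALUE", "5E16.8", snap.bond_req, 5, "%16.8E")
    _section(stream, "ANGLE_FORCE_CONSTANT", "5E16.8", snap.angle_k, 5, "%16.8E")
    _section(stream, "ANGLE_EQUIL_VALUE", "5E16.8", snap.angle_eq, 5, "%16.8E")
    _section(stream, "DIHEDRAL_FORCE_CONSTANT", "5E16.8", snap.dih_k, 5, "%16.8E")
    _section(stream, "DIHEDRAL_PERIODICITY", "5E16.8", snap.dih_per, 5, "%16.8E")
    _section(stream, "DIHEDRAL_PHASE", "5E16.8", snap.dih_phase, 5, "%16.8E")
    _section(stream, "SCEE_SCALE_FACTOR", "5E16.8", snap.scee, 5, "%16.8E")
    _section(stream, "SCNB_SCALE_FACTOR", "5E16.8", snap.scnb, 5, "%16.8E")
    _section(stream, "SOLTY", "5E16.8", snap.solty, 5, "%16.8E")
    _section(stream, "LENNARD_JONES_ACOEF", "5E16.8", snap.lj_a, 5, "%16.8E")
    _section(stream, "LENNARD_JONES_BCOEF", "5E16.8", snap.lj_b, 5, "%16.8E")
    _section(stream, "BONDS_INC_HYDROGEN", "10I8", snap.bonds_h, 10, "%8d")
    _section(stream, "BONDS_WITHOUT_HYDROGEN", "10I8", snap.bonds_nonh, 10, "%8d")
    _section(stream, "ANGLES_INC_HYDROGEN", "10I8", snap.angles_h, 10, "%8d")
    _section(stream, "ANGLES_WITHOUT_HYDROGEN", "10I8", snap.angles_nonh, 10, "%8d")
    _section(stream, "DIHEDRALS_INC_HYDROGEN", "10I8", snap.dih_h, 10, "%8d")
    _section(stream, "DIHEDRALS_WITHOUT_HYDROGEN", "10I8", snap.dih_nonh, 10, "%8d")
    _section(stream, "EXCLUDED_ATOMS_LIST", "10I8", snap.excluded, 10, "%8d")
    _section(stream, "HBOND_ACOEF", "5E16.8", [], 5, "%16.8E")
    _section(stream, "HBOND_BCOEF", "5E16.8", [], 5, "%16.8E")
    _section(stream, "HBCUT", "5E16.8", [], 5, "%16.8E")
    _section(stream, "AMBER_ATOM_TYPE", "20a4", snap.amber_types, 20, "%-4s")
    _section(stream, "TREE_CHAIN_CLASSIFICATION", "20a4",
             ["BLA"] * natom, 20, "%-4s")
    _section(stream, "JOIN_ARRAY", "10I8", [0] * natom, 10, "%8d")
    _section(stream, "IROTAT", "10I8", [0] * natom, 10, "%8d")
    if snap.box is not None:
        _section(stream, "SOLVENT_POINTERS", "3I8",
                 snap.solvent_pointers or [len(snap.res_labels), 1, 2], 3, "%8d")
        _section(stream, "ATOMS_PER_MOLECULE", "10I8",
                 snap.atoms_per_molecule or [natom], 10, "%8d")
        _section(stream, "BOX_DIMENSIONS", "5E16.8", snap.box, 5, "%16.8E")
    stream.write("%FLAG RADIUS_SET\n%FORMAT(1a80)\n")
    stream.write(snap.radius_set + "\n")
    _section(stream, "RADII", "5E16.8", snap.radii, 5, "%16.8E")
    _section(stream, "SCREEN", "5E16.8", snap.screen, 5, "%16.8E")
    _section(stream, "IPOL", "1I8", [0], 1, "%8d")


def write_amber_prmtop(mol: Molecule, ff: ForceField, stream) -> None:
    """Emit the topology file for a typed, charged, term-enumerated molecule."""
    write_prmtop_snapshot(build_snapshot(mol, ff), stream)


def write_coordinates(mol: Molecule, stream, title: str | None = None) -> None:
    """AMBER ASCII restart: title, atom count, %12.7f coordinates, box line."""
    pos = mol.positions()
    if pos.shape[0] != mol.natoms or mol.natoms == 0:
        raise ValueError("every atom needs a position to write coordinates")
    for a in mol.atoms:
        if not a.find_v("position")[0]:
            raise ValueError(f"atom {a.user_id} has no position")
    stream.write((title or mol.name or "MOL") + "\n")
    stream.write("%5d\n" % mol.natoms)
    flat = pos.reshape(-1)
    for k in range(0, len(flat), 6):
        stream.write("".join("%12.7f" % v for v in flat[k : k + 6]) + "\n")
    boxv = mol.find_prop("v", "box")
    if boxv is not None:
        stream.write("".join("%12.7f" % v
                             for v in (boxv[0], boxv[1], boxv[2],
                                       90.0, 90.0, 90.0)) + "\n")


# ---------------------------------------------------------------------------
# reading (for round-trips and independent checks)


def _parse_sections(text: str):
    version = None
    sections: dict[str, list[str]] = {}
    order: list[str] = []
    current = None
    for line in text.splitlines():
        if line.startswith("%VERSION"):
            version = line
            continue
        if line.startswith("%FLAG"):
            current = line.split()[1]
            sections[current] = []
            order.append(current)
            continue
        if line.startswith("%FORMAT"):
            continue
        if current is not None:
            sections[current].append(line)
    return version, sections, order


def _ints(lines) -> list[int]:
    out = []
    for line in lines:
        out.extend(int(tok) for tok in line.split())
    return out


def _reals(lines) -> list[float]:
    out = []
    for line in lines:
        out.extend(float(tok) for tok in line.split())
    return out


def _names(lines, width=4) -> list[str]:
    out = []
    for line in lines:
        for k in range(0, len(line), width):
            field_ = line[k : k + width]
            if field_.strip():
                out.append(field_.strip())
    return out


def read_amber_prmtop(stream) -> TopologySnapshot:
    """Parse a %FLAG-style prmtop back into a snapshot."""
    text = stream if isinstance(stream, str) else stream.read()
    _version, sec, _order = _parse_sections(text)
    snap = TopologySnapshot()
    snap.title = "\n".join(sec.get("TITLE", [""])).strip()
    pointers = _ints(sec["POINTERS"])
    snap.atom_names = _names(sec["ATOM_NAME"])
    snap.charges = _reals(sec["CHARGE"])
    snap.atomic_numbers = _ints(sec.get("ATOMIC_NUMBER", []))
    snap.masses = _reals(sec["MASS"])
    snap.type_index = _ints(sec["ATOM_TYPE_INDEX"])
    snap.nexcl = _ints(sec["NUMBER_EXCLUDED_ATOMS"])
    snap.ico = _ints(sec["NONBONDED_PARM_INDEX"])
    snap.res_labels = _names(sec["RESIDUE_LABEL"])
    snap.res_pointers = _ints(sec["RESIDUE_POINTER"])
    snap.bond_k = _reals(sec["BOND_FORCE_CONSTANT"])
    snap.bond_req = _reals(sec["BOND_EQUIL_VALUE"])
    snap.angle_k = _reals(sec["ANGLE_FORCE_CONSTANT"])
    snap.angle_eq = _reals(sec["ANGLE_EQUIL_VALUE"])
    snap.dih_k = _reals(sec["DIHEDRAL_FORCE_CONSTANT"])
    snap.dih_per = _reals(sec["DIHEDRAL_PERIODICITY"])
    snap.dih_phase = _reals(sec["DIHEDRAL_PHASE"])
    snap.scee = _reals(sec.get("SCEE_SCALE_FACTOR", []))
    snap.scnb = _reals(sec.get("SCNB_SCALE_FACTOR", []))
    snap.solty = _reals(sec.get("SOLTY", []))
    snap.lj_a = _reals(sec["LENNARD_JONES_ACOEF"])
    snap.lj_b = _reals(sec["LENNARD_JONES_BCOEF"])
    snap.bonds_h = _ints(sec["BONDS_INC_HYDROGEN"])
    snap.bonds_nonh = _ints(sec["BONDS_WITHOUT_HYDROGEN"])
    snap.angles_h = _ints(sec["ANGLES_INC_HYDROGEN"])
    snap.angles_nonh = _ints(sec["ANGLES_WITHOUT_HYDROGEN"])
    snap.dih_h = _ints(sec["DIHEDRALS_INC_HYDROGEN"])
    snap.dih_nonh = _ints(sec["DIHEDRALS_WITHOUT_HYDROGEN"])
    snap.excluded = _ints(sec["EXCLUDED_ATOMS_LIST"])
    snap.amber_types = _names(sec["AMBER_ATOM_TYPE"])
    snap.radii = _reals(sec.get("RADII", []))
    snap.screen = _reals(sec.get("SCREEN", []))
    if "RADIUS_SET" in sec:
        snap.radius_set = "\n".join(sec["RADIUS_SET"]).strip()
    if pointers[27]:  # IFBOX
        snap.box = _reals(sec["BOX_DIMENSIONS"])
        snap.solvent_pointers = _ints(sec.get("SOLVENT_POINTERS", []))
        snap.atoms_per_molecule = _ints(sec.get("ATOMS_PER_MOLECULE", []))
    return snap
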