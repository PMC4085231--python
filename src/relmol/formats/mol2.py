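"""TRIPOS MOL2 reader and writer.

Atoms carry ``name``, ``position``, SYBYL ``type``, partial charge ``pchg``
and inferred ``element``; bonds carry ``order`` (1/2/3, aromatic stored as
the internal order code 4, amide as 5); @<TRIPOS>SUBSTRUCTURE rows become
residues.  The writer emits a single default residue when none exists.
"""

from __future__ import annotations

import io

from .. import elements
from ..hashkeys import ATOM, BOND, RESD
from ..model import Molecule
from ..structops import AMIDE_ORDER, AROMATIC_ORDER

__all__ = ["read_mol2", "write_mol2"]

_ORDER_FROM_MOL2 = {"1": 1, "2": 2, "3": 3, "ar": AROMATIC_ORDER,
                    "am": AMIDE_ORDER, "du": 1, "un": 1, "nc": 0}
_MOL2_FROM_ORDER = {1: "1", 2: "2", 3: "3", AROMATIC_ORDER: "ar",
                    AMIDE_ORDER: "am", 0: "nc"}


def _sections(text: str):
    """Split a MOL2 record into {section name: [(lineno, line), ...]}."""
    out: dict[str, list[tuple[int, str]]] = {}
    current = None
    for lineno, line in enumerate(text.splitlines(), start=1):
        if line.startswith("@<TRIPOS>"):
            current = line[9:].strip().upper()
            out.setdefault(current, [])
            continue
        if current is not None and line.strip() and not line.startswith("#"):
            out[current].append((lineno, line))
    return out


def _element_from_sybyl(sybyl: str, name: str) -> int:
    base = sybyl.split(".")[0]
    try:
        return elements.atomic_number(base)
    except KeyError:
        try:
            return elements.guess_element_from_pdb_name(name)
        except (KeyError, ValueError):
            return 0


def read_mol2(stream, name: str = "") -> Molecule:
    from . import ParseError

    text = stream if isinstance(stream, str) else stream.read()
    sec = _sections(text)
    if "MOLECULE" not in sec:
        raise ParseError("missing @<TRIPOS>MOLECULE section")
    mol_lines = sec["MOLECULE"]
    mol_name = mol_lines[0][1].strip() if mol_lines else ""
    mol = Molecule(name or mol_name)

    id_to_index: dict[int, int] = {}
    subst_of_atom: dict[int, int] = {}
    for lineno, line in sec.get("ATOM", []):
        parts = line.split()
        if len(parts) < 6:
            raise ParseError(f"short ATOM row {line!r}", lineno)
        try:
            aid = int(parts[0])
            x, y, z = float(parts[2]), float(parts[3]), float(parts[4])
        except ValueError:
            raise ParseError(f"bad ATOM row {line!r}", lineno) from None
        atom = mol.create(ATOM)
        atom.set_s("name", parts[1])
        atom.set_v("position", (x, y, z))
        atom.set_s("type", parts[5])
        atom.set_i("element", _element_from_sybyl(parts[5], parts[1]))
        if len(parts) >= 7:
            subst_of_atom[atom.index] = int(parts[6])
        if len(parts) >= 8:
            atom.set_s("resnhint", parts[7])
        if len(parts) >= 9:
            atom.set_d("pchg", float(parts[8]))
        id_to_index[aid] = atom.index

    for lineno, line in sec.get("BOND", []):
        parts = line.split()
        if len(parts) < 4:
            raise ParseError(f"short BOND row {line!r}", lineno)
        try:
            a1, a2 = int(parts[1]), int(parts[2])
        except ValueError:
            raise ParseError(f"bad BOND row {line!r}", lineno) from None
        order = _ORDER_FROM_MOL2.get(parts[3].lower())
        if order is None:
            raise ParseError(f"unknown bond type {parts[3]!r}", lineno)
        bond = mol.create(BOND)
        ha = mol.handle(ATOM, id_to_index[a1])
        hb = mol.handle(ATOM, id_to_index[a2])
        bond.relate(ha)
        bond.relate(hb)
        bond.set_i("order", order)
        ha.relate(hb)

    subst_ids = sorted({v for v in subst_of_atom.values()})
    subst_names: dict[int, str] = {}
    for _lineno, line in sec.get("SUBSTRUCTURE", []):
        parts = line.split()
        if len(parts) >= 2:
            try:
                subst_names[int(parts[0])] = parts[1]
            except ValueError:
                continue
    if not subst_ids and mol.natoms:
        subst_ids = [1]
        subst_of_atom = {i: 1 for i in range(mol.natoms)}
    res_handle = {}
    for sid in subst_ids:
        res = mol.create(RESD)
        rname = subst_names.get(sid)
        if rname is None:
            hints = {mol.handle(ATOM, ai).find_s("resnhint")[1]
                     for ai, s in subst_of_atom.items() if s == sid}
            hints.discard(None)
            rname = sorted(hints)[0] if hints else "RES"
        res.set_s("name", rname)
        res.set_i("seq", sid)
        res_handle[sid] = res
    for ai, sid in subst_of_atom.items():
        res_handle[sid].relate(mol.handle(ATOM, ai))
    return mol


def write_mol2(mol: Molecule, stream) -> None:
    natom = mol.natoms
    nbond = mol.count(BOND)
    res_of: dict[int, int] = {}
    res_rows = []
    nres = mol.nresds
    if nres == 0 and natom:
        res_rows.append((1, "RES"))
        res_of = {i: 1 for i in range(natom)}
    else:
        for ri, res in enumerate(mol.resds, start=1):
            res_rows.append((ri, res.find_s("name")[1] or "RES"))
            for a in res.related(ATOM):
                res_of[a.index] = ri
    stream.write("@<TRIPOS>MOLECULE\n")
    stream.write(f"{mol.name or 'MOL'}\n")
    stream.write(f"{natom:>5d}{nbond:>6d}{len(res_rows):>6d}     0     0\n")
    stream.write("SMALL\nUSER_CHARGES\n")
    stream.write("@<TRIPOS>ATOM\n")
    name_of_res = dict(res_rows)
    for atom in mol.atoms:
        x, y, z = atom.get_v("position")
        aname = atom.find_s("name")[1]
        if not aname:
            try:
                aname = elements.symbol(atom.get_i("element"))
            except KeyError:
                aname = "X"
        sybyl = atom.find_s("type")[1]
        if not sybyl:
            try:
                sybyl = elements.symbol(atom.get_i("element"))
            except KeyError:
                sybyl = "Du"
        sid = res_of.get(atom.index, 1)
        charge = atom.find_d("pchg")[1] or 0.0
        stream.write(
            "%7d %-8s %9.4f %9.4f %9.4f %-8s %3d %-8s %9.4f\n"
            % (atom.user_id, aname, x, y, z, sybyl, sid,
               name_of_res.get(sid, "RES"), charge)
        )
    stream.write("@<TRIPOS>BOND\n")
    for bond in mol.objects(BOND):
        atoms = bond.related(ATOM)
        order = bond.find_i("order")[1] or 1
        stream.write("%6d %5d %5d %-4s\n"
                     % (bond.user_id, atoms[0].user_id, atoms[1].user_id,
                        _MOL2_FROM_ORDER.get(order, "1")))
    stream.write("@<TRIPOS>SUBSTRUCTURE\n")
    root = {sid: min((ai for ai, s in res_of.items() if s == sid), default=0)
            for sid, _ in res_rows}
    for sid, rname in res_rows:
        stream.write("%6d %-8s %6d RESIDUE\n" % (sid, rname, root[sid] + 1))


def loads(text: str) -> Molecule:  # pragma: no cover - convenience
    return read_mol2(io.StringIO(text))
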