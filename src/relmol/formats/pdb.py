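"""PDB v3 fixed-column reader and writer.

Lines are dispatched on their first record-name characters.  ATOM/HETATM
records become atoms with ``name``, ``position`` and ``element`` properties;
a new residue is opened whenever ``(residue_seq, chain)`` changes; CONECT
records become bonds; TER marks a chain break; everything else is skipped.
Parsing is fixed-column first with a whitespace-token fallback for slightly
nonconforming files.  No bonds are inferred in the absence of CONECT
(bond-order perception and templates live elsewhere).
"""

from __future__ import annotations

import io
import warnings

from .. import elements
from ..hashkeys import ATOM, RESD
from ..model import Molecule

__all__ = ["read_pdb", "write_pdb"]


def _as_text_stream(stream):
    if isinstance(stream, str):
        return io.StringIO(stream)
    return stream


def _parse_atom_line(line: str, lineno: int):
    from . import ParseError

    try:
        serial = int(line[6:11])
    except ValueError:
        parts = line.split()
        try:
            serial = int(parts[1])
        except (IndexError, ValueError):
            raise ParseError(f"bad atom serial in {line!r}", lineno) from None
    name_raw = line[12:16]
    name = name_raw.strip()
    resname = line[17:20].strip() or line[17:21].strip()
    chain = line[21:22].strip()
    try:
        resseq = int(line[22:26])
    except ValueError:
        resseq = 0
    try:
        x = float(line[30:38])
        y = float(line[38:46])
        z = float(line[46:54])
    except ValueError:
        parts = line.split()
        try:
            x, y, z = (float(p) for p in parts[-6:-3]) if len(parts) >= 9 else (
                float(parts[-3]), float(parts[-2]), float(parts[-1]))
        except (IndexError, ValueError):
            raise ParseError(f"non-numeric coordinates in {line!r}", lineno) from None
    try:
        occ = float(line[54:60])
    except (ValueError, IndexError):
        occ = 1.0
    try:
        bfac = float(line[60:66])
    except (ValueError, IndexError):
        bfac = 0.0
    elem_field = line[76:78].strip() if len(line) >= 78 else ""
    if elem_field:
        try:
            z_elem = elements.atomic_number(elem_field)
        except KeyError:
            z_elem = elements.guess_element_from_pdb_name(name_raw)
    else:
        z_elem = elements.guess_element_from_pdb_name(name_raw or name)
    return serial, name, resname, chain, resseq, (x, y, z), occ, bfac, z_elem


def read_pdb(stream, name: str = "") -> Molecule:
    """Parse a PDB text stream (or string) into a molecule."""
    fh = _as_text_stream(stream)
    mol = Molecule(name)
    serial_to_index: dict[int, int] = {}
    current_res = None
    current_key = None
    conect: list[tuple[int, int]] = []
    for lineno, line in enumerate(fh, start=1):
        record = line[:6].strip().upper()
        tag = record[:4]
        if tag in ("ATOM", "HETA"):
            (serial, aname, resname, chain, resseq, pos, occ, bfac,
             z_elem) = _parse_atom_line(line.rstrip("\n"), lineno)
            atom = mol.create(ATOM)
            atom.set_s("name", aname)
            atom.set_v("position", pos)
            atom.set_i("element", z_elem)
            atom.set_d("occupancy", occ)
            atom.set_d("bfactor", bfac)
            serial_to_index[serial] = atom.index
            key = (resseq, chain, resname)
            if key != current_key:
                current_res = mol.create(RESD)
                current_res.set_s("name", resname)
                current_res.set_i("seq", resseq)
                current_res.set_s("chain", chain)
                current_key = key
            current_res.relate(atom)
        elif tag == "TER":
            current_key = None  # force a new residue grouping after TER
        elif tag == "CONE":
            fields = line.split()
            try:
                ids = [int(f) for f in fields[1:]]
            except ValueError:
                continue
            if ids:
                base = ids[0]
                for other in ids[1:]:
                    conect.append((min(base, other), max(base, other)))
        # every other record type is skipped
    seen = set()
    for i, j in conect:
        if (i, j) in seen or i == j:
            continue
        seen.add((i, j))
        if i in serial_to_index and j in serial_to_index:
            from ..hashkeys import BOND

            bond = mol.create(BOND)
            a = mol.handle(ATOM, serial_to_index[i])
            b = mol.handle(ATOM, serial_to_index[j])
            bond.relate(a)
            bond.relate(b)
            a.relate(b)
    return mol


def _format_atom_name(name: str) -> str:
    if len(name) > 4:
        warnings.warn(f"atom name {name!r} truncated to 4 characters for PDB")
        name = name[:4]
    if len(name) == 4:
        return name
    return f" {name:<3s}"


def write_pdb(mol: Molecule, stream) -> None:
    """Write fixed-column PDB v3.  Atoms need position and name properties."""
    from ..hashkeys import BOND

    natom = mol.natoms
    # residue membership per atom (for resname/resseq columns)
    res_of: dict[int, tuple[str, int, str]] = {}
    for ri, res in enumerate(mol.resds):
        rname = res.find_s("name")[1] or "UNK"
        rseq = res.find_i("seq")[1] or (ri + 1)
        chain = res.find_s("chain")[1] or ""
        for a in res.related(ATOM):
            res_of[a.index] = (rname, rseq, chain)
    for atom in mol.atoms:
        found, _ = atom.find_v("position")
        if not found:
            nm = atom.find_s("name")[1] or f"#{atom.user_id}"
            raise ValueError(f"atom {nm} has no position; cannot write PDB")
    for atom in mol.atoms:
        name = atom.find_s("name")[1] or elements.symbol(atom.get_i("element"))
        x, y, z = atom.get_v("position")
        rname, rseq, chain = res_of.get(atom.index, ("UNK", 1, ""))
        occ = atom.find_d("occupancy")[1]
        occ = 1.0 if occ is None else occ
        bfac = atom.find_d("bfactor")[1] or 0.0
        try:
            esym = elements.symbol(atom.get_i("element"))
        except (KeyError, Exception):
            esym = ""
        serial = atom.user_id % 100000  # serials roll over at 5 columns
        stream.write(
            "ATOM  %5d %s %-3s %1s%4d    %8.3f%8.3f%8.3f%6.2f%6.2f          %2s\n"
            % (serial, _format_atom_name(name), rname[:3], chain[:1] or " ",
               rseq % 10000, x, y, z, occ, bfac, esym.rjust(2)[:2])
        )
    # CONECT records preserve explicit bonds
    neighbors: dict[int, list[int]] = {}
    for bond in mol.objects(BOND):
        atoms = bond.related(ATOM)
        if len(atoms) != 2:
            continue
        i, j = atoms[0].user_id, atoms[1].user_id
        neighbors.setdefault(i, []).append(j)
        neighbors.setdefault(j, []).append(i)
    for i in sorted(neighbors):
        row = neighbors[i]
        for k in range(0, len(row), 4):
            chunk = row[k : k + 4]
            stream.write("CONECT%5d" % (i % 100000)
                         + "".join("%5d" % (j % 100000) for j in chunk) + "\n")
    stream.write("END\n")
    _ = natom
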