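"""MDL MOL/SDF V2000 reader and writer.

The atom block yields atoms with ``element`` and ``position``; the bond
block yields bonds with ``order`` (4 = aromatic); ``M  CHG`` lines set
formal charges (the legacy atom-block charge column is ignored, per the
V2000 rule that an M CHG line supersedes it); data fields (``> <tag>``)
become molecule-level text properties.  V3000 input is rejected.
"""

from __future__ import annotations

from .. import elements
from ..hashkeys import ATOM, BOND, RESD
from ..model import Molecule

__all__ = ["read_sdf", "write_sdf", "split_sdf_records"]


def _read_counts(line: str, lineno: int):
    from . import ParseError

    if "V3000" in line:
        raise ParseError("V3000 connection tables are not supported", lineno)
    try:
        natom = int(line[0:3])
        nbond = int(line[3:6])
    except ValueError:
        parts = line.split()
        try:
            natom, nbond = int(parts[0]), int(parts[1])
        except (IndexError, ValueError):
            raise ParseError(f"bad counts line {line!r}", lineno) from None
    return natom, nbond


def read_sdf(stream, name: str = "") -> Molecule:
    """Parse one MOL/SDF V2000 record (string or stream)."""
    from . import ParseError

    text = stream if isinstance(stream, str) else stream.read()
    lines = text.splitlines()
    if len(lines) < 4:
        raise ParseError("record too short for a V2000 connection table")
    title = lines[0].strip()
    natom, nbond = _read_counts(lines[3], 4)
    if len(lines) < 4 + natom + nbond:
        raise ParseError(
            f"counts line declares {natom} atoms / {nbond} bonds but the "
            f"record has only {len(lines) - 4} block lines", 4)
    mol = Molecule(name or title)
    for i in range(natom):
        lineno = 5 + i
        line = lines[4 + i]
        try:
            x = float(line[0:10])
            y = float(line[10:20])
            z = float(line[20:30])
            sym = line[31:34].strip()
        except (ValueError, IndexError):
            parts = line.split()
            try:
                x, y, z, sym = float(parts[0]), float(parts[1]), float(parts[2]), parts[3]
            except (IndexError, ValueError):
                raise ParseError(f"bad atom line {line!r}", lineno) from None
        atom = mol.create(ATOM)
        atom.set_v("position", (x, y, z))
        try:
            atom.set_i("element", elements.atomic_number(sym))
        except KeyError:
            raise ParseError(f"unknown element {sym!r}", lineno) from None
        atom.set_s("name", f"{sym}{atom.user_id}")
    for i in range(nbond):
        lineno = 5 + natom + i
        line = lines[4 + natom + i]
        try:
            a1 = int(line[0:3])
            a2 = int(line[3:6])
            order = int(line[6:9])
        except (ValueError, IndexError):
            parts = line.split()
            try:
                a1, a2, order = int(parts[0]), int(parts[1]), int(parts[2])
            except (IndexError, ValueError):
                raise ParseError(f"bad bond line {line!r}", lineno) from None
        if not (1 <= a1 <= natom and 1 <= a2 <= natom):
            raise ParseError(f"bond references atom out of range: {line!r}", lineno)
        bond = mol.create(BOND)
        ha = mol.handle(ATOM, a1 - 1)
        hb = mol.handle(ATOM, a2 - 1)
        bond.relate(ha)
        bond.relate(hb)
        bond.set_i("order", order)
        ha.relate(hb)
    # properties block and data fields
    i = 4 + natom + nbond
    datatag = None
    databuf: list[str] = []
    while i < len(lines):
        line = lines[i]
        if line.startswith("M  CHG"):
            parts = line.split()
            npairs = int(parts[2])
            for k in range(npairs):
                aid = int(parts[3 + 2 * k])
                chg = int(parts[4 + 2 * k])
                mol.handle(ATOM, aid - 1).set_i("fcharge", chg)
        elif line.startswith("M  END"):
            pass
        elif line.startswith(">"):
            if datatag is not None:
                mol.set_prop("s", datatag, "\n".join(databuf).strip())
            start = line.find("<")
            end = line.find(">", start + 1)
            datatag = line[start + 1 : end] if 0 <= start < end else line[1:].strip()
            databuf = []
        elif line.strip() == "$$$$":
            break
        elif datatag is not None:
            databuf.append(line)
        i += 1
    if datatag is not None:
        mol.set_prop("s", datatag, "\n".join(databuf).strip())
    if mol.natoms and mol.nresds == 0:
        res = mol.create(RESD)
        res.set_s("name", (mol.name or "MOL")[:3].upper() or "MOL")
        res.set_i("seq", 1)
        for a in mol.atoms:
            res.relate(a)
    return mol


def write_sdf(mol: Molecule, stream) -> None:
    natom = mol.natoms
    nbond = mol.count(BOND)
    stream.write(f"{mol.name or 'MOL'}\n  relmol\n\n")
    stream.write("%3d%3d  0  0  0  0  0  0  0  0999 V2000\n" % (natom, nbond))
    charges = []
    for atom in mol.atoms:
        found, pos = atom.find_v("position")
        x, y, z = pos if found else (0.0, 0.0, 0.0)
        sym = elements.symbol(atom.get_i("element"))
        stream.write("%10.4f%10.4f%10.4f %-3s 0  0  0  0  0  0  0  0  0  0  0  0\n"
                     % (x, y, z, sym))
        chg = atom.find_i("fcharge")[1]
        if chg:
            charges.append((atom.user_id, chg))
    for bond in mol.objects(BOND):
        atoms = bond.related(ATOM)
        order = bond.find_i("order")[1] or 1
        stream.write("%3d%3d%3d  0\n" % (atoms[0].user_id, atoms[1].user_id, order))
    for k in range(0, len(charges), 8):
        chunk = charges[k : k + 8]
        stream.write("M  CHG%3d" % len(chunk)
                     + "".join("%4d%4d" % pair for pair in chunk) + "\n")
    stream.write("M  END\n")
    for tag in mol.prop_names("s"):
        stream.write(f"> <{tag}>\n{mol.get_prop('s', tag)}\n\n")
    stream.write("$$$$\n")


def split_sdf_records(text: str) -> list[str]:
    """Split concatenated SDF text on ``$$$$`` separators."""
    records = []
    buf: list[str] = []
    for line in text.splitlines():
        buf.append(line)
        if line.strip() == "$$$$":
            records.append("\n".join(buf))
            buf = []
    if any(l.strip() for l in buf):
        records.append("\n".join(buf))
    return records
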