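"""Multi-molecule database loader for concatenated MOL2 or SDF files.

Each record is stored under its own title; unnamed records get sequential
``mol_<n>`` names and duplicate names are suffixed ``_2``, ``_3``, ... with
a warning.  The OFF format is recognised but unsupported.
"""

from __future__ import annotations

import warnings

from ..model import MoleculeDatabase
from .mol2 import read_mol2
from .sdf import read_sdf, split_sdf_records

__all__ = ["load_mdb", "UnsupportedFormatError"]


class UnsupportedFormatError(ValueError):
    pass


def _split_mol2_records(text: str) -> list[str]:
    records = []
    buf: list[str] = []
    for line in text.splitlines():
        if line.startswith("@<TRIPOS>MOLECULE") and buf:
            records.append("\n".join(buf))
            buf = []
        buf.append(line)
    if any(l.strip() for l in buf):
        records.append("\n".join(buf))
    return records


def load_mdb(stream, format_hint: str) -> MoleculeDatabase:
    """Load every record of a multi-molecule file into a database."""
    fmt = format_hint.lower()
    if fmt == "off":
        raise UnsupportedFormatError(
            "OFF-format molecule databases are not supported")
    if fmt not in ("mol2", "sdf"):
        raise ValueError(f"format_hint must be 'mol2' or 'sdf', got {format_hint!r}")
    text = stream if isinstance(stream, str) else stream.read()
    if fmt == "sdf":
        records = [read_sdf(r) for r in split_sdf_records(text)]
    else:
        records = [read_mol2(r) for r in _split_mol2_records(text)]
    db = MoleculeDatabase()
    for k, mol in enumerate(records, start=1):
        name = mol.name or f"mol_{k}"
        if name in db:
            base = name
            n = 2
            while f"{base}_{n}" in db:
                n += 1
            name = f"{base}_{n}"
            warnings.warn(f"duplicate molecule name {base!r}; stored as {name!r}")
        mol.name = name
        db.put(name, mol)
    return db
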