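"""Molecule file formats: PDB v3 fixed-column, TRIPOS MOL2, MDL SDF V2000."""

from .pdb import read_pdb, write_pdb
from .mol2 import read_mol2, write_mol2
from .sdf import read_sdf, write_sdf
from .mdb import load_mdb

__all__ = [
    "read_pdb", "write_pdb",
    "read_mol2", "write_mol2",
    "read_sdf", "write_sdf",
    "load_mdb",
    "ParseError",
]


class ParseError(ValueError):
    """A format violation, carrying the offending line number."""

    def __init__(self, message: str, line: int | None = None) -> None:
        if line is not None:
            message = f"line {line}: {message}"
        super().__init__(message)
        self.line = line
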