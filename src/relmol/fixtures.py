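"""Self-contained fixture molecules, a tiny force field, and their files.

Everything a test or demo needs is generated programmatically here — no
external downloads: a TIP3P-like water, methane, benzene, a 4-residue
peptide-like chain, monatomic Na+/Cl- ions, a 216-water solvent cube
(synthetic: a jittered lattice standing in for an equilibrated box, with a
deterministic seed), and a small AMBER-dialect parameter file that covers
every atom-type tuple the fixtures can generate.  ``generate_fixtures``
renders each molecule to PDB/MOL2/SDF plus the force-field text and writes a
checksum manifest; regeneration is byte-identical.
"""

from __future__ import annotations

import hashlib
import io
import json
import math
import os

import numpy as np

from .forcefield import ForceField, read_frc
from .formats import write_mol2, write_pdb, write_sdf
from .hashkeys import ATOM, BOND, RESD
from .model import Molecule
from .solvate import SolventTemplate

__all__ = [
    "water", "methane", "benzene", "peptide_chain", "water_cube",
    "water_template", "sodium_ion", "chloride_ion",
    "tiny_forcefield_text", "tiny_forcefield", "generate_fixtures",
]


def _add_atom(mol, res, name, z, pos, atype, q):
    atom = mol.create(ATOM)
    atom.set_s("name", name)
    atom.set_i("element", z)
    atom.set_v("position", pos)
    atom.set_s("type", atype)
    atom.set_d("pchg", q)
    res.relate(atom)
    return atom


def _bond(mol, a, b, order=1):
    bond = mol.create(BOND)
    bond.relate(a)
    bond.relate(b)
    bond.set_i("order", order)
    a.relate(b)
    return bond


def water(name: str = "wat") -> Molecule:
    """One TIP3P-like water (geometry 0.9572 A, 104.52 deg)."""
    mol = Molecule(name)
    res = mol.create(RESD)
    res.set_s("name", "WAT")
    res.set_i("seq", 1)
    r = 0.9572
    half = math.radians(104.52 / 2)
    o = _add_atom(mol, res, "O", 8, (0.0, 0.0, 0.0), "OW", -0.834)
    h1 = _add_atom(mol, res, "H1", 1,
                   (r * math.sin(half), r * math.cos(half), 0.0), "HW", 0.417)
    h2 = _add_atom(mol, res, "H2", 1,
                   (-r * math.sin(half), r * math.cos(half), 0.0), "HW", 0.417)
    _bond(mol, o, h1)
    _bond(mol, o, h2)
    return mol


def methane(name: str = "mth") -> Molecule:
    mol = Molecule(name)
    res = mol.create(RESD)
    res.set_s("name", "MTH")
    res.set_i("seq", 1)
    c = _add_atom(mol, res, "C1", 6, (0.0, 0.0, 0.0), "CT", -0.24)
    d = 1.09 / math.sqrt(3)
    dirs = [(d, d, d), (d, -d, -d), (-d, d, -d), (-d, -d, d)]
    for k, v in enumerate(dirs, start=1):
        h = _add_atom(mol, res, f"H{k}", 1, v, "HC", 0.06)
        _bond(mol, c, h)
    return mol


def benzene(name: str = "bnz", with_orders: bool = True) -> Molecule:
    """Benzene at ideal geometry (C-C 1.39, C-H 1.08); Kekule orders unless
    ``with_orders`` is false (bond orders left unset for perception tests)."""
    mol = Molecule(name)
    res = mol.create(RESD)
    res.set_s("name", "BNZ")
    res.set_i("seq", 1)
    rc, rh = 1.39, 1.39 + 1.08
    carbons, hydrogens = [], []
    for k in range(6):
        th = math.pi / 3 * k
        carbons.append(_add_atom(mol, res, f"C{k + 1}", 6,
                                 (rc * math.cos(th), rc * math.sin(th), 0.0),
                                 "CA", -0.115))
    for k in range(6):
        th = math.pi / 3 * k
        hydrogens.append(_add_atom(mol, res, f"H{k + 1}", 1,
                                   (rh * math.cos(th), rh * math.sin(th), 0.0),
                                   "HA", 0.115))
    for k in range(6):
        order = (2 if k % 2 == 0 else 1) if with_orders else 0
        b = _bond(mol, carbons[k], carbons[(k + 1) % 6])
        b.set_i("order", order)
        _bond(mol, carbons[k], hydrogens[k])
    return mol


def peptide_chain(nres: int = 4, name: str = "pep") -> Molecule:
    """A 4-residue peptide-like backbone (N-CA-C per residue, amide links)."""
    mol = Molecule(name)
    prev_c = None
    x = 0.0
    for r in range(nres):
        res = mol.create(RESD)
        res.set_s("name", "GLX")
        res.set_i("seq", r + 1)
        y = 0.4 if r % 2 == 0 else -0.4
        n = _add_atom(mol, res, "N", 7, (x, y, 0.0), "N", -0.3)
        ca = _add_atom(mol, res, "CA", 6, (x + 1.45, -y, 0.0), "CT", 0.1)
        c = _add_atom(mol, res, "C", 6, (x + 2.97, y, 0.0), "C", 0.2)
        _bond(mol, n, ca)
        _bond(mol, ca, c)
        if prev_c is not None:
            _bond(mol, prev_c, n)
        prev_c = c
        x += 4.30
    return mol


def sodium_ion(name: str = "na+") -> Molecule:
    mol = Molecule(name)
    res = mol.create(RESD)
    res.set_s("name", "NA+")
    res.set_i("seq", 1)
    a = _add_atom(mol, res, "NA+", 11, (0.0, 0.0, 0.0), "Na+", 1.0)
    a.set_i("fcharge", 1)
    return mol


def chloride_ion(name: str = "cl-") -> Molecule:
    mol = Molecule(name)
    res = mol.create(RESD)
    res.set_s("name", "CL-")
    res.set_i("seq", 1)
    a = _add_atom(mol, res, "CL-", 17, (0.0, 0.0, 0.0), "Cl-", -1.0)
    a.set_i("fcharge", -1)
    return mol


def water_cube(n_side: int = 6, spacing: float = 3.104, jitter: float = 0.10,
               seed: int = 20140627, name: str = "cube") -> Molecule:
    """A synthetic solvent cube: n_side^3 waters on a jittered lattice.

    This is a generated stand-in for an equilibrated water box — spacing
    3.104 A reproduces TIP3P density (~0.0334 waters/A^3); the jitter and
    random orientations are deterministic for a given seed.
    """
    rng = np.random.default_rng(seed)
    mol = Molecule(name)
    edge = n_side * spacing
    r = 0.9572
    half = math.radians(104.52 / 2)
    base = np.array([
        [0.0, 0.0, 0.0],
        [r * math.sin(half), r * math.cos(half), 0.0],
        [-r * math.sin(half), r * math.cos(half), 0.0],
    ])
    seq = 0
    for i in range(n_side):
        for j in range(n_side):
            for k in range(n_side):
                seq += 1
                res = mol.create(RESD)
                res.set_s("name", "WAT")
                res.set_i("seq", seq)
                centre = (np.array([i, j, k]) + 0.5) * spacing - edge / 2
                centre = centre + rng.uniform(-jitter, jitter, 3)
                # random rotation from a normalised quaternion
                quat = rng.normal(size=4)
                quat /= np.linalg.norm(quat)
                from scipy.spatial.transform import Rotation

                pts = Rotation.from_quat(quat).apply(base) + centre
                o = _add_atom(mol, res, "O", 8, pts[0], "OW", -0.834)
                h1 = _add_atom(mol, res, "H1", 1, pts[1], "HW", 0.417)
                h2 = _add_atom(mol, res, "H2", 1, pts[2], "HW", 0.417)
                _bond(mol, o, h1)
                _bond(mol, o, h2)
    mol.set_prop("v", "box", (edge, edge, edge))
    return mol


def water_template(n_side: int = 6, **kw) -> SolventTemplate:
    spacing = kw.pop("spacing", 3.104)
    mol = water_cube(n_side=n_side, spacing=spacing, **kw)
    return SolventTemplate(mol, solvlen=n_side * spacing)


def single_water_template() -> SolventTemplate:
    """A one-residue template (cell edge = 3.104 A) for small tests."""
    return SolventTemplate(water(), solvlen=3.104)


TINY_FRCMOD = """\
fixture force field (AMBER frcmod dialect) covering the packaged molecules
MASS
OW  16.00
HW   1.008
CT  12.01
HC   1.008
CA  12.01
HA   1.008
N   14.01
C   12.01
O   16.00
H    1.008
Na+ 22.99
Cl- 35.45

BOND
OW-HW  553.0    0.9572
CT-HC  340.0    1.090
CT-CT  310.0    1.526
CA-CA  469.0    1.400
CA-HA  367.0    1.080
N-CT   337.0    1.449
CT-C   317.0    1.522
C-N    490.0    1.335
C-O    570.0    1.229
N-H    434.0    1.010

ANGLE
HW-OW-HW   100.0   104.52
HC-CT-HC    35.0   109.50
CA-CA-CA    63.0   120.00
CA-CA-HA    50.0   120.00
N-CT-C      63.0   110.10
CT-C-N      70.0   116.60
C-N-CT      50.0   121.90
CT-C-O      80.0   120.40
N-C-O       80.0   122.90
CT-CT-HC    50.0   109.50
C-N-H       50.0   120.00
CT-N-H      38.0   118.04
HC-CT-C     50.0   109.50
HC-CT-N     50.0   109.50

DIHE
X -CA-CA-X    4   14.50       180.0      2.
X -CT-C -X    4    0.00       180.0      2.
X -C -N -X    4   10.00       180.0      2.
X -N -CT-X    6    0.00         0.0      3.
N -CT-C -N    1    0.40         0.0     -2.
N -CT-C -N    1    1.35       180.0      3.

IMPROPER
X -X -C -O         10.5        180.0      2.
X -X -CA-HA         1.1        180.0      2.
X -X -N -H          1.0        180.0      2.

NONBON
  OW   1.7683   0.1520
  HW   0.0000   0.0000
  CT   1.9080   0.1094
  HC   1.4870   0.0157
  CA   1.9080   0.0860
  HA   1.4590   0.0150
  N    1.8240   0.1700
  C    1.9080   0.0860
  O    1.6612   0.2100
  H    0.6000   0.0157
  Na+  1.8680   0.00277
  Cl-  2.4700   0.1000
"""


def tiny_forcefield_text() -> str:
    return TINY_FRCMOD


def tiny_forcefield() -> ForceField:
    return read_frc(TINY_FRCMOD)


def all_fixture_molecules() -> dict:
    return {
        "water": water(),
        "methane": methane(),
        "benzene": benzene(),
        "chain": peptide_chain(),
        "na_ion": sodium_ion(),
        "cl_ion": chloride_ion(),
    }


def generate_fixtures(output_dir: str) -> dict:
    """Render every fixture to PDB/MOL2/SDF (plus the solvent cube as PDB
    and the force field) under ``output_dir``; returns the manifest."""
    os.makedirs(output_dir, exist_ok=True)
    manifest: dict[str, str] = {}

    def emit(fname: str, text: str) -> None:
        path = os.path.join(output_dir, fname)
        with open(path, "w") as fh:
            fh.write(text)
        manifest[fname] = hashlib.sha256(text.encode()).hexdigest()

    for key, mol in all_fixture_molecules().items():
        for fmt, writer in (("pdb", write_pdb), ("mol2", write_mol2),
                            ("sdf", write_sdf)):
            buf = io.StringIO()
            writer(mol, buf)
            emit(f"{key}.{fmt}", buf.getvalue())
    cube = water_cube()
    buf = io.StringIO()
    write_pdb(cube, buf)
    emit("watbox.pdb", buf.getvalue())
    buf = io.StringIO()
    write_mol2(cube, buf)  # keeps atom types and charges for pipelines
    emit("watbox.mol2", buf.getvalue())
    emit("tiny.frcmod", TINY_FRCMOD)
    manifest_path = os.path.join(output_dir, "manifest.json")
    with open(manifest_path, "w") as fh:
        json.dump(manifest, fh, indent=1, sort_keys=True)
        fh.write("\n")
    return manifest
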