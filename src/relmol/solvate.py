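"""Solvation builders: shell, cuboid box, truncated-octahedron box, cap, ions.

All four modes share one engine: the solute's bounding box is stretched by
the requested margin, solvent-template copies are tiled across it on a grid
of spacing ``solvlen`` (the edge of one solvent cell), and each candidate
solvent residue is kept or discarded by geometric tests — a clash cut
(distance below ``closeness x (r1 + r2)`` to any solute atom, where r1/r2
are solute/solvent van-der-Waals radii; an additive ``r1 + r2 + closeness``
variant is selectable), a region test (box interior, truncated-octahedron
interior, or cap sphere) applied to the residue centroid, and for shells an
outer border (minimum solute distance above ``extent`` discards).  Tiling is
fully deterministic.  ``addions`` places counter-ions at extrema of a coarse
Coulomb potential grid.
"""

from __future__ import annotations

import math
from dataclasses import dataclass

import numpy as np

from . import elements
from .hashkeys import ATOM, BOND, RESD
from .model import Molecule

__all__ = ["SolventTemplate", "solvate_shell", "solvate_box", "solvate_oct",
           "solvate_cap", "addions"]


@dataclass
class SolventTemplate:
    """A solvent cell: a (multi-)residue molecule plus its cell edge length."""

    mol: Molecule
    solvlen: float

    def __post_init__(self) -> None:
        if self.solvlen <= 0:
            raise ValueError("solvlen must be positive")


@dataclass
class _ResidueData:
    names: list
    types: list
    charges: list
    zs: list
    pos: np.ndarray       # (m, 3), template frame
    radii: np.ndarray     # (m,)
    bonds: list           # (local_i, local_j, order)
    resname: str


def _template_residues(template: SolventTemplate) -> list[_ResidueData]:
    mol = template.mol
    if mol.natoms == 0:
        raise ValueError("solvent template has no atoms")
    # center the template at the origin (invariant of the template contract)
    allpos = mol.positions()
    centroid = allpos.mean(axis=0)
    out = []
    for res in mol.resds:
        atoms = list(res.related(ATOM))
        local = {a.index: k for k, a in enumerate(atoms)}
        pos = np.array([a.pos for a in atoms]) - centroid
        zs = [a.get_i("element") for a in atoms]
        bonds = []
        for b in mol.bonds:
            ba = b.related(ATOM)
            if len(ba) == 2 and ba[0].index in local and ba[1].index in local:
                bonds.append((local[ba[0].index], local[ba[1].index],
                              b.find_i("order")[1] or 1))
        out.append(_ResidueData(
            names=[a.find_s("name")[1] or elements.symbol(z)
                   for a, z in zip(atoms, zs)],
            types=[a.find_s("type")[1] or "" for a in atoms],
            charges=[a.find_d("pchg")[1] or 0.0 for a in atoms],
            zs=zs,
            pos=pos,
            radii=np.array([elements.vdw_radius(z) for z in zs]),
            bonds=bonds,
            resname=res.find_s("name")[1] or "WAT",
        ))
    if not out:
        raise ValueError("solvent template has no residues")
    return out


def _solute_arrays(mol: Molecule):
    if mol.natoms == 0:
        raise ValueError("solute has no atoms")
    pos = mol.positions()
    radii = np.array([elements.vdw_radius(a.get_i("element")) for a in mol.atoms])
    return pos, radii


def _append_residue(mol: Molecule, data: _ResidueData, coords: np.ndarray) -> None:
    res = mol.create(RESD)
    res.set_s("name", data.resname)
    res.set_i("seq", mol.nresds)
    new_atoms = []
    for k in range(len(data.zs)):
        atom = mol.create(ATOM)
        atom.set_s("name", data.names[k])
        atom.set_i("element", data.zs[k])
        atom.set_v("position", coords[k])
        if data.types[k]:
            atom.set_s("type", data.types[k])
        atom.set_d("pchg", data.charges[k])
        res.relate(atom)
        new_atoms.append(atom)
    for i, j, order in data.bonds:
        bond = mol.create(BOND)
        bond.relate(new_atoms[i])
        bond.relate(new_atoms[j])
        bond.set_i("order", order)
        new_atoms[i].relate(new_atoms[j])


def _clash(coords: np.ndarray, res_radii: np.ndarray, solute_pos: np.ndarray,
           solute_radii: np.ndarray, closeness: float, clash_rule: str) -> bool:
    d = np.linalg.norm(coords[:, None, :] - solute_pos[None, :, :], axis=2)
    if clash_rule == "scale":
        cut = closeness * (solute_radii[None, :] + res_radii[:, None])
    elif clash_rule == "add":
        cut = solute_radii[None, :] + res_radii[:, None] + closeness
    else:
        raise ValueError(f"unknown clash rule {clash_rule!r}")
    return bool((d < cut).any())


def _min_distance(coords: np.ndarray, solute_pos: np.ndarray) -> float:
    d = np.linalg.norm(coords[:, None, :] - solute_pos[None, :, :], axis=2)
    return float(d.min())


def _tile(mol: Molecule, template: SolventTemplate, margin: float,
          closeness: float, clash_rule: str, region_test, extent: float | None,
          ) -> tuple[int, np.ndarray]:
    """Shared tiling engine; returns (number added, region size vector)."""
    if closeness <= 0:
        raise ValueError("closeness must be positive")
    solute_pos, solute_radii = _solute_arrays(mol)
    lo = solute_pos.min(axis=0) - margin
    hi = solute_pos.max(axis=0) + margin
    size = hi - lo
    residues = _template_residues(template)
    sl = template.solvlen
    counts = [max(1, int(math.ceil(s / sl))) for s in size]
    added = 0
    for ix in range(counts[0]):
        for iy in range(counts[1]):
            for iz in range(counts[2]):
                offset = lo + sl * (np.array([ix, iy, iz]) + 0.5)
                for data in residues:
                    coords = data.pos + offset
                    centroid = coords.mean(axis=0)
                    if not region_test(centroid, lo, hi):
                        continue
                    if _clash(coords, data.radii, solute_pos, solute_radii,
                              closeness, clash_rule):
                        continue
                    if extent is not None and _min_distance(coords, solute_pos) > extent:
                        continue
                    _append_residue(mol, data, coords)
                    added += 1
    return added, size


def _in_box(centroid, lo, hi) -> bool:
    return bool(np.all(centroid >= lo) and np.all(centroid <= hi))


def _in_oct(centroid, lo, hi) -> bool:
    # anisotropic truncated octahedron: in normalised half-length coordinates
    # u = (x - cx) / (Lx/2), keep |u| + |v| + |w| <= 3/2 (the classic
    # |x|+|y|+|z| <= 3a/4 corner clipping of a cube of side a)
    if not _in_box(centroid, lo, hi):
        return False
    c = (lo + hi) / 2.0
    half = np.maximum((hi - lo) / 2.0, 1e-12)
    u = np.abs((centroid - c) / half)
    return bool(u.sum() <= 1.5 + 1e-12)


def solvate_shell(mol: Molecule, template: SolventTemplate, closeness: float,
                  extent: float, clash_rule: str = "scale") -> int:
    """Add a solvent shell: keep residues with min solute distance in
    [clash cut, extent].  Returns the number of residues added."""
    if extent <= 0 or closeness <= 0:
        raise ValueError("closeness and extent must be positive")
    if extent <= closeness:
        raise ValueError("extent must exceed closeness for a shell")
    added, size = _tile(mol, template, extent, closeness, clash_rule,
                        _in_box, extent)
    mol.set_prop("v", "box", tuple(size))
    return added


def solvate_box(mol: Molecule, template: SolventTemplate, buffer: float,
                closeness: float = 1.0, clash_rule: str = "scale") -> int:
    """Cuboid solvation: solute bounding box stretched by ``buffer``."""
    if buffer < 0:
        raise ValueError("buffer must be non-negative")
    added, size = _tile(mol, template, buffer, closeness, clash_rule,
                        _in_box, None)
    mol.set_prop("v", "box", tuple(size))
    mol.set_prop("s", "boxshape", "cuboid")
    return added


def solvate_oct(mol: Molecule, template: SolventTemplate, buffer: float,
                closeness: float = 1.0, clash_rule: str = "scale") -> int:
    """Truncated-octahedron solvation (never more residues than the box)."""
    if buffer < 0:
        raise ValueError("buffer must be non-negative")
    added, size = _tile(mol, template, buffer, closeness, clash_rule,
                        _in_oct, None)
    mol.set_prop("v", "box", tuple(size))
    mol.set_prop("s", "boxshape", "truncated_octahedron")
    return added


def solvate_cap(mol: Molecule, template: SolventTemplate, center,
                radius: float, closeness: float = 1.0,
                clash_rule: str = "scale") -> int:
    """Spherical cap of solvent about ``center``."""
    if radius <= 0:
        raise ValueError("cap radius must be positive")
    c = np.asarray(center, dtype=float)

    def in_cap(centroid, lo, hi) -> bool:
        return bool(np.linalg.norm(centroid - c) <= radius + 1e-12)

    solute_pos, _ = _solute_arrays(mol)
    # the tiling region must cover the cap sphere as well as the solute
    margin = float(radius + np.abs(solute_pos.mean(axis=0) - c).max())
    added, _size = _tile(mol, template, margin, closeness, clash_rule,
                         in_cap, None)
    mol.set_prop("v", "cap_center", tuple(c))
    mol.set_prop("d", "cap_radius", float(radius))
    return added


def net_charge(mol: Molecule) -> float:
    total = 0.0
    for a in mol.atoms:
        found, q = a.find_d("pchg")
        if found:
            total += q
        else:
            total += a.find_i("fcharge")[1] or 0
    return total


def addions(mol: Molecule, ion_template: Molecule, count: "int | str" = "auto",
            closeness: float = 3.0, grid_spacing: float = 2.0) -> int:
    """Place counter-ions at Coulomb-potential extrema.

    ``count='auto'`` places ceil(|net charge|) ions, requiring the ion's
    charge to oppose the solute's net charge; an explicit integer places
    exactly that many.  Each ion lands on the coarse-grid point with the
    most favourable potential that stays at least ``closeness`` Angstrom
    from every existing atom.  Returns the number of ions placed.
    """
    ion_res = _template_residues(SolventTemplate(ion_template, 1.0))[0]
    ion_charge = sum(ion_res.charges)
    if ion_charge == 0:
        fc = sum(a.find_i("fcharge")[1] or 0 for a in ion_template.atoms)
        ion_charge = float(fc)
        ion_res.charges = [float(fc)] if len(ion_res.charges) == 1 else ion_res.charges
    if count == "auto":
        q_net = net_charge(mol)
        n = int(math.ceil(abs(q_net) - 1e-9))
        if n == 0:
            return 0
        if ion_charge == 0 or q_net * ion_charge > 0:
            raise ValueError(
                "auto ion placement needs an ion of sign opposite to the "
                f"solute net charge ({q_net:+.3f})")
    else:
        n = int(count)
        if n < 0:
            raise ValueError("ion count must be non-negative")
        if n == 0:
            return 0
    pos = mol.positions()
    charges = np.array([a.find_d("pchg")[1] or float(a.find_i("fcharge")[1] or 0)
                        for a in mol.atoms])
    lo = pos.min(axis=0) - 6.0
    hi = pos.max(axis=0) + 6.0
    axes = [np.arange(lo[k], hi[k] + 1e-9, grid_spacing) for k in range(3)]
    gx, gy, gz = np.meshgrid(*axes, indexing="ij")
    grid = np.column_stack([gx.ravel(), gy.ravel(), gz.ravel()])
    d = np.linalg.norm(grid[:, None, :] - pos[None, :, :], axis=2)
    potential = (charges[None, :] / np.maximum(d, 0.1)).sum(axis=1)
    blocked = (d < closeness).any(axis=1)
    placed = 0
    for _ in range(n):
        score = potential * np.sign(ion_charge)
        score = np.where(blocked, np.inf, score)
        k = int(np.argmin(score))
        if not np.isfinite(score[k]):
            raise ValueError("no grid point satisfies the closeness cut")
        point = grid[k]
        coords = ion_res.pos + point
        _append_residue(mol, ion_res, coords)
        placed += 1
        dd = np.linalg.norm(grid - point[None, :], axis=1)
        potential += ion_charge / np.maximum(dd, 0.1)
        blocked |= dd < closeness
    return placed
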