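"""Bonded, direct nonbonded and Generalized-Born energies (kcal/mol).

Bonded terms use the AMBER functional forms

    E_bond  = sum k (r - r0)^2
    E_angle = sum k (theta - theta0)^2
    E_tors  = sum (Vn/2) (1 + cos(n phi - gamma))

The direct nonbonded sum runs over unique pairs, excludes 1-2 and 1-3
neighbours, scales 1-4 pairs by 1/1.2 (electrostatics) and 1/2.0
(Lennard-Jones), and under periodic boundary conditions applies the
minimum-image convention with a cutoff below half the shortest box edge
(no Ewald summation).  The Coulomb prefactor is INVCHG2 = 332.05
kcal*Angstrom/(mol*e^2).

The Generalized-Born polar desolvation term is

    E_GB = -INVCHG2 (1 - 1/eps) sum_{j = i+1..n} q_i q_j / f_GB,
    f_GB = [ r_ij^2 + a_ij^2 exp(-r_ij^2 / (2 a_ij^2)) ]^(1/2),
    a_ij^2 = a_i a_j,

summed over distinct pairs exactly as written — no self-energy (i = j) term
and no bonded exclusions — with water dielectric eps = 78.5 by default and
the effective Born radii a_i taken from the per-atom ``born`` property (an
mbondi-like per-element default fills absent values).  The exponent
denominator 2*a_ij^2 is kept as the model's definition; the GB literature's
common 4*a_i*a_j variant is available as an option.
"""

from __future__ import annotations

import math
from dataclasses import dataclass, field

import numpy as np

from . import elements
from .forcefield import ForceField, MissingParameterError
from .hashkeys import ANGL, ATOM, BOND, OOPS, TORS
from .model import Molecule, ObjectHandle

__all__ = [
    "INVCHG2", "DEFAULT_DIELECTRIC", "GBParameters", "EnergyReport",
    "enumerate_terms", "eval_bond", "eval_angl", "eval_tors", "eval_oops",
    "nonbond_direct", "nonbond_egb", "energy_report", "born_radii",
    "exclusion_pairs", "derive_coulomb_constant", "dihedral_angle",
]

#: Coulomb conversion constant, kcal*Angstrom/(mol*e^2)
INVCHG2 = 332.05
#: dielectric constant of water
DEFAULT_DIELECTRIC = 78.5

SCEE = 1.2  # 1-4 electrostatic divider
SCNB = 2.0  # 1-4 Lennard-Jones divider


def derive_coulomb_constant() -> float:
    """Recompute the Coulomb prefactor K_e * e^2 * N_A per Angstrom in
    kcal/mol from CODATA physical constants."""
    from scipy import constants

    k_e = 1.0 / (4.0 * math.pi * constants.epsilon_0)   # N m^2 / C^2
    joule_per_mol = k_e * constants.e**2 * constants.N_A / 1e-10
    return joule_per_mol / (constants.calorie * 1000.0)


# ---------------------------------------------------------------------------
# term enumeration


def _neighbor_map(mol: Molecule) -> dict[int, list[int]]:
    nbrs: dict[int, list[int]] = {a.index: [] for a in mol.atoms}
    for bond in mol.objects(BOND):
        atoms = bond.related(ATOM)
        if len(atoms) != 2:
            continue
        i, j = atoms[0].index, atoms[1].index
        if j not in nbrs[i]:
            nbrs[i].append(j)
        if i not in nbrs[j]:
            nbrs[j].append(i)
    return nbrs


def _term_tuple(h: ObjectHandle) -> tuple[int, ...]:
    return tuple(a.index for a in h.related(ATOM))


def _is_trigonal_center(mol: Molecule, idx: int, nbrs) -> bool:
    atom = mol.handle(ATOM, idx)
    z = atom.get_i("element")
    if z not in (6, 7) or len(nbrs[idx]) != 3:
        return False
    from .structops import AROMATIC_ORDER

    def has_unsat(a: ObjectHandle) -> bool:
        return any((b.find_i("order")[1] or 1) in (2, AROMATIC_ORDER)
                   for b in a.related(BOND))

    return has_unsat(atom) or any(has_unsat(mol.handle(ATOM, j))
                                  for j in nbrs[idx])


def enumerate_terms(mol: Molecule) -> None:
    """Create angle / torsion / improper objects from the bond graph.

    Angles are connected triples, torsions connected quadruples unique up to
    reversal, impropers sit at trigonal C/N centres (centre atom third, per
    the AMBER convention).  Re-invocation never duplicates terms.
    """
    nbrs = _neighbor_map(mol)
    existing_angl = {_term_tuple(h) for h in mol.objects(ANGL)}
    existing_tors = {_term_tuple(h) for h in mol.objects(TORS)}
    existing_oops = {_term_tuple(h) for h in mol.objects(OOPS)}

    def make(tc, indices):
        term = mol.create(tc)
        for i in indices:
            term.relate(mol.handle(ATOM, i))

    for j in sorted(nbrs):
        around = sorted(nbrs[j])
        for a in range(len(around)):
            for b in range(a + 1, len(around)):
                i, k = around[a], around[b]
                t = (i, j, k) if (i, j, k) <= (k, j, i) else (k, j, i)
                if t not in existing_angl and tuple(reversed(t)) not in existing_angl:
                    existing_angl.add(t)
                    make(ANGL, t)
    for j in sorted(nbrs):
        for k in sorted(nbrs[j]):
            if k <= j:
                continue
            for i in sorted(nbrs[j]):
                if i == k:
                    continue
                for l in sorted(nbrs[k]):
                    if l == j or l == i:
                        continue
                    t = (i, j, k, l)
                    r = tuple(reversed(t))
                    canon = min(t, r)
                    if canon in existing_tors:
                        continue
                    existing_tors.add(canon)
                    make(TORS, canon)
    for c in sorted(nbrs):
        if not _is_trigonal_center(mol, c, nbrs):
            continue
        i, j, l = sorted(nbrs[c])
        t = (i, j, c, l)
        if t not in existing_oops:
            existing_oops.add(t)
            make(OOPS, t)


# ---------------------------------------------------------------------------
# bonded energies


def _atom_type(a: ObjectHandle) -> str:
    found, t = a.find_s("type")
    if not found or not t:
        raise MissingParameterError("atom type", (a.find_s("name")[1] or
                                                  str(a.user_id),))
    return t


def eval_bond(mol: Molecule, ff: ForceField) -> float:
    total = 0.0
    for bond in mol.objects(BOND):
        a, b = bond.related(ATOM)
        k, r0 = ff.bond(_atom_type(a), _atom_type(b))
        r = float(np.linalg.norm(a.pos - b.pos))
        total += k * (r - r0) ** 2
    return total


def _angle_value(p1, p2, p3) -> float:
    v1 = p1 - p2
    v2 = p3 - p2
    cosang = np.dot(v1, v2) / (np.linalg.norm(v1) * np.linalg.norm(v2))
    return float(math.acos(max(-1.0, min(1.0, cosang))))


def eval_angl(mol: Molecule, ff: ForceField) -> float:
    total = 0.0
    for angle in mol.objects(ANGL):
        a, b, c = angle.related(ATOM)
        k, th0 = ff.angle(_atom_type(a), _atom_type(b), _atom_type(c))
        th = _angle_value(a.pos, b.pos, c.pos)
        total += k * (th - th0) ** 2
    return total


def dihedral_angle(p1, p2, p3, p4) -> float:
    """Signed dihedral angle (radians) of four points."""
    b1 = p2 - p1
    b2 = p3 - p2
    b3 = p4 - p3
    n1 = np.cross(b1, b2)
    n2 = np.cross(b2, b3)
    m1 = np.cross(n1, b2 / np.linalg.norm(b2))
    x = np.dot(n1, n2)
    y = np.dot(m1, n2)
    return float(math.atan2(y, x))


def eval_tors(mol: Molecule, ff: ForceField) -> float:
    total = 0.0
    for tors in mol.objects(TORS):
        a, b, c, d = tors.related(ATOM)
        terms = ff.torsion(_atom_type(a), _atom_type(b), _atom_type(c),
                           _atom_type(d))
        phi = dihedral_angle(a.pos, b.pos, c.pos, d.pos)
        for term in terms:
            total += (term.pk / term.idivf) * (
                1.0 + math.cos(term.pn * phi - term.phase))
    return total


def eval_oops(mol: Molecule, ff: ForceField) -> float:
    total = 0.0
    for oops in mol.objects(OOPS):
        a, b, c, d = oops.related(ATOM)
        terms = ff.improper(_atom_type(a), _atom_type(b), _atom_type(c),
                            _atom_type(d))
        phi = dihedral_angle(a.pos, b.pos, c.pos, d.pos)
        for term in terms:
            total += (term.pk / term.idivf) * (
                1.0 + math.cos(term.pn * phi - term.phase))
    return total


# ---------------------------------------------------------------------------
# nonbonded


def exclusion_pairs(mol: Molecule) -> tuple[set, set]:
    """(excluded 1-2/1-3 pairs, scaled 1-4 pairs), as i<j index tuples.

    A pair's class is its shortest bond-graph separation, so ring atoms that
    are simultaneously 1-4 and 1-3 are excluded, not scaled.
    """
    nbrs = _neighbor_map(mol)
    excluded: set[tuple[int, int]] = set()
    scaled: set[tuple[int, int]] = set()
    for i in nbrs:
        # BFS to depth 3
        dist = {i: 0}
        frontier = [i]
        for depth in (1, 2, 3):
            nxt = []
            for u in frontier:
                for v in nbrs[u]:
                    if v not in dist:
                        dist[v] = depth
                        nxt.append(v)
            frontier = nxt
        for j, d in dist.items():
            if j <= i:
                continue
            if d in (1, 2):
                excluded.add((i, j))
            elif d == 3:
                scaled.add((i, j))
    return excluded, scaled


def _charges(mol: Molecule) -> np.ndarray:
    out = []
    for a in mol.atoms:
        found, q = a.find_d("pchg")
        if not found:
            raise ValueError(f"atom {a.user_id} has no partial charge")
        out.append(q)
    return np.array(out)


def nonbond_direct(mol: Molecule, ff: ForceField, cutoff: float | None = None,
                   box=None) -> tuple[float, float]:
    """Direct pairwise (electrostatic, Lennard-Jones) energies in kcal/mol.

    ``box`` (3-vector, Angstrom) switches on orthorhombic minimum-image
    periodicity; then ``cutoff`` is required and must stay below half the
    shortest box edge.
    """
    n = mol.natoms
    if n == 0:
        return 0.0, 0.0
    pos = mol.positions()
    q = _charges(mol)
    rmin2 = np.empty(n)
    eps = np.empty(n)
    for a in mol.atoms:
        r_, e_ = ff.vdw(_atom_type(a))
        rmin2[a.index] = r_
        eps[a.index] = e_
    if box is not None:
        box = np.asarray(box, dtype=float)
        if cutoff is None:
            raise ValueError("periodic evaluation requires a cutoff")
        if cutoff >= box.min() / 2.0:
            raise ValueError(
                f"cutoff {cutoff} must be below half the shortest box edge "
                f"({box.min() / 2.0})")
    excluded, scaled = exclusion_pairs(mol)
    diff = pos[:, None, :] - pos[None, :, :]
    if box is not None:
        diff -= box[None, None, :] * np.round(diff / box[None, None, :])
    r = np.linalg.norm(diff, axis=2)
    iu, ju = np.triu_indices(n, k=1)
    rij = r[iu, ju]
    elec_scale = np.ones(len(iu))
    vdw_scale = np.ones(len(iu))
    for k in range(len(iu)):
        pair = (int(iu[k]), int(ju[k]))
        if pair in excluded:
            elec_scale[k] = vdw_scale[k] = 0.0
        elif pair in scaled:
            elec_scale[k] = 1.0 / SCEE
            vdw_scale[k] = 1.0 / SCNB
    if cutoff is not None:
        inside = rij <= cutoff
        elec_scale = np.where(inside, elec_scale, 0.0)
        vdw_scale = np.where(inside, vdw_scale, 0.0)
    with np.errstate(divide="ignore", invalid="ignore"):
        inv_r = np.where(rij > 0, 1.0 / rij, 0.0)
    elec = float(INVCHG2 * np.sum(elec_scale * q[iu] * q[ju] * inv_r))
    rmin_pair = rmin2[iu] + rmin2[ju]
    eps_pair = np.sqrt(eps[iu] * eps[ju])
    ratio6 = np.where(rij > 0, (rmin_pair * inv_r) ** 6, 0.0)
    lj = eps_pair * (ratio6**2 - 2.0 * ratio6)
    vdw = float(np.sum(vdw_scale * lj))
    return elec, vdw


# ---------------------------------------------------------------------------
# Generalized Born


def born_radii(mol: Molecule) -> np.ndarray:
    """Per-atom effective Born radii: the ``born`` property, or the
    packaged per-element default where unset."""
    out = []
    for a in mol.atoms:
        found, r = a.find_d("born")
        if found and r != 0.0:
            if r < 0:
                raise ValueError(f"atom {a.user_id} has a non-positive Born "
                                 f"radius ({r})")
            out.append(r)
        else:
            out.append(elements.born_radius(a.get_i("element")))
    return np.array(out)


@dataclass
class GBParameters:
    """Inputs of the pairwise GB sum."""

    dielectric: float = DEFAULT_DIELECTRIC
    invchg2: float = INVCHG2
    exponent_rule: str = "model"  # "model": 2*a_ij^2; "literature": 4*a_i*a_j
    charges: np.ndarray | None = None
    radii: np.ndarray | None = None

    def __post_init__(self) -> None:
        if self.dielectric <= 1:
            raise ValueError("solvent dielectric must exceed 1")
        if self.exponent_rule not in ("model", "literature"):
            raise ValueError(f"unknown exponent rule {self.exponent_rule!r}")


def gb_f(r: np.ndarray, ai: np.ndarray, aj: np.ndarray,
         exponent_rule: str = "model") -> np.ndarray:
    """The GB effective distance f_GB(r; a_i, a_j)."""
    aij2 = ai * aj
    denom = 2.0 * aij2 if exponent_rule == "model" else 4.0 * aij2
    return np.sqrt(r**2 + aij2 * np.exp(-(r**2) / denom))


def nonbond_egb(mol: Molecule, gb: GBParameters | None = None) -> float:
    """Pairwise GB polar desolvation energy (kcal/mol), distinct pairs only."""
    gb = gb or GBParameters()
    n = mol.natoms
    if n < 2:
        return 0.0
    q = gb.charges if gb.charges is not None else _charges(mol)
    alpha = gb.radii if gb.radii is not None else born_radii(mol)
    q = np.asarray(q, dtype=float)
    alpha = np.asarray(alpha, dtype=float)
    if len(q) != n or len(alpha) != n:
        raise ValueError("charges/radii length must equal the atom count")
    if np.any(alpha <= 0):
        bad = int(np.argmax(alpha <= 0)) + 1
        raise ValueError(f"atom {bad} has a non-positive Born radius")
    pos = mol.positions()
    iu, ju = np.triu_indices(n, k=1)
    r = np.linalg.norm(pos[iu] - pos[ju], axis=1)
    f = gb_f(r, alpha[iu], alpha[ju], gb.exponent_rule)
    return float(-gb.invchg2 * (1.0 - 1.0 / gb.dielectric)
                 * np.sum(q[iu] * q[ju] / f))


# ---------------------------------------------------------------------------
# report


@dataclass
class EnergyReport:
    bond: float = 0.0
    angle: float = 0.0
    torsion: float = 0.0
    improper: float = 0.0
    elec_direct: float = 0.0
    vdw: float = 0.0
    egb: float = 0.0
    extras: dict = field(default_factory=dict)

    @property
    def total(self) -> float:
        return (self.bond + self.angle + self.torsion + self.improper
                + self.elec_direct + self.vdw + self.egb)

    def __str__(self) -> str:
        lines = [
            f"bond      {self.bond:14.4f} kcal/mol",
            f"angle     {self.angle:14.4f} kcal/mol",
            f"torsion   {self.torsion:14.4f} kcal/mol",
            f"improper  {self.improper:14.4f} kcal/mol",
            f"elec      {self.elec_direct:14.4f} kcal/mol",
            f"vdw       {self.vdw:14.4f} kcal/mol",
        ]
        if self.egb:
            lines.append(f"egb       {self.egb:14.4f} kcal/mol")
        lines.append(f"total     {self.total:14.4f} kcal/mol")
        return "\n".join(lines)


def energy_report(mol: Molecule, ff: ForceField, gb: bool = False,
                  cutoff: float | None = None, box=None) -> EnergyReport:
    """Evaluate every term (enumerating angles/torsions when absent)."""
    if mol.count(ANGL) == 0 and mol.count(TORS) == 0:
        enumerate_terms(mol)
    elec, vdw = nonbond_direct(mol, ff, cutoff=cutoff, box=box)
    report = EnergyReport(
        bond=eval_bond(mol, ff),
        angle=eval_angl(mol, ff),
        torsion=eval_tors(mol, ff),
        improper=eval_oops(mol, ff),
        elec_direct=elec,
        vdw=vdw,
    )
    if gb:
        report.egb = nonbond_egb(mol)
    return report
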