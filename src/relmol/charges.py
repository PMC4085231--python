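"""Fallback partial-charge assignment (Gasteiger-style PEOE).

``assign_partial_charges`` runs a small iterative electronegativity
equalisation with per-element orbital parameters, seeded from formal
charges, and stores the result in the ``pchg`` property.  It is a built-in
fallback with per-element (not per-hybridisation) parameters — adequate for
rough electrostatics on the packaged fixtures, not a replacement for a real
charge model (AM1-BCC, RESP).  Total charge is conserved exactly because
every update is a pairwise transfer along a bond.

Implicit hydrogens (the ``nhyd`` property) are treated as real electronegative
partners so that, e.g., a bare SMILES oxygen still polarises.
"""

from __future__ import annotations

from .hashkeys import ATOM, BOND
from .model import Molecule

__all__ = ["assign_partial_charges"]

# (a, b, c) of chi(q) = a + b q + c q^2, per element
_PEOE = {
    1: (7.17, 6.24, -0.56),
    6: (7.98, 9.18, 1.88),
    7: (11.54, 10.82, 1.36),
    8: (14.18, 12.92, 1.39),
    9: (14.66, 13.85, 2.31),
    15: (8.90, 8.24, 0.96),
    16: (10.14, 9.13, 1.38),
    17: (11.00, 9.69, 1.35),
    35: (10.08, 8.47, 1.16),
    53: (9.90, 7.96, 0.96),
}
_DEFAULT = (7.5, 7.0, 1.0)

_N_ITER = 6


def _chi(z: int, q: float) -> float:
    a, b, c = _PEOE.get(z, _DEFAULT)
    return a + b * q + c * q * q


def _chi_plus(z: int) -> float:
    a, b, c = _PEOE.get(z, _DEFAULT)
    return a + b + c


def assign_partial_charges(mol: Molecule) -> None:
    n = mol.natoms
    q = [float(a.find_i("fcharge")[1] or 0) for a in mol.atoms]
    z = [a.get_i("element") for a in mol.atoms]
    nhyd = [a.find_i("nhyd")[1] or 0 for a in mol.atoms]
    qh = [0.0] * n  # charge pooled on each atom's implicit hydrogens
    pairs = []
    for bond in mol.objects(BOND):
        atoms = bond.related(ATOM)
        if len(atoms) == 2:
            pairs.append((atoms[0].index, atoms[1].index))
    damp = 1.0
    for _ in range(_N_ITER):
        damp *= 0.5
        dq = [0.0] * n
        dqh = [0.0] * n
        for i, j in pairs:
            ci = _chi(z[i], q[i])
            cj = _chi(z[j], q[j])
            if ci == cj:
                continue
            donor = i if ci < cj else j
            scale = _chi_plus(z[donor])
            t = (cj - ci) / scale * damp
            dq[i] += t
            dq[j] -= t
        for i in range(n):
            if nhyd[i]:
                ci = _chi(z[i], q[i])
                ch = _chi(1, qh[i] / nhyd[i])
                donor_scale = _chi_plus(1) if ch < ci else _chi_plus(z[i])
                t = (ch - ci) / donor_scale * damp * nhyd[i]
                dq[i] += t
                dqh[i] -= t
        for i in range(n):
            q[i] += dq[i]
            qh[i] += dqh[i]
    for a in mol.atoms:
        i = a.index
        total = q[i] + (qh[i] if nhyd[i] else 0.0)
        # fold implicit-H charge back so the molecule's net charge is exact
        a.set_d("pchg", total if nhyd[i] else q[i])
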