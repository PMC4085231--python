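import numpy as np
import pytest
from hypothesis import HealthCheck, settings

import relmol as rm
from relmol import fixtures as fx

settings.register_profile(
    "ci", derandomize=True, deadline=None,
    suppress_health_check=[HealthCheck.too_slow])
settings.load_profile("ci")


@pytest.fixture(scope="session")
def tiny_ff():
    return fx.tiny_forcefield()


@pytest.fixture()
def water():
    return fx.water()


@pytest.fixture()
def methane():
    return fx.methane()


@pytest.fixture()
def benzene():
    return fx.benzene()


@pytest.fixture()
def chain():
    return fx.peptide_chain()


ELEMENTS = [1, 6, 7, 8, 16, 17]


def spread_positions(mol: rm.Molecule, rng: np.random.Generator,
                     spacing: float = 3.0, jitter: float = 0.5) -> None:
    """Re-place atoms on a jittered cubic grid (minimum separation about
    ``spacing - 2 * jitter``), keeping pair energies well-conditioned."""
    n = mol.natoms
    side = int(np.ceil(n ** (1 / 3)))
    pts = []
    for i in range(side):
        for j in range(side):
            for k in range(side):
                pts.append((i, j, k))
    pts = np.array(pts[:n], dtype=float) * spacing
    pts += rng.uniform(-jitter, jitter, pts.shape)
    mol.set_positions(np.round(pts, 3))


def random_molecule(rng: np.random.Generator, n_atoms: int | None = None,
                    n_res: int | None = None, charges: bool = True,
                    box: float = 20.0) -> rm.Molecule:
    """A random but well-formed molecule: contiguous residues, a random
    bond forest plus extra edges, 3-decimal coordinates."""
    n = n_atoms or int(rng.integers(2, 30))
    mol = rm.Molecule(f"rnd{n}")
    nres = n_res or int(rng.integers(1, max(2, n // 3 + 1)))
    cuts = sorted(rng.choice(np.arange(1, n), size=min(nres - 1, n - 1),
                             replace=False).tolist()) if nres > 1 else []
    bounds = [0] + cuts + [n]
    atoms = []
    for ri in range(len(bounds) - 1):
        res = mol.create(rm.RESD)
        res.set_s("name", f"R{ri % 10}")
        res.set_i("seq", ri + 1)
        for ai in range(bounds[ri], bounds[ri + 1]):
            a = mol.create(rm.ATOM)
            z = int(rng.choice(ELEMENTS))
            a.set_i("element", z)
            a.set_s("name", f"{'HCNOSL'[ELEMENTS.index(z)]}{ai % 99 + 1}")
            a.set_v("position", np.round(rng.uniform(-box, box, 3), 3))
            if charges:
                a.set_d("pchg", float(np.round(rng.uniform(-1, 1), 4)))
            res.relate(a)
            atoms.append(a)
    # spanning forest + extras
    for i in range(1, n):
        if rng.random() < 0.9:
            j = int(rng.integers(0, i))
            b = mol.create(rm.BOND)
            b.relate(atoms[j])
            b.relate(atoms[i])
            b.set_i("order", int(rng.integers(1, 4)))
            atoms[j].relate(atoms[i])
    for _ in range(n // 5):
        i, j = rng.integers(0, n, 2)
        if i != j and not atoms[int(i)].is_related(atoms[int(j)]):
            b = mol.create(rm.BOND)
            b.relate(atoms[int(i)])
            b.relate(atoms[int(j)])
            b.set_i("order", 1)
            atoms[int(i)].relate(atoms[int(j)])
    return mol
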