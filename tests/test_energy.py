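"""Term enumeration, bonded/nonbonded energies, Generalized-Born closed forms."""

import math

import numpy as np
import pytest

import relmol as rm
from relmol import fixtures as fx
from relmol.energy import GBParameters, INVCHG2, exclusion_pairs, gb_f
from relmol.forcefield import ForceField, TorsionTerm
from conftest import random_molecule


def linear_chain(n, spacing=1.5, types=None):
    mol = rm.Molecule("chain")
    res = mol.create(rm.RESD)
    res.set_i("seq", 1)
    atoms = []
    for i in range(n):
        a = mol.create(rm.ATOM)
        a.set_i("element", 6)
        a.set_s("name", f"C{i+1}")
        a.set_s("type", (types or ["CT"] * n)[i])
        a.set_d("pchg", 0.0)
        a.set_v("position", (i * spacing, 0.3 * (i % 2), 0.0))
        res.relate(a)
        atoms.append(a)
    for i in range(n - 1):
        b = mol.create(rm.BOND)
        b.relate(atoms[i])
        b.relate(atoms[i + 1])
        atoms[i].relate(atoms[i + 1])
    return mol


class TestEnumerate:
    def test_four_atom_chain(self):
        mol = linear_chain(4)
        rm.enumerate_terms(mol)
        assert mol.count(rm.ANGL) == 2
        assert mol.count(rm.TORS) == 1
        quad = [a.index for a in mol.objects(rm.TORS)[0].related(rm.ATOM)]
        assert quad in ([0, 1, 2, 3], [3, 2, 1, 0])

    def test_star_methane(self, methane):
        rm.enumerate_terms(methane)
        assert methane.count(rm.ANGL) == 6
        assert methane.count(rm.TORS) == 0

    def test_reinvocation_is_idempotent(self, benzene):
        rm.enumerate_terms(benzene)
        counts = (benzene.count(rm.ANGL), benzene.count(rm.TORS),
                  benzene.count(rm.OOPS))
        rm.enumerate_terms(benzene)
        assert (benzene.count(rm.ANGL), benzene.count(rm.TORS),
                benzene.count(rm.OOPS)) == counts

    def test_matches_brute_force_triple_and_quad_counts(self):
        rng = np.random.default_rng(51)
        for _ in range(5):
            mol = random_molecule(rng, n_atoms=12, charges=False)
            nbrs = {a.index: {x.index for x in a.related(rm.ATOM)}
                    for a in mol.atoms}
            triples = {(min(i, k), j, max(i, k))
                       for j in nbrs for i in nbrs[j] for k in nbrs[j]
                       if i != k}
            quads = set()
            for j in nbrs:
                for k in nbrs[j]:
                    for i in nbrs[j] - {k}:
                        for l in nbrs[k] - {j, i}:
                            quads.add(min((i, j, k, l), (l, k, j, i)))
            rm.enumerate_terms(mol)
            assert mol.count(rm.ANGL) == len(triples)
            assert mol.count(rm.TORS) == len(quads)

    def test_benzene_has_one_improper_per_carbon(self, benzene):
        rm.enumerate_terms(benzene)
        assert benzene.count(rm.OOPS) == 6


class TestBondedHandValues:
    def test_single_bond_energy(self):
        mol = linear_chain(2, spacing=1.1)
        ff = ForceField(bond_params={("CT", "CT"): (100.0, 1.0)})
        mol.atoms[1].set_v("position", (1.1, 0.0, 0.0))
        assert rm.eval_bond(mol, ff) == pytest.approx(1.0, abs=1e-12)

    def test_angle_at_equilibrium_is_zero(self, water, tiny_ff):
        rm.enumerate_terms(water)
        assert rm.eval_angl(water, tiny_ff) == pytest.approx(0.0, abs=1e-9)

    def test_torsion_hand_value(self):
        mol = linear_chain(4)
        # planar cis chain -> phi = 0
        for i, a in enumerate(mol.atoms):
            a.set_v("position", [(0, 0, 0), (1, 1, 0), (2, 1, 0),
                                 (3, 0, 0)][i])
        rm.enumerate_terms(mol)
        ff = ForceField(torsion_params={
            ("CT", "CT", "CT", "CT"): [TorsionTerm(pk=1.0, phase=0.0, pn=1)]})
        assert rm.eval_tors(mol, ff) == pytest.approx(2.0, abs=1e-9)

    def test_multi_term_torsion_is_sum_of_fourier_terms(self):
        mol = linear_chain(4)
        rm.enumerate_terms(mol)
        t1 = TorsionTerm(pk=0.4, phase=0.0, pn=2)
        t2 = TorsionTerm(pk=1.35, phase=math.pi, pn=3)
        both = ForceField(torsion_params={("CT", "CT", "CT", "CT"): [t1, t2]})
        only1 = ForceField(torsion_params={("CT", "CT", "CT", "CT"): [t1]})
        only2 = ForceField(torsion_params={("CT", "CT", "CT", "CT"): [t2]})
        assert rm.eval_tors(mol, both) == pytest.approx(
            rm.eval_tors(mol, only1) + rm.eval_tors(mol, only2), abs=1e-12)

    def test_missing_parameter_names_the_tuple(self):
        mol = linear_chain(2)
        with pytest.raises(rm.MissingParameterError, match="CT-CT"):
            rm.eval_bond(mol, ForceField())


class TestNonbondDirect:
    def two_charges(self, q=1.0, d=1.0, vdw=(0.0, 0.0)):
        mol = rm.Molecule("two")
        res = mol.create(rm.RESD)
        res.set_i("seq", 1)
        for x in (0.0, d):
            a = mol.create(rm.ATOM)
            a.set_i("element", 11)
            a.set_s("type", "QQ")
            a.set_d("pchg", q)
            a.set_v("position", (x, 0.0, 0.0))
            res.relate(a)
        ff = ForceField(vdw_params={"QQ": vdw})
        return mol, ff

    def test_unit_charges_at_one_angstrom(self):
        mol, ff = self.two_charges()
        elec, vdw = rm.nonbond_direct(mol, ff)
        assert elec == pytest.approx(INVCHG2, abs=1e-12)
        assert vdw == 0.0

    def test_lj_minimum_is_minus_epsilon(self):
        mol, ff = self.two_charges(q=0.0, d=3.8, vdw=(1.9, 0.25))
        _elec, vdw = rm.nonbond_direct(mol, ff)
        assert vdw == pytest.approx(-0.25, abs=1e-12)

    def test_bonded_pair_is_excluded(self):
        mol, ff = self.two_charges()
        b = mol.create(rm.BOND)
        b.relate(mol.atoms[0])
        b.relate(mol.atoms[1])
        mol.atoms[0].relate(mol.atoms[1])
        elec, vdw = rm.nonbond_direct(mol, ff)
        assert elec == 0.0 and vdw == 0.0

    def test_exclusions_use_shortest_graph_distance(self):
        # cyclobutane: every pair is 1-2 or 1-3, never scaled 1-4
        mol = linear_chain(4)
        b = mol.create(rm.BOND)
        b.relate(mol.atoms[3])
        b.relate(mol.atoms[0])
        mol.atoms[3].relate(mol.atoms[0])
        excluded, scaled = exclusion_pairs(mol)
        assert scaled == set()
        assert len(excluded) == 6

    def test_one_four_scaling(self):
        mol = linear_chain(4, spacing=1.0)
        for a in mol.atoms:
            a.set_d("pchg", 1.0)
            a.set_v("position", (float(a.index), 0.0, 0.0))
        ff = ForceField(vdw_params={"CT": (0.0, 0.0)})
        elec, _ = rm.nonbond_direct(mol, ff)
        # only the (0,3) pair survives, at r=3, scaled by 1/1.2
        assert elec == pytest.approx(INVCHG2 / 3.0 / 1.2, abs=1e-9)

    def test_matches_brute_force_on_random_systems(self):
        from conftest import spread_positions

        rng = np.random.default_rng(61)
        for n in (20, 60):
            mol = random_molecule(rng, n_atoms=n)
            spread_positions(mol, rng)
            for a in mol.atoms:
                a.set_s("type", "QQ" if a.index % 2 else "PP")
            ff = ForceField(vdw_params={"QQ": (1.8, 0.1), "PP": (1.2, 0.05)})
            elec, vdw = rm.nonbond_direct(mol, ff)
            excl, scaled = exclusion_pairs(mol)
            pos = mol.positions()
            q = [a.get_d("pchg") for a in mol.atoms]
            ref_e = ref_v = 0.0
            for i in range(n):
                for j in range(i + 1, n):
                    if (i, j) in excl:
                        continue
                    se = 1 / 1.2 if (i, j) in scaled else 1.0
                    sv = 1 / 2.0 if (i, j) in scaled else 1.0
                    r = float(np.linalg.norm(pos[i] - pos[j]))
                    ref_e += se * INVCHG2 * q[i] * q[j] / r
                    ri = 1.8 if i % 2 else 1.2
                    rj = 1.8 if j % 2 else 1.2
                    ei = 0.1 if i % 2 else 0.05
                    ej = 0.1 if j % 2 else 0.05
                    eps = math.sqrt(ei * ej)
                    rmin = ri + rj
                    ref_v += sv * eps * ((rmin / r) ** 12 - 2 * (rmin / r) ** 6)
            assert elec == pytest.approx(ref_e, abs=1e-9)
            assert vdw == pytest.approx(ref_v, abs=1e-9)

    def test_pbc_cutoff_must_fit_the_box(self):
        mol, ff = self.two_charges()
        with pytest.raises(ValueError):
            rm.nonbond_direct(mol, ff, cutoff=6.0, box=(10.0, 10.0, 10.0))

    def test_minimum_image_wraps_distances(self):
        mol, ff = self.two_charges(d=9.0)
        elec, _ = rm.nonbond_direct(mol, ff, cutoff=4.0, box=(10.0, 10.0, 10.0))
        # images are 1 A apart across the boundary
        assert elec == pytest.approx(INVCHG2 / 1.0, abs=1e-9)


class TestGeneralizedBorn:
    def gb_pair(self, d, alpha=(1.0, 1.0), q=(1.0, 1.0)):
        mol = rm.Molecule("gb")
        res = mol.create(rm.RESD)
        res.set_i("seq", 1)
        for k, x in enumerate((0.0, d)):
            a = mol.create(rm.ATOM)
            a.set_i("element", 8)
            a.set_d("pchg", q[k])
            a.set_d("born", alpha[k])
            a.set_v("position", (x, 0.0, 0.0))
            res.relate(a)
        return mol

    def test_default_dielectric(self):
        assert GBParameters().dielectric == 78.5

    def test_zero_distance_closed_form(self):
        mol = self.gb_pair(0.0)
        expected = -INVCHG2 * (1 - 1 / 78.5)
        assert rm.nonbond_egb(mol) == pytest.approx(expected, abs=1e-9)

    def test_fgb_at_zero_distance_equals_alpha_ij(self):
        for ai, aj in [(1.0, 1.0), (0.5, 2.0), (1.3, 0.7)]:
            f = gb_f(np.array([0.0]), np.array([ai]), np.array([aj]))[0]
            assert f == pytest.approx(math.sqrt(ai * aj), abs=1e-12)

    def test_long_range_limit_is_coulomb_screening(self):
        mol = self.gb_pair(50.0)
        expected = -INVCHG2 * (1 - 1 / 78.5) / 50.0
        assert rm.nonbond_egb(mol) == pytest.approx(expected, rel=1e-6)

    def test_fgb_bounds(self):
        rng = np.random.default_rng(71)
        r = rng.uniform(0, 20, 200)
        ai = rng.uniform(0.3, 3.0, 200)
        aj = rng.uniform(0.3, 3.0, 200)
        f = gb_f(r, ai, aj)
        assert np.all(f >= np.maximum(r, 0.0) - 1e-12)
        assert np.all(f <= np.sqrt(r**2 + ai * aj) + 1e-12)

    def test_no_exclusions_in_the_pairwise_sum(self):
        """Bonded pairs contribute to the GB sum exactly like any pair."""
        mol = self.gb_pair(1.0)
        e_without = rm.nonbond_egb(mol)
        b = mol.create(rm.BOND)
        b.relate(mol.atoms[0])
        b.relate(mol.atoms[1])
        assert rm.nonbond_egb(mol) == pytest.approx(e_without, abs=1e-12)

    def test_invariance_under_rigid_motion_and_relabeling(self):
        rng = np.random.default_rng(73)
        mol = random_molecule(rng, n_atoms=15)
        for a in mol.atoms:
            a.set_d("born", float(rng.uniform(0.8, 2.0)))
        e0 = rm.nonbond_egb(mol)
        rm.rotate(mol, (1, 2, 3), 77.0, origin=(1, 0, 0))
        rm.translate(mol, (5, -3, 2))
        assert rm.nonbond_egb(mol) == pytest.approx(e0, abs=1e-9)

    def test_literature_exponent_variant_differs(self):
        mol = self.gb_pair(2.0)
        e_model = rm.nonbond_egb(mol, GBParameters())
        e_lit = rm.nonbond_egb(mol, GBParameters(exponent_rule="literature"))
        assert e_model != pytest.approx(e_lit, abs=1e-9)

    def test_missing_charge_names_the_atom(self):
        mol = rm.Molecule("m")
        res = mol.create(rm.RESD)
        res.set_i("seq", 1)
        a = mol.create(rm.ATOM)
        a.set_i("element", 6)
        a.set_v("position", (0, 0, 0))
        b = mol.create(rm.ATOM)
        b.set_i("element", 6)
        b.set_v("position", (1, 0, 0))
        with pytest.raises(ValueError, match="atom 1"):
            rm.nonbond_egb(mol)

    def test_nonpositive_born_radius_rejected(self):
        mol = self.gb_pair(1.0, alpha=(1.0, -0.5))
        with pytest.raises(ValueError):
            rm.nonbond_egb(mol)


def test_energy_report_total_is_sum_of_parts(benzene, tiny_ff):
    rep = rm.energy_report(benzene, tiny_ff, gb=True)
    parts = (rep.bond + rep.angle + rep.torsion + rep.improper
             + rep.elec_direct + rep.vdw + rep.egb)
    assert rep.total == pytest.approx(parts, abs=1e-9)
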