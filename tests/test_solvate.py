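"""Solvation builders and ion placement against brute-force filters."""

import numpy as np
import pytest

import relmol as rm
from relmol import elements
from relmol import fixtures as fx
from conftest import random_molecule


def shell_oracle(solute, template, closeness, extent):
    """Re-derive the retained solvent placements with plain loops."""
    solute_pos = solute.positions()
    solute_rad = [elements.vdw_radius(a.get_i("element"))
                  for a in solute.atoms]
    tmol = template.mol
    tpos = tmol.positions()
    tpos = tpos - tpos.mean(axis=0)
    trad = [elements.vdw_radius(a.get_i("element")) for a in tmol.atoms]
    lo = solute_pos.min(axis=0) - extent
    hi = solute_pos.max(axis=0) + extent
    sl = template.solvlen
    counts = [max(1, int(np.ceil((hi[k] - lo[k]) / sl))) for k in range(3)]
    kept = []
    for ix in range(counts[0]):
        for iy in range(counts[1]):
            for iz in range(counts[2]):
                offset = lo + sl * (np.array([ix, iy, iz]) + 0.5)
                coords = tpos + offset
                centroid = coords.mean(axis=0)
                if np.any(centroid < lo) or np.any(centroid > hi):
                    continue
                clash = False
                dmin = np.inf
                for k in range(len(coords)):
                    for s in range(len(solute_pos)):
                        d = float(np.linalg.norm(coords[k] - solute_pos[s]))
                        dmin = min(dmin, d)
                        if d < closeness * (trad[k] + solute_rad[s]):
                            clash = True
                if not clash and dmin <= extent:
                    kept.append(np.round(centroid, 6))
    return sorted(map(tuple, kept))


def added_water_centroids(mol, n_before):
    out = []
    for res in list(mol.resds)[n_before:]:
        pos = np.array([a.pos for a in res.related(rm.ATOM)])
        out.append(tuple(np.round(pos.mean(axis=0), 6)))
    return sorted(out)


def test_shell_matches_brute_force_filter_on_random_solutes():
    rng = np.random.default_rng(41)
    template = fx.single_water_template()
    for _ in range(12):
        solute = random_molecule(rng, n_atoms=int(rng.integers(1, 6)),
                                 charges=False, box=3.0)
        nres = solute.nresds
        closeness, extent = 1.0, float(rng.uniform(4.0, 7.0))
        got = rm.solvate_shell(solute, template, closeness, extent)
        ref = shell_oracle_positions = shell_oracle(
            _strip_added(solute, nres), template, closeness, extent)
        assert added_water_centroids(solute, nres) == ref
        assert got == len(ref)


def _strip_added(mol, nres):
    """The oracle needs the original solute: rebuild it from residues[:nres]."""
    out = rm.Molecule("orig")
    for res in list(mol.resds)[:nres]:
        r = out.create(rm.RESD)
        r.set_i("seq", res.user_id)
        for a in res.related(rm.ATOM):
            na = out.create(rm.ATOM)
            na.set_i("element", a.get_i("element"))
            na.set_v("position", a.get_v("position"))
            r.relate(na)
    return out


def test_every_retained_solvent_is_inside_the_band(methane):
    template = fx.single_water_template()
    solute_pos = methane.positions().copy()
    solute_rad = [elements.vdw_radius(a.get_i("element"))
                  for a in methane.atoms]
    n0 = methane.nresds
    closeness, extent = 1.0, 6.0
    rm.solvate_shell(methane, template, closeness, extent)
    for res in list(methane.resds)[n0:]:
        coords = np.array([a.pos for a in res.related(rm.ATOM)])
        rads = [elements.vdw_radius(a.get_i("element"))
                for a in res.related(rm.ATOM)]
        d = np.linalg.norm(coords[:, None] - solute_pos[None, :], axis=2)
        assert d.min() <= extent + 1e-9
        cut = closeness * (np.array(rads)[:, None]
                           + np.array(solute_rad)[None, :])
        assert np.all(d >= cut - 1e-9)


def test_unreachable_extent_yields_empty_shell(methane):
    # huge clash cut: everything within the shell band collides
    n = rm.solvate_shell(methane, fx.single_water_template(),
                         closeness=2.0, extent=5.0)
    assert n == 0


def test_invalid_shell_parameters():
    template = fx.single_water_template()
    with pytest.raises(ValueError):
        rm.solvate_shell(fx.methane(), template, -1.0, 5.0)
    with pytest.raises(ValueError):
        rm.solvate_shell(fx.methane(), template, 3.0, 2.0)


def test_oct_never_exceeds_box_count():
    rng = np.random.default_rng(43)
    template = fx.single_water_template()
    for _ in range(8):
        base = random_molecule(rng, n_atoms=int(rng.integers(1, 5)),
                               charges=False, box=4.0)
        buffer = float(rng.uniform(4.0, 9.0))
        m_box = _strip_added(base, base.nresds)
        m_oct = _strip_added(base, base.nresds)
        nb = rm.solvate_box(m_box, template, buffer)
        no = rm.solvate_oct(m_oct, template, buffer)
        assert no <= nb


def test_box_solvent_centres_inside_region():
    mol = rm.Molecule("pt")
    res = mol.create(rm.RESD)
    res.set_i("seq", 1)
    a = mol.create(rm.ATOM)
    a.set_i("element", 8)
    a.set_v("position", (0.0, 0.0, 0.0))
    res.relate(a)
    rm.solvate_box(mol, fx.single_water_template(), 10.0)
    for r in list(mol.resds)[1:]:
        c = np.mean([x.pos for x in r.related(rm.ATOM)], axis=0)
        assert np.all(np.abs(c) <= 10.0 + 1e-9)
    assert tuple(mol.get_prop("v", "box")) == (20.0, 20.0, 20.0)


def test_cap_keeps_centres_within_radius(methane):
    centre = (6.0, 0.0, 0.0)
    n0 = methane.nresds
    n = rm.solvate_cap(methane, fx.single_water_template(), centre, 5.0)
    assert n > 0
    for r in list(methane.resds)[n0:]:
        c = np.mean([x.pos for x in r.related(rm.ATOM)], axis=0)
        assert np.linalg.norm(c - centre) <= 5.0 + 1e-9


def test_shell_is_subset_of_box_at_equal_margin(methane):
    template = fx.single_water_template()
    m_shell = fx.methane()
    m_box = fx.methane()
    rm.solvate_shell(m_shell, template, 1.0, 6.0)
    rm.solvate_box(m_box, template, 6.0, closeness=1.0)
    shell_c = added_water_centroids(m_shell, 1)
    box_c = added_water_centroids(m_box, 1)
    assert set(shell_c) <= set(box_c)


def test_tiling_is_deterministic(methane):
    a, b = fx.methane(), fx.methane()
    template = fx.single_water_template()
    rm.solvate_shell(a, template, 1.0, 6.0)
    rm.solvate_shell(b, template, 1.0, 6.0)
    assert np.array_equal(a.positions(), b.positions())


class TestAddIons:
    def _charged_solute(self, q_each, n=4):
        mol = rm.Molecule("ion_host")
        res = mol.create(rm.RESD)
        res.set_s("name", "CHG")
        res.set_i("seq", 1)
        for i in range(n):
            a = mol.create(rm.ATOM)
            a.set_i("element", 8)
            a.set_s("name", f"O{i+1}")
            a.set_s("type", "O")
            a.set_v("position", (2.5 * i, 0.0, 0.0))
            a.set_d("pchg", q_each)
            res.relate(a)
        return mol

    def test_auto_neutralises_minus_two(self):
        mol = self._charged_solute(-0.5)
        n0 = mol.nresds
        n = rm.addions(mol, fx.sodium_ion(), "auto")
        assert n == 2
        assert mol.nresds == n0 + 2
        assert abs(sum(a.get_d("pchg") for a in mol.atoms)) < 1e-9

    def test_auto_on_neutral_solute_is_a_noop(self):
        mol = self._charged_solute(0.0)
        assert rm.addions(mol, fx.sodium_ion(), "auto") == 0

    def test_wrong_sign_ion_is_an_error(self):
        mol = self._charged_solute(-0.5)
        with pytest.raises(ValueError):
            rm.addions(mol, fx.chloride_ion(), "auto")

    def test_explicit_count(self):
        mol = self._charged_solute(0.1)
        n0 = mol.nresds
        assert rm.addions(mol, fx.chloride_ion(), 3) == 3
        assert mol.nresds == n0 + 3

    def test_ions_respect_the_closeness_cut(self):
        mol = self._charged_solute(-0.5)
        existing = mol.positions().copy()
        rm.addions(mol, fx.sodium_ion(), "auto", closeness=3.0)
        ions = mol.positions()[len(existing):]
        for p in ions:
            assert np.linalg.norm(existing - p, axis=1).min() >= 3.0 - 1e-9

    def test_placement_is_deterministic(self):
        a = self._charged_solute(-0.5)
        b = self._charged_solute(-0.5)
        rm.addions(a, fx.sodium_ion(), "auto")
        rm.addions(b, fx.sodium_ion(), "auto")
        assert np.array_equal(a.positions(), b.positions())
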