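"""The relational store: tables, handles, relations, deletion, database."""

import numpy as np
import pytest

import relmol as rm


def build_chain(n=3, bonds=True):
    """A-B-C... chain with an angle object over every consecutive triple."""
    mol = rm.Molecule("chain")
    atoms = [mol.create(rm.ATOM) for _ in range(n)]
    for i, a in enumerate(atoms):
        a.set_i("element", 6)
        a.set_v("position", (float(i), 0.0, 0.0))
    bond_handles = []
    if bonds:
        for i in range(n - 1):
            b = mol.create(rm.BOND)
            b.relate(atoms[i])
            b.relate(atoms[i + 1])
            atoms[i].relate(atoms[i + 1])
            bond_handles.append(b)
        for i in range(n - 2):
            ang = mol.create(rm.ANGL)
            for j in (i, i + 1, i + 2):
                ang.relate(atoms[j])
    return mol, atoms, bond_handles


def test_create_increments_counts_and_user_ids():
    mol = rm.Molecule("m")
    a1 = mol.create(rm.ATOM)
    assert mol.count(rm.ATOM) == 1
    b = mol.create(rm.BOND)
    assert mol.count(rm.BOND) == 1
    assert len(mol.adjacencies) == 0  # no relations yet
    a2 = mol.create(rm.ATOM)
    assert (a1.user_id, a2.user_id) == (1, 2)
    assert b.user_id == 1


def test_create_rejects_non_typecode():
    mol = rm.Molecule("m")
    with pytest.raises(TypeError):
        mol.create("atom")


def test_relations_are_stored_in_both_directions():
    mol = rm.Molecule("m")
    atom = mol.create(rm.ATOM)
    bond = mol.create(rm.BOND)
    res = mol.create(rm.RESD)
    bond.relate(atom)
    res.relate(atom)
    assert [h.index for h in atom.related(rm.BOND)] == [0]
    assert [h.index for h in bond.related(rm.ATOM)] == [0]
    assert [h.index for h in atom.related(rm.RESD)] == [0]
    assert [h.index for h in res.related(rm.ATOM)] == [0]
    # duplicate relation is a no-op
    bond.relate(atom)
    assert len(bond.related(rm.ATOM)) == 1


def test_cross_molecule_relation_rejected():
    m1, m2 = rm.Molecule("a"), rm.Molecule("b")
    a = m1.create(rm.ATOM)
    b = m2.create(rm.ATOM)
    with pytest.raises(ValueError):
        a.relate(b)


def test_property_kinds_round_trip():
    mol = rm.Molecule("m")
    a = mol.create(rm.ATOM)
    a.set_i("element", 8)
    a.set_d("pchg", -0.834)
    a.set_s("name", "O")
    a.set_v("position", (1.0, 2.0, 3.0))
    a.set_a("blob", {"anything": [1, 2]})
    assert a.get_i("element") == 8
    assert a.get_d("pchg") == -0.834
    assert a.get_s("name") == "O"
    assert a.get_v("position") == (1.0, 2.0, 3.0)
    assert a.get_a("blob") == {"anything": [1, 2]}


def test_vector_column_is_stored_flat():
    mol = rm.Molecule("m")
    a = mol.create(rm.ATOM)
    a.set_v("position", (1.0, 2.0, 3.0))
    table = mol.component(rm.ATOM)
    key = rm.encode_name("position")
    assert table.cols["v"][key] == [1.0, 2.0, 3.0]
    b = mol.create(rm.ATOM)
    b.set_v("position", (4.0, 5.0, 6.0))
    assert table.cols["v"][key] == [1.0, 2.0, 3.0, 4.0, 5.0, 6.0]


def test_missing_property_single_vs_two_result_forms():
    mol = rm.Molecule("m")
    a = mol.create(rm.ATOM)
    with pytest.raises(rm.MissingPropertyError):
        a.get_s("name")
    found, value = a.find_s("name")
    assert found is False and value is None


def test_kind_mismatch_on_existing_column_is_a_type_error():
    mol = rm.Molecule("m")
    a = mol.create(rm.ATOM)
    a.set_i("element", 6)
    with pytest.raises(TypeError):
        a.set_d("element", 6.0)


def test_lazy_column_backfills_defaults_for_existing_objects():
    mol = rm.Molecule("m")
    a1 = mol.create(rm.ATOM)
    a2 = mol.create(rm.ATOM)
    a2.set_s("name", "CA")
    assert a1.get_s("name") == ""
    a2.set_v("position", (1.0, 1.0, 1.0))
    assert a1.get_v("position") == (0.0, 0.0, 0.0)


def test_iteration_skips_other_types_and_supports_random_access():
    mol = rm.Molecule("m")
    for _ in range(3):
        mol.create(rm.ATOM)
    for _ in range(2):
        mol.create(rm.RESD)
    atoms = mol.atoms
    assert len(atoms) == 3
    assert [h.type.code for h in atoms] == ["atom"] * 3
    for k in range(3):
        assert atoms.at(k).index == list(atoms)[k].index
    assert len(mol.resds) == 2


def test_related_range_of_a_bond_is_its_two_atoms_in_order():
    mol, atoms, bonds = build_chain(2)
    got = bonds[0].related(rm.ATOM)
    assert [h.index for h in got] == [0, 1]


def test_delete_lone_atom_clears_adjacency():
    mol = rm.Molecule("m")
    a = mol.create(rm.ATOM)
    res = mol.create(rm.RESD)
    res.relate(a)
    a.delete()
    assert mol.count(rm.ATOM) == 0
    assert mol.adjacency(rm.RESD, rm.ATOM).rows == [[]]


def test_delete_bonded_atom_cascades_to_bond():
    mol, atoms, bonds = build_chain(2)
    atoms[0].delete()
    assert mol.count(rm.ATOM) == 1
    assert mol.count(rm.BOND) == 0


def test_delete_middle_atom_of_chain_removes_bonds_and_angle():
    mol, atoms, _ = build_chain(3)
    assert mol.count(rm.ANGL) == 1
    atoms[1].delete()
    assert mol.count(rm.ATOM) == 2
    assert mol.count(rm.BOND) == 0
    assert mol.count(rm.ANGL) == 0


def test_cascade_matches_rebuild_from_scratch():
    """Deleting atom k is equivalent to rebuilding without it (and without
    the terms that mention it)."""
    mol, atoms, _ = build_chain(5)
    atoms[2].delete()
    # rebuild: atoms 0,1,3,4; bonds (0,1) and (3,4); no angle spans the gap
    # except (2,3,4) -> after reindexing (2,3) bond and no angles... build:
    ref = rm.Molecule("ref")
    ref_atoms = [ref.create(rm.ATOM) for _ in range(4)]
    for i, j in [(0, 1), (2, 3)]:
        b = ref.create(rm.BOND)
        b.relate(ref_atoms[i])
        b.relate(ref_atoms[j])
    assert mol.count(rm.ATOM) == ref.count(rm.ATOM)
    assert mol.count(rm.BOND) == ref.count(rm.BOND)
    got_pairs = sorted(tuple(h.index for h in b.related(rm.ATOM))
                       for b in mol.bonds)
    ref_pairs = sorted(tuple(h.index for h in b.related(rm.ATOM))
                       for b in ref.bonds)
    assert got_pairs == ref_pairs
    assert mol.count(rm.ANGL) == 0  # angles (0,1,2),(1,2,3),(2,3,4) all hit atom 2
    # remaining atoms keep their data (positions shifted down)
    assert [tuple(a.pos) for a in mol.atoms] == [
        (0.0, 0.0, 0.0), (1.0, 0.0, 0.0), (3.0, 0.0, 0.0), (4.0, 0.0, 0.0)]


def test_stale_handle_is_detected():
    mol = rm.Molecule("m")
    a = mol.create(rm.ATOM)
    a.delete()
    with pytest.raises(rm.StaleHandleError):
        a.get_i("element")
    h = mol.handle(rm.ATOM, 5)
    with pytest.raises(rm.StaleHandleError):
        h.set_i("element", 6)


def test_database_put_get_overwrite_and_missing():
    db = rm.MoleculeDatabase()
    wat = rm.Molecule("wat")
    db.put("wat", wat)
    assert db.get_mol("wat") is wat
    with pytest.raises(KeyError):
        db.get_mol("missing")
    wat2 = rm.Molecule("wat2")
    db.put("wat", wat2)
    assert db.get_mol("wat") is wat2
    with pytest.raises(ValueError):
        db.put("", wat)


def _check_integrity(mol):
    for (src, tgt), adj in mol.adjacencies.items():
        assert len(adj.rows) == mol.count(src), (src.code, tgt.code)
        for i, row in enumerate(adj.rows):
            for j in row:
                assert 0 <= j < mol.count(tgt)
                rev = mol.adjacencies.get((tgt, src))
                assert rev is not None and i in rev.rows[j], "symmetry"
    for tc, table in mol.components.items():
        for kind in ("i", "d", "s", "a"):
            for col in table.cols[kind].values():
                assert len(col) == table.n
        for key, col in table.cols["v"].items():
            assert len(col) == table.n * table.vec_width[key]


def test_referential_integrity_under_random_mutation():
    """Fuzz create/relate/delete; adjacency indices always stay in range,
    relations stay symmetric, columns stay object_count long."""
    rng = np.random.default_rng(7)
    mol = rm.Molecule("fuzz")
    for step in range(400):
        op = rng.random()
        na = mol.count(rm.ATOM)
        if op < 0.45 or na < 2:
            a = mol.create(rm.ATOM)
            a.set_i("element", int(rng.choice([1, 6, 7, 8])))
            a.set_v("position", rng.uniform(-5, 5, 3))
        elif op < 0.75:
            i, j = rng.integers(0, na, 2)
            if i != j:
                ai, aj = mol.handle(rm.ATOM, int(i)), mol.handle(rm.ATOM, int(j))
                if not ai.is_related(aj):
                    b = mol.create(rm.BOND)
                    b.relate(ai)
                    b.relate(aj)
                    ai.relate(aj)
        else:
            mol.handle(rm.ATOM, int(rng.integers(0, na))).delete()
        if step % 25 == 0:
            _check_integrity(mol)
    _check_integrity(mol)
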