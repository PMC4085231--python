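"""PDB / MOL2 / SDF readers and writers, and the multi-molecule loader."""

import io

import numpy as np
import pytest

import relmol as rm
from relmol import fixtures as fx
from conftest import random_molecule

WATER_PDB = """\
REMARK  a three-atom water
ATOM      1  O   HOH A   1       0.000   0.000   0.000  1.00  0.00           O
ATOM      2  H1  HOH A   1       0.757   0.586   0.000  1.00  0.00           H
ATOM      3  H2  HOH A   1      -0.757   0.586   0.000  1.00  0.00           H
END
"""


class TestPdb:
    def test_fixture_water_counts(self):
        mol = rm.read_pdb(WATER_PDB)
        assert mol.natoms == 3
        assert mol.nresds == 1
        assert [a.get_s("name") for a in mol.atoms] == ["O", "H1", "H2"]
        assert [a.get_i("element") for a in mol.atoms] == [8, 1, 1]
        assert np.allclose(mol.atoms[1].pos, (0.757, 0.586, 0.0))

    def test_empty_stream_gives_empty_molecule(self):
        mol = rm.read_pdb("")
        assert mol.natoms == 0 and mol.nresds == 0

    def test_unknown_records_are_skipped(self):
        text = ("REMARK hello\n"
                "ATOM      1  C   LIG A   1       1.000   2.000   3.000\n")
        assert rm.read_pdb(text).natoms == 1

    def test_malformed_coordinates_raise_with_line_number(self):
        bad = "ATOM      1  C   LIG A   1       xx.000   2.000   3.000\n"
        with pytest.raises(rm.ParseError) as err:
            rm.read_pdb(bad)
        assert "line 1" in str(err.value)

    def test_residues_split_on_seq_and_chain_change(self):
        text = (
            "ATOM      1  N   ALA A   1       0.000   0.000   0.000\n"
            "ATOM      2  CA  ALA A   1       1.000   0.000   0.000\n"
            "ATOM      3  N   GLY A   2       2.000   0.000   0.000\n"
            "ATOM      4  N   GLY B   2       3.000   0.000   0.000\n")
        mol = rm.read_pdb(text)
        assert mol.nresds == 3
        assert [len(r.related(rm.ATOM)) for r in mol.resds] == [2, 1, 1]

    def test_conect_records_become_bonds(self):
        text = WATER_PDB.replace("END\n",
                                 "CONECT    1    2    3\nEND\n")
        mol = rm.read_pdb(text)
        assert mol.count(rm.BOND) == 2

    def test_round_trip_preserves_fields(self, water):
        buf = io.StringIO()
        rm.write_pdb(water, buf)
        back = rm.read_pdb(buf.getvalue())
        assert back.natoms == water.natoms
        assert back.nresds == water.nresds
        assert [a.get_s("name") for a in back.atoms] == [
            a.get_s("name") for a in water.atoms]
        assert np.allclose(back.positions(), water.positions(), atol=5e-4)

    def test_long_atom_name_truncated_with_warning(self):
        mol = rm.Molecule("m")
        res = mol.create(rm.RESD)
        res.set_s("name", "LIG")
        res.set_i("seq", 1)
        a = mol.create(rm.ATOM)
        a.set_s("name", "CARBON")
        a.set_i("element", 6)
        a.set_v("position", (0, 0, 0))
        res.relate(a)
        buf = io.StringIO()
        with pytest.warns(UserWarning):
            rm.write_pdb(mol, buf)
        assert rm.read_pdb(buf.getvalue()).atoms[0].get_s("name") == "CARB"

    def test_missing_position_error_names_the_atom(self):
        mol = rm.Molecule("m")
        res = mol.create(rm.RESD)
        res.set_i("seq", 1)
        a = mol.create(rm.ATOM)
        a.set_s("name", "ZQ")
        a.set_i("element", 6)
        res.relate(a)
        with pytest.raises(ValueError, match="ZQ"):
            rm.write_pdb(mol, io.StringIO())

    def test_ten_thousand_atom_chain_serials(self):
        mol = rm.Molecule("big")
        res = mol.create(rm.RESD)
        res.set_s("name", "CHN")
        res.set_i("seq", 1)
        n = 10_000
        for i in range(n):
            a = mol.create(rm.ATOM)
            a.set_s("name", "C")
            a.set_i("element", 6)
            a.set_v("position", (i * 0.01, 0.0, 0.0))
            res.relate(a)
        buf = io.StringIO()
        rm.write_pdb(mol, buf)
        lines = [l for l in buf.getvalue().splitlines() if l.startswith("ATOM")]
        assert len(lines) == n
        # serial column stays 5 wide and equals user id (rolls at 100000)
        assert int(lines[-1][6:11]) == n
        back = rm.read_pdb(buf.getvalue())
        assert back.natoms == n


class TestMol2:
    def test_benzene_counts_and_aromatic_orders(self, benzene):
        for b in benzene.bonds:
            atoms = b.related(rm.ATOM)
            if all(a.get_i("element") == 6 for a in atoms):
                b.set_i("order", 4)  # aromatic
        buf = io.StringIO()
        rm.write_mol2(benzene, buf)
        text = buf.getvalue()
        assert text.count(" ar") == 6
        back = rm.read_mol2(text)
        assert back.natoms == 12
        assert back.count(rm.BOND) == 12
        orders = [b.get_i("order") for b in back.bonds]
        assert orders.count(4) == 6

    def test_missing_molecule_section_is_a_parse_error(self):
        with pytest.raises(rm.ParseError):
            rm.read_mol2("@<TRIPOS>ATOM\n1 C 0 0 0 C.3 1 RES 0.0\n")

    def test_molecule_without_residues_gets_a_default_substructure(self):
        mol = rm.Molecule("bare")
        a = mol.create(rm.ATOM)
        a.set_s("name", "C1")
        a.set_i("element", 6)
        a.set_v("position", (0, 0, 0))
        buf = io.StringIO()
        rm.write_mol2(mol, buf)
        back = rm.read_mol2(buf.getvalue())
        assert back.nresds == 1

    def test_charges_round_trip_to_four_decimals(self, water):
        buf = io.StringIO()
        rm.write_mol2(water, buf)
        back = rm.read_mol2(buf.getvalue())
        for a, b in zip(water.atoms, back.atoms):
            assert abs(a.get_d("pchg") - b.get_d("pchg")) < 1e-4


METHANE_SDF = """\
methane
  fixture

  5  4  0  0  0  0  0  0  0  0999 V2000
    0.0000    0.0000    0.0000 C   0  0  0  0  0  0  0  0  0  0  0  0
    0.6294    0.6294    0.6294 H   0  0  0  0  0  0  0  0  0  0  0  0
    0.6294   -0.6294   -0.6294 H   0  0  0  0  0  0  0  0  0  0  0  0
   -0.6294    0.6294   -0.6294 H   0  0  0  0  0  0  0  0  0  0  0  0
   -0.6294   -0.6294    0.6294 H   0  0  0  0  0  0  0  0  0  0  0  0
  1  2  1  0
  1  3  1  0
  1  4  1  0
  1  5  1  0
M  END
$$$$
"""


class TestSdf:
    def test_methane_counts(self):
        mol = rm.read_sdf(METHANE_SDF)
        assert mol.natoms == 5
        assert mol.count(rm.BOND) == 4
        assert all(b.get_i("order") == 1 for b in mol.bonds)

    def test_chg_property_line_sets_formal_charge(self):
        text = METHANE_SDF.replace("M  END", "M  CHG  1   1  -1\nM  END")
        mol = rm.read_sdf(text)
        assert mol.atoms[0].get_i("fcharge") == -1

    def test_counts_line_block_mismatch_is_a_parse_error(self):
        bad = METHANE_SDF.replace("  5  4", " 25  4")
        with pytest.raises(rm.ParseError):
            rm.read_sdf(bad)

    def test_v3000_is_rejected(self):
        bad = METHANE_SDF.replace("V2000", "V3000")
        with pytest.raises(rm.ParseError, match="V3000"):
            rm.read_sdf(bad)

    def test_data_fields_become_molecule_properties(self):
        text = METHANE_SDF.replace(
            "$$$$", "> <logP>\n1.09\n\n$$$$")
        mol = rm.read_sdf(text)
        assert mol.get_prop("s", "logP") == "1.09"
        buf = io.StringIO()
        rm.write_sdf(mol, buf)
        assert rm.read_sdf(buf.getvalue()).get_prop("s", "logP") == "1.09"


class TestLoadMdb:
    def test_sdf_records_keyed_by_title(self):
        text = METHANE_SDF + METHANE_SDF.replace("methane", "ethane")
        db = rm.load_mdb(text, "sdf")
        assert set(db.names()) == {"methane", "ethane"}

    def test_mol2_blocks(self, water, methane):
        buf = io.StringIO()
        rm.write_mol2(water, buf)
        rm.write_mol2(methane, buf)
        db = rm.load_mdb(buf.getvalue(), "mol2")
        assert len(db) == 2

    def test_duplicate_names_suffixed_with_warning(self):
        text = METHANE_SDF * 2
        with pytest.warns(UserWarning):
            db = rm.load_mdb(text, "sdf")
        assert set(db.names()) == {"methane", "methane_2"}

    def test_off_format_is_an_explicit_unsupported_error(self):
        from relmol.formats.mdb import UnsupportedFormatError

        with pytest.raises(UnsupportedFormatError):
            rm.load_mdb("anything", "off")


def _atom_tuple(mol, fields):
    out = []
    for a in mol.atoms:
        row = []
        for f in fields:
            if f == "pos":
                row.append(tuple(np.round(a.pos, 3)))
            elif f == "name":
                row.append(a.find_s("name")[1])
            elif f == "element":
                row.append(a.get_i("element"))
            elif f == "pchg":
                row.append(round(a.find_d("pchg")[1] or 0.0, 4))
            elif f == "fcharge":
                row.append(a.find_i("fcharge")[1] or 0)
        out.append(tuple(row))
    return out


def _bond_tuples(mol):
    return sorted(tuple(sorted(h.index for h in b.related(rm.ATOM)))
                  + (b.find_i("order")[1] or 1,)
                  for b in mol.bonds)


def _res_partition(mol):
    return [sorted(a.index for a in r.related(rm.ATOM)) for r in mol.resds]


@pytest.mark.parametrize("fmt", ["pdb", "mol2", "sdf"])
def test_random_molecule_round_trips(fmt):
    """Reader-of-writer identity on each format's preserved field set."""
    rng = np.random.default_rng(42)
    readers = {"pdb": rm.read_pdb, "mol2": rm.read_mol2, "sdf": rm.read_sdf}
    writers = {"pdb": rm.write_pdb, "mol2": rm.write_mol2, "sdf": rm.write_sdf}
    for _ in range(25):
        mol = random_molecule(rng)
        buf = io.StringIO()
        writers[fmt](mol, buf)
        back = readers[fmt](buf.getvalue())
        assert back.natoms == mol.natoms
        assert np.allclose(back.positions(), mol.positions(),
                           atol=5e-4 if fmt == "pdb" else 1.5e-4)
        assert [a.get_i("element") for a in back.atoms] == [
            a.get_i("element") for a in mol.atoms]
        if fmt == "pdb":
            assert _atom_tuple(back, ["name"]) == _atom_tuple(mol, ["name"])
            assert _res_partition(back) == _res_partition(mol)
        if fmt == "mol2":
            assert _atom_tuple(back, ["name", "pchg"]) == _atom_tuple(
                mol, ["name", "pchg"])
            assert _bond_tuples(back) == _bond_tuples(mol)
            assert _res_partition(back) == _res_partition(mol)
        if fmt == "sdf":
            assert _bond_tuples(back) == _bond_tuples(mol)
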