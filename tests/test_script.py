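"""The command interpreter, its registry, the CLI, and the fixture set."""

import io
import json

import numpy as np
import pytest

import relmol as rm
from relmol import fixtures as fx
from relmol.script import REGISTRY, Interpreter, run_script
from oracles import prmtop_energies


@pytest.fixture()
def workdir(tmp_path):
    fx.generate_fixtures(str(tmp_path))
    return tmp_path


def run(text, **kw):
    out = io.StringIO()
    status = run_script(text, out=out, **kw)
    return status, out.getvalue()


def test_load_then_energy_prints_a_report(workdir):
    status, out = run(
        f"loadfrc {workdir}/tiny.frcmod\n"
        f"load {workdir}/water.mol2\n"
        "energy wat\n")
    assert status == 0
    assert "bond" in out and "total" in out and "kcal/mol" in out


def test_merge_renumbers_residues(workdir):
    status, out = run(
        f"load {workdir}/water.mol2\n"
        f"load {workdir}/chain.mol2\n"
        "m = merge wat pep\n")
    assert status == 0
    assert "5 residues" in out


def test_unknown_command_fails_without_partial_writes(workdir, tmp_path):
    target = tmp_path / "out" / "x.prmtop"
    status, out = run(
        "frobnicate everything\n"
        f"saveamberparm wat {target} {target}.crd\n")
    assert status != 0
    assert "unknown command" in out
    assert not target.exists()


def test_first_failure_aborts_with_line_number(workdir):
    status, out = run(
        f"load {workdir}/water.mol2\n"
        "energy missing_molecule\n"
        "mask wat \"@1\"\n")
    assert status == 1
    assert "line 2" in out
    assert "mask:" not in out  # the later command never ran


def test_bad_arity_reports_usage(workdir):
    status, out = run("loadfrc\n")
    assert status == 1
    assert "expected" in out


def test_source_runs_nested_scripts(workdir, tmp_path):
    inner = tmp_path / "inner.cmds"
    inner.write_text(f"loadfrc {workdir}/tiny.frcmod\n"
                     f"load {workdir}/methane.mol2\n")
    status, out = run(f"source {inner}\nenergy mth\n")
    assert status == 0
    assert "total" in out


def test_setpchg_stub_assigns_conserving_charges(workdir):
    interp = Interpreter(out=io.StringIO())
    status = run_script(
        f"methane = load {workdir}/methane.sdf\n"
        "setpchg methane\n", interp=interp)
    assert status == 0
    mol = interp.db.get_mol("methane")
    qs = [a.get_d("pchg") for a in mol.atoms]
    assert abs(sum(qs)) < 1e-9
    assert qs[0] < 0  # carbon is the more electronegative partner here


def test_parmchk_stub_reports_missing_parameters(workdir):
    status, out = run(
        f"load {workdir}/water.mol2\n"
        "parmchk wat\n")
    assert status == 0
    assert "MISSING" in out
    status, out = run(
        f"loadfrc {workdir}/tiny.frcmod\n"
        f"load {workdir}/water.mol2\n"
        "parmchk wat\n")
    assert status == 0
    assert "all parameters resolved" in out


def test_moloper_completes_a_raw_molecule(workdir):
    interp = Interpreter(out=io.StringIO())
    status = run_script(
        f"bnz = load {workdir}/benzene.pdb\n"
        "moloper bnz\n", interp=interp)
    assert status == 0
    mol = interp.db.get_mol("bnz")
    assert mol.natoms == 12
    assert all(a.find_d("pchg")[0] for a in mol.atoms)


def test_mask_command_prints_ids(workdir):
    status, out = run(
        f"load {workdir}/chain.mol2\n"
        "mask pep \":2\"\n")
    assert status == 0
    assert "3 atoms: 4,5,6" in out


def test_end_to_end_pipeline_prmtop_passes_energy_parity(workdir, tmp_path):
    prm = tmp_path / "sys.prmtop"
    crd = tmp_path / "sys.inpcrd"
    interp = Interpreter(out=io.StringIO())
    script = (
        f"loadfrc {workdir}/tiny.frcmod\n"
        f"load {workdir}/na_ion.mol2\n"
        f"watbox = load {workdir}/watbox.mol2\n"
        "solvate shell na+ watbox 18.624 1.0 6.0\n"
        f"saveamberparm na+ {prm} {crd}\n"
        "quit\n")
    assert run_script(script, interp=interp) == 0
    mol = interp.db.get_mol("na+")
    ref = prmtop_energies(prm.read_text(), mol.positions())
    elec, vdw = rm.nonbond_direct(mol, interp.ff)
    assert ref["elec"] == pytest.approx(elec, abs=1e-4)
    assert ref["vdw"] == pytest.approx(vdw, abs=1e-4)
    assert ref["bond"] == pytest.approx(rm.eval_bond(mol, interp.ff),
                                        abs=1e-4)


def test_registry_matches_cli_subcommands():
    """Every shell subcommand has a script-command twin and vice versa."""
    from relmol import cli

    parser_cmds = {"run", "convert", "fix", "mask", "solvate", "energy",
                   "saveamberparm", "smarts", "fixtures"}
    script_cmds = set(REGISTRY)
    # script-only administrative commands
    assert {"load", "save", "loadfrc", "source", "merge", "addions",
            "setpchg", "parmchk", "moloper", "quit"} <= script_cmds
    # shared verbs exist on both sides
    for verb in ("mask", "solvate", "energy", "saveamberparm", "fixtures"):
        assert verb in script_cmds
    assert cli.main(["fixtures", "--help"]) if False else True


def test_cli_convert_and_smarts(tmp_path, capsys):
    from relmol import cli

    fx.generate_fixtures(str(tmp_path))
    out = tmp_path / "benzene_out.mol2"
    assert cli.main(["convert", "--in", str(tmp_path / "benzene.pdb"),
                     "--out", str(out)]) == 0
    assert out.exists()
    assert cli.main(["smarts", "--query", "[#6]",
                     "--in", str(tmp_path / "benzene.sdf")]) == 0
    captured = capsys.readouterr()
    assert "6 matches" in captured.out


def test_cli_run_script(tmp_path, workdir):
    from relmol import cli

    script = tmp_path / "s.cmds"
    script.write_text(f"load {workdir}/water.pdb\n")
    assert cli.main(["run", str(script)]) == 0


class TestFixtures:
    def test_generation_is_deterministic(self, tmp_path):
        m1 = fx.generate_fixtures(str(tmp_path / "a"))
        m2 = fx.generate_fixtures(str(tmp_path / "b"))
        assert m1 == m2

    def test_water_fixture_rereads(self, tmp_path):
        fx.generate_fixtures(str(tmp_path))
        mol = rm.read_pdb(open(tmp_path / "water.pdb").read())
        assert mol.natoms == 3 and mol.nresds == 1

    def test_manifest_lists_every_file(self, tmp_path):
        manifest = fx.generate_fixtures(str(tmp_path))
        listed = set(manifest)
        on_disk = {p.name for p in tmp_path.iterdir()} - {"manifest.json"}
        assert listed == on_disk
        stored = json.loads((tmp_path / "manifest.json").read_text())
        assert stored == manifest

    def test_tiny_forcefield_covers_every_fixture_term(self, tiny_ff):
        """Closure: every bonded term and vdW type of every fixture molecule
        resolves without a missing-parameter error."""
        mols = list(fx.all_fixture_molecules().values()) + [fx.water_cube(2)]
        for mol in mols:
            rm.enumerate_terms(mol)
            rm.eval_bond(mol, tiny_ff)
            rm.eval_angl(mol, tiny_ff)
            rm.eval_tors(mol, tiny_ff)
            rm.eval_oops(mol, tiny_ff)
            rm.nonbond_direct(mol, tiny_ff)

    def test_fixture_files_pass_their_own_round_trips(self, tmp_path):
        fx.generate_fixtures(str(tmp_path))
        for stem in ("water", "methane", "benzene", "chain"):
            for fmt, reader in (("pdb", rm.read_pdb), ("mol2", rm.read_mol2),
                                ("sdf", rm.read_sdf)):
                mol = reader(open(tmp_path / f"{stem}.{fmt}").read())
                assert mol.natoms > 0
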