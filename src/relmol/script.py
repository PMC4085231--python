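"""The LEaP-like command layer.

Every command is a class with a uniform ``exec()`` entry point, registered
by name in one registry; scripts are newline-separated commands in a
``[name =] command arg ...`` grammar (double-quote quoting, ``#`` comments).
The first failing command aborts the script with its message and a nonzero
status.  ``setpchg`` and ``parmchk`` are documented stubs: the former
applies the packaged electronegativity-equalisation fallback, the latter
reports missing parameters instead of generating them (the original
commands delegate to external programs).
"""

from __future__ import annotations

import shlex
import sys

from .charges import assign_partial_charges
from .energy import energy_report, enumerate_terms
from .forcefield import ForceField, MissingParameterError, read_frc
from .formats import read_mol2, read_pdb, read_sdf, write_mol2, write_pdb, write_sdf
from .hashkeys import ANGL, ATOM, BOND, RESD, TORS
from .mask import mask_atoms
from .model import Molecule, MoleculeDatabase
from .solvate import SolventTemplate, addions, solvate_box, solvate_cap, \
    solvate_oct, solvate_shell
from .structops import add_hydrogens, fixbond

__all__ = ["Command", "CommandError", "Interpreter", "run_script", "REGISTRY"]


class CommandError(RuntimeError):
    pass


class Interpreter:
    """Holds the molecule database, the force field, and command state."""

    def __init__(self, out=None) -> None:
        self.db = MoleculeDatabase()
        self.ff = ForceField()
        self.out = out or sys.stdout

    def say(self, text: str) -> None:
        self.out.write(text + "\n")

    def get_mol(self, name: str) -> Molecule:
        try:
            return self.db.get_mol(name)
        except KeyError as exc:
            raise CommandError(str(exc)) from None


REGISTRY: dict[str, type] = {}


def command(name: str):
    def deco(cls):
        cls.name = name
        REGISTRY[name] = cls
        return cls

    return deco


class Command:
    """Base command: subclasses implement :meth:`exec` returning success."""

    name = "?"

    def __init__(self, interp: Interpreter, args: list[str],
                 target: str | None = None) -> None:
        self.interp = interp
        self.args = args
        self.target = target  # assignment name, if any

    def exec(self) -> bool:  # pragma: no cover - abstract
        raise NotImplementedError

    def need(self, n: int, usage: str) -> None:
        if len(self.args) != n:
            raise CommandError(f"{self.name}: expected {usage}")

    def store(self, mol: Molecule, default_name: str) -> None:
        name = self.target or default_name
        mol.name = name
        self.interp.db.put(name, mol)


_READERS = {"pdb": read_pdb, "ent": read_pdb, "mol2": read_mol2,
            "sdf": read_sdf, "mol": read_sdf}
_WRITERS = {"pdb": write_pdb, "mol2": write_mol2, "sdf": write_sdf,
            "mol": write_sdf}


def _format_of(path: str, hint: str | None = None) -> str:
    fmt = (hint or path.rsplit(".", 1)[-1]).lower()
    if fmt not in _READERS:
        raise CommandError(f"unknown molecule format {fmt!r}")
    return fmt


@command("load")
class LoadCommand(Command):
    """load <file> [format] — read a molecule into the database."""

    def exec(self) -> bool:
        if not 1 <= len(self.args) <= 2:
            raise CommandError("load: expected <file> [format]")
        path = self.args[0]
        fmt = _format_of(path, self.args[1] if len(self.args) == 2 else None)
        try:
            with open(path) as fh:
                mol = _READERS[fmt](fh)
        except OSError as exc:
            raise CommandError(f"load: {exc}") from None
        default = path.rsplit("/", 1)[-1].rsplit(".", 1)[0]
        self.store(mol, mol.name or default)
        self.interp.say(f"loaded {mol.name}: {mol.natoms} atoms, "
                        f"{mol.nresds} residues")
        return True


@command("save")
class SaveCommand(Command):
    """save <mol> <file> [format]"""

    def exec(self) -> bool:
        if not 2 <= len(self.args) <= 3:
            raise CommandError("save: expected <mol> <file> [format]")
        mol = self.interp.get_mol(self.args[0])
        fmt = _format_of(self.args[1],
                         self.args[2] if len(self.args) == 3 else None)
        with open(self.args[1], "w") as fh:
            _WRITERS[fmt](mol, fh)
        self.interp.say(f"saved {self.args[0]} to {self.args[1]}")
        return True


@command("loadfrc")
class LoadFrcCommand(Command):
    """loadfrc <file> — read (or overlay) force-field parameters."""

    def exec(self) -> bool:
        self.need(1, "<file>")
        try:
            with open(self.args[0]) as fh:
                read_frc(fh, into=self.interp.ff)
        except OSError as exc:
            raise CommandError(f"loadfrc: {exc}") from None
        self.interp.say(f"loaded parameters from {self.args[0]}")
        return True


@command("source")
class SourceCommand(Command):
    """source <script> — interpret a nested command file."""

    def exec(self) -> bool:
        self.need(1, "<script>")
        try:
            with open(self.args[0]) as fh:
                text = fh.read()
        except OSError as exc:
            raise CommandError(f"source: {exc}") from None
        status = run_script(text, interp=self.interp)
        if status != 0:
            raise CommandError(f"source: {self.args[0]} failed")
        return True


@command("merge")
class MergeCommand(Command):
    """merge <mol> <mol> ... — concatenate molecules, renumbering residues."""

    def exec(self) -> bool:
        if len(self.args) < 2:
            raise CommandError("merge: expected at least two molecule names")
        out = Molecule(self.target or "merged")
        seq = 0
        for name in self.args:
            src = self.interp.get_mol(name)
            amap = {}
            res_list = list(src.resds) or [None]
            for res in res_list:
                seq += 1
                new_res = out.create(RESD)
                new_res.set_s("name",
                              (res.find_s("name")[1] if res else None) or "RES")
                new_res.set_i("seq", seq)
                atoms = res.related(ATOM) if res else src.atoms
                for a in atoms:
                    na = out.create(ATOM)
                    for key in ("name", "type"):
                        f, v = a.find_s(key)
                        if f:
                            na.set_s(key, v)
                    for key in ("element", "fcharge", "nhyd"):
                        f, v = a.find_i(key)
                        if f:
                            na.set_i(key, v)
                    for key in ("pchg", "born"):
                        f, v = a.find_d(key)
                        if f:
                            na.set_d(key, v)
                    f, v = a.find_v("position")
                    if f:
                        na.set_v("position", v)
                    new_res.relate(na)
                    amap[a.index] = na
            for b in src.bonds:
                ba = b.related(ATOM)
                if len(ba) == 2 and ba[0].index in amap and ba[1].index in amap:
                    nb = out.create(BOND)
                    nb.relate(amap[ba[0].index])
                    nb.relate(amap[ba[1].index])
                    f, v = b.find_i("order")
                    nb.set_i("order", v if f else 1)
                    amap[ba[0].index].relate(amap[ba[1].index])
        self.store(out, out.name)
        self.interp.say(f"merged {len(self.args)} molecules -> {out.name}: "
                        f"{out.natoms} atoms, {out.nresds} residues")
        return True


def _template_from(interp: Interpreter, name: str, solvlen: float
                   ) -> SolventTemplate:
    return SolventTemplate(interp.get_mol(name), solvlen)


@command("solvate")
class SolvateCommand(Command):
    """solvate <mode> <mol> <template> <solvlen> <args...>

    modes: shell <closeness> <extent>; box|oct <buffer> [closeness];
    cap <cx> <cy> <cz> <radius> [closeness]
    """

    def exec(self) -> bool:
        if len(self.args) < 5:
            raise CommandError("solvate: expected <mode> <mol> <template> "
                               "<solvlen> <args...>")
        mode = self.args[0]
        mol = self.interp.get_mol(self.args[1])
        template = _template_from(self.interp, self.args[2],
                                  float(self.args[3]))
        rest = [float(x) for x in self.args[4:]]
        try:
            if mode == "shell":
                n = solvate_shell(mol, template, *rest)
            elif mode == "box":
                n = solvate_box(mol, template, *rest)
            elif mode == "oct":
                n = solvate_oct(mol, template, *rest)
            elif mode == "cap":
                n = solvate_cap(mol, template, rest[0:3], *rest[3:])
            else:
                raise CommandError(f"solvate: unknown mode {mode!r}")
        except ValueError as exc:
            raise CommandError(f"solvate: {exc}") from None
        self.interp.say(f"solvate {mode}: added {n} solvent residues")
        return True


@command("addions")
class AddIonsCommand(Command):
    """addions <mol> <ion> <count|auto>"""

    def exec(self) -> bool:
        self.need(3, "<mol> <ion> <count|auto>")
        mol = self.interp.get_mol(self.args[0])
        ion = self.interp.get_mol(self.args[1])
        count = self.args[2] if self.args[2] == "auto" else int(self.args[2])
        try:
            n = addions(mol, ion, count)
        except ValueError as exc:
            raise CommandError(f"addions: {exc}") from None
        if n == 0:
            self.interp.say("addions: net charge is zero; nothing to do")
        else:
            self.interp.say(f"addions: placed {n} ions")
        return True


@command("translate")
class TranslateCommand(Command):
    """translate <mol> <dx> <dy> <dz>"""

    def exec(self) -> bool:
        self.need(4, "<mol> <dx> <dy> <dz>")
        from .structops import translate

        mol = self.interp.get_mol(self.args[0])
        translate(mol, [float(x) for x in self.args[1:4]])
        return True


@command("setpchg")
class SetPchgCommand(Command):
    """setpchg <mol> — fallback partial charges (stub for Antechamber)."""

    def exec(self) -> bool:
        self.need(1, "<mol>")
        mol = self.interp.get_mol(self.args[0])
        assign_partial_charges(mol)
        self.interp.say(f"setpchg: fallback charges on {mol.natoms} atoms "
                        "(built-in electronegativity equalisation)")
        return True


@command("parmchk")
class ParmchkCommand(Command):
    """parmchk <mol> — report missing parameters (stub: does not generate)."""

    def exec(self) -> bool:
        self.need(1, "<mol>")
        mol = self.interp.get_mol(self.args[0])
        enumerate_terms(mol)
        missing = []
        from .energy import eval_angl, eval_bond, eval_oops, eval_tors, \
            nonbond_direct

        for fn in (eval_bond, eval_angl, eval_tors, eval_oops):
            try:
                fn(mol, self.interp.ff)
            except MissingParameterError as exc:
                missing.append(str(exc))
        try:
            nonbond_direct(mol, self.interp.ff)
        except (MissingParameterError, ValueError) as exc:
            missing.append(str(exc))
        if missing:
            for m in missing:
                self.interp.say(f"parmchk: MISSING {m}")
        else:
            self.interp.say("parmchk: all parameters resolved")
        return True


@command("moloper")
class MolOperCommand(Command):
    """moloper <mol> — fixbond + addHs + fallback charges."""

    def exec(self) -> bool:
        self.need(1, "<mol>")
        mol = self.interp.get_mol(self.args[0])
        fixbond(mol)
        add_hydrogens(mol)
        assign_partial_charges(mol)
        self.interp.say(f"moloper: {mol.natoms} atoms after completion")
        return True


@command("mask")
class MaskCommand(Command):
    """mask <mol> <expression> — print matching atom ids."""

    def exec(self) -> bool:
        self.need(2, "<mol> <expression>")
        mol = self.interp.get_mol(self.args[0])
        try:
            atoms = mask_atoms(mol, self.args[1])
        except ValueError as exc:
            raise CommandError(f"mask: {exc}") from None
        ids = [a.user_id for a in atoms]
        self.interp.say(f"mask: {len(ids)} atoms: "
                        + ",".join(str(i) for i in ids))
        return True


@command("energy")
class EnergyCommand(Command):
    """energy <mol> [gb] — print an energy report."""

    def exec(self) -> bool:
        if not 1 <= len(self.args) <= 2:
            raise CommandError("energy: expected <mol> [gb]")
        mol = self.interp.get_mol(self.args[0])
        gb = len(self.args) == 2 and self.args[1] == "gb"
        try:
            report = energy_report(mol, self.interp.ff, gb=gb)
        except (MissingParameterError, ValueError) as exc:
            raise CommandError(f"energy: {exc}") from None
        self.interp.say(str(report))
        return True


@command("saveamberparm")
class SaveAmberParmCommand(Command):
    """saveamberparm <mol> <prmtop> <inpcrd>"""

    def exec(self) -> bool:
        self.need(3, "<mol> <prmtop> <inpcrd>")
        from .amber import write_amber_prmtop, write_coordinates

        mol = self.interp.get_mol(self.args[0])
        if mol.count(ANGL) == 0 and mol.count(TORS) == 0:
            enumerate_terms(mol)
        try:
            with open(self.args[1], "w") as fh:
                write_amber_prmtop(mol, self.interp.ff, fh)
            with open(self.args[2], "w") as fh:
                write_coordinates(mol, fh)
        except (MissingParameterError, ValueError) as exc:
            raise CommandError(f"saveamberparm: {exc}") from None
        self.interp.say(f"saveamberparm: wrote {self.args[1]} and "
                        f"{self.args[2]}")
        return True


@command("fixtures")
class FixturesCommand(Command):
    """fixtures <dir> — write the packaged fixture files."""

    def exec(self) -> bool:
        self.need(1, "<dir>")
        from .fixtures import generate_fixtures

        try:
            manifest = generate_fixtures(self.args[0])
        except OSError as exc:
            raise CommandError(f"fixtures: {exc}") from None
        self.interp.say(f"fixtures: wrote {len(manifest)} files to "
                        f"{self.args[0]}")
        return True


@command("quit")
class QuitCommand(Command):
    def exec(self) -> bool:
        return True


def _parse_line(line: str):
    tokens = shlex.split(line, comments=True)
    if not tokens:
        return None, None, None
    target = None
    if len(tokens) >= 3 and tokens[1] == "=":
        target = tokens[0]
        tokens = tokens[2:]
    return target, tokens[0], tokens[1:]


def run_script(text_or_stream, interp: Interpreter | None = None, out=None) -> int:
    """Execute a command script; returns 0 on success, 1 on first failure."""
    text = (text_or_stream if isinstance(text_or_stream, str)
            else text_or_stream.read())
    interp = interp or Interpreter(out=out)
    if out is not None:
        interp.out = out
    for lineno, raw in enumerate(text.splitlines(), start=1):
        line = raw.strip()
        if not line or line.startswith("#"):
            continue
        try:
            target, name, args = _parse_line(line)
        except ValueError as exc:
            interp.say(f"error: line {lineno}: {exc}")
            return 1
        if name is None:
            continue
        cls = REGISTRY.get(name)
        if cls is None:
            interp.say(f"error: line {lineno}: unknown command {name!r}")
            return 1
        cmd = cls(interp, args, target=target)
        try:
            ok = cmd.exec()
        except CommandError as exc:
            interp.say(f"error: line {lineno}: {exc}")
            return 1
        if not ok:
            interp.say(f"error: line {lineno}: {name} failed")
            return 1
        if name == "quit":
            break
    return 0
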