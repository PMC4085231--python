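"""The atom-mask selection language.

``@`` selects atoms and ``:`` selects residues, by 1-based id, id range
(``n-m``), comma list, or name (``*`` suffix wildcard allowed); ``&``, ``|``
and ``!`` compose; ``expr < @r`` keeps the atoms within ``r`` Angstrom of
any atom of ``expr`` (the core atoms themselves qualify at distance 0) and
``expr > @r`` is its strict complement; ``expr < :r`` / ``> :r`` do the same
at residue granularity (a residue qualifies when any of its atoms does).
Whitespace is insignificant.
"""

from __future__ import annotations

from dataclasses import dataclass, field

import numpy as np

from .hashkeys import ATOM, RESD
from .model import Molecule

__all__ = ["parse_mask", "match_mask", "mask_atoms", "MaskError", "MaskNode"]


class MaskError(ValueError):
    def __init__(self, message: str, position: int | None = None) -> None:
        if position is not None:
            message = f"position {position}: {message}"
        super().__init__(message)
        self.position = position


@dataclass
class MaskNode:
    """A node of the parsed mask expression tree."""

    kind: str  # atom_node | resd_node | dist_node | and | or | not
    items: list = field(default_factory=list)     # id ints, (lo, hi) ranges, names
    children: list = field(default_factory=list)  # sub-expressions
    threshold: float = 0.0                        # dist_node only
    granularity: str = "atom"                     # dist_node: atom | resd
    direction: str = "<"                          # dist_node: < | >


class _Parser:
    def __init__(self, text: str) -> None:
        self.text = text
        self.pos = 0

    def _skip_ws(self) -> None:
        while self.pos < len(self.text) and self.text[self.pos].isspace():
            self.pos += 1

    def peek(self) -> str:
        self._skip_ws()
        return self.text[self.pos] if self.pos < len(self.text) else ""

    def take(self) -> str:
        ch = self.peek()
        self.pos += 1
        return ch

    def error(self, msg: str):
        raise MaskError(msg, self.pos)

    # grammar: or := and ('|' and)* ; and := unary ('&' unary)* ;
    # unary := '!' unary | postfix ; postfix := primary (distop)* ;
    # primary := '@' ids | ':' ids | '(' or ')'
    def parse(self) -> MaskNode:
        node = self.parse_or()
        if self.peek():
            self.error(f"unexpected trailing {self.peek()!r}")
        return node

    def parse_or(self) -> MaskNode:
        node = self.parse_and()
        while self.peek() == "|":
            self.take()
            rhs = self.parse_and()
            node = MaskNode("or", children=[node, rhs])
        return node

    def parse_and(self) -> MaskNode:
        node = self.parse_unary()
        while self.peek() == "&":
            self.take()
            rhs = self.parse_unary()
            node = MaskNode("and", children=[node, rhs])
        return node

    def parse_unary(self) -> MaskNode:
        if self.peek() == "!":
            self.take()
            return MaskNode("not", children=[self.parse_unary()])
        return self.parse_postfix()

    def parse_postfix(self) -> MaskNode:
        node = self.parse_primary()
        while self.peek() and self.peek() in "<>":
            op = self.take()
            gran_ch = self.peek()
            if gran_ch not in "@:":
                self.error(f"expected '@' or ':' after {op!r}")
            self.take()
            threshold = self._number()
            node = MaskNode("dist_node", children=[node], threshold=threshold,
                            granularity="atom" if gran_ch == "@" else "resd",
                            direction=op)
        return node

    def parse_primary(self) -> MaskNode:
        ch = self.peek()
        if ch == "(":
            self.take()
            node = self.parse_or()
            if self.peek() != ")":
                self.error("expected ')'")
            self.take()
            return node
        if ch == "@":
            self.take()
            return MaskNode("atom_node", items=self._id_list())
        if ch == ":":
            self.take()
            return MaskNode("resd_node", items=self._id_list())
        if ch == "":
            self.error("unexpected end of expression")
        self.error(f"expected '@', ':' or '(', found {ch!r}")

    def _number(self) -> float:
        self._skip_ws()
        start = self.pos
        while self.pos < len(self.text) and (self.text[self.pos].isdigit()
                                             or self.text[self.pos] == "."):
            self.pos += 1
        if self.pos == start:
            self.error("expected a numeric distance threshold")
        return float(self.text[start:self.pos])

    def _id_list(self) -> list:
        items: list = []
        while True:
            self._skip_ws()
            start = self.pos
            ch = self.peek()
            if ch.isdigit():
                lo = self._int()
                if self.peek() == "-":
                    self.take()
                    hi = self._int()
                    if lo > hi:
                        self.error(f"range {lo}-{hi} has lo > hi")
                    items.append((lo, hi))
                else:
                    items.append(lo)
            elif ch and (ch.isalpha() or ch in "_'*"):
                name = ""
                while (self.pos < len(self.text)
                       and (self.text[self.pos].isalnum()
                            or self.text[self.pos] in "_'*")):
                    name += self.text[self.pos]
                    self.pos += 1
                items.append(name)
            else:
                self.pos = start
                self.error("empty id list")
            if self.peek() == ",":
                self.take()
                continue
            break
        return items

    def _int(self) -> int:
        self._skip_ws()
        start = self.pos
        while self.pos < len(self.text) and self.text[self.pos].isdigit():
            self.pos += 1
        if self.pos == start:
            self.error("expected an integer id")
        return int(self.text[start:self.pos])


def parse_mask(text: str) -> MaskNode:
    """Parse a mask expression into its node tree."""
    if not text or not text.strip():
        raise MaskError("empty mask expression")
    return _Parser(text).parse()


# ---------------------------------------------------------------------------
# evaluation


def _name_matches(pattern: str, name: str) -> bool:
    if pattern.endswith("*"):
        return name.startswith(pattern[:-1])
    return name == pattern


def _select_ids(items: list, mol: Molecule, tc) -> set[int]:
    n = mol.count(tc)
    out: set[int] = set()
    names = None
    for item in items:
        if isinstance(item, int):
            if not 1 <= item <= n:
                raise MaskError(f"id {item} out of range (1..{n})")
            out.add(item - 1)
        elif isinstance(item, tuple):
            lo, hi = item
            if lo < 1 or hi > n:
                raise MaskError(f"range {lo}-{hi} out of range (1..{n})")
            out.update(range(lo - 1, hi))
        else:
            if names is None:
                names = [mol.handle(tc, i).find_s("name")[1] or ""
                         for i in range(n)]
            out.update(i for i, nm in enumerate(names) if _name_matches(item, nm))
    return out


def _residue_atoms(mol: Molecule) -> list[list[int]]:
    return [[a.index for a in res.related(ATOM)] for res in mol.resds]


def _evaluate(node: MaskNode, mol: Molecule, include_core: bool) -> set[int]:
    all_atoms = set(range(mol.natoms))
    if node.kind == "atom_node":
        return _select_ids(node.items, mol, ATOM)
    if node.kind == "resd_node":
        res_sel = _select_ids(node.items, mol, RESD)
        res_atoms = _residue_atoms(mol)
        out: set[int] = set()
        for r in res_sel:
            out.update(res_atoms[r])
        return out
    if node.kind == "not":
        return all_atoms - _evaluate(node.children[0], mol, include_core)
    if node.kind == "and":
        return (_evaluate(node.children[0], mol, include_core)
                & _evaluate(node.children[1], mol, include_core))
    if node.kind == "or":
        return (_evaluate(node.children[0], mol, include_core)
                | _evaluate(node.children[1], mol, include_core))
    if node.kind == "dist_node":
        core = _evaluate(node.children[0], mol, include_core)
        pos = mol.positions()
        if pos.size == 0 and core:
            raise MaskError("distance selection needs atom positions")
        if core:
            core_idx = sorted(core)
            d = np.linalg.norm(pos[:, None, :] - pos[None, core_idx, :], axis=2)
            dmin = d.min(axis=1)
            within = {i for i in range(mol.natoms)
                      if dmin[i] <= node.threshold + 1e-12}
        else:
            within = set()
        if not include_core:
            within -= core
        if node.granularity == "resd":
            res_atoms = _residue_atoms(mol)
            sel: set[int] = set()
            for atoms in res_atoms:
                if any(a in within for a in atoms):
                    sel.update(atoms)
            within = sel
        if node.direction == ">":
            return all_atoms - within
        return within
    raise MaskError(f"unknown node kind {node.kind!r}")  # pragma: no cover


def match_mask(node: MaskNode, mol: Molecule, include_core: bool = True) -> list[int]:
    """Evaluate a parsed mask; returns sorted 0-based atom indices."""
    return sorted(_evaluate(node, mol, include_core))


def mask_atoms(mol: Molecule, expression: str, include_core: bool = True):
    """Parse-and-match convenience; returns atom handles."""
    idx = match_mask(parse_mask(expression), mol, include_core)
    return [mol.handle(ATOM, i) for i in idx]
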