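"""SMILES reader (and a non-canonical writer) over the relational model.

The parser walks the string one character at a time, tracking whether the
cursor is inside a bracket atom — the same character means different things
in and out of brackets (``C`` outside is a plain carbon; inside a bracket it
may carry an isotope, ``[13C]``).  Charges are read from ``+``/``-``
(:func:`parse_charge`), ring open/close digits from digits outside brackets
(:func:`parse_ring`), isotope weights from leading digits inside brackets
(:func:`parse_weight`) and element symbols from letters
(:func:`parse_alpha`).  Implicit hydrogens are recorded as the per-atom
``nhyd`` count, never as atom objects.

Supported subset: organic-subset atoms; bracket atoms with isotope, charge
and explicit H count; branches; ring bonds 0-9 and ``%nn``; bond symbols
``- = # :``; aromatic lowercase atoms (checked to close into rings).
Stereo markers (``/ \\ @``) are parsed and ignored with a warning.
"""

from __future__ import annotations

import warnings

from . import elements
from .hashkeys import ATOM, BOND, RESD
from .model import Molecule, ObjectHandle
from .structops import AROMATIC_ORDER, bond_order_sum

__all__ = ["read_smiles", "write_smiles", "SmilesError"]


class SmilesError(ValueError):
    def __init__(self, message: str, position: int | None = None) -> None:
        if position is not None:
            message = f"position {position}: {message}"
        super().__init__(message)
        self.position = position


ORGANIC = {"B": 5, "C": 6, "N": 7, "O": 8, "P": 15, "S": 16,
           "F": 9, "Cl": 17, "Br": 35, "I": 53}
AROMATIC_SYMBOLS = {"b": 5, "c": 6, "n": 7, "o": 8, "p": 15, "s": 16}
_BOND_ORDERS = {"-": 1, "=": 2, "#": 3, ":": AROMATIC_ORDER}


class _Cursor:
    """Character cursor with bracket state."""

    __slots__ = ("text", "pos", "in_bracket")

    def __init__(self, text: str) -> None:
        self.text = text
        self.pos = 0
        self.in_bracket = False

    def peek(self) -> str:
        return self.text[self.pos] if self.pos < len(self.text) else ""

    def take(self) -> str:
        ch = self.peek()
        self.pos += 1
        if ch == "[":
            self.in_bracket = True
        elif ch == "]":
            self.in_bracket = False
        return ch


def parse_charge(cur: _Cursor) -> int:
    """Read ``+``/``-`` (repeated or followed by digits) at the cursor."""
    sign = 1 if cur.peek() == "+" else -1
    symbol = cur.take()
    count = 1
    digits = ""
    while cur.peek().isdigit():
        digits += cur.take()
    if digits:
        count = int(digits)
    else:
        while cur.peek() == symbol:
            cur.take()
            count += 1
    return sign * count


def parse_weight(cur: _Cursor) -> int:
    """Read the isotope weight digits at the start of a bracket."""
    digits = ""
    while cur.peek().isdigit():
        digits += cur.take()
    return int(digits)


def parse_alpha(cur: _Cursor, organic_only: bool) -> tuple[int, bool]:
    """Read an element symbol at the cursor; returns (atomic number, aromatic)."""
    pos = cur.pos
    ch = cur.peek()
    if ch in AROMATIC_SYMBOLS:
        cur.take()
        return AROMATIC_SYMBOLS[ch], True
    if ch.isupper():
        two = cur.text[cur.pos : cur.pos + 2]
        if organic_only:
            if two in ("Cl", "Br"):
                cur.take()
                cur.take()
                return ORGANIC[two], False
            if ch in ORGANIC:
                cur.take()
                return ORGANIC[ch], False
            raise SmilesError(f"{ch!r} is not an organic-subset atom", pos)
        if len(two) == 2 and two[1].islower():
            try:
                z = elements.atomic_number(two)
            except KeyError:
                z = None
            if z is not None:
                cur.take()
                cur.take()
                return z, False
        try:
            z = elements.atomic_number(ch)
        except KeyError:
            raise SmilesError(f"unknown element {ch!r}", pos) from None
        cur.take()
        return z, False
    raise SmilesError(f"expected an element symbol, found {ch!r}", pos)


def parse_ring(cur: _Cursor) -> int:
    """Read a ring-closure label: a single digit or ``%nn``."""
    ch = cur.take()
    if ch == "%":
        digits = ""
        while cur.peek().isdigit():
            digits += cur.take()
        if len(digits) < 2:
            raise SmilesError("'%' ring label needs two digits", cur.pos)
        return int(digits)
    return int(ch)


def _bracket_atom(mol: Molecule, cur: _Cursor) -> ObjectHandle:
    open_pos = cur.pos
    cur.take()  # consume '['
    atom = mol.create(ATOM)
    if cur.peek().isdigit():
        atom.set_i("weight", parse_weight(cur))
    z, arom = parse_alpha(cur, organic_only=False)
    atom.set_i("element", z)
    if arom:
        atom.set_i("arom", 1)
    hcount = 0
    seen_stereo = False
    while True:
        ch = cur.peek()
        if ch == "":
            raise SmilesError("unclosed bracket", open_pos)
        if ch == "]":
            cur.take()
            break
        if ch == "@":
            cur.take()
            seen_stereo = True
        elif ch == "H":
            cur.take()
            digits = ""
            while cur.peek().isdigit():
                digits += cur.take()
            hcount = int(digits) if digits else 1
        elif ch in "+-":
            atom.set_i("fcharge", parse_charge(cur))
        elif ch == ":":
            cur.take()
            while cur.peek().isdigit():
                cur.take()  # atom-map class, ignored
        else:
            raise SmilesError(f"unsupported bracket token {ch!r}", cur.pos)
    if seen_stereo:
        warnings.warn("stereo markers in SMILES are parsed and ignored")
    atom.set_i("nhyd", hcount)
    atom.set_i("explicit_h", 1)
    atom.set_s("name", elements.symbol(z) + str(atom.user_id))
    return atom


def _make_bond(mol: Molecule, a: ObjectHandle, b: ObjectHandle, order: int | None) -> None:
    if order is None:
        a_arom = a.find_i("arom")[1] or 0
        b_arom = b.find_i("arom")[1] or 0
        order = AROMATIC_ORDER if (a_arom and b_arom) else 1
    bond = mol.create(BOND)
    bond.relate(a)
    bond.relate(b)
    bond.set_i("order", order)
    a.relate(b)


def read_smiles(text: str, name: str = "") -> Molecule:
    """Parse a SMILES string into a molecule (implicit H as ``nhyd`` counts)."""
    if not text or not text.strip():
        raise SmilesError("empty SMILES string")
    mol = Molecule(name or text.strip())
    cur = _Cursor(text.strip())
    prev: ObjectHandle | None = None
    pending_order: int | None = None
    stack: list[ObjectHandle | None] = []
    rings: dict[int, tuple[ObjectHandle, int | None, int]] = {}

    def attach(atom: ObjectHandle) -> None:
        nonlocal prev, pending_order
        if prev is not None:
            _make_bond(mol, prev, atom, pending_order)
        prev = atom
        pending_order = None

    while cur.peek():
        ch = cur.peek()
        pos = cur.pos
        if ch == "[":
            attach(_bracket_atom(mol, cur))
        elif ch.isdigit() or ch == "%":
            if prev is None:
                raise SmilesError("ring label before any atom", pos)
            label = parse_ring(cur)
            if label in rings:
                other, order_o, _ = rings.pop(label)
                order = pending_order if pending_order is not None else order_o
                if other.index == prev.index:
                    raise SmilesError(f"ring bond {label} closes on its own atom", pos)
                _make_bond(mol, prev, other, order)
                pending_order = None
            else:
                rings[label] = (prev, pending_order, pos)
                pending_order = None
        elif ch in _BOND_ORDERS:
            cur.take()
            pending_order = _BOND_ORDERS[ch]
        elif ch in "/\\":
            cur.take()
            warnings.warn("stereo bond markers are parsed and ignored")
            pending_order = 1
        elif ch == "(":
            cur.take()
            stack.append(prev)
        elif ch == ")":
            cur.take()
            if not stack:
                raise SmilesError("unbalanced ')'", pos)
            prev = stack.pop()
        elif ch == ".":
            cur.take()
            prev = None
            pending_order = None
        elif ch.isupper() or ch in AROMATIC_SYMBOLS:
            z, arom = parse_alpha(cur, organic_only=True)
            atom = mol.create(ATOM)
            atom.set_i("element", z)
            if arom:
                atom.set_i("arom", 1)
            atom.set_s("name", elements.symbol(z) + str(atom.user_id))
            attach(atom)
        else:
            raise SmilesError(f"unexpected character {ch!r}", pos)
    if rings:
        label, (_a, _o, pos) = sorted(rings.items())[0]
        raise SmilesError(f"unclosed ring digit {label}", pos)
    if stack:
        raise SmilesError("unclosed '('")
    _assign_implicit_h(mol)
    _check_aromatic_rings(mol)
    res = mol.create(RESD)
    res.set_s("name", "LIG")
    res.set_i("seq", 1)
    for a in mol.atoms:
        res.relate(a)
    return mol


def _assign_implicit_h(mol: Molecule) -> None:
    import math

    for atom in mol.atoms:
        if atom.find_i("explicit_h")[1]:
            continue
        z = atom.get_i("element")
        valences = elements.standard_valences(z)
        if not valences:
            atom.set_i("nhyd", 0)
            continue
        charge = atom.find_i("fcharge")[1] or 0
        used = int(math.ceil(bond_order_sum(atom) - 1e-9))
        nh = 0
        for v in valences:
            target = v + charge if (charge > 0 and z in (7, 8, 15, 16)) else v - abs(
                charge) if charge < 0 else v
            if target >= used:
                nh = target - used
                break
        atom.set_i("nhyd", nh)


def _check_aromatic_rings(mol: Molecule) -> None:
    """Every lowercase (aromatic) atom must close into a ring."""
    degree = {a.index: len(a.related(ATOM)) for a in mol.atoms}
    nbrs = {a.index: [n.index for n in a.related(ATOM)] for a in mol.atoms}
    queue = [i for i, d in degree.items() if d <= 1]
    while queue:
        i = queue.pop()
        degree[i] = 0
        for j in nbrs[i]:
            if degree[j] > 0:
                degree[j] -= 1
                if degree[j] == 1:
                    queue.append(j)
    for atom in mol.atoms:
        if (atom.find_i("arom")[1] or 0) and degree[atom.index] < 2:
            raise SmilesError(
                f"aromatic atom {atom.user_id} does not close into a ring")


# ---------------------------------------------------------------------------
# writer (non-canonical)


def _atom_token(atom: ObjectHandle) -> str:
    z = atom.get_i("element")
    sym = elements.symbol(z)
    arom = atom.find_i("arom")[1] or 0
    charge = atom.find_i("fcharge")[1] or 0
    weight = atom.find_i("weight")[1] or 0
    nhyd = atom.find_i("nhyd")[1] or 0
    body = sym.lower() if arom else sym
    if charge == 0 and weight == 0 and sym in ORGANIC and not atom.find_i("explicit_h")[1]:
        return body
    token = "["
    if weight:
        token += str(weight)
    token += body
    if nhyd:
        token += "H" + (str(nhyd) if nhyd > 1 else "")
    if charge:
        sign = "+" if charge > 0 else "-"
        token += sign + (str(abs(charge)) if abs(charge) > 1 else "")
    return token + "]"


def write_smiles(mol: Molecule) -> str:
    """Emit a (non-canonical) SMILES string for the heavy-atom graph."""
    n = mol.natoms
    if n == 0:
        raise SmilesError("cannot write SMILES for an empty molecule")
    nbrs: dict[int, list[tuple[int, int]]] = {a.index: [] for a in mol.atoms}
    from .hashkeys import BOND

    for bond in mol.objects(BOND):
        atoms = bond.related(ATOM)
        if len(atoms) != 2:
            continue
        order = bond.find_i("order")[1] or 1
        i, j = atoms[0].index, atoms[1].index
        nbrs[i].append((j, order))
        nbrs[j].append((i, order))
    done: set[int] = set()
    parts = []
    for a in mol.atoms:
        if a.index not in done:
            frag_atoms, text = _fragment(mol, a.index, nbrs)
            done.update(frag_atoms)
            parts.append(text)
    return ".".join(parts)


def _fragment(mol: Molecule, start: int, nbrs) -> tuple[set[int], str]:
    """DFS SMILES emission for one connected fragment."""
    visited: set[int] = set()
    ring_labels: dict[tuple[int, int], int] = {}
    ring_at: dict[int, list[tuple[int, int]]] = {}
    counter = [1]

    # first pass: find back edges via DFS
    order_of: dict[tuple[int, int], int] = {}
    for i, lst in nbrs.items():
        for j, o in lst:
            order_of[(i, j)] = o
    parent: dict[int, int | None] = {start: None}
    seen = {start}
    stack = [start]
    tree: dict[int, list[int]] = {i: [] for i in nbrs}
    back_edges: list[tuple[int, int]] = []
    while stack:
        i = stack.pop()
        for j, _o in sorted(nbrs[i], reverse=True):
            if j not in seen:
                seen.add(j)
                parent[j] = i
                tree[i].append(j)
                stack.append(j)
            elif parent.get(i) != j:
                e = (min(i, j), max(i, j))
                if e not in [tuple(x) for x in back_edges]:
                    back_edges.append(e)
    back_edges = sorted(set(back_edges))
    for e in back_edges:
        lbl = counter[0]
        counter[0] += 1
        ring_labels[e] = lbl
        ring_at.setdefault(e[0], []).append((e[1], lbl))
        ring_at.setdefault(e[1], []).append((e[0], lbl))

    def bond_sym(order: int, i: int, j: int) -> str:
        ai = mol.handle(ATOM, i)
        aj = mol.handle(ATOM, j)
        both_arom = (ai.find_i("arom")[1] or 0) and (aj.find_i("arom")[1] or 0)
        if order == AROMATIC_ORDER:
            return "" if both_arom else ":"
        if order == 1:
            return "-" if both_arom else ""
        return {2: "=", 3: "#"}.get(order, "")

    emitted_label: set[tuple[int, int]] = set()

    def rec(i: int) -> str:
        visited.add(i)
        out = _atom_token(mol.handle(ATOM, i))
        for j, lbl in ring_at.get(i, []):
            e = (min(i, j), max(i, j))
            sym = bond_sym(order_of[(i, j)], i, j) if e not in emitted_label else ""
            emitted_label.add(e)
            out += sym + (str(lbl) if lbl < 10 else f"%{lbl:02d}")
        kids = [j for j in sorted(tree[i]) if j not in visited]
        for k, j in enumerate(kids):
            if j in visited:
                continue
            sub = bond_sym(order_of[(i, j)], i, j) + rec(j)
            out += f"({sub})" if k < len(kids) - 1 else sub
        return out

    text = rec(start)
    return visited, text
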