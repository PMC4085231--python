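"""SMARTS reader and substructure matcher.

A query is stored as a molecule-like graph whose atoms and bonds carry
predicate properties (kind ``a``).  Atom predicates are an OR-list of
AND-lists of primitives; supported primitives are atomic number (``#n``),
element symbols (aliphatic uppercase / aromatic lowercase), ``a``/``A``
(aromatic/aliphatic), formal charge (``+``/``-``), degree (``D<n>``), ring
membership (``R``) and the wildcard ``*``; ``!`` negates, ``&``/``;`` and
juxtaposition conjoin, ``,`` alternates.  Bond primitives are ``- = # : ~``;
an unwritten bond means "single or aromatic".  Anything else raises an
unsupported-token error — never silent acceptance.

Matching enumerates every subgraph monomorphism (symmetric duplicates
retained) in deterministic lexicographic order of matched atom indices.
"""

from __future__ import annotations

from . import elements
from .hashkeys import ATOM, BOND
from .model import Molecule, ObjectHandle
from .smiles import AROMATIC_SYMBOLS, SmilesError
from .structops import AROMATIC_ORDER

__all__ = ["read_smarts", "match_smarts", "SmartsError", "QueryGraph"]


class SmartsError(ValueError):
    def __init__(self, message: str, position: int | None = None) -> None:
        if position is not None:
            message = f"position {position}: {message}"
        super().__init__(message)
        self.position = position


# a primitive is (negated, kind, value); an atom predicate is [[prim, ...], ...]
# meaning OR over the outer list, AND over each inner list.

QueryGraph = Molecule  # a query is a molecule-like graph with predicate props

_BOND_PRIMS = {"-": "single", "=": "double", "#": "triple",
               ":": "aromatic", "~": "any"}


def _parse_bracket(text: str, start: int) -> tuple[list, int]:
    """Parse a bracket atom expression starting after '['; returns (pred, end).

    Operator precedence follows the SMARTS convention:
    ``!`` > ``&`` (and, also implicit) > ``,`` (or) > ``;`` (and).
    The result is normalised to an OR-list of AND-lists by distributing the
    low-precedence ``;`` clauses over the alternatives.
    """
    tokens, end = _tokenize_bracket(text, start)
    # split on ';' (low and), then on ',' (or); '&' and juxtaposition were
    # already folded into consecutive primitives
    clauses: list[list[list]] = [[[]]]  # clauses -> alternatives -> prims
    for tok in tokens:
        if tok == ";":
            clauses.append([[]])
        elif tok == ",":
            clauses[-1].append([])
        else:
            clauses[-1][-1].append(tok)
    for clause in clauses:
        for alt in clause:
            if not alt:
                raise SmartsError("empty bracket expression", start)
    # cartesian distribution of the AND-ed clauses
    alternatives = clauses[0]
    for clause in clauses[1:]:
        alternatives = [a + b for a in alternatives for b in clause]
    return alternatives, end


def _tokenize_bracket(text: str, start: int):
    """Scan bracket contents into primitive tuples and ','/';' separators."""
    tokens: list = []
    i = start
    negate = False
    while i < len(text):
        ch = text[i]
        if ch == "]":
            if negate:
                raise SmartsError("dangling '!'", i)
            return tokens, i + 1
        if ch in ",;":
            if negate:
                raise SmartsError("dangling '!'", i)
            tokens.append(ch)
            i += 1
            continue
        if ch == "&":
            i += 1
            continue
        if ch == "!":
            negate = not negate
            i += 1
            continue
        prim = None
        if ch == "#":
            j = i + 1
            digits = ""
            while j < len(text) and text[j].isdigit():
                digits += text[j]
                j += 1
            if not digits:
                raise SmartsError("'#' needs an atomic number", i)
            prim = ("anum", int(digits))
            i = j
        elif ch == "*":
            prim = ("any", None)
            i += 1
        elif ch == "a":
            prim = ("arom", None)
            i += 1
        elif ch == "A":
            prim = ("aliph", None)
            i += 1
        elif ch == "D":
            j = i + 1
            digits = ""
            while j < len(text) and text[j].isdigit():
                digits += text[j]
                j += 1
            prim = ("degree", int(digits) if digits else 1)
            i = j
        elif ch == "R":
            j = i + 1
            while j < len(text) and text[j].isdigit():
                j += 1  # ring-count qualifier collapses to membership
            prim = ("ring", None)
            i = j
        elif ch in "+-":
            sign = 1 if ch == "+" else -1
            j = i + 1
            digits = ""
            while j < len(text) and text[j].isdigit():
                digits += text[j]
                j += 1
            if digits:
                count = int(digits)
            else:
                count = 1
                while j < len(text) and text[j] == ch:
                    count += 1
                    j += 1
            prim = ("charge", sign * count)
            i = j
        elif ch in AROMATIC_SYMBOLS:
            # two-letter aromatic (se, as) unsupported; single letters only
            prim = ("elem_arom", AROMATIC_SYMBOLS[ch])
            i += 1
        elif ch.isupper():
            two = text[i : i + 2]
            z = None
            if len(two) == 2 and two[1].islower() and two not in ("Db",):
                try:
                    z = elements.atomic_number(two)
                    i += 2
                except KeyError:
                    z = None
            if z is None:
                try:
                    z = elements.atomic_number(ch)
                except KeyError:
                    raise SmartsError(f"unsupported primitive {ch!r}", i) from None
                i += 1
            prim = ("elem_aliph", z)
        else:
            raise SmartsError(f"unsupported primitive {ch!r}", i)
        tokens.append((negate, *prim))
        negate = False
    raise SmartsError("unclosed bracket", start - 1)


def read_smarts(text: str) -> QueryGraph:
    """Parse a SMARTS pattern into a query graph."""
    if not text or not text.strip():
        raise SmartsError("empty SMARTS string")
    s = text.strip()
    query = Molecule(s)
    prev: ObjectHandle | None = None
    pending_bond: str | None = None
    stack: list[ObjectHandle | None] = []
    rings: dict[int, tuple[ObjectHandle, str | None, int]] = {}

    def new_atom(pred: list) -> ObjectHandle:
        atom = query.create(ATOM)
        atom.set_a("pred", pred)
        return atom

    def attach(atom: ObjectHandle) -> None:
        nonlocal prev, pending_bond
        if prev is not None:
            _add_query_bond(query, prev, atom, pending_bond)
        prev = atom
        pending_bond = None

    i = 0
    while i < len(s):
        ch = s[i]
        if ch == "[":
            pred, i = _parse_bracket(s, i + 1)
            attach(new_atom(pred))
        elif ch == "*":
            attach(new_atom([[(False, "any", None)]]))
            i += 1
        elif ch in AROMATIC_SYMBOLS:
            attach(new_atom([[(False, "elem_arom", AROMATIC_SYMBOLS[ch])]]))
            i += 1
        elif ch.isupper():
            two = s[i : i + 2]
            if two in ("Cl", "Br"):
                z = elements.atomic_number(two)
                i += 2
            else:
                try:
                    z = elements.atomic_number(ch)
                except KeyError:
                    raise SmartsError(f"unsupported token {ch!r}", i) from None
                i += 1
            attach(new_atom([[(False, "elem_aliph", z)]]))
        elif ch in _BOND_PRIMS:
            pending_bond = _BOND_PRIMS[ch]
            i += 1
        elif ch.isdigit() or ch == "%":
            if prev is None:
                raise SmartsError("ring label before any atom", i)
            if ch == "%":
                j = i + 1
                digits = ""
                while j < len(s) and s[j].isdigit():
                    digits += s[j]
                    j += 1
                if len(digits) < 2:
                    raise SmartsError("'%' ring label needs two digits", i)
                label = int(digits)
                i = j
            else:
                label = int(ch)
                i += 1
            if label in rings:
                other, bond_o, _pos = rings.pop(label)
                _add_query_bond(query, prev, other,
                                pending_bond if pending_bond else bond_o)
                pending_bond = None
            else:
                rings[label] = (prev, pending_bond, i)
                pending_bond = None
        elif ch == "(":
            stack.append(prev)
            i += 1
        elif ch == ")":
            if not stack:
                raise SmartsError("unbalanced ')'", i)
            prev = stack.pop()
            i += 1
        else:
            raise SmartsError(f"unsupported token {ch!r}", i)
    if rings:
        label, (_a, _b, pos) = sorted(rings.items())[0]
        raise SmartsError(f"unclosed ring digit {label}", pos)
    if stack:
        raise SmartsError("unclosed '('")
    return query


def _add_query_bond(query: Molecule, a: ObjectHandle, b: ObjectHandle,
                    pred: str | None) -> None:
    bond = query.create(BOND)
    bond.relate(a)
    bond.relate(b)
    bond.set_a("pred", pred or "default")
    a.relate(b)


# ---------------------------------------------------------------------------
# matching


def _ring_membership(mol: Molecule) -> set[int]:
    """Atoms that lie on at least one cycle (iterated leaf stripping)."""
    degree = {a.index: len(a.related(ATOM)) for a in mol.atoms}
    nbrs = {a.index: list({n.index for n in a.related(ATOM)}) for a in mol.atoms}
    queue = [i for i, d in degree.items() if d <= 1]
    alive = {i: d for i, d in degree.items()}
    while queue:
        i = queue.pop()
        if alive[i] == 0:
            continue
        alive[i] = 0
        for j in nbrs[i]:
            if alive[j] > 0:
                alive[j] -= 1
                if alive[j] == 1:
                    queue.append(j)
    return {i for i, d in alive.items() if d >= 2}


class _TargetData:
    """Cached per-atom facts about the molecule being searched."""

    def __init__(self, mol: Molecule) -> None:
        self.mol = mol
        self.element = [a.get_i("element") for a in mol.atoms]
        self.charge = [a.find_i("fcharge")[1] or 0 for a in mol.atoms]
        self.nbrs: dict[int, dict[int, int]] = {a.index: {} for a in mol.atoms}
        arom_flag = [a.find_i("arom")[1] or 0 for a in mol.atoms]
        for bond in mol.objects(BOND):
            atoms = bond.related(ATOM)
            if len(atoms) != 2:
                continue
            order = bond.find_i("order")[1] or 1
            i, j = atoms[0].index, atoms[1].index
            self.nbrs[i][j] = order
            self.nbrs[j][i] = order
            if order == AROMATIC_ORDER:
                arom_flag[i] = arom_flag[j] = 1
        self.arom = arom_flag
        self.degree = [len(self.nbrs[a.index]) for a in mol.atoms]
        self.in_ring = _ring_membership(mol)


def _prim_holds(prim, data: _TargetData, i: int) -> bool:
    neg, kind, value = prim
    if kind == "any":
        ok = True
    elif kind == "anum":
        ok = data.element[i] == value
    elif kind == "elem_aliph":
        ok = data.element[i] == value and not data.arom[i]
    elif kind == "elem_arom":
        ok = data.element[i] == value and bool(data.arom[i])
    elif kind == "arom":
        ok = bool(data.arom[i])
    elif kind == "aliph":
        ok = not data.arom[i]
    elif kind == "charge":
        ok = data.charge[i] == value
    elif kind == "degree":
        ok = data.degree[i] == value
    elif kind == "ring":
        ok = i in data.in_ring
    else:  # pragma: no cover - parser guarantees known kinds
        raise SmartsError(f"unknown primitive kind {kind!r}")
    return not ok if neg else ok


def atom_predicate_holds(pred, data: _TargetData, i: int) -> bool:
    return any(all(_prim_holds(p, data, i) for p in conj) for conj in pred)


def bond_predicate_holds(pred: str, order: int) -> bool:
    if pred == "any":
        return True
    if pred == "default":
        return order in (1, AROMATIC_ORDER)
    return {"single": 1, "double": 2, "triple": 3,
            "aromatic": AROMATIC_ORDER}[pred] == order


def match_smarts(query: QueryGraph, mol: Molecule) -> list[tuple[int, ...]]:
    """All subgraph monomorphisms of ``query`` into ``mol``.

    Returns 0-based atom-index tuples (one per query atom), sorted
    lexicographically; symmetric duplicates are retained.
    """
    nq = query.natoms
    if nq == 0 or mol.natoms == 0:
        return []
    data = _TargetData(mol)
    preds = [query.handle(ATOM, k).get_a("pred") for k in range(nq)]
    qbonds: dict[int, list[tuple[int, str]]] = {k: [] for k in range(nq)}
    for bond in query.objects(BOND):
        atoms = bond.related(ATOM)
        bp = bond.get_a("pred")
        a, b = atoms[0].index, atoms[1].index
        qbonds[a].append((b, bp))
        qbonds[b].append((a, bp))

    results: list[tuple[int, ...]] = []
    mapping: list[int] = []
    used: set[int] = set()

    def ok(k: int, i: int) -> bool:
        if i in used or not atom_predicate_holds(preds[k], data, i):
            return False
        for other_q, bp in qbonds[k]:
            if other_q < k:
                j = mapping[other_q]
                order = data.nbrs[i].get(j)
                if order is None or not bond_predicate_holds(bp, order):
                    return False
        return True

    def backtrack(k: int) -> None:
        if k == nq:
            results.append(tuple(mapping))
            return
        for i in range(mol.natoms):
            if ok(k, i):
                mapping.append(i)
                used.add(i)
                backtrack(k + 1)
                mapping.pop()
                used.remove(i)

    backtrack(0)
    results.sort()
    return results
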