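"""Independent oracles used by the test suite.

Everything here is deliberately naive — plain double loops and a separate
text parser — so that it exercises none of the library code paths it
checks.
"""

from __future__ import annotations

import math


# ---------------------------------------------------------------------------
# base-40 positional encoding (independent of relmol.hashkeys)


def base40_encode(name: str) -> int:
    digits = []
    for ch in name:
        if ch.islower():
            digits.append(ord(ch) - ord("a"))
        elif ch.isupper():
            digits.append(ord(ch) - ord("A"))
        elif ch.isdigit():
            digits.append(int(ch))
        elif ch == "_":
            digits.append(36)
    value = 0
    for d in digits:
        value = 40 * value + d
    return value


# ---------------------------------------------------------------------------
# naive mask interpreter over a plain-data molecule description


def eval_mask_ast(ast, atoms, residues):
    """Evaluate a mask AST over plain data.

    ``ast`` is nested tuples: ("atom", items) / ("resd", items) /
    ("and"|"or", a, b) / ("not", a) / ("dist", core, op, gran, r).
    ``atoms``: list of dicts {name, pos}; ``residues``: list of
    (name, [atom indices]).
    """
    kind = ast[0]
    n = len(atoms)
    if kind == "atom":
        out = set()
        for item in ast[1]:
            if isinstance(item, int):
                out.add(item - 1)
            elif isinstance(item, tuple):
                out.update(range(item[0] - 1, item[1]))
            else:
                for i, a in enumerate(atoms):
                    if _match_name(item, a["name"]):
                        out.add(i)
        return out
    if kind == "resd":
        out = set()
        for item in ast[1]:
            if isinstance(item, int):
                out.update(residues[item - 1][1])
            elif isinstance(item, tuple):
                for r in range(item[0] - 1, item[1]):
                    out.update(residues[r][1])
            else:
                for rname, members in residues:
                    if _match_name(item, rname):
                        out.update(members)
        return out
    if kind == "not":
        return set(range(n)) - eval_mask_ast(ast[1], atoms, residues)
    if kind == "and":
        return (eval_mask_ast(ast[1], atoms, residues)
                & eval_mask_ast(ast[2], atoms, residues))
    if kind == "or":
        return (eval_mask_ast(ast[1], atoms, residues)
                | eval_mask_ast(ast[2], atoms, residues))
    if kind == "dist":
        _k, core_ast, op, gran, r = ast
        core = eval_mask_ast(core_ast, atoms, residues)
        within = set()
        for i, a in enumerate(atoms):
            best = None
            for c in core:
                d = _dist(a["pos"], atoms[c]["pos"])
                if best is None or d < best:
                    best = d
            if best is not None and best <= r + 1e-12:
                within.add(i)
        if gran == "resd":
            sel = set()
            for _rname, members in residues:
                if any(m in within for m in members):
                    sel.update(members)
            within = sel
        if op == ">":
            return set(range(n)) - within
        return within
    raise ValueError(kind)


def _match_name(pattern, name):
    if pattern.endswith("*"):
        return name.startswith(pattern[:-1])
    return name == pattern


def _dist(p, q):
    return math.sqrt(sum((a - b) ** 2 for a, b in zip(p, q)))


def render_mask_ast(ast) -> str:
    kind = ast[0]
    if kind in ("atom", "resd"):
        sym = "@" if kind == "atom" else ":"
        parts = []
        for item in ast[1]:
            if isinstance(item, tuple):
                parts.append(f"{item[0]}-{item[1]}")
            else:
                parts.append(str(item))
        return sym + ",".join(parts)
    if kind == "not":
        return "(!(" + render_mask_ast(ast[1]) + "))"
    if kind in ("and", "or"):
        op = "&" if kind == "and" else "|"
        return ("(" + render_mask_ast(ast[1]) + op
                + render_mask_ast(ast[2]) + ")")
    if kind == "dist":
        _k, core, op, gran, r = ast
        sym = "@" if gran == "atom" else ":"
        return "(" + render_mask_ast(core) + f" {op} {sym}{r}" + ")"
    raise ValueError(kind)


# ---------------------------------------------------------------------------
# independent prmtop parser + AMBER energy evaluator


def parse_prmtop(text: str) -> dict:
    sections: dict[str, list[str]] = {}
    current = None
    for line in text.splitlines():
        if line.startswith("%FLAG"):
            current = line.split()[1]
            sections[current] = []
        elif line.startswith("%") or current is None:
            continue
        else:
            sections[current].append(line)
    out = {}
    for key, lines in sections.items():
        joined = " ".join(lines).split()
        if key in ("TITLE", "RADIUS_SET", "TREE_CHAIN_CLASSIFICATION",
                   "ATOM_NAME", "RESIDUE_LABEL", "AMBER_ATOM_TYPE"):
            out[key] = joined
        else:
            try:
                out[key] = [int(tok) for tok in joined]
            except ValueError:
                out[key] = [float(tok) for tok in joined]
    return out


def prmtop_energies(text: str, coords) -> dict:
    """Bond/angle/dihedral/elec/vdw energies straight from a prmtop.

    ``coords`` is an (n, 3) sequence.  Charges in the file are in prmtop
    units (q * 18.2223...), so q_i q_j / r is already kcal/mol.  1-4 pairs
    are taken from dihedral entries with a non-negative third index, with
    the per-term SCEE/SCNB dividers.
    """
    top = parse_prmtop(text)
    q = top["CHARGE"]
    scee = top.get("SCEE_SCALE_FACTOR", [])
    scnb = top.get("SCNB_SCALE_FACTOR", [])
    ntypes = top["POINTERS"][1]
    tidx = top["ATOM_TYPE_INDEX"]
    ico = top["NONBONDED_PARM_INDEX"]
    acoef = top["LENNARD_JONES_ACOEF"]
    bcoef = top["LENNARD_JONES_BCOEF"]

    def r(i, j):
        return _dist(coords[i], coords[j])

    e_bond = 0.0
    for lst in (top["BONDS_INC_HYDROGEN"], top["BONDS_WITHOUT_HYDROGEN"]):
        for k in range(0, len(lst), 3):
            i, j, t = lst[k] // 3, lst[k + 1] // 3, lst[k + 2] - 1
            e_bond += top["BOND_FORCE_CONSTANT"][t] * (
                r(i, j) - top["BOND_EQUIL_VALUE"][t]) ** 2
    e_angle = 0.0
    for lst in (top["ANGLES_INC_HYDROGEN"], top["ANGLES_WITHOUT_HYDROGEN"]):
        for k in range(0, len(lst), 4):
            i, j, l, t = (lst[k] // 3, lst[k + 1] // 3, lst[k + 2] // 3,
                          lst[k + 3] - 1)
            th = _angle(coords[i], coords[j], coords[l])
            e_angle += top["ANGLE_FORCE_CONSTANT"][t] * (
                th - top["ANGLE_EQUIL_VALUE"][t]) ** 2
    e_dih = 0.0
    e_elec14 = 0.0
    e_vdw14 = 0.0
    for lst in (top["DIHEDRALS_INC_HYDROGEN"],
                top["DIHEDRALS_WITHOUT_HYDROGEN"]):
        for k in range(0, len(lst), 5):
            i3, j3, k3, l3, t = lst[k : k + 5]
            i, j, kk, ll = abs(i3) // 3, abs(j3) // 3, abs(k3) // 3, abs(l3) // 3
            phi = _dihedral(coords[i], coords[j], coords[kk], coords[ll])
            t0 = t - 1
            e_dih += top["DIHEDRAL_FORCE_CONSTANT"][t0] * (
                1.0 + math.cos(top["DIHEDRAL_PERIODICITY"][t0] * phi
                               - top["DIHEDRAL_PHASE"][t0]))
            if k3 >= 0 and l3 >= 0:
                rij = r(i, ll)
                e_elec14 += q[i] * q[ll] / rij / (scee[t0] if scee else 1.2)
                a_, b_ = _lj(tidx, ico, acoef, bcoef, ntypes, i, ll)
                e_vdw14 += (a_ / rij**12 - b_ / rij**6) / (
                    scnb[t0] if scnb else 2.0)
    # nonbonded with the exclusion list
    n = top["POINTERS"][0]
    excluded = set()
    cursor = 0
    for i in range(n):
        cnt = top["NUMBER_EXCLUDED_ATOMS"][i]
        for m in range(cnt):
            j = top["EXCLUDED_ATOMS_LIST"][cursor + m]
            if j > 0:
                excluded.add((i, j - 1))
        cursor += cnt
    e_elec = 0.0
    e_vdw = 0.0
    for i in range(n):
        for j in range(i + 1, n):
            if (i, j) in excluded:
                continue
            rij = r(i, j)
            e_elec += q[i] * q[j] / rij
            a_, b_ = _lj(tidx, ico, acoef, bcoef, ntypes, i, j)
            e_vdw += a_ / rij**12 - b_ / rij**6
    return {
        "bond": e_bond,
        "angle": e_angle,
        "dihedral": e_dih,
        "elec": e_elec + e_elec14,
        "vdw": e_vdw + e_vdw14,
    }


def _lj(tidx, ico, acoef, bcoef, ntypes, i, j):
    ti, tj = tidx[i], tidx[j]
    idx = ico[ntypes * (ti - 1) + tj - 1]
    return acoef[idx - 1], bcoef[idx - 1]


def _angle(p1, p2, p3):
    v1 = [a - b for a, b in zip(p1, p2)]
    v2 = [a - b for a, b in zip(p3, p2)]
    dot = sum(a * b for a, b in zip(v1, v2))
    n1 = math.sqrt(sum(a * a for a in v1))
    n2 = math.sqrt(sum(a * a for a in v2))
    return math.acos(max(-1.0, min(1.0, dot / (n1 * n2))))


def _cross(u, v):
    return [u[1] * v[2] - u[2] * v[1],
            u[2] * v[0] - u[0] * v[2],
            u[0] * v[1] - u[1] * v[0]]


def _dihedral(p1, p2, p3, p4):
    b1 = [a - b for a, b in zip(p2, p1)]
    b2 = [a - b for a, b in zip(p3, p2)]
    b3 = [a - b for a, b in zip(p4, p3)]
    n1 = _cross(b1, b2)
    n2 = _cross(b2, b3)
    nb2 = math.sqrt(sum(a * a for a in b2))
    m1 = _cross(n1, [a / nb2 for a in b2])
    x = sum(a * b for a, b in zip(n1, n2))
    y = sum(a * b for a, b in zip(m1, n2))
    return math.atan2(y, x)
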