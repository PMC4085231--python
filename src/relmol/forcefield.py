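"""AMBER-style force-field parameter files.

``read_frc`` parses the section-labelled dialect (MASS / BOND / ANGLE /
DIHE / IMPROPER / NONBON, the frcmod layout; plain parm.dat files that use
the same section keywords parse identically).  Torsions may span several
Fourier terms: a negative periodicity on one line announces a continuation
line for the same atom-type quartet.  A second file read with
``read_frc(stream, into=ff)`` overlays the first, replacing matching keys —
the frcmod convention.

Keys are canonicalised so that (a, b) and (b, a) bonds, (a, b, c) and
(c, b, a) angles, and a torsion quartet and its reverse are the same entry.
The wildcard type ``X`` matches any type; lookups prefer the most specific
(fewest-wildcard) match.
"""

from __future__ import annotations

from dataclasses import dataclass, field

__all__ = ["ForceField", "read_frc", "MissingParameterError", "TorsionTerm"]

WILDCARD = "X"


class MissingParameterError(KeyError):
    def __init__(self, kind: str, types: tuple) -> None:
        super().__init__(f"no {kind} parameter for atom types {'-'.join(types)}")
        self.kind = kind
        self.types = types


@dataclass(frozen=True)
class TorsionTerm:
    """One Fourier term: E = (pk / idivf) * (1 + cos(pn * phi - phase))."""

    pk: float        # barrier / 2, kcal/mol
    phase: float     # radians
    pn: int          # periodicity
    idivf: int = 1   # divider over equivalent paths


def _canon_bond(t1: str, t2: str) -> tuple:
    return tuple(min((t1, t2), (t2, t1)))


def _canon_angle(t1: str, t2: str, t3: str) -> tuple:
    return min((t1, t2, t3), (t3, t2, t1))


def _canon_torsion(ts: tuple) -> tuple:
    return min(ts, tuple(reversed(ts)))


@dataclass
class ForceField:
    masses: dict = field(default_factory=dict)          # type -> amu
    bond_params: dict = field(default_factory=dict)     # (t1,t2) -> (k, r0)
    angle_params: dict = field(default_factory=dict)    # (t1,t2,t3) -> (k, th0 rad)
    torsion_params: dict = field(default_factory=dict)  # quartet -> [TorsionTerm]
    improper_params: dict = field(default_factory=dict)
    vdw_params: dict = field(default_factory=dict)      # type -> (rmin/2, eps)

    # -- lookups ----------------------------------------------------------
    def mass(self, t: str) -> float:
        try:
            return self.masses[t]
        except KeyError:
            raise MissingParameterError("mass", (t,)) from None

    def bond(self, t1: str, t2: str) -> tuple:
        try:
            return self.bond_params[_canon_bond(t1, t2)]
        except KeyError:
            raise MissingParameterError("bond", (t1, t2)) from None

    def angle(self, t1: str, t2: str, t3: str) -> tuple:
        try:
            return self.angle_params[_canon_angle(t1, t2, t3)]
        except KeyError:
            raise MissingParameterError("angle", (t1, t2, t3)) from None

    def vdw(self, t: str) -> tuple:
        try:
            return self.vdw_params[t]
        except KeyError:
            raise MissingParameterError("vdW", (t,)) from None

    @staticmethod
    def _match(key: tuple, pattern: tuple) -> int:
        """Specificity of a wildcard match (-1: no match)."""
        score = 0
        for k, p in zip(key, pattern):
            if p == WILDCARD:
                continue
            if p != k:
                return -1
            score += 1
        return score

    def _wildcard_lookup(self, table: dict, key: tuple, kind: str):
        exact = table.get(_canon_torsion(key))
        if exact is not None:
            return exact
        best, best_score = None, -1
        for pattern, value in table.items():
            for cand in (pattern, tuple(reversed(pattern))):
                score = self._match(key, cand)
                if score > best_score:
                    best, best_score = value, score
        if best is None:
            raise MissingParameterError(kind, key)
        return best

    def torsion(self, t1: str, t2: str, t3: str, t4: str) -> list:
        return self._wildcard_lookup(self.torsion_params, (t1, t2, t3, t4),
                                     "torsion")

    def improper(self, t1: str, t2: str, center: str, t4: str) -> list:
        """Improper lookup: the centre type is third; the outer three match
        in any order (wildcards allowed)."""
        key = (t1, t2, center, t4)
        exact = self.improper_params.get(key)
        if exact is not None:
            return exact
        best, best_score = None, -1
        outer = (t1, t2, t4)
        import itertools

        for pattern, value in self.improper_params.items():
            if pattern[2] != center and pattern[2] != WILDCARD:
                continue
            pouter = (pattern[0], pattern[1], pattern[3])
            for perm in itertools.permutations(outer):
                score = self._match(perm, pouter)
                if score >= 0 and pattern[2] == center:
                    score += 1
                if score > best_score:
                    best, best_score = value, score
        if best is None:
            raise MissingParameterError("improper", key)
        return best


# ---------------------------------------------------------------------------
# parsing

_SECTION_KEYWORDS = {
    "MASS": "mass",
    "BOND": "bond",
    "ANGL": "angle",
    "ANGLE": "angle",
    "DIHE": "torsion",
    "DIHEDRAL": "torsion",
    "IMPROPER": "improper",
    "IMPR": "improper",
    "NONB": "vdw",
    "NONBON": "vdw",
}


def _split_types_and_numbers(line: str, ntypes: int, lineno: int, section: str):
    """Split a parameter line into its dash-separated type field and floats."""
    from .formats import ParseError

    # the type field is everything before the first standalone numeric token
    tokens = line.split()
    type_tokens = []
    rest_start = None
    joined = ""
    for k, tok in enumerate(tokens):
        probe = (joined + tok).replace(" ", "")
        if _count_types(probe) >= ntypes:
            type_tokens.append(tok)
            joined = probe
            rest_start = k + 1
            break
        type_tokens.append(tok)
        joined = probe
    if rest_start is None:
        raise ParseError(f"[{section}] cannot find {ntypes} atom types in "
                         f"{line!r}", lineno)
    types = tuple(t for t in joined.split("-") if t)
    if len(types) != ntypes:
        raise ParseError(f"[{section}] expected {ntypes} atom types in "
                         f"{line!r}, found {len(types)}", lineno)
    numbers = []
    for tok in tokens[rest_start:]:
        try:
            numbers.append(float(tok))
        except ValueError:
            break  # trailing comment
    return types, numbers


def _count_types(joined: str) -> int:
    return len([t for t in joined.split("-") if t])


def read_frc(stream, into: ForceField | None = None) -> ForceField:
    """Parse an AMBER parameter / frcmod stream into a :class:`ForceField`.

    With ``into`` given, entries overlay the existing tables (frcmod rule).
    """
    from .formats import ParseError

    text = stream if isinstance(stream, str) else stream.read()
    ff = into if into is not None else ForceField()
    section = None
    pending_torsion: tuple | None = None
    for lineno, raw in enumerate(text.splitlines(), start=1):
        line = raw.rstrip()
        stripped = line.strip()
        if not stripped:
            section = None if section == "title" else section
            continue
        word = stripped.split()[0].upper()
        if word in _SECTION_KEYWORDS and len(stripped.split()) == 1:
            section = _SECTION_KEYWORDS[word]
            pending_torsion = None
            continue
        if word == "END":
            break
        if section is None:
            section = "title"  # leading title / remark lines
            continue
        if section == "title":
            continue
        try:
            if section == "mass":
                types, nums = _split_types_and_numbers(line, 1, lineno, "MASS")
                if not nums:
                    raise ParseError(f"[MASS] missing mass value in {line!r}",
                                     lineno)
                ff.masses[types[0]] = nums[0]
            elif section == "bond":
                types, nums = _split_types_and_numbers(line, 2, lineno, "BOND")
                if len(nums) < 2:
                    raise ParseError(f"[BOND] need k and r0 in {line!r}", lineno)
                ff.bond_params[_canon_bond(*types)] = (nums[0], nums[1])
            elif section == "angle":
                types, nums = _split_types_and_numbers(line, 3, lineno, "ANGLE")
                if len(nums) < 2:
                    raise ParseError(f"[ANGLE] need k and theta0 in {line!r}",
                                     lineno)
                import math

                ff.angle_params[_canon_angle(*types)] = (
                    nums[0], math.radians(nums[1]))
            elif section == "torsion":
                types, nums = _split_types_and_numbers(line, 4, lineno, "DIHE")
                if len(nums) < 4:
                    raise ParseError(f"[DIHE] need idivf, pk, phase, pn in "
                                     f"{line!r}", lineno)
                import math

                key = _canon_torsion(types)
                term = TorsionTerm(pk=nums[1], phase=math.radians(nums[2]),
                                   pn=abs(int(round(nums[3]))),
                                   idivf=max(1, int(round(nums[0]))))
                if pending_torsion == key:
                    ff.torsion_params[key].append(term)
                else:
                    ff.torsion_params[key] = [term]
                pending_torsion = key if nums[3] < 0 else None
            elif section == "improper":
                types, nums = _split_types_and_numbers(line, 4, lineno,
                                                       "IMPROPER")
                if len(nums) < 3:
                    raise ParseError(f"[IMPROPER] need pk, phase, pn in "
                                     f"{line!r}", lineno)
                import math

                term = TorsionTerm(pk=nums[0], phase=math.radians(nums[1]),
                                   pn=abs(int(round(nums[2]))), idivf=1)
                ff.improper_params[types] = [term]
            elif section == "vdw":
                stripped_tokens = stripped.split()
                if stripped_tokens[0].upper() in ("MOD4", "RE"):
                    stripped_tokens = stripped_tokens[1:]
                if not stripped_tokens:
                    continue
                t = stripped_tokens[0]
                try:
                    rmin2 = float(stripped_tokens[1])
                    eps = float(stripped_tokens[2])
                except (IndexError, ValueError):
                    raise ParseError(f"[NONBON] need rmin/2 and epsilon in "
                                     f"{line!r}", lineno) from None
                ff.vdw_params[t] = (rmin2, eps)
        except ParseError:
            raise
        except ValueError as exc:
            raise ParseError(f"[{section}] {exc}", lineno) from None
    return ff
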