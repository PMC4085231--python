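"""Base-40 positional name encoding and molecular-object type codes.

Every property and object-type name in the relational store is keyed by a
64-bit integer rather than by string comparison.  The encoding walks the
name left to right: a lowercase letter contributes its position from ``a``
(``a`` = 0), an uppercase letter its position from ``A`` (``A`` = 0), a
digit its own value, and an underscore 36; any other character is skipped.
After each admissible character the running sum is multiplied by 40 and the
character value added.  Names are limited to 10 admissible characters so the
code always fits a signed 64-bit integer (40**10 < 2**63).
"""

from __future__ import annotations

from dataclasses import dataclass

__all__ = [
    "encode_name",
    "as_key",
    "TypeCode",
    "register_type",
    "registered_types",
    "find_type",
    "ATOM",
    "BOND",
    "RESD",
    "ANGL",
    "TORS",
    "OOPS",
    "TOR2",
    "PTOR",
    "MAX_NAME_CHARS",
]

MAX_NAME_CHARS = 10

_UNDERSCORE_VALUE = 36


def _char_value(ch: str) -> int | None:
    if "a" <= ch <= "z":
        return ord(ch) - ord("a")
    if "A" <= ch <= "Z":
        return ord(ch) - ord("A")
    if "0" <= ch <= "9":
        return ord(ch) - ord("0")
    if ch == "_":
        return _UNDERSCORE_VALUE
    return None


def encode_name(name: str) -> int:
    """Encode ``name`` as a base-40 positional integer key.

    Non-admissible characters (anything other than letters, digits and the
    underscore) are skipped.  Raises ``ValueError`` if no admissible
    character remains or if more than 10 admissible characters are present.
    """
    total = 0
    count = 0
    for ch in name:
        v = _char_value(ch)
        if v is None:
            continue
        count += 1
        if count > MAX_NAME_CHARS:
            raise ValueError(
                f"name {name!r} has more than {MAX_NAME_CHARS} admissible "
                "characters; longer names risk 64-bit overflow"
            )
        total = total * 40 + v
    if count == 0:
        raise ValueError(f"name {name!r} contains no admissible characters")
    return total


def as_key(name_or_key: "str | int") -> int:
    """Accept either a property name or an already-encoded integer key."""
    if isinstance(name_or_key, int):
        return name_or_key
    return encode_name(name_or_key)


@dataclass(frozen=True)
class TypeCode:
    """A registered molecular-object type: a 4-character code plus its key."""

    code: str
    key: int

    def __repr__(self) -> str:  # pragma: no cover - cosmetic
        return f"TypeCode({self.code!r})"


_REGISTRY: dict[str, TypeCode] = {}


def register_type(code: str) -> TypeCode:
    """Register (or fetch) a molecular-object type by its 4-character code.

    Registration is idempotent.  A key collision with a differently named
    registered type is rejected, keeping the code -> key map injective.
    """
    if len(code) != 4:
        raise ValueError(f"type code must be exactly 4 characters, got {code!r}")
    existing = _REGISTRY.get(code)
    if existing is not None:
        return existing
    key = encode_name(code)
    for tc in _REGISTRY.values():
        if tc.key == key:
            raise ValueError(f"type code {code!r} collides with {tc.code!r}")
    tc = TypeCode(code, key)
    _REGISTRY[code] = tc
    return tc


def registered_types() -> tuple[TypeCode, ...]:
    return tuple(_REGISTRY.values())


def find_type(code: str) -> TypeCode:
    try:
        return _REGISTRY[code]
    except KeyError:
        raise KeyError(f"unregistered molecular-object type {code!r}") from None


# The eight built-in molecular-object types.  tor2 (torsion-torsion) and
# ptor (pi-torsion) are registered for extensibility; no energy terms are
# evaluated for them here.
ATOM = register_type("atom")
BOND = register_type("bond")
RESD = register_type("resd")
ANGL = register_type("angl")
TORS = register_type("tors")
OOPS = register_type("oops")
TOR2 = register_type("tor2")
PTOR = register_type("ptor")
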