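"""The relational molecule store.

A :class:`Molecule` owns every kind of molecular object (MO) directly —
atoms, bonds, residues, angles, torsions, impropers — with no nesting: a
residue never *contains* atoms, it merely has relations to them.  Properties
live in per-type columnar :class:`ComponentTable`\\ s (one flat array per
property, numeric-vector properties flattened into a single 1-D array), and
relations live in :class:`AdjacencyTable`\\ s keyed by an ordered pair of
object types.  :class:`ObjectHandle` is a lightweight ``(molecule, type,
index)`` reference that carries no data of its own; all reading, mutation
and traversal goes through it.

Property kinds follow the five-letter convention: ``i`` (integer), ``d``
(double/real), ``s`` (string), ``v`` (numeric vector, fixed width per
column) and ``a`` (any opaque Python object; excluded from file formats).
"""

from __future__ import annotations

from collections.abc import Iterator, Sequence

import numpy as np

from .hashkeys import (
    ANGL,
    ATOM,
    BOND,
    OOPS,
    PTOR,
    RESD,
    TOR2,
    TORS,
    TypeCode,
    as_key,
    encode_name,
)

__all__ = [
    "ComponentTable",
    "AdjacencyTable",
    "Molecule",
    "ObjectHandle",
    "MoRange",
    "MoleculeDatabase",
    "MissingPropertyError",
    "StaleHandleError",
]

#: object types whose definition depends on their member atoms; deleting an
#: atom cascade-deletes these.
CASCADE_TYPES = (BOND, ANGL, TORS, OOPS, TOR2, PTOR)

KINDS = ("i", "d", "s", "v", "a")

_DEFAULTS = {"i": 0, "d": 0.0, "s": "", "a": None}


class MissingPropertyError(KeyError):
    """Raised by the single-result property getters for absent keys."""


class StaleHandleError(IndexError):
    """Raised when dereferencing a handle whose index is out of range."""


class ComponentTable:
    """Columnar property storage for one molecular-object type."""

    __slots__ = ("n", "cols", "vec_width", "key_names")

    def __init__(self) -> None:
        self.n = 0
        # cols[kind][key] -> list (for "v": flat list of floats)
        self.cols: dict[str, dict[int, list]] = {k: {} for k in KINDS}
        self.vec_width: dict[int, int] = {}
        self.key_names: dict[int, str] = {}

    # -- structure -------------------------------------------------------
    def add_object(self) -> int:
        idx = self.n
        self.n += 1
        for kind in ("i", "d", "s", "a"):
            for col in self.cols[kind].values():
                col.append(_DEFAULTS[kind])
        for key, col in self.cols["v"].items():
            col.extend([0.0] * self.vec_width[key])
        return idx

    def remove_object(self, idx: int) -> None:
        for kind in ("i", "d", "s", "a"):
            for col in self.cols[kind].values():
                del col[idx]
        for key, col in self.cols["v"].items():
            w = self.vec_width[key]
            del col[idx * w : (idx + 1) * w]
        self.n -= 1

    def ensure_column(self, kind: str, key: int, width: int | None = None,
                      name: str | None = None) -> list:
        if kind not in KINDS:
            raise ValueError(f"unknown property kind {kind!r}")
        table = self.cols[kind]
        col = table.get(key)
        if col is None:
            for other in KINDS:
                if other != kind and key in self.cols[other]:
                    raise TypeError(
                        f"property key {self.key_names.get(key, key)!r} already "
                        f"exists with kind {other!r}, requested {kind!r}"
                    )
            if kind == "v":
                if width is None:
                    raise ValueError("vector column needs a width")
                self.vec_width[key] = width
                col = [0.0] * (self.n * width)
            else:
                col = [_DEFAULTS[kind]] * self.n
            table[key] = col
            if name is not None:
                self.key_names[key] = name
        elif kind == "v" and width is not None and width != self.vec_width[key]:
            raise ValueError(
                f"vector column width mismatch: column has {self.vec_width[key]}, "
                f"value has {width}"
            )
        return col

    def has_column(self, kind: str, key: int) -> bool:
        return key in self.cols[kind]


class AdjacencyTable:
    """Per-source ordered lists of related target-object indices."""

    __slots__ = ("source_type", "target_type", "rows")

    def __init__(self, source_type: TypeCode, target_type: TypeCode, n_source: int) -> None:
        self.source_type = source_type
        self.target_type = target_type
        self.rows: list[list[int]] = [[] for _ in range(n_source)]

    def add(self, src: int, tgt: int) -> None:
        row = self.rows[src]
        if tgt not in row:
            row.append(tgt)

    def add_source(self) -> None:
        self.rows.append([])

    def remove_source(self, idx: int) -> None:
        del self.rows[idx]

    def remove_target(self, idx: int) -> None:
        for row in self.rows:
            kept = [j for j in row if j != idx]
            if len(kept) != len(row):
                row[:] = kept
            for k, j in enumerate(row):
                if j > idx:
                    row[k] = j - 1


class Molecule:
    """Owner of typed component tables and adjacency tables."""

    def __init__(self, name: str = "") -> None:
        self.name = name
        self.components: dict[TypeCode, ComponentTable] = {}
        self.adjacencies: dict[tuple[TypeCode, TypeCode], AdjacencyTable] = {}
        # molecule-level properties: key -> (kind, value)
        self._props: dict[int, tuple[str, object]] = {}
        self._prop_names: dict[int, str] = {}

    # -- components ------------------------------------------------------
    def component(self, tc: TypeCode, create: bool = False) -> ComponentTable | None:
        table = self.components.get(tc)
        if table is None and create:
            table = ComponentTable()
            self.components[tc] = table
        return table

    def adjacency(self, src: TypeCode, tgt: TypeCode, create: bool = False
                  ) -> AdjacencyTable | None:
        adj = self.adjacencies.get((src, tgt))
        if adj is None and create:
            n = self.count(src)
            adj = AdjacencyTable(src, tgt, n)
            self.adjacencies[(src, tgt)] = adj
        return adj

    def count(self, tc: TypeCode) -> int:
        table = self.components.get(tc)
        return 0 if table is None else table.n

    # -- object creation / traversal -------------------------------------
    def create(self, tc: TypeCode) -> "ObjectHandle":
        if not isinstance(tc, TypeCode):
            raise TypeError(f"expected a registered TypeCode, got {tc!r}")
        table = self.component(tc, create=True)
        idx = table.add_object()
        for (s, _t), adj in self.adjacencies.items():
            if s is tc:
                adj.add_source()
        return ObjectHandle(self, tc, idx)

    def handle(self, tc: TypeCode, idx: int) -> "ObjectHandle":
        return ObjectHandle(self, tc, idx)

    def objects(self, tc: TypeCode) -> "MoRange":
        return MoRange(self, tc)

    @property
    def atoms(self) -> "MoRange":
        return MoRange(self, ATOM)

    @property
    def bonds(self) -> "MoRange":
        return MoRange(self, BOND)

    @property
    def resds(self) -> "MoRange":
        return MoRange(self, RESD)

    @property
    def natoms(self) -> int:
        return self.count(ATOM)

    @property
    def nresds(self) -> int:
        return self.count(RESD)

    # -- molecule-level properties ----------------------------------------
    def set_prop(self, kind: str, key: "str | int", value) -> None:
        if kind not in KINDS:
            raise ValueError(f"unknown property kind {kind!r}")
        k = as_key(key)
        if isinstance(key, str):
            self._prop_names[k] = key
        self._props[k] = (kind, value)

    def get_prop(self, kind: str, key: "str | int"):
        k = as_key(key)
        entry = self._props.get(k)
        if entry is None or entry[0] != kind:
            raise MissingPropertyError(f"molecule has no {kind!r} property {key!r}")
        return entry[1]

    def find_prop(self, kind: str, key: "str | int"):
        k = as_key(key)
        entry = self._props.get(k)
        if entry is None or entry[0] != kind:
            return None
        return entry[1]

    def prop_names(self, kind: str) -> list[str]:
        return [self._prop_names.get(k, str(k))
                for k, (kd, _v) in self._props.items() if kd == kind]

    # -- geometry convenience ---------------------------------------------
    def positions(self) -> np.ndarray:
        """All atom positions as an (natom, 3) array (a copy)."""
        table = self.component(ATOM)
        key = encode_name("position")
        if table is None or not table.has_column("v", key):
            return np.zeros((0, 3))
        flat = np.asarray(table.cols["v"][key], dtype=float)
        return flat.reshape(table.n, 3)

    def set_positions(self, arr: np.ndarray) -> None:
        table = self.component(ATOM, create=True)
        arr = np.asarray(arr, dtype=float)
        if arr.shape != (table.n, 3):
            raise ValueError(f"expected shape ({table.n}, 3), got {arr.shape}")
        key = encode_name("position")
        col = table.ensure_column("v", key, width=3, name="position")
        col[:] = arr.reshape(-1).tolist()

    def __repr__(self) -> str:  # pragma: no cover - cosmetic
        return (f"Molecule({self.name!r}, atoms={self.count(ATOM)}, "
                f"bonds={self.count(BOND)}, resds={self.count(RESD)})")


class ObjectHandle:
    """A ``(molecule, type, index)`` reference.  Holds no property data.

    ``index`` is the internal 0-based position; ``user_id`` is the external
    1-based number used by file formats and the mask language.
    """

    __slots__ = ("mol", "type", "index")

    def __init__(self, mol: Molecule, tc: TypeCode, index: int) -> None:
        self.mol = mol
        self.type = tc
        self.index = index

    # -- identity ---------------------------------------------------------
    @property
    def user_id(self) -> int:
        return self.index + 1

    def __eq__(self, other) -> bool:
        return (isinstance(other, ObjectHandle) and other.mol is self.mol
                and other.type is self.type and other.index == self.index)

    def __hash__(self) -> int:
        return hash((id(self.mol), self.type.code, self.index))

    def __repr__(self) -> str:  # pragma: no cover - cosmetic
        return f"<{self.type.code} #{self.user_id} of {self.mol.name!r}>"

    def _table(self) -> ComponentTable:
        table = self.mol.component(self.type)
        if table is None or self.index >= table.n or self.index < 0:
            raise StaleHandleError(
                f"stale handle: {self.type.code} index {self.index} out of range")
        return table

    # -- property access ---------------------------------------------------
    def _set(self, kind: str, key: "str | int", value, width: int | None = None) -> None:
        table = self._table()
        k = as_key(key)
        name = key if isinstance(key, str) else None
        col = table.ensure_column(kind, k, width=width, name=name)
        if kind == "v":
            w = table.vec_width[k]
            col[self.index * w : (self.index + 1) * w] = [float(x) for x in value]
        else:
            col[self.index] = value

    def _get(self, kind: str, key: "str | int"):
        table = self._table()
        k = as_key(key)
        if not table.has_column(kind, k):
            raise MissingPropertyError(
                f"{self.type.code} object has no {kind!r} property {key!r}")
        col = table.cols[kind][k]
        if kind == "v":
            w = table.vec_width[k]
            return tuple(col[self.index * w : (self.index + 1) * w])
        return col[self.index]

    def _find(self, kind: str, key: "str | int"):
        """Two-result form: returns (found, value)."""
        try:
            return True, self._get(kind, key)
        except MissingPropertyError:
            return False, None

    # the five-kind accessor family
    def set_i(self, key, value) -> None:
        self._set("i", key, int(value))

    def get_i(self, key) -> int:
        return self._get("i", key)

    def find_i(self, key):
        return self._find("i", key)

    def set_d(self, key, value) -> None:
        self._set("d", key, float(value))

    def get_d(self, key) -> float:
        return self._get("d", key)

    def find_d(self, key):
        return self._find("d", key)

    def set_s(self, key, value) -> None:
        self._set("s", key, str(value))

    def get_s(self, key) -> str:
        return self._get("s", key)

    def find_s(self, key):
        return self._find("s", key)

    def set_v(self, key, value) -> None:
        seq = [float(x) for x in value]
        self._set("v", key, seq, width=len(seq))

    def get_v(self, key) -> tuple:
        return self._get("v", key)

    def find_v(self, key):
        return self._find("v", key)

    def set_a(self, key, value) -> None:
        self._set("a", key, value)

    def get_a(self, key):
        return self._get("a", key)

    def find_a(self, key):
        return self._find("a", key)

    # -- common-property shortcuts -----------------------------------------
    @property
    def pos(self) -> np.ndarray:
        return np.asarray(self.get_v("position"), dtype=float)

    @pos.setter
    def pos(self, value) -> None:
        self.set_v("position", value)

    # -- relations ----------------------------------------------------------
    def relate(self, other: "ObjectHandle") -> None:
        """Record the relation in both directions.  Duplicate is a no-op."""
        if other.mol is not self.mol:
            raise ValueError("cannot relate objects of different molecules")
        self._table()
        other._table()
        fwd = self.mol.adjacency(self.type, other.type, create=True)
        rev = self.mol.adjacency(other.type, self.type, create=True)
        fwd.add(self.index, other.index)
        rev.add(other.index, self.index)

    def related(self, tc: TypeCode) -> "MoRange":
        self._table()
        adj = self.mol.adjacency(self.type, tc)
        indices = list(adj.rows[self.index]) if adj is not None else []
        return MoRange(self.mol, tc, indices)

    def is_related(self, other: "ObjectHandle") -> bool:
        adj = self.mol.adjacency(self.type, other.type)
        return adj is not None and other.index in adj.rows[self.index]

    # -- deletion ------------------------------------------------------------
    def delete(self) -> None:
        """Remove this object.  Deleting an atom cascade-deletes every bond,
        angle, torsion or improper that relates to it."""
        self._table()
        mol, tc, idx = self.mol, self.type, self.index
        if tc is ATOM:
            for dep in CASCADE_TYPES:
                adj = mol.adjacency(ATOM, dep)
                if adj is None:
                    continue
                for j in sorted(set(adj.rows[idx]), reverse=True):
                    _remove_object(mol, dep, j)
        _remove_object(mol, tc, idx)
        self.index = -1  # mark stale


def _remove_object(mol: Molecule, tc: TypeCode, idx: int) -> None:
    for (s, t), adj in mol.adjacencies.items():
        if s is tc and t is tc:
            adj.remove_source(idx)
            adj.remove_target(idx)
        elif s is tc:
            adj.remove_source(idx)
        elif t is tc:
            adj.remove_target(idx)
    mol.component(tc).remove_object(idx)


class MoRange(Sequence):
    """An ordered, random-access range of molecular objects.

    With ``indices=None`` it is a live view of all objects of one type
    (length tracks the component table); with an explicit index list it is a
    snapshot, as returned by :meth:`ObjectHandle.related`.
    """

    __slots__ = ("mol", "type", "indices")

    def __init__(self, mol: Molecule, tc: TypeCode,
                 indices: list[int] | None = None) -> None:
        self.mol = mol
        self.type = tc
        self.indices = indices

    def __len__(self) -> int:
        if self.indices is not None:
            return len(self.indices)
        return self.mol.count(self.type)

    def __getitem__(self, i) -> ObjectHandle:
        if isinstance(i, slice):
            idxs = (self.indices if self.indices is not None
                    else list(range(len(self))))[i]
            return MoRange(self.mol, self.type, list(idxs))
        n = len(self)
        if i < 0:
            i += n
        if not 0 <= i < n:
            raise IndexError(i)
        idx = self.indices[i] if self.indices is not None else i
        return ObjectHandle(self.mol, self.type, idx)

    def at(self, i: int) -> ObjectHandle:
        return self[i]

    def __iter__(self) -> Iterator[ObjectHandle]:
        for i in range(len(self)):
            yield self[i]


class MoleculeDatabase:
    """Named molecule store: unique names, lookup by name."""

    def __init__(self) -> None:
        self._entries: dict[str, Molecule] = {}

    def put(self, name: str, mol: Molecule) -> None:
        if not name:
            raise ValueError("molecule name must be non-empty")
        self._entries[name] = mol

    def get_mol(self, name: str) -> Molecule:
        try:
            return self._entries[name]
        except KeyError:
            raise KeyError(f"no molecule named {name!r} in database") from None

    def remove(self, name: str) -> None:
        del self._entries[name]

    def names(self) -> list[str]:
        return list(self._entries)

    def __contains__(self, name: str) -> bool:
        return name in self._entries

    def __len__(self) -> int:
        return len(self._entries)

    def __iter__(self) -> Iterator[str]:
        return iter(self._entries)
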