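"""The L4 number system: 4-bit logical codes for elementary spatial relations.

An L4 number is a 2x2 table of connection bits between two region-like
figures ("spots") *a*, *b* and their environments (complements) ``~a``,
``~b``::

    | ab   ab~ |
    | a~b  a~b~|

read row-major as a 4-character binary code, e.g. ``1101`` for "a strictly
includes b".  Sixteen codes exist; five of them name the classical
qualitative relations (intersection, separation, the two inclusions and
indiscernibility, cf. RCC-5).  On top of the scalar codes the module builds
vectors and matrices of L4 numbers — a spot is *represented on a basis* of
known spots by the vector of its relations with them — together with the
inner product for atomic (mutually separated) bases, matrix-vector
products, the indistinguishability (identity) matrix, the structural
inverse, and the chain transform that re-expresses a relation vector on a
different basis via the realized intersection cells of both bases.

Figures are taken to live on a finite pixel grid embedded in an unbounded
empty plane, so the environments of any two grid-bounded figures always
share the off-grid background: the ``a~b~`` bit of their relation is 1.
The inner product honours the same convention through an implicit
background atom.
"""

from __future__ import annotations

import enum
import json
import warnings
from dataclasses import dataclass
from typing import Iterable, Sequence

__all__ = [
    "L4Number",
    "Relation",
    "ERLabel",
    "L4Vector",
    "L4Matrix",
    "classify_er",
    "transpose_l4",
    "l4_inner_product",
    "l4_matvec_atomic",
    "indistinguishability_matrix",
    "l4_matrix_inverse",
    "basis_transform",
    "SeparatedBasesWarning",
]


@dataclass(frozen=True, order=True)
class L4Number:
    """One 4-bit logical number ``(ab, ab~, a~b, a~b~)``."""

    c11: int
    c12: int
    c21: int
    c22: int

    def __post_init__(self) -> None:
        for bit in (self.c11, self.c12, self.c21, self.c22):
            if bit not in (0, 1):
                raise ValueError(f"L4 bits must be 0 or 1, got {bit!r}")

    @classmethod
    def from_code(cls, code: str) -> "L4Number":
        """Build from a 4-character binary string such as ``"1101"``."""
        if len(code) != 4 or set(code) - {"0", "1"}:
            raise ValueError(f"not a 4-bit binary code: {code!r}")
        return cls(*(int(ch) for ch in code))

    @classmethod
    def from_int(cls, value: int) -> "L4Number":
        if not 0 <= value <= 15:
            raise ValueError("L4 numbers occupy the range 0..15")
        return cls((value >> 3) & 1, (value >> 2) & 1, (value >> 1) & 1, value & 1)

    @property
    def code(self) -> str:
        return f"{self.c11}{self.c12}{self.c21}{self.c22}"

    @property
    def hex(self) -> str:
        """Single hex digit, msb = ab."""
        return format(self.as_int(), "x")

    def as_int(self) -> int:
        return (self.c11 << 3) | (self.c12 << 2) | (self.c21 << 1) | self.c22

    def transpose(self) -> "L4Number":
        return L4Number(self.c11, self.c21, self.c12, self.c22)

    def __repr__(self) -> str:  # pragma: no cover - cosmetic
        return f"L4Number({self.code})"


class Relation(enum.Enum):
    """Named elementary relations carried by the five canonical codes."""

    INTERSECTION = "1111"       # a >< b
    SEPARATION = "0111"         # a <> b
    INCLUSION_MORE = "1101"     # a > b
    INCLUSION_LESS = "1011"     # a < b
    INDISCERNIBILITY = "1001"   # a ~= b
    OTHER = None


@dataclass(frozen=True)
class ERLabel:
    """Classification of an L4 code: a named relation plus the raw code."""

    relation: Relation
    code: str

    @property
    def label(self) -> str:
        return self.relation.name.lower()


_CODE_TO_RELATION = {r.value: r for r in Relation if r.value is not None}


def classify_er(x: L4Number) -> ERLabel:
    """Name the relation encoded by *x*; unnamed codes map to ``OTHER``."""
    return ERLabel(_CODE_TO_RELATION.get(x.code, Relation.OTHER), x.code)


def transpose_l4(x: L4Number) -> L4Number:
    """Exchange the roles of the two figures: swap the off-diagonal bits."""
    return x.transpose()


@dataclass(frozen=True)
class L4Vector:
    """Ordered relations of one spot with every spot of a basis."""

    entries: tuple[L4Number, ...]
    basis_id: str = ""

    def __post_init__(self) -> None:
        object.__setattr__(self, "entries", tuple(self.entries))

    def __len__(self) -> int:
        return len(self.entries)

    def __getitem__(self, i: int) -> L4Number:
        return self.entries[i]

    def __iter__(self):
        return iter(self.entries)

    @property
    def hex(self) -> str:
        return "".join(e.hex for e in self.entries)

    @classmethod
    def from_hex(cls, digits: str, basis_id: str = "") -> "L4Vector":
        return cls(tuple(L4Number.from_int(int(d, 16)) for d in digits), basis_id)

    def to_json(self) -> str:
        return json.dumps({"basis_id": self.basis_id, "codes": self.hex})

    @classmethod
    def from_json(cls, text: str) -> "L4Vector":
        doc = json.loads(text)
        return cls.from_hex(doc["codes"], doc.get("basis_id", ""))


@dataclass(frozen=True)
class L4Matrix:
    """Grid of L4 numbers; entry (j, i) is the relation of row-spot j with
    column-spot i, so row j is the L4 vector of y_j on the column basis."""

    entries: tuple[tuple[L4Number, ...], ...]
    row_basis_id: str = ""
    col_basis_id: str = ""

    def __post_init__(self) -> None:
        rows = tuple(tuple(r) for r in self.entries)
        if rows and len({len(r) for r in rows}) != 1:
            raise ValueError("ragged L4 matrix")
        object.__setattr__(self, "entries", rows)

    @property
    def shape(self) -> tuple[int, int]:
        return (len(self.entries), len(self.entries[0]) if self.entries else 0)

    def row(self, j: int) -> L4Vector:
        return L4Vector(self.entries[j], self.col_basis_id)

    def __getitem__(self, idx: tuple[int, int]) -> L4Number:
        j, i = idx
        return self.entries[j][i]

    def to_json(self) -> str:
        return json.dumps(
            {
                "row_basis_id": self.row_basis_id,
                "col_basis_id": self.col_basis_id,
                "rows": ["".join(e.hex for e in row) for row in self.entries],
            }
        )

    @classmethod
    def from_json(cls, text: str) -> "L4Matrix":
        doc = json.loads(text)
        rows = tuple(
            tuple(L4Number.from_int(int(d, 16)) for d in row) for row in doc["rows"]
        )
        return cls(rows, doc.get("row_basis_id", ""), doc.get("col_basis_id", ""))


def _check_same_basis(aU: L4Vector, bU: L4Vector) -> None:
    if len(aU) != len(bU):
        raise ValueError(f"vector lengths differ: {len(aU)} != {len(bU)}")
    if aU.basis_id != bU.basis_id:
        raise ValueError(
            f"vectors live on different bases: {aU.basis_id!r} vs {bU.basis_id!r}"
        )


def l4_inner_product(aU: L4Vector, bU: L4Vector) -> L4Number:
    """Scalar product of two vectors on an atomic (mutually separated) basis.

    Each output bit is the disjunction over basis atoms of the conjunction
    of the matching connection bits: for atom ``u``, ``a u`` is the c11 bit
    of the entry and ``~a u`` its c21 bit.  An implicit background atom —
    connecting both environments but neither figure — realises the
    unbounded empty plane around the grid, so c22 is always 1.
    """
    _check_same_basis(aU, bU)
    c11 = c12 = c21 = 0
    for ea, eb in zip(aU, bU):
        c11 |= ea.c11 & eb.c11
        c12 |= ea.c11 & eb.c21
        c21 |= ea.c21 & eb.c11
    return L4Number(c11, c12, c21, 1)


def l4_matvec_atomic(M: L4Matrix, v: L4Vector) -> L4Vector:
    """Transform *v* (on the atomic column basis of *M*) to M's row basis.

    Entry i of the result is the relation of the unknown spot with row-spot
    i, i.e. the inner product of *v* with row i (the unknown spot supplies
    the left-hand, a-side bits).
    """
    if M.shape[1] != len(v):
        raise ValueError(f"matrix columns {M.shape[1]} != vector length {len(v)}")
    if M.col_basis_id != v.basis_id:
        raise ValueError(
            f"column basis {M.col_basis_id!r} does not match vector basis "
            f"{v.basis_id!r}"
        )
    out = tuple(l4_inner_product(v, M.row(j)) for j in range(M.shape[0]))
    return L4Vector(out, M.row_basis_id)


def indistinguishability_matrix(n: int, basis_id: str = "") -> L4Matrix:
    """Identity-like matrix: indiscernibility on the diagonal, separation off."""
    if n < 1:
        raise ValueError("the indistinguishability matrix needs n >= 1")
    diag = L4Number.from_code("1001")
    off = L4Number.from_code("0111")
    rows = tuple(
        tuple(diag if i == j else off for i in range(n)) for j in range(n)
    )
    return L4Matrix(rows, basis_id, basis_id)


def l4_matrix_inverse(M: L4Matrix) -> L4Matrix:
    """Structural transpose with every entry transposed; swaps the basis ids."""
    nrow, ncol = M.shape
    rows = tuple(
        tuple(M[j, i].transpose() for j in range(nrow)) for i in range(ncol)
    )
    return L4Matrix(rows, M.col_basis_id, M.row_basis_id)


class SeparatedBasesWarning(UserWarning):
    """Raised when two bases share no connection: no mapping is possible."""


def basis_transform(
    aX: L4Vector,
    X: Sequence,
    Y: Sequence,
    cap: int = 2**16,
) -> L4Vector:
    """Re-express the relation vector of an unknown spot on a new basis.

    Runs the chain through the realized intersection cells: the cells U of
    the X spots (entered with the approximate product rule plus the
    boundary corrections), the cells W of U and V together (each W cell
    sits inside exactly one U cell and inherits its relation), the cells V
    of the Y spots and finally Y itself (both with the atomic-basis inner
    product).  X and Y are sequences of :class:`~spotrecon.spots.PixelSpot`
    on a common grid.

    Only *realized* (non-empty) intersections are enumerated; if their
    number would exceed *cap* a ``ValueError`` is raised.  When the two
    bases are mutually separated no inclusion information can cross and a
    :class:`SeparatedBasesWarning` is emitted.
    """
    # local imports: spots/scanning already depend on the scalar types above
    from .scanning import apply_cell_corrections, cell_codes_from_square_codes
    from .spots import PixelSpot, connection
    import numpy as np

    if len(aX) != len(X):
        raise ValueError("aX length does not match the X basis size")
    if not X or not Y:
        raise ValueError("empty basis")
    shape = X[0].mask.shape
    for s in list(X) + list(Y):
        if s.mask.shape != shape:
            raise ValueError("basis spots live on different grids")

    if not any(connection(x, y) for x in X for y in Y):
        warnings.warn(
            "X and Y are mutually separated: the transform carries no "
            "inclusion information",
            SeparatedBasesWarning,
            stacklevel=2,
        )

    def realized(spots: Sequence) -> tuple[np.ndarray, list[tuple[int, ...]]]:
        """Label grid pixels by their cover signature over *spots*."""
        n = len(spots)
        if n > 62:
            raise ValueError("at most 62 spots per explicit basis")
        sig = np.zeros(shape, dtype=np.int64)
        for j, s in enumerate(spots):
            sig |= s.mask.astype(np.int64) << j
        values, labels = np.unique(sig, return_inverse=True)
        if len(values) > cap:
            raise ValueError(
                f"{len(values)} realized intersections exceed the cap {cap}"
            )
        sigs = [tuple(j for j in range(n) if (int(v) >> j) & 1) for v in values]
        return labels.reshape(shape), sigs

    codes = np.array([[e.c11, e.c12, e.c21, e.c22] for e in aX], dtype=np.uint8)

    # --- aU on the intersection cells of X: product rule + corrections ---
    labels_U, sigs_U = realized(X)
    cell_codes = cell_codes_from_square_codes(codes, sigs_U)
    cell_codes, _status = apply_cell_corrections(cell_codes)

    # --- W refines both U and V; each W cell inherits from its U parent ---
    labels_V, sigs_V = realized(Y)
    both = labels_U.astype(np.int64) * (labels_V.max() + 1) + labels_V
    w_values, w_labels = np.unique(both, return_inverse=True)
    w_parent_U = (w_values // (labels_V.max() + 1)).astype(int)
    w_parent_V = (w_values % (labels_V.max() + 1)).astype(int)
    aW = cell_codes[w_parent_U]  # rule: w < u  =>  <a|w> = <a|u>

    # --- aV and aY via the atomic inner product (background atom implied) ---
    def atomic_product(a_bits: np.ndarray, member: np.ndarray) -> np.ndarray:
        """a_bits: (n_atoms, 4); member: bool (n_atoms,) marking atoms of b."""
        a, at = a_bits[:, 0].astype(bool), a_bits[:, 2].astype(bool)
        c11 = int(np.any(a & member))
        c12 = int(np.any(a & ~member))
        c21 = int(np.any(at & member))
        return np.array([c11, c12, c21, 1], dtype=np.uint8)

    aV = np.stack(
        [atomic_product(aW, w_parent_V == v) for v in range(len(sigs_V))]
    )
    out = []
    for j in range(len(Y)):
        member = np.array([j in sig for sig in sigs_V])
        bits = atomic_product(aV, member)
        out.append(L4Number(*(int(b) for b in bits)))
    return L4Vector(tuple(out), basis_id="Y")
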