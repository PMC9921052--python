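"""Sliding-square scanning bases, their realized intersection cells, the
approximate cell-mapping product rule and the boundary-correction rules.

The scan data of an unknown figure is one L4 code per basis square.  To
turn that purely qualitative vector back into pixels the basis is first
refined into its *cells* (granules): maximal pixel sets covered by exactly
the same squares.  For a sliding square of side ``k`` and period ``p`` the
covering squares of a pixel form a rectangle in square-index space, so the
cells can be labelled in O(H*W) without ever enumerating the ``2^n``
nominal intersection codes; with ``k = 4`` and ``p = 1`` every interior
pixel is its own cell, which is what gives the method single-pixel
resolution despite the coarse probes.

The product rule evaluates, for every cell, conjunctions over its covering
squares and over the complements of all non-covering squares; both are
computed exactly with integral-image window sums over the square grid.
The corrections then classify each cell:

* ``INSIDE``  — some covering square is included in the figure (sound:
  the cell lies inside that square, hence inside the figure);
* ``OUTSIDE`` — the product-rule connection bit is 0, i.e. some covering
  square misses the figure or the figure sits inside a non-covering
  square (sound: the cell cannot meet the figure);
* ``AMBIGUOUS`` — everything else: boundary cells and sub-square-size
  structure that qualitative data cannot resolve.

How ambiguous cells are binarized is decided downstream (see
:mod:`spotrecon.reconstruct`).
"""

from __future__ import annotations

import enum
from dataclasses import dataclass
from typing import Sequence

import numpy as np

from .l4 import L4Number, L4Vector

__all__ = [
    "SquareBasis",
    "CellBasis",
    "CellStatus",
    "build_square_basis",
    "realized_cells",
    "map_to_cells",
    "apply_corrections",
    "cell_codes_from_square_codes",
    "apply_cell_corrections",
    "included_square_near",
    "cells_to_mask",
]


class CellStatus(enum.IntEnum):
    OUTSIDE = 0
    INSIDE = 1
    AMBIGUOUS = 2


@dataclass(frozen=True)
class SquareBasis:
    """All fully in-bounds k x k squares stepped by p pixels, row-major."""

    shape: tuple[int, int]
    k: int
    p: int

    def __post_init__(self) -> None:
        H, W = self.shape
        if not (1 <= self.k <= min(H, W)):
            raise ValueError(f"square side k={self.k} out of range for {self.shape}")
        if self.p < 1:
            raise ValueError(f"scan period p={self.p} must be >= 1")

    @property
    def n_rows(self) -> int:
        return (self.shape[0] - self.k) // self.p + 1

    @property
    def n_cols(self) -> int:
        return (self.shape[1] - self.k) // self.p + 1

    def __len__(self) -> int:
        return self.n_rows * self.n_cols

    @property
    def positions(self) -> list[tuple[int, int]]:
        """Top-left corners, row-major."""
        return [
            (r * self.p, c * self.p)
            for r in range(self.n_rows)
            for c in range(self.n_cols)
        ]

    @property
    def basis_id(self) -> str:
        H, W = self.shape
        return f"squares[{H}x{W},k={self.k},p={self.p}]"

    def square_mask(self, index: int) -> np.ndarray:
        r, c = divmod(index, self.n_cols)
        m = np.zeros(self.shape, dtype=bool)
        m[r * self.p : r * self.p + self.k, c * self.p : c * self.p + self.k] = True
        return m

    def window_sums(self, img: np.ndarray) -> np.ndarray:
        """k x k sums of *img* at every square position, shape (n_rows, n_cols)."""
        a = np.asarray(img, dtype=np.int64)
        P = np.zeros((a.shape[0] + 1, a.shape[1] + 1), dtype=np.int64)
        np.cumsum(np.cumsum(a, axis=0), axis=1, out=P[1:, 1:])
        k = self.k
        full = P[k:, k:] - P[:-k, k:] - P[k:, :-k] + P[:-k, :-k]
        return full[:: self.p, :: self.p]

    def cover_index_bounds(self, axis: int) -> tuple[np.ndarray, np.ndarray]:
        """Per-pixel range [lo, hi] of square indices covering that pixel
        along *axis*; hi < lo marks pixels no square covers."""
        n_pix = self.shape[axis]
        n_idx = self.n_rows if axis == 0 else self.n_cols
        i = np.arange(n_pix)
        lo = np.maximum(0, -((-(i - self.k + 1)) // self.p))  # ceil div
        hi = np.minimum(np.minimum(i, n_pix - self.k) // self.p, n_idx - 1)
        return lo.astype(np.int64), hi.astype(np.int64)


def build_square_basis(shape: tuple[int, int], k: int, p: int) -> SquareBasis:
    """Deterministic row-major scanning basis of in-bounds squares."""
    return SquareBasis(tuple(shape), int(k), int(p))


@dataclass(frozen=True, eq=False)
class CellBasis:
    """Realized intersection cells of a square basis.

    Cells partition the grid: two pixels share a cell iff they are covered
    by exactly the same squares.  Per cell the covering squares form the
    index rectangle [lo_r..hi_r] x [lo_c..hi_c]; the single cell of
    entirely uncovered pixels (if any) carries an empty rectangle and is
    flagged in ``covered``.
    """

    basis: SquareBasis
    labels: np.ndarray          # (H, W) cell id per pixel
    lo_r: np.ndarray
    hi_r: np.ndarray
    lo_c: np.ndarray
    hi_c: np.ndarray
    pix_lo_r: np.ndarray        # per-cell pixel bounding boxes
    pix_hi_r: np.ndarray
    pix_lo_c: np.ndarray
    pix_hi_c: np.ndarray
    covered: np.ndarray         # bool per cell
    sizes: np.ndarray           # pixels per cell

    @property
    def n_cells(self) -> int:
        return len(self.covered)

    @property
    def n_cov(self) -> np.ndarray:
        """Number of covering squares per cell."""
        nr = np.maximum(0, self.hi_r - self.lo_r + 1)
        nc = np.maximum(0, self.hi_c - self.lo_c + 1)
        return nr * nc

    @property
    def basis_id(self) -> str:
        return "cells/" + self.basis.basis_id

    def signature(self, cell_id: int) -> tuple[int, ...]:
        """Sorted ids of the squares covering the cell (binary-index coding)."""
        if not self.covered[cell_id]:
            return ()
        ncol = self.basis.n_cols
        return tuple(
            int(r) * ncol + int(c)
            for r in range(self.lo_r[cell_id], self.hi_r[cell_id] + 1)
            for c in range(self.lo_c[cell_id], self.hi_c[cell_id] + 1)
        )

    def cell_mask(self, cell_id: int) -> np.ndarray:
        return self.labels == cell_id


def realized_cells(basis: SquareBasis) -> CellBasis:
    """Group pixels by identical cover signature; never touches 2^n codes."""
    H, W = basis.shape
    lo_r, hi_r = basis.cover_index_bounds(0)
    lo_c, hi_c = basis.cover_index_bounds(1)
    row_none = hi_r < lo_r
    col_none = hi_c < lo_c

    # per-pixel signature keys; uncovered pixels all share one sentinel key
    row_key = np.where(row_none, -1, lo_r * (basis.n_rows + 1) + hi_r)
    col_key = np.where(col_none, -1, lo_c * (basis.n_cols + 1) + hi_c)
    key = np.where(
        (row_key[:, None] < 0) | (col_key[None, :] < 0),
        -1,
        row_key[:, None] * (basis.n_cols + 1) ** 2 + col_key[None, :],
    )
    _, labels = np.unique(key, return_inverse=True)
    labels = labels.reshape(H, W)
    n_cells = labels.max() + 1

    rr, cc = np.meshgrid(np.arange(H), np.arange(W), indexing="ij")
    flat = labels.ravel()

    def per_cell(values: np.ndarray, reduce: str) -> np.ndarray:
        out = np.full(
            n_cells, np.iinfo(np.int64).max if reduce == "min" else np.iinfo(np.int64).min
        )
        getattr(np, "minimum" if reduce == "min" else "maximum").at(
            out, flat, values.ravel()
        )
        return out

    cov = ~((row_none[:, None]) | (col_none[None, :]))
    # representative pixel per cell (first in raster order)
    first = np.full(n_cells, H * W, dtype=np.int64)
    np.minimum.at(first, flat, np.arange(H * W))
    rep_r, rep_c = np.divmod(first, W)

    return CellBasis(
        basis=basis,
        labels=labels,
        lo_r=lo_r[rep_r],
        hi_r=hi_r[rep_r],
        lo_c=lo_c[rep_c],
        hi_c=hi_c[rep_c],
        pix_lo_r=per_cell(np.broadcast_to(rr, (H, W)), "min"),
        pix_hi_r=per_cell(np.broadcast_to(rr, (H, W)), "max"),
        pix_lo_c=per_cell(np.broadcast_to(cc, (H, W)), "min"),
        pix_hi_c=per_cell(np.broadcast_to(cc, (H, W)), "max"),
        covered=cov.ravel()[first],
        sizes=np.bincount(flat, minlength=n_cells),
    )


# ---------------------------------------------------------------------------
# vectorized per-cell aggregation over square-index rectangles


def _prefix(values: np.ndarray) -> np.ndarray:
    P = np.zeros((values.shape[0] + 1, values.shape[1] + 1), dtype=np.int64)
    np.cumsum(np.cumsum(values, axis=0), axis=1, out=P[1:, 1:])
    return P


def _rect_sum(P, lo_r, hi_r, lo_c, hi_c) -> np.ndarray:
    """Sums over [lo_r..hi_r] x [lo_c..hi_c]; empty ranges give 0."""
    hr = np.maximum(hi_r + 1, lo_r)
    hc = np.maximum(hi_c + 1, lo_c)
    return P[hr, hc] - P[lo_r, hc] - P[hr, lo_c] + P[lo_r, lo_c]


def _cover_sum(cells: CellBasis, values: np.ndarray) -> np.ndarray:
    """Per-cell sum of a per-square quantity over the covering squares."""
    P = _prefix(values)
    out = _rect_sum(P, cells.lo_r, cells.hi_r, cells.lo_c, cells.hi_c)
    out[~cells.covered] = 0
    return out


def included_square_near(
    cells: CellBasis, included: np.ndarray, radius: int
) -> np.ndarray:
    """Per cell: does any square flagged in *included* (bool, square grid)
    have its support within Chebyshev distance *radius* of the cell?"""
    b = cells.basis
    P = _prefix(included.astype(np.int64))

    def idx_bounds(pix_lo, pix_hi, n_idx, n_pix):
        lo = np.maximum(0, -((-(pix_lo - radius - b.k + 1)) // b.p))
        hi = np.minimum(np.minimum(pix_hi + radius, n_pix - b.k) // b.p, n_idx - 1)
        return lo, hi

    lo_r, hi_r = idx_bounds(cells.pix_lo_r, cells.pix_hi_r, b.n_rows, b.shape[0])
    lo_c, hi_c = idx_bounds(cells.pix_lo_c, cells.pix_hi_c, b.n_cols, b.shape[1])
    return _rect_sum(P, lo_r, hi_r, lo_c, hi_c) > 0


def _as_code_array(aX, n: int) -> np.ndarray:
    """Accept an ERVector-like (.codes), an L4Vector, an (n, 4) array or a
    sequence of L4Number; return uint8 (n, 4)."""
    if hasattr(aX, "codes"):
        codes = np.asarray(aX.codes, dtype=np.uint8)
    elif isinstance(aX, L4Vector):
        codes = np.array([[e.c11, e.c12, e.c21, e.c22] for e in aX], dtype=np.uint8)
    else:
        arr = np.asarray(aX)
        if arr.ndim == 2 and arr.shape[1] == 4:
            codes = arr.astype(np.uint8)
        else:
            codes = np.array(
                [[e.c11, e.c12, e.c21, e.c22] for e in aX], dtype=np.uint8
            )
    if codes.shape != (n, 4):
        raise ValueError(f"scan vector length {codes.shape[0]} != basis size {n}")
    return codes


def map_cell_codes(codes: np.ndarray, cells: CellBasis) -> np.ndarray:
    """Exact product-rule codes for every cell, as a uint8 (n_cells, 4) array.

    The connection row of a cell conjoins the figure's connection with every
    covering square and its overreach beyond every non-covering square; the
    environment row is the mirror image.  Disjunction rows are the matching
    sums.  All four are evaluated with integral-image rectangle sums.
    """
    b = cells.basis
    n = len(b)
    grids = [codes[:, i].reshape(b.n_rows, b.n_cols) for i in range(4)]
    totals = [int(g.sum()) for g in grids]
    cov = [_cover_sum(cells, g) for g in grids]
    n_cov = cells.n_cov

    def and_cov(i):
        return cov[i] == n_cov

    def and_noncov(i):
        return (totals[i] - cov[i]) == (n - n_cov)

    def or_cov(i):
        return cov[i] > 0

    def or_noncov(i):
        return (totals[i] - cov[i]) > 0

    c11 = and_cov(0) & and_noncov(1)
    c12 = or_cov(1) | or_noncov(0)
    c21 = and_cov(2) & and_noncov(3)
    c22 = or_cov(3) | or_noncov(2)
    return np.stack([c11, c12, c21, c22], axis=1).astype(np.uint8)


def cell_codes_from_square_codes(
    codes: np.ndarray, signatures: Sequence[tuple[int, ...]]
) -> np.ndarray:
    """Product-rule codes for explicitly listed cell signatures (general
    bases of arbitrary spots; used by the basis-chain transform)."""
    codes = np.asarray(codes, dtype=np.uint8)
    n = len(codes)
    out = np.zeros((len(signatures), 4), dtype=np.uint8)
    for idx, sig in enumerate(signatures):
        member = np.zeros(n, dtype=bool)
        member[list(sig)] = True
        c11 = codes[member, 0].all() and codes[~member, 1].all()
        c12 = codes[member, 1].any() or codes[~member, 0].any()
        c21 = codes[member, 2].all() and codes[~member, 3].all()
        c22 = codes[member, 3].any() or codes[~member, 2].any()
        out[idx] = (c11, c12, c21, c22)
    return out


def apply_cell_corrections(
    cell_codes: np.ndarray,
) -> tuple[np.ndarray, np.ndarray]:
    """Sound boundary corrections on product-rule cell codes.

    Returns ``(corrected_codes, statuses)``: INSIDE cells become the
    inclusion code 1101, OUTSIDE cells the separation code 0111, ambiguous
    cells keep their product-rule code.
    """
    c11 = cell_codes[:, 0].astype(bool)
    c21 = cell_codes[:, 2].astype(bool)
    statuses = np.full(len(cell_codes), int(CellStatus.AMBIGUOUS), dtype=np.int8)
    statuses[~c11] = int(CellStatus.OUTSIDE)
    statuses[c11 & ~c21] = int(CellStatus.INSIDE)
    corrected = cell_codes.copy()
    corrected[statuses == CellStatus.INSIDE] = (1, 1, 0, 1)
    corrected[statuses == CellStatus.OUTSIDE] = (0, 1, 1, 1)
    return corrected, statuses


# ---------------------------------------------------------------------------
# interface wrappers working in L4Vector terms


def map_to_cells(aX, basis: SquareBasis, cells: CellBasis) -> L4Vector:
    """Map scan data from the squares onto the realized cells (product rule)."""
    codes = _as_code_array(aX, len(basis))
    cc = map_cell_codes(codes, cells)
    return L4Vector(
        tuple(L4Number(*(int(v) for v in row)) for row in cc), cells.basis_id
    )


def apply_corrections(
    aU, aX, basis: SquareBasis, cells: CellBasis
) -> tuple[L4Vector, np.ndarray]:
    """Correct the cell codes and classify every cell.

    Returns the corrected L4 vector on the cells and an int array of
    :class:`CellStatus` values (INSIDE / OUTSIDE / AMBIGUOUS).
    """
    cell_codes = _as_code_array(aU, cells.n_cells)
    _ = _as_code_array(aX, len(basis))  # validates consistency of the pair
    corrected, statuses = apply_cell_corrections(cell_codes)
    vec = L4Vector(
        tuple(L4Number(*(int(v) for v in row)) for row in corrected),
        cells.basis_id,
    )
    return vec, statuses


def cells_to_mask(cells: CellBasis, keep: np.ndarray) -> np.ndarray:
    """Render per-cell booleans back to a pixel raster."""
    keep = np.asarray(keep, dtype=bool)
    if keep.shape != (cells.n_cells,):
        raise ValueError("one boolean per cell required")
    return keep[cells.labels]
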