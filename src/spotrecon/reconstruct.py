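"""Qualitative-scan image reconstruction and quality metrics.

Forward problem: scan a binary figure with every square of a sliding
basis and keep only the 4-bit elementary relation per square — no counts,
distances or overlap areas.  Inverse problem: refine the basis into its
intersection cells, push the scan vector onto the cells with the product
rule, apply the boundary corrections, and render the inside cells.

Ambiguous cells (sub-square-size structure: sharp tips, specks, pinholes)
are binarized with a *neighbourhood inclusion* rule: an ambiguous cell is
filled iff some square included in the figure lies within Chebyshev
distance ``inclusion_radius`` of it.  The corrections leave at most a
one-cell ambiguity layer around solid convex bodies, so the default
radius is 1: thin features attached to a solid body are kept while
isolated specks are rejected — the denoising behaviour of the method.
With radius 0 the classification is strict and only provably-inside
cells survive.

Grayscale images are handled by slicing the intensity axis into cumulative
threshold layers (a chain of nested spots), reconstructing every layer
independently and recombining by the highest claiming layer.
"""

from __future__ import annotations

import json
import warnings
from dataclasses import dataclass
from pathlib import Path

import numpy as np

from .l4 import L4Number, L4Vector
from .scanning import (
    CellStatus,
    SquareBasis,
    apply_cell_corrections,
    build_square_basis,
    cells_to_mask,
    included_square_near,
    map_cell_codes,
    realized_cells,
)
from .spots import PixelSpot

__all__ = [
    "ERVector",
    "GrayLayers",
    "ReconMetrics",
    "scan_er",
    "reconstruct_binary",
    "slice_layers",
    "recombine_layers",
    "reconstruct_gray",
    "misfit",
    "metrics",
    "snr_db",
]


@dataclass(frozen=True, eq=False)
class ERVector:
    """Qualitative scan data: one L4 code per basis square (row-major).

    ``codes`` is a uint8 array of shape (n_squares, 4) in bit order
    (ab, ab~, a~b, a~b~); ``k``, ``p`` and ``shape`` identify the basis.
    """

    codes: np.ndarray
    shape: tuple[int, int]
    k: int
    p: int

    def __post_init__(self) -> None:
        codes = np.asarray(self.codes, dtype=np.uint8)
        basis = self.basis
        if codes.shape != (len(basis), 4):
            raise ValueError(
                f"expected {(len(basis), 4)} codes for {basis.basis_id}, "
                f"got {codes.shape}"
            )
        codes.setflags(write=False)
        object.__setattr__(self, "codes", codes)
        object.__setattr__(self, "shape", tuple(self.shape))

    @property
    def basis(self) -> SquareBasis:
        return SquareBasis(tuple(self.shape), self.k, self.p)

    def __len__(self) -> int:
        return len(self.codes)

    def entry(self, i: int) -> L4Number:
        return L4Number(*(int(b) for b in self.codes[i]))

    def as_l4_vector(self) -> L4Vector:
        return L4Vector(
            tuple(L4Number(*(int(b) for b in row)) for row in self.codes),
            self.basis.basis_id,
        )

    @property
    def hex(self) -> str:
        nibbles = (
            (self.codes[:, 0] << 3)
            | (self.codes[:, 1] << 2)
            | (self.codes[:, 2] << 1)
            | self.codes[:, 3]
        )
        return "".join(format(int(v), "x") for v in nibbles)

    def save(self, path: str | Path) -> None:
        doc = {
            "shape": list(self.shape),
            "k": self.k,
            "p": self.p,
            "codes": self.hex,
        }
        Path(path).write_text(json.dumps(doc))

    @classmethod
    def load(cls, path: str | Path) -> "ERVector":
        doc = json.loads(Path(path).read_text())
        vals = np.array([int(ch, 16) for ch in doc["codes"]], dtype=np.uint8)
        codes = np.stack(
            [(vals >> 3) & 1, (vals >> 2) & 1, (vals >> 1) & 1, vals & 1], axis=1
        )
        return cls(codes, tuple(doc["shape"]), doc["k"], doc["p"])


def scan_er(a: PixelSpot, basis: SquareBasis) -> ERVector:
    """Elementary relation of the figure with every basis square.

    Only the four qualitative connection bits are retained: the figure
    connects a square iff they overlap, overreaches it iff it has pixels
    outside, and so on; the environments always share the off-grid
    background.
    """
    if a.shape != basis.shape:
        raise ValueError(f"figure shape {a.shape} != basis shape {basis.shape}")
    W = basis.window_sums(a.mask)
    area = a.area
    c11 = (W > 0).astype(np.uint8)
    c12 = (area > W).astype(np.uint8)          # figure reaches outside the square
    c21 = (W < basis.k * basis.k).astype(np.uint8)  # square reaches outside figure
    c22 = np.ones_like(c11)
    codes = np.stack(
        [c11.ravel(), c12.ravel(), c21.ravel(), c22.ravel()], axis=1
    )
    return ERVector(codes, basis.shape, basis.k, basis.p)


def reconstruct_binary(
    aX: ERVector,
    basis: SquareBasis | None = None,
    *,
    inclusion_radius: int | None = None,
) -> PixelSpot:
    """Invert a qualitative scan: cells -> product rule -> corrections ->
    binarization.  Deterministic.

    ``inclusion_radius`` controls the ambiguous-cell rule described in the
    module docstring; ``None`` selects the default radius 1 (one cell layer).
    """
    if basis is None:
        basis = aX.basis
    elif (basis.shape, basis.k, basis.p) != (aX.shape, aX.k, aX.p):
        raise ValueError(
            f"basis {basis.basis_id} inconsistent with scan metadata "
            f"{aX.basis.basis_id}"
        )
    rho = 1 if inclusion_radius is None else int(inclusion_radius)
    codes = np.asarray(aX.codes, dtype=np.uint8)

    cells = realized_cells(basis)
    cell_codes = map_cell_codes(codes, cells)
    _, statuses = apply_cell_corrections(cell_codes)

    keep = statuses == CellStatus.INSIDE
    ambiguous = statuses == CellStatus.AMBIGUOUS
    if ambiguous.any():
        included = ((codes[:, 0] == 1) & (codes[:, 2] == 0)).reshape(
            basis.n_rows, basis.n_cols
        )
        if included.any() and rho >= 0:
            keep |= ambiguous & included_square_near(cells, included, rho)
    return PixelSpot(cells_to_mask(cells, keep))


# ---------------------------------------------------------------------------
# grayscale layering


@dataclass(frozen=True, eq=False)
class GrayLayers:
    """Cumulative-threshold slicing of a grayscale image.

    ``masks[l]`` is the figure of pixels with intensity >= ``levels[l]``;
    the masks are nested (each contains the next) — the chain of
    intersected spots that represents the intensity axis.  ``base`` is the
    intensity below the first threshold.
    """

    levels: np.ndarray
    masks: np.ndarray  # (L, H, W) bool
    base: float

    def __post_init__(self) -> None:
        object.__setattr__(self, "levels", np.asarray(self.levels, dtype=float))
        object.__setattr__(self, "masks", np.asarray(self.masks, dtype=bool))

    def __len__(self) -> int:
        return len(self.levels)

    def spot(self, l: int) -> PixelSpot:
        return PixelSpot(self.masks[l])


def slice_layers(img: np.ndarray, L: int) -> GrayLayers:
    """Slice the intensity range into *L* cumulative threshold layers."""
    if L < 1:
        raise ValueError("need at least one layer")
    img = np.asarray(img, dtype=float)
    vmin, vmax = float(img.min()), float(img.max())
    if vmax <= vmin:
        warnings.warn("constant image: a single trivial layer", stacklevel=2)
        return GrayLayers(
            np.array([vmin]), np.ones((1,) + img.shape, dtype=bool), vmin
        )
    step = (vmax - vmin) / L
    levels = vmin + step * np.arange(1, L + 1)
    masks = img[None, :, :] >= levels[:, None, None]
    return GrayLayers(levels, masks, vmin)


def recombine_layers(layers: GrayLayers) -> np.ndarray:
    """Intensity of each pixel = level of the highest layer claiming it."""
    out = np.full(layers.masks.shape[1:], layers.base, dtype=float)
    for lvl, mask in zip(layers.levels, layers.masks):  # ascending levels
        out[mask] = lvl
    return out


def reconstruct_gray(
    layer_ERs: list[ERVector],
    basis: SquareBasis,
    levels: np.ndarray,
    base: float = 0.0,
    *,
    inclusion_radius: int | None = None,
) -> np.ndarray:
    """Reconstruct every intensity layer independently and recombine."""
    levels = np.asarray(levels, dtype=float)
    if len(layer_ERs) != len(levels):
        raise ValueError(
            f"{len(layer_ERs)} scan vectors for {len(levels)} levels"
        )
    out = np.full(basis.shape, base, dtype=float)
    order = np.argsort(levels)
    for idx in order:  # ascending: the highest claiming layer wins
        mask = reconstruct_binary(
            layer_ERs[idx], basis, inclusion_radius=inclusion_radius
        ).mask
        out[mask] = levels[idx]
    return out


# ---------------------------------------------------------------------------
# quality metrics


@dataclass(frozen=True)
class ReconMetrics:
    """Area misfit between original and reconstructed inner regions."""

    mer: float       # percent
    noi: int         # inner-region pixels, original
    nri: int         # inner-region pixels, reconstruction

    def to_json(self) -> str:
        return json.dumps({"mer": round(self.mer, 1), "NOI": self.noi, "NRI": self.nri})


def metrics(original: PixelSpot, recon: PixelSpot) -> ReconMetrics:
    if original.shape != recon.shape:
        raise ValueError("shape mismatch between original and reconstruction")
    noi, nri = original.area, recon.area
    if noi == 0:
        raise ValueError("the original figure has an empty inner region")
    return ReconMetrics(abs(noi - nri) / noi * 100.0, noi, nri)


def misfit(original: PixelSpot, recon: PixelSpot) -> float:
    """Area misfit |NOI - NRI| / NOI in percent."""
    return metrics(original, recon).mer


def snr_db(clean: np.ndarray, noisy: np.ndarray) -> float:
    """SNR of a noisy image against its clean original, in decibels:
    20*log10(mean(clean) / std(noisy - clean)); +inf for zero noise."""
    clean = np.asarray(clean, dtype=float)
    noisy = np.asarray(noisy, dtype=float)
    if clean.shape != noisy.shape:
        raise ValueError("shape mismatch")
    sigma = float(np.std(noisy - clean))
    if sigma == 0.0:
        return float("inf")
    return 20.0 * np.log10(float(np.mean(clean)) / sigma)
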