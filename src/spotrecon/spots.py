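"""Crisp figures as pixel masks with the spot axioms.

A :class:`PixelSpot` is a finite binary figure on a rectangular grid that is
itself embedded in an unbounded empty plane.  Connection between two spots
means the existence of a common region (shared pixels); a spot never
connects its own environment.  The environment of a grid-bounded figure is
its on-grid complement *plus* the off-grid background, so the environments
of any two finite figures always connect — without this convention the
relation of near-full-grid figures degenerates and the canonical codes
become unreachable.
"""

from __future__ import annotations

import json
from dataclasses import dataclass, field
from pathlib import Path

import numpy as np
from PIL import Image

from .l4 import L4Number

__all__ = [
    "PixelSpot",
    "connection",
    "environment",
    "er",
    "intersection_parts",
    "spot_union",
    "spot_intersection",
    "load_mask",
    "save_mask",
]


@dataclass(frozen=True, eq=False)
class PixelSpot:
    """A crisp figure: a 2-D bit raster, 1 = inner region.

    ``offgrid`` marks spots that extend into the unbounded background
    beyond the grid (environments of finite figures); ordinary figures
    leave it False.
    """

    mask: np.ndarray
    offgrid: bool = False

    def __post_init__(self) -> None:
        m = np.asarray(self.mask)
        if m.ndim != 2:
            raise ValueError("a PixelSpot mask must be 2-D")
        m = m.astype(bool)
        m.setflags(write=False)
        object.__setattr__(self, "mask", m)

    @classmethod
    def empty(cls, shape: tuple[int, int]) -> "PixelSpot":
        return cls(np.zeros(shape, dtype=bool))

    @classmethod
    def full(cls, shape: tuple[int, int]) -> "PixelSpot":
        return cls(np.ones(shape, dtype=bool))

    @classmethod
    def from_indices(
        cls, shape: tuple[int, int], rows, cols
    ) -> "PixelSpot":
        m = np.zeros(shape, dtype=bool)
        m[rows, cols] = True
        return cls(m)

    @property
    def shape(self) -> tuple[int, int]:
        return self.mask.shape

    @property
    def area(self) -> int:
        return int(self.mask.sum())

    def is_empty(self) -> bool:
        return not (self.mask.any() or self.offgrid)

    def __eq__(self, other) -> bool:
        if not isinstance(other, PixelSpot):
            return NotImplemented
        return (
            self.offgrid == other.offgrid
            and self.shape == other.shape
            and bool(np.array_equal(self.mask, other.mask))
        )

    def __hash__(self) -> int:
        return hash((self.shape, self.offgrid, self.mask.tobytes()))


def _check_shapes(a: PixelSpot, b: PixelSpot) -> None:
    if a.shape != b.shape:
        raise ValueError(f"shape mismatch: {a.shape} vs {b.shape}")


def connection(a: PixelSpot, b: PixelSpot) -> int:
    """1 iff the spots share a common region (>= 1 pixel, or both extend
    into the off-grid background).  Symmetric; mere adjacency does not
    connect."""
    _check_shapes(a, b)
    return int(bool(np.any(a.mask & b.mask)) or (a.offgrid and b.offgrid))


def environment(a: PixelSpot) -> PixelSpot:
    """The complement spot: on-grid complement plus the off-grid plane."""
    return PixelSpot(~a.mask, offgrid=not a.offgrid)


def er(a: PixelSpot, b: PixelSpot) -> L4Number:
    """The elementary relation of *a* with *b* as a 4-bit L4 number."""
    _check_shapes(a, b)
    ea, eb = environment(a), environment(b)
    return L4Number(
        connection(a, b), connection(a, eb), connection(ea, b), connection(ea, eb)
    )


def intersection_parts(
    a: PixelSpot, b: PixelSpot
) -> tuple[PixelSpot, PixelSpot, PixelSpot, PixelSpot]:
    """The four parts A = a^~b, B = ~a^b, C = a^b, D = ~a^~b.

    The parts partition the grid; A|C = a and B|C = b.
    """
    _check_shapes(a, b)
    A = PixelSpot(a.mask & ~b.mask)
    B = PixelSpot(~a.mask & b.mask)
    C = PixelSpot(a.mask & b.mask)
    D = PixelSpot(~a.mask & ~b.mask, offgrid=not (a.offgrid or b.offgrid))
    return A, B, C, D


def spot_union(a: PixelSpot, b: PixelSpot) -> PixelSpot:
    """Union: a probe connects it iff the probe connects a or b."""
    _check_shapes(a, b)
    return PixelSpot(a.mask | b.mask, offgrid=a.offgrid or b.offgrid)


def spot_intersection(a: PixelSpot, b: PixelSpot) -> PixelSpot:
    """Intersection: a probe connects its environment iff it connects
    either environment."""
    _check_shapes(a, b)
    return PixelSpot(a.mask & b.mask, offgrid=a.offgrid and b.offgrid)


# ---------------------------------------------------------------------------
# mask I/O: PNG/PGM (0/255) and plain text rasters of 0/1


def save_mask(spot: PixelSpot | np.ndarray, path: str | Path) -> None:
    mask = spot.mask if isinstance(spot, PixelSpot) else np.asarray(spot, bool)
    path = Path(path)
    if path.suffix.lower() in {".png", ".pgm"}:
        Image.fromarray((mask.astype(np.uint8)) * 255).save(path)
    else:
        lines = ["".join("1" if v else "0" for v in row) for row in mask]
        path.write_text("\n".join(lines) + "\n")
    sidecar = path.with_suffix(path.suffix + ".json")
    sidecar.write_text(json.dumps({"shape": list(mask.shape), "format": "binary"}))


def load_mask(path: str | Path) -> PixelSpot:
    path = Path(path)
    if path.suffix.lower() in {".png", ".pgm"}:
        arr = np.asarray(Image.open(path).convert("L"))
        return PixelSpot(arr > 127)
    rows = [line for line in path.read_text().splitlines() if line.strip()]
    return PixelSpot(np.array([[ch == "1" for ch in row] for row in rows]))


def save_gray(img: np.ndarray, path: str | Path) -> None:
    """8-bit grayscale PNG/PGM; input is clipped to [0, 1] and scaled."""
    arr = np.clip(np.asarray(img, dtype=float), 0.0, 1.0)
    Image.fromarray((arr * 255).round().astype(np.uint8)).save(Path(path))


def load_gray(path: str | Path) -> np.ndarray:
    """Grayscale image as floats in [0, 1]."""
    return np.asarray(Image.open(Path(path)).convert("L"), dtype=float) / 255.0
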