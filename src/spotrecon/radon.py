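"""Spot-based inverse Radon transform for binary figures.

Forward model: parallel-beam ray sums of a binary image over a set of
projection angles (the sinogram).  The spot-based inverse never
back-projects values; instead it compares *logical* sinograms.  The
sinogram of every basis square is computed analytically (closed-form box
projections), both sinograms are thresholded, and the elementary relation
of the figure with each square is read off the bit patterns: the figure
connects the square if their supports overlap at some angle, and the
square is included in the figure if every ray that meets the square also
meets the figure at every angle (inclusion of figures implies inclusion of
all their projections — the sound direction).  The resulting qualitative
scan vector is inverted by the cell machinery of
:mod:`spotrecon.scanning` exactly as for direct scans.

Conventions: rotation about the grid centre ((H-1)/2, (W-1)/2); the
projection coordinate of a point is u = x cos(theta) + y sin(theta); the
offset axis is unit-spaced and spans the grid diagonal; angles are degrees
in [0, 180).  Ray values are bin-integrated path lengths, so the total
mass at every angle equals the figure area.
"""

from __future__ import annotations

import warnings
from dataclasses import dataclass
from pathlib import Path

import numpy as np
from skimage.transform import iradon

from .l4 import L4Number
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
    "Sinogram",
    "LogicalSinogram",
    "default_offsets",
    "forward_sinogram",
    "binarize_sinogram",
    "square_logical_sinogram",
    "er_from_sinograms",
    "radon_reconstruct",
    "fbp_baseline",
]


@dataclass(frozen=True, eq=False)
class Sinogram:
    """Parallel-beam ray sums: ``values[i, j]`` at ``angles[i]`` degrees and
    offset ``offsets[j]`` (pixels from the rotation centre)."""

    angles: np.ndarray
    offsets: np.ndarray
    values: np.ndarray

    def __post_init__(self) -> None:
        angles = np.asarray(self.angles, dtype=float)
        offsets = np.asarray(self.offsets, dtype=float)
        values = np.asarray(self.values, dtype=float)
        if values.shape != (len(angles), len(offsets)):
            raise ValueError(
                f"values shape {values.shape} != (n_angles, n_offsets) "
                f"({len(angles)}, {len(offsets)})"
            )
        for arr in (angles, offsets, values):
            arr.setflags(write=False)
        object.__setattr__(self, "angles", angles)
        object.__setattr__(self, "offsets", offsets)
        object.__setattr__(self, "values", values)

    def to_csv(self, path: str | Path) -> None:
        """First row = offsets, first column = angles."""
        M = np.zeros((len(self.angles) + 1, len(self.offsets) + 1))
        M[0, 1:] = self.offsets
        M[1:, 0] = self.angles
        M[1:, 1:] = self.values
        np.savetxt(path, M, delimiter=",")

    @classmethod
    def from_csv(cls, path: str | Path) -> "Sinogram":
        M = np.loadtxt(path, delimiter=",")
        return cls(M[1:, 0], M[0, 1:], M[1:, 1:])


@dataclass(frozen=True, eq=False)
class LogicalSinogram:
    """Thresholded sinogram bits plus the threshold used."""

    angles: np.ndarray
    offsets: np.ndarray
    bits: np.ndarray
    tau: float

    def __post_init__(self) -> None:
        object.__setattr__(self, "bits", np.asarray(self.bits, dtype=bool))


def default_offsets(shape: tuple[int, int]) -> np.ndarray:
    """Unit-spaced symmetric offsets spanning the grid diagonal."""
    half = int(np.ceil(float(np.hypot(*shape)) / 2.0))
    return np.arange(-half, half + 1, dtype=float)


def _trapezoid_cdf(t: np.ndarray, w1: float, w2: float) -> np.ndarray:
    """CDF of the projection profile of an axis-aligned unit-area box with
    projected widths w1, w2 (profile integral normalised to w1*... the box
    projection has integral = box area = w1*w2/(|cos||sin|); here the
    profile is scaled so its integral is 1)."""
    a = abs(w1 - w2) / 2.0
    b = (w1 + w2) / 2.0
    m = b - a  # ramp length = min(w1, w2)
    h = 0.5 / (a + m / 2.0)  # peak height of the unit-integral trapezoid
    x = np.abs(t)
    if m <= 1e-12:
        s = h * np.minimum(x, b)
    else:
        ramp = np.clip(x - a, 0.0, m)
        s = h * (np.minimum(x, a) + ramp - ramp**2 / (2.0 * m))
    s = np.minimum(s, 0.5)
    return 0.5 + np.sign(t) * s


def _bin_weights(u: np.ndarray, offsets: np.ndarray, w1: float, w2: float,
                 scale: float) -> tuple[np.ndarray, np.ndarray]:
    """Bin-integrated projection mass around positions *u* for a box whose
    total projected mass is *scale*.  Returns (bin_indices, weights) flat."""
    o0 = offsets[0]
    j0 = np.rint(u - o0).astype(np.int64)
    reach = int(np.ceil((w1 + w2) / 2.0 + 0.5)) + 1
    js = j0[:, None] + np.arange(-reach, reach + 1)[None, :]
    t = (js + o0) - u[:, None]
    w = _trapezoid_cdf(t + 0.5, w1, w2) - _trapezoid_cdf(t - 0.5, w1, w2)
    valid = (js >= 0) & (js < len(offsets))
    return js[valid], scale * w[valid]


def forward_sinogram(
    a: PixelSpot, angles, offsets: np.ndarray | None = None
) -> Sinogram:
    """Parallel-beam sinogram of a binary figure (bin-integrated ray sums)."""
    angles = np.atleast_1d(np.asarray(angles, dtype=float))
    if angles.size == 0:
        raise ValueError("at least one projection angle is required")
    if offsets is None:
        offsets = default_offsets(a.shape)
    if not a.mask.any():
        warnings.warn("empty figure: all-zero sinogram", stacklevel=2)
        return Sinogram(angles, offsets, np.zeros((len(angles), len(offsets))))

    H, W = a.shape
    cy, cx = (H - 1) / 2.0, (W - 1) / 2.0
    rows, cols = np.nonzero(a.mask)
    x = cols - cx
    y = rows - cy
    values = np.zeros((len(angles), len(offsets)))
    for i, ang in enumerate(angles):
        th = np.deg2rad(ang)
        c, s = np.cos(th), np.sin(th)
        u = x * c + y * s
        js, w = _bin_weights(u, offsets, abs(c), abs(s), 1.0)
        np.add.at(values[i], js, w)
    return Sinogram(angles, offsets, values)


def binarize_sinogram(s: Sinogram, tau: float = 0.5) -> LogicalSinogram:
    """Elementwise threshold; tau = 0.5 (half a unit pixel path) suits
    noise-free data, larger values suppress sinogram noise."""
    if tau < 0:
        raise ValueError("tau must be non-negative")
    return LogicalSinogram(s.angles, s.offsets, s.values > tau, float(tau))


def _square_support_halfwidth(k: int, theta_deg: float, tau: float) -> float:
    """Half-width of the offset interval where the bin-integrated projection
    of a k x k square exceeds tau (0 if it never does)."""
    th = np.deg2rad(theta_deg)
    w1, w2 = k * abs(np.cos(th)), k * abs(np.sin(th))
    scale = float(k * k)
    b = (w1 + w2) / 2.0 + 0.5

    def bin_val(t: float) -> float:
        return scale * float(
            _trapezoid_cdf(np.array(t + 0.5), w1, w2)
            - _trapezoid_cdf(np.array(t - 0.5), w1, w2)
        )

    if bin_val(0.0) <= tau:
        return -1.0  # the square never rises above the threshold
    lo, hi = 0.0, b
    for _ in range(60):
        mid = (lo + hi) / 2.0
        if bin_val(mid) > tau:
            lo = mid
        else:
            hi = mid
    return lo


def _square_centers(basis: SquareBasis) -> tuple[np.ndarray, np.ndarray]:
    H, W = basis.shape
    cy, cx = (H - 1) / 2.0, (W - 1) / 2.0
    half = (basis.k - 1) / 2.0
    yc = np.arange(basis.n_rows) * basis.p + half - cy
    xc = np.arange(basis.n_cols) * basis.p + half - cx
    return yc, xc


def square_logical_sinogram(
    basis: SquareBasis,
    index: int,
    angles,
    offsets: np.ndarray | None = None,
    tau: float = 0.5,
) -> LogicalSinogram:
    """Analytic thresholded sinogram of one basis square."""
    angles = np.atleast_1d(np.asarray(angles, dtype=float))
    if offsets is None:
        offsets = default_offsets(basis.shape)
    yc, xc = _square_centers(basis)
    r, c = divmod(index, basis.n_cols)
    bits = np.zeros((len(angles), len(offsets)), dtype=bool)
    for i, ang in enumerate(angles):
        th = np.deg2rad(ang)
        u = xc[c] * np.cos(th) + yc[r] * np.sin(th)
        hw = _square_support_halfwidth(basis.k, ang, tau)
        if hw >= 0:
            bits[i] = np.abs(offsets - u) <= hw
    return LogicalSinogram(angles, offsets, bits, float(tau))


def er_from_sinograms(sa: LogicalSinogram, sx: LogicalSinogram) -> L4Number:
    """Elementary relation of a figure with a basis square read from their
    logical sinograms: connection = supports overlap at some angle,
    environment connection = some ray meets the square but not the figure.
    The environment bits towards the sinogram complements are fixed to 1."""
    if sa.bits.shape != sx.bits.shape or not np.allclose(
        sa.angles, sx.angles
    ) or not np.allclose(sa.offsets, sx.offsets):
        raise ValueError("logical sinograms live on different (angle, offset) grids")
    c11 = int(np.any(sa.bits & sx.bits))
    c21 = int(np.any(~sa.bits & sx.bits))
    return L4Number(c11, 1, c21, 1)


def sinogram_scan_codes(
    s: Sinogram, basis: SquareBasis, tau: float = 0.5
) -> np.ndarray:
    """L4 codes of the figure against every basis square, derived purely
    from the thresholded sinogram (vectorised interval arithmetic)."""
    logical = binarize_sinogram(s, tau)
    sa = logical.bits
    offsets = s.offsets
    n_off = len(offsets)
    P = np.zeros((len(s.angles), n_off + 1), dtype=np.int64)
    np.cumsum(sa, axis=1, out=P[:, 1:])

    yc, xc = _square_centers(basis)
    c11 = np.zeros((basis.n_rows, basis.n_cols), dtype=bool)
    c21 = np.zeros((basis.n_rows, basis.n_cols), dtype=bool)
    o0 = offsets[0]
    for i, ang in enumerate(s.angles):
        th = np.deg2rad(ang)
        u = xc[None, :] * np.cos(th) + yc[:, None] * np.sin(th)
        hw = _square_support_halfwidth(basis.k, ang, tau)
        if hw < 0:
            continue
        lo = np.clip(np.ceil(u - hw - o0).astype(np.int64), 0, n_off)
        hi = np.clip(np.floor(u + hw - o0).astype(np.int64) + 1, 0, n_off)
        hi = np.maximum(hi, lo)
        cnt = hi - lo
        cnt_sa = P[i][hi] - P[i][lo]
        c11 |= cnt_sa > 0
        c21 |= cnt_sa < cnt
    ones = np.ones(len(basis), dtype=np.uint8)
    return np.stack(
        [c11.ravel().astype(np.uint8), ones, c21.ravel().astype(np.uint8), ones],
        axis=1,
    )


def radon_reconstruct(
    s: Sinogram,
    shape: tuple[int, int],
    k: int,
    p: int,
    tau: float = 0.5,
    *,
    inclusion_radius: int = 0,
) -> PixelSpot:
    """Reconstruct a binary figure from its sinogram via logical square
    relations and the qualitative cell machinery.  Deterministic.

    Sinogram-derived connection bits are ORs over angles and therefore
    over-approximate true connection, so ambiguous cells default to the
    strict rule (``inclusion_radius = 0``): only cells carried by an
    included square survive.
    """
    H, W = shape
    if np.max(np.abs(s.offsets)) * 2 < np.hypot(H, W) - 2:
        raise ValueError("sinogram offset axis does not span the image diagonal")
    basis = build_square_basis(shape, k, p)
    codes = sinogram_scan_codes(s, basis, tau)

    cells = realized_cells(basis)
    cell_codes = map_cell_codes(codes, cells)
    _, statuses = apply_cell_corrections(cell_codes)
    keep = statuses == CellStatus.INSIDE
    ambiguous = statuses == CellStatus.AMBIGUOUS
    if ambiguous.any() and inclusion_radius > 0:
        included = ((codes[:, 0] == 1) & (codes[:, 2] == 0)).reshape(
            basis.n_rows, basis.n_cols
        )
        if included.any():
            keep |= ambiguous & included_square_near(
                cells, included, inclusion_radius
            )
    return PixelSpot(cells_to_mask(cells, keep))


def fbp_baseline(
    s: Sinogram, filter_name: str = "hann", output_size: int | None = None
) -> np.ndarray:
    """Classical filtered back-projection (comparison baseline only)."""
    if filter_name not in {"ramp", "hann"}:
        raise ValueError(f"unknown filter {filter_name!r}; use 'ramp' or 'hann'")
    if output_size is None:
        output_size = int((len(s.offsets) - 1) / np.sqrt(2.0))
    return iradon(
        s.values.T,
        theta=np.asarray(s.angles, dtype=float),
        filter_name=filter_name,
        output_size=output_size,
        circle=False,
    )
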