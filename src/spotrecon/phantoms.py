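"""Seeded synthetic figures and noise: every pipeline is testable offline.

The generators stand in for the classical test figures of qualitative
reconstruction experiments: a filled five-pointed star, an ellipse for the
tomography runs, a Shepp-Logan head phantom and a plateaued radial-ramp
disc for the grayscale layering, plus seeded noise models.  Identical
parameters (including the seed) always give bit-identical output.

Default geometries keep a margin of at least the scanning-square side from
the grid edge so every figure pixel is covered by a full complement of
squares.
"""

from __future__ import annotations

from dataclasses import dataclass, field
from typing import Any

import numpy as np
from skimage.data import shepp_logan_phantom
from skimage.draw import polygon
from skimage.transform import resize

from .radon import Sinogram
from .spots import PixelSpot

__all__ = [
    "PhantomSpec",
    "generate",
    "make_star",
    "make_ellipse",
    "make_circle",
    "make_shepp_logan",
    "make_ramp_disc",
    "add_saltpepper",
    "add_gaussian",
    "add_sinogram_salt",
]


def make_star(
    shape: tuple[int, int] = (128, 128),
    n_points: int = 5,
    r_outer: float | None = None,
    r_inner: float | None = None,
    rotation: float = -90.0,
) -> PixelSpot:
    """Filled star polygon centred on the grid (default: five points, one
    pointing up, radii 56/26 on a 128 grid and scaled with the grid)."""
    if r_outer is None:
        r_outer = 56.0 / 128.0 * min(shape)
    if r_inner is None:
        r_inner = 26.0 / 128.0 * min(shape)
    if not 0 < r_inner < r_outer:
        raise ValueError("need 0 < r_inner < r_outer")
    if r_outer > min(shape) / 2:
        raise ValueError("star does not fit the grid")
    H, W = shape
    cy, cx = (H - 1) / 2.0, (W - 1) / 2.0
    ang = np.deg2rad(rotation + 360.0 * np.arange(2 * n_points) / (2 * n_points))
    rad = np.where(np.arange(2 * n_points) % 2 == 0, r_outer, r_inner)
    rr, cc = polygon(cy + rad * np.sin(ang), cx + rad * np.cos(ang), shape)
    mask = np.zeros(shape, dtype=bool)
    mask[rr, cc] = True
    return PixelSpot(mask)


def make_ellipse(
    shape: tuple[int, int] = (128, 128),
    semi_a: float | None = None,
    semi_b: float | None = None,
    center: tuple[float, float] | None = None,
    angle: float = 0.0,
) -> PixelSpot:
    """Filled ellipse; ``semi_a`` lies along the (rotated) column axis.
    Default semi-axes are 40/24 on a 128 grid, scaled with the grid."""
    H, W = shape
    if semi_a is None:
        semi_a = 40.0 / 128.0 * min(shape)
    if semi_b is None:
        semi_b = 24.0 / 128.0 * min(shape)
    if center is None:
        center = ((H - 1) / 2.0, (W - 1) / 2.0)
    cy, cx = center
    r_max = max(semi_a, semi_b)
    if (
        cy - r_max < -0.5 or cy + r_max > H - 0.5
        or cx - r_max < -0.5 or cx + r_max > W - 0.5
    ):
        raise ValueError("ellipse out of bounds")
    yy, xx = np.mgrid[0:H, 0:W]
    th = np.deg2rad(angle)
    xr = (xx - cx) * np.cos(th) + (yy - cy) * np.sin(th)
    yr = -(xx - cx) * np.sin(th) + (yy - cy) * np.cos(th)
    return PixelSpot((xr / semi_a) ** 2 + (yr / semi_b) ** 2 <= 1.0)


def make_circle(
    shape: tuple[int, int] = (128, 128),
    radius: float | None = None,
    center: tuple[float, float] | None = None,
) -> PixelSpot:
    if radius is None:
        radius = 40.0 / 128.0 * min(shape)
    return make_ellipse(shape, radius, radius, center)


def make_shepp_logan(shape: tuple[int, int] = (128, 128)) -> np.ndarray:
    """The standard Shepp-Logan head phantom resampled to *shape*, in [0, 1]."""
    img = resize(
        shepp_logan_phantom(), shape, order=1, anti_aliasing=True, mode="constant"
    )
    return np.clip(img, 0.0, 1.0)


def make_ramp_disc(
    shape: tuple[int, int] = (128, 128),
    r_outer: float | None = None,
    r_core: float | None = None,
) -> np.ndarray:
    """Disc with a flat unit-intensity core and a linear radial ramp to 0.

    The core keeps every cumulative-threshold layer at least ``r_core`` in
    radius, well above the resolution limit of the scanning squares.
    Defaults: 48/20 on a 128 grid, scaled with the grid.
    """
    if r_outer is None:
        r_outer = 48.0 / 128.0 * min(shape)
    if r_core is None:
        r_core = 20.0 / 128.0 * min(shape)
    if not 0 < r_core < r_outer <= min(shape) / 2:
        raise ValueError("need 0 < r_core < r_outer <= min(shape)/2")
    H, W = shape
    yy, xx = np.mgrid[0:H, 0:W]
    r = np.hypot(yy - (H - 1) / 2.0, xx - (W - 1) / 2.0)
    return np.clip((r_outer - r) / (r_outer - r_core), 0.0, 1.0)


def add_saltpepper(a: PixelSpot, p_flip: float, seed: int) -> PixelSpot:
    """Flip every pixel independently with probability ``p_flip`` (seeded)."""
    if not 0.0 <= p_flip <= 1.0:
        raise ValueError("p_flip must lie in [0, 1]")
    rng = np.random.default_rng(seed)
    flips = rng.random(a.shape) < p_flip
    return PixelSpot(a.mask ^ flips)


def add_gaussian(img: np.ndarray, target_snr_db: float, seed: int) -> np.ndarray:
    """Additive white Gaussian noise calibrated to the requested SNR, where
    SNR(dB) = 20 log10(mean(img) / noise std)."""
    img = np.asarray(img, dtype=float)
    sigma = float(np.mean(img)) / 10.0 ** (target_snr_db / 20.0)
    rng = np.random.default_rng(seed)
    return img + rng.normal(0.0, sigma, img.shape)


def add_sinogram_salt(
    s: Sinogram, rate: float = 0.05, amplitude: float | None = None, seed: int = 0
) -> Sinogram:
    """Impulse ("salt") noise on a sinogram: each bin independently gains a
    positive impulse with probability *rate*, uniform in
    [amplitude/2, amplitude] (default amplitude = the sinogram maximum)."""
    if not 0.0 <= rate <= 1.0:
        raise ValueError("rate must lie in [0, 1]")
    rng = np.random.default_rng(seed)
    amp = float(np.max(s.values)) if amplitude is None else float(amplitude)
    hits = rng.random(s.values.shape) < rate
    impulses = rng.uniform(amp / 2.0, amp, s.values.shape)
    return Sinogram(s.angles, s.offsets, s.values + hits * impulses)


@dataclass(frozen=True)
class PhantomSpec:
    """Declarative phantom description: identical spec => identical raster."""

    kind: str  # star | ellipse | circle | shepp_logan | ramp_disc
    shape: tuple[int, int] = (128, 128)
    params: dict[str, Any] = field(default_factory=dict)
    seed: int = 0

    def __post_init__(self) -> None:
        if self.kind not in {"star", "ellipse", "circle", "shepp_logan", "ramp_disc"}:
            raise ValueError(f"unknown phantom kind {self.kind!r}")


def generate(spec: PhantomSpec) -> PixelSpot | np.ndarray:
    """Build the phantom a spec describes (binary spot or gray raster)."""
    makers = {
        "star": make_star,
        "ellipse": make_ellipse,
        "circle": make_circle,
        "shepp_logan": make_shepp_logan,
        "ramp_disc": make_ramp_disc,
    }
    return makers[spec.kind](spec.shape, **spec.params)
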