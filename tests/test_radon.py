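"""Sinograms, logical sinogram relations and the spot-based inverse Radon."""

import numpy as np
import pytest

from spotrecon import (
    PixelSpot,
    Sinogram,
    binarize_sinogram,
    build_square_basis,
    er_from_sinograms,
    fbp_baseline,
    forward_sinogram,
    make_circle,
    make_ellipse,
    misfit,
    radon_reconstruct,
    reconstruct_binary,
    scan_er,
    square_logical_sinogram,
)
from spotrecon.radon import sinogram_scan_codes


def angles(n):
    return np.arange(n) * 180.0 / n


class TestForwardSinogram:
    def test_center_pixel_peaks_at_zero_offset(self):
        a = PixelSpot.from_indices((31, 31), 15, 15)
        s = forward_sinogram(a, angles(12))
        mid = len(s.offsets) // 2
        for i in range(12):
            assert s.values[i].argmax() == mid
            assert s.values[i].sum() == pytest.approx(1.0, abs=1e-9)

    def test_axis_aligned_rectangle_profile(self, rect_factory):
        a = rect_factory((32, 32), 10, 8, 20, 24)  # height 10, width 16
        s = forward_sinogram(a, [0.0])
        # at 0 degrees rays integrate along rows: plateau of height 10
        assert s.values[0].max() == pytest.approx(10.0, abs=1e-9)
        assert np.isclose(s.values[0], 10.0, atol=1e-9).sum() == 15  # interior bins

    def test_mass_conservation_random_blob(self, rng):
        a = PixelSpot(rng.random((40, 40)) < 0.3)
        s = forward_sinogram(a, angles(18))
        assert np.allclose(s.values.sum(axis=1), a.area, rtol=1e-12)

    def test_empty_figure_warns_zero(self):
        with pytest.warns(UserWarning, match="empty"):
            s = forward_sinogram(PixelSpot.empty((16, 16)), angles(4))
        assert not s.values.any()

    def test_no_angles_rejected(self):
        with pytest.raises(ValueError):
            forward_sinogram(PixelSpot.full((8, 8)), [])

    def test_csv_roundtrip(self, tmp_path):
        s = forward_sinogram(make_circle((32, 32), radius=10), angles(6))
        s.to_csv(tmp_path / "s.csv")
        back = Sinogram.from_csv(tmp_path / "s.csv")
        assert np.allclose(back.values, s.values)
        assert np.allclose(back.angles, s.angles)
        assert np.allclose(back.offsets, s.offsets)


class TestLogicalSinograms:
    def test_binarize_trivia(self):
        s = forward_sinogram(make_circle((32, 32), radius=8), angles(4))
        assert not binarize_sinogram(Sinogram(s.angles, s.offsets, 0 * s.values)).bits.any()
        b0 = binarize_sinogram(s, 0.0)
        assert np.array_equal(b0.bits, s.values > 0)
        with pytest.raises(ValueError):
            binarize_sinogram(s, -1.0)

    def test_square_logical_matches_rasterized_square(self):
        """Dual route: the analytic interval support of a square must equal
        the thresholded rasterized sinogram of the same square."""
        basis = build_square_basis((32, 32), 5, 4)
        th = angles(8)
        for idx in (0, 3, len(basis) - 1):
            analytic = square_logical_sinogram(basis, idx, th, tau=0.5)
            raster = binarize_sinogram(
                forward_sinogram(PixelSpot(basis.square_mask(idx)), th), 0.5
            )
            assert np.array_equal(analytic.bits, raster.bits)

    def test_er_between_sinograms(self, rect_factory):
        shape = (48, 48)
        fig = rect_factory(shape, 8, 8, 24, 24)
        basis = build_square_basis(shape, 5, 1)
        th = angles(6)
        sa = binarize_sinogram(forward_sinogram(fig, th), 0.5)

        def square_bits(r, c):
            return square_logical_sinogram(basis, r * basis.n_cols + c, th, tau=0.5)

        inside = er_from_sinograms(sa, square_bits(12, 12))
        assert (inside.c11, inside.c21) == (1, 0)
        far = er_from_sinograms(sa, square_bits(38, 38))
        assert far.c11 in (0, 1)  # shadows may overlap at some angle
        straddle = er_from_sinograms(sa, square_bits(22, 22))
        assert (straddle.c11, straddle.c21) == (1, 1)
        assert inside.c12 == 1 and inside.c22 == 1  # fixed environment bits

    def test_er_grid_mismatch(self):
        s6 = binarize_sinogram(forward_sinogram(make_circle((32, 32), 8), angles(6)))
        s4 = binarize_sinogram(forward_sinogram(make_circle((32, 32), 8), angles(4)))
        with pytest.raises(ValueError):
            er_from_sinograms(s6, s4)

    @pytest.mark.parametrize("n_angles", [1, 3, 18])
    def test_inclusion_soundness_every_angle_count(self, n_angles):
        """A square fully inside the figure is sinogram-included (c21 = 0)
        regardless of the number of angles."""
        fig = make_ellipse((64, 64), semi_a=22, semi_b=14)
        basis = build_square_basis((64, 64), 5, 1)
        codes = sinogram_scan_codes(
            forward_sinogram(fig, angles(n_angles)), basis, 0.5
        )
        truly_inside = (basis.window_sums(fig.mask) == 25).ravel()
        assert (codes[truly_inside, 2] == 0).all()


class TestRadonReconstruct:
    def test_ellipse_reconstruction_compact(self):
        ell = make_ellipse((128, 128))
        s = forward_sinogram(ell, angles(18))
        rec = radon_reconstruct(s, (128, 128), 5, 1, 0.5)
        assert misfit(ell, rec) < 6.0
        # compact: reconstruction stays near the true figure
        yy, xx = np.mgrid[0:128, 0:128]
        inside_box = (np.abs(xx - 63.5) < 46) & (np.abs(yy - 63.5) < 30)
        assert not rec.mask[~inside_box].any()

    def test_converges_to_direct_scan_with_many_angles(self):
        ell = make_ellipse((128, 128))
        basis = build_square_basis((128, 128), 5, 1)
        r_rad = radon_reconstruct(forward_sinogram(ell, angles(90)), (128, 128), 5, 1)
        r_dir = reconstruct_binary(scan_er(ell, basis), basis)
        assert (r_rad.mask == r_dir.mask).mean() >= 0.99

    def test_geometry_mismatch(self):
        s = forward_sinogram(make_circle((32, 32), 8), angles(6))
        with pytest.raises(ValueError):
            radon_reconstruct(s, (128, 128), 5, 1)


class TestFBP:
    def test_unknown_filter(self):
        s = forward_sinogram(make_circle((32, 32), 8), angles(6))
        with pytest.raises(ValueError):
            fbp_baseline(s, "shepp")

    def test_linearity(self):
        a = forward_sinogram(make_circle((32, 32), 6, center=(12.0, 12.0)), angles(8))
        b = forward_sinogram(make_circle((32, 32), 5, center=(20.0, 20.0)), angles(8))
        both = Sinogram(a.angles, a.offsets, a.values + b.values)
        lhs = fbp_baseline(both, "hann", output_size=32)
        rhs = fbp_baseline(a, "hann", output_size=32) + fbp_baseline(
            b, "hann", output_size=32
        )
        assert np.allclose(lhs, rhs, atol=1e-9)

    def test_many_angle_disc_recovers(self):
        disc = make_circle((128, 128), radius=30)
        img = fbp_baseline(forward_sinogram(disc, angles(180)), "ramp", output_size=128)
        thr = img > 0.5
        iou = (thr & disc.mask).sum() / (thr | disc.mask).sum()
        assert iou > 0.9
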