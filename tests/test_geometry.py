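"""Centre detection, ray-length bound, polar resampling and back-projection."""

import numpy as np
import pytest
from hypothesis import given, settings
from hypothesis import strategies as st

from detrusor import (
    BModeImage,
    CenterDetectionError,
    CenterEstimate,
    ProbeGeometry,
    contour_to_cartesian,
    detect_center,
    invert_costs,
    max_ray_length,
    radial_gradient,
    resample_polar,
)


def image_from_profile(profile):
    """Image whose every column equals the given depth profile."""
    arr = np.tile(np.asarray(profile, float)[:, None], (1, 32))
    return BModeImage(pixels=np.clip(arr, 0, 255))


def center(row, col=16, spacing=0.2, peaks=None):
    peaks = peaks or (row - 10, row + 10)
    return CenterEstimate(
        row_px=row, col_px=col, depth_mm=row * spacing, peak_depths_px=peaks
    )


class TestDetectCenter:
    def test_two_gaussian_bumps_give_midpoint(self):
        rows = np.arange(600.0)
        profile = 40 + 150 * (
            np.exp(-((rows - 100) ** 2) / (2 * 15**2))
            + np.exp(-((rows - 500) ** 2) / (2 * 15**2))
        )
        est = detect_center(image_from_profile(profile))
        # oracle: dense grid search on an independently fitted quartic
        coeffs = np.polyfit(rows, profile, 4)
        dense = np.polyval(coeffs, np.linspace(0, 599, 60000))
        local_max = np.flatnonzero(
            (dense[1:-1] > dense[:-2]) & (dense[1:-1] >= dense[2:])
        )
        expected = np.linspace(0, 599, 60000)[local_max + 1].mean()
        assert est.row_px == pytest.approx(expected, abs=2)
        assert est.row_px == pytest.approx(300, abs=10)
        assert est.peak_depths_px[0] < est.row_px < est.peak_depths_px[1]

    def test_symmetric_profile_gives_axis_row(self):
        rows = np.arange(600.0)
        R = 300.0
        profile = 50 + 100 * np.exp(-((np.abs(rows - R) - 150) ** 2) / (2 * 20**2))
        est = detect_center(image_from_profile(profile))
        assert est.row_px == pytest.approx(R, abs=1)

    def test_monotone_profile_raises(self):
        with pytest.raises(CenterDetectionError):
            detect_center(image_from_profile(np.linspace(0, 200, 500)))

    def test_blank_image_raises(self):
        with pytest.raises(CenterDetectionError):
            detect_center(image_from_profile(np.zeros(500)))

    def test_invariant_to_intensity_offset(self):
        rows = np.arange(700.0)
        profile = 30 + 120 * (
            np.exp(-((rows - 150) ** 2) / (2 * 20**2))
            + np.exp(-((rows - 450) ** 2) / (2 * 20**2))
        )
        a = detect_center(image_from_profile(profile))
        b = detect_center(image_from_profile(profile + 40))
        assert a.row_px == b.row_px


class TestMaxRayLength:
    def test_zero_depth_gives_half_probe_width(self):
        assert max_ray_length(
            center(0, peaks=(-1, 1)), ProbeGeometry()
        ) == pytest.approx(15.0)

    def test_hand_evaluated_formula(self):
        c = CenterEstimate(row_px=250, col_px=16, depth_mm=50.0, peak_depths_px=(100, 400))
        rb = max_ray_length(c, ProbeGeometry(probe_width_mm=30, fov_deg=60))
        assert rb == pytest.approx(15 + 50 * np.tan(np.deg2rad(30)), abs=1e-9)
        assert rb == pytest.approx(43.87, abs=0.01)

    def test_arctan_variant_matches_printed_form(self):
        c = CenterEstimate(row_px=250, col_px=16, depth_mm=50.0, peak_depths_px=(100, 400))
        rb = max_ray_length(c, ProbeGeometry(), mode="arctan")
        assert rb == pytest.approx(15 + 50 * np.arctan(np.deg2rad(30)), abs=1e-9)

    def test_vanishing_fov_limit(self):
        c = center(100)
        assert max_ray_length(c, ProbeGeometry(fov_deg=1e-6)) == pytest.approx(15.0)

    @given(
        d1=st.floats(0, 100),
        d2=st.floats(0, 100),
        f1=st.floats(10, 120),
        f2=st.floats(10, 120),
    )
    @settings(max_examples=50, deadline=None)
    def test_monotone_in_depth_and_fov(self, d1, d2, f1, f2):
        mk = lambda d: CenterEstimate(
            row_px=max(int(d / 0.2), 1), col_px=0, depth_mm=d,
            peak_depths_px=(-1, max(int(d / 0.2), 1) + 1),
        )
        lo_d, hi_d = sorted([d1, d2])
        lo_f, hi_f = sorted([f1, f2])
        assert max_ray_length(mk(lo_d), ProbeGeometry(fov_deg=lo_f)) <= max_ray_length(
            mk(hi_d), ProbeGeometry(fov_deg=lo_f)
        ) + 1e-12
        assert max_ray_length(mk(lo_d), ProbeGeometry(fov_deg=lo_f)) <= max_ray_length(
            mk(lo_d), ProbeGeometry(fov_deg=hi_f)
        ) + 1e-12


class TestRadialGradient:
    def test_constant_image_zero_gradient(self):
        img = BModeImage(pixels=np.full((64, 64), 80.0))
        g = radial_gradient(img, center(32, 32))
        assert np.allclose(g, 0)

    def test_step_edge_peaks_at_edge_row(self):
        px = np.zeros((64, 64))
        px[40:, :] = 200.0
        img = BModeImage(pixels=px)
        g = radial_gradient(img, center(20, 32), smooth_sigma_px=1.0, mode="depth")
        assert np.argmax(g[:, 32]) in (39, 40)

    def test_phantom_wall_edge_polarity_on_midline(self, clean_phantom):
        s = clean_phantom
        c = detect_center(s.image)
        g = radial_gradient(s.image, c)
        # anterior midline above the centre: outward = decreasing row, so the
        # lumen->wall transition is a positive outward derivative (inner
        # boundary) and wall->tissue a negative one (outer boundary)
        col = g[: c.row_px, s.spec.apex_column]
        inner_rising = np.argmax(col[::-1])
        outer_falling = np.argmin(col[::-1])
        assert inner_rising < outer_falling  # inner (rising) is closer to the centre


class TestPolarResampling:
    def make_ring(self, radius_px, h=256, w=256, sigma=1.5):
        cy, cx = h // 2, w // 2
        yy, xx = np.mgrid[0:h, 0:w]
        dist = np.hypot(yy - cy, xx - cx)
        return np.exp(-((dist - radius_px) ** 2) / (2 * sigma**2)), center(cy, cx)

    def test_ring_peaks_at_ring_radius_on_every_ray(self):
        ring, c = self.make_ring(60)
        polar = resample_polar(ring, c, max_radius_mm=20.0, radial_step_mm=0.2,
                               pixel_spacing_mm=0.2)
        peaks = polar.values.argmax(axis=1)
        assert np.all(np.abs(peaks - 60) <= 1)

    def test_single_column_when_radius_below_step(self):
        ring, c = self.make_ring(10)
        polar = resample_polar(ring, c, max_radius_mm=0.15, radial_step_mm=0.2,
                               pixel_spacing_mm=0.2)
        assert polar.values.shape == (360, 1)

    def test_all_zero_gradient_gives_identical_rays(self):
        zeros = np.zeros((128, 128))
        polar = resample_polar(zeros, center(64, 64), 10.0, 0.2, 0.2)
        assert np.allclose(polar.values, polar.values[0])

    def test_center_outside_image_rejected(self):
        with pytest.raises(ValueError):
            resample_polar(np.zeros((32, 32)), center(100, 100), 5.0, 0.2, 0.2)


class TestInvertCosts:
    def test_definition_and_double_inversion(self):
        vals = np.tile(np.array([0.0, 2.0, 5.0]), (360, 1))
        from detrusor.geometry import PolarCostImage

        polar = PolarCostImage(values=vals, radial_step_mm=0.2, center=center(64, 64),
                               max_radius_mm=0.6)
        inv = invert_costs(polar)
        assert np.allclose(inv.values[0], [5.0, 3.0, 0.0])
        assert inv.values.min() == 0.0
        double = invert_costs(inv)
        assert np.allclose(double.values, vals - vals.min())

    def test_constant_field_inverts_to_zero(self):
        from detrusor.geometry import PolarCostImage

        polar = PolarCostImage(values=np.full((360, 5), 7.0), radial_step_mm=0.2,
                               center=center(10, 10), max_radius_mm=1.0)
        assert np.allclose(invert_costs(polar).values, 0.0)


class TestBackProjection:
    @pytest.mark.parametrize("radius_px", [10, 50, 150, 300])
    def test_polar_cartesian_round_trip_within_one_pixel(self, radius_px):
        h = w = 2 * radius_px + 64
        ring, c = TestPolarResampling().make_ring(radius_px, h=h, w=w)
        max_r_mm = (radius_px + 20) * 0.2
        polar = resample_polar(ring, c, max_r_mm, 0.2, 0.2)
        path = polar.values.argmax(axis=1)
        contour = contour_to_cartesian(path, polar)
        dist = np.hypot(contour.x - c.col_px, contour.y - c.row_px)
        assert np.all(np.abs(dist - radius_px) <= 1.0)

    def test_constant_radius_path_is_circle(self):
        from detrusor.geometry import PolarCostImage

        polar = PolarCostImage(values=np.zeros((360, 50)), radial_step_mm=0.2,
                               center=center(100, 100), max_radius_mm=10.0)
        contour = contour_to_cartesian(np.full(360, 25), polar)
        dist = np.hypot(contour.x - 100, contour.y - 100)
        assert np.allclose(dist, 25.0, atol=1e-9)

    def test_zero_radius_path_degenerates(self):
        from detrusor.geometry import PolarCostImage

        polar = PolarCostImage(values=np.zeros((360, 10)), radial_step_mm=0.2,
                               center=center(50, 50), max_radius_mm=2.0)
        contour = contour_to_cartesian(np.zeros(360, int), polar)
        assert np.allclose(contour.x, 50) and np.allclose(contour.y, 50)
        assert contour.to_mask((100, 100)).sum() <= 1
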