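"""Contour extraction, spline fitting, tangent angles and QC filters."""

import numpy as np
import pytest

from nanofil.contours import (
    FilamentContour,
    RejectionRecord,
    SegmentationConfig,
    extract_contour,
    fit_smooth_curve,
    qc_contour_length,
    qc_focal_plane,
    tangent_angles,
)
from nanofil.synthetics import RenderConfig, WlcParameters, render_filament_image, sample_wlc_contour


def render_line(angle=0.0, half_um=15.0, noise="none"):
    t = np.linspace(-half_um, half_um, 200) * 1e-6
    pts = np.column_stack([t * np.cos(angle), t * np.sin(angle)])
    cfg = RenderConfig(noise=noise, background=100.0)
    img = render_filament_image(FilamentContour.from_polyline(pts), cfg)
    return img, pts, cfg


class TestExtractContour:
    def test_straight_filament_round_trip(self):
        """Noise-free rendered line recovers an ordered chain close to the
        generating line (sub-pixel RMS off-axis)."""
        img, pts, cfg = render_line()
        seg = SegmentationConfig(pixel_size=cfg.pixel_size)
        chain = extract_contour(img, seg)
        assert isinstance(chain, np.ndarray)
        # the generating line is horizontal through the image center
        h = img.shape[0]
        y_line = (h / 2 - 0.5) * cfg.pixel_size
        rms = np.sqrt(np.mean((chain[:, 1] - y_line) ** 2)) / cfg.pixel_size
        assert rms < 0.5

    def test_blank_image_rejected(self):
        img = np.full((64, 64), 100.0)
        rec = extract_contour(img, SegmentationConfig())
        assert isinstance(rec, RejectionRecord)
        assert rec.reason == "no object"

    def test_two_objects_rejected(self):
        img = np.full((64, 64), 100.0)
        img[10:12, 5:40] = 1000.0
        img[50:52, 5:40] = 1000.0
        rec = extract_contour(img, SegmentationConfig())
        assert isinstance(rec, RejectionRecord)
        assert rec.reason == "multiple objects"


class TestFitSmoothCurve:
    def test_straight_segment_length(self):
        t = np.linspace(0, 20e-6, 40)
        pts = np.column_stack([t, np.zeros_like(t)])
        c = fit_smooth_curve(pts)
        assert c.length == pytest.approx(20e-6, rel=1e-3)

    def test_semicircle_arc_length(self):
        R = 5e-6
        th = np.linspace(0, np.pi, 60)
        pts = np.column_stack([R * np.cos(th), R * np.sin(th)])
        c = fit_smooth_curve(pts)
        assert c.length == pytest.approx(np.pi * R, rel=0.01)

    def test_reversal_invariance(self):
        rng = np.random.default_rng(0)
        t = np.linspace(0, 1, 50)
        pts = np.column_stack([t * 20e-6, 2e-6 * np.sin(4 * t)])
        a = fit_smooth_curve(pts).length
        b = fit_smooth_curve(pts[::-1]).length
        assert b == pytest.approx(a, rel=1e-3)

    def test_too_few_points(self):
        with pytest.raises(ValueError):
            fit_smooth_curve(np.zeros((5, 2)))

    @pytest.mark.parametrize("lp_um", [3.0, 10.0])
    def test_wlc_ground_truth_points_length(self, lp_um):
        """Given exact contour points (no imaging), the spline stage
        reproduces the chain length within 3% even for flexible chains."""
        p = WlcParameters(
            contour_length=30e-6, persistence_length=lp_um * 1e-6, arc_step=0.3e-6, seed=5
        )
        c = sample_wlc_contour(p)
        fitted = fit_smooth_curve(c.points, smoothing=0.0)
        assert fitted.length == pytest.approx(c.length, rel=0.03)


class TestTangentAngles:
    def test_straight_segment_constant_angle(self):
        t = np.linspace(0, 20e-6, 40)
        pts = np.column_stack([t * np.cos(np.pi / 6), t * np.sin(np.pi / 6)])
        prof = tangent_angles(fit_smooth_curve(pts), 1e-6)
        assert np.allclose(prof.angles, np.pi / 6, atol=1e-6)

    def test_circle_arc_curvature(self):
        R = 5e-6
        th = np.linspace(0, np.pi, 200)
        pts = np.column_stack([R * np.cos(th), R * np.sin(th)])
        prof = tangent_angles(fit_smooth_curve(pts, smoothing=0.0), 0.2e-6)
        dtheta_ds = np.gradient(prof.angles, prof.stations)
        interior = slice(5, -5)
        assert np.abs(dtheta_ds[interior]) == pytest.approx(1 / R, rel=0.01)

    def test_unwrapping_spans_three_half_pi(self):
        R = 5e-6
        th = np.linspace(0, 1.5 * np.pi, 300)
        pts = np.column_stack([R * np.cos(th), R * np.sin(th)])
        prof = tangent_angles(fit_smooth_curve(pts, smoothing=0.0), 0.2e-6)
        assert np.all(np.abs(np.diff(prof.angles)) < 0.5)
        assert abs(prof.angles[-1] - prof.angles[0]) == pytest.approx(1.5 * np.pi, rel=0.02)

    def test_polyline_contour_reproduces_generator_angles(self):
        """Tangent profiles read off a ground-truth WLC polyline equal the
        generating segment angles to machine precision."""
        from nanofil.synthetics import sample_wlc_angles

        p = WlcParameters(seed=4)
        theta = sample_wlc_angles(p)
        c = sample_wlc_contour(p)
        prof = tangent_angles(c, p.arc_step)
        # stations fall on segment boundaries; compare to generator angles
        n = min(len(theta), len(prof.angles))
        d = np.unwrap(theta[:n]) - prof.angles[:n]
        assert np.sqrt(np.mean((d - d.mean()) ** 2)) < 1e-6

    def test_coarse_spacing_rejected(self):
        t = np.linspace(0, 20e-6, 40)
        c = fit_smooth_curve(np.column_stack([t, np.zeros_like(t)]))
        with pytest.raises(ValueError):
            tangent_angles(c, c.length / 5)


class TestPipelineInvariance:
    def test_translation_and_rotation_of_image(self):
        """Contour length is invariant under image translation and 90-degree
        rotation; tangent angles shift by exactly pi/2 under the rotation."""
        img, _, cfg = render_line(angle=np.pi / 6)
        seg = SegmentationConfig(pixel_size=cfg.pixel_size)
        base = fit_smooth_curve(extract_contour(img, seg))

        rolled = np.roll(img, (7, -4), axis=(0, 1))
        shifted = fit_smooth_curve(extract_contour(rolled, seg))
        assert shifted.length == pytest.approx(base.length, rel=0.01)

        rotated = np.rot90(img)
        rot = fit_smooth_curve(extract_contour(rotated, seg))
        assert rot.length == pytest.approx(base.length, rel=0.01)
        a0 = tangent_angles(base, 1e-6).angles.mean() % np.pi
        a1 = tangent_angles(rot, 1e-6).angles.mean() % np.pi
        delta = (a1 - a0) % np.pi
        assert min(delta, np.pi - delta) == pytest.approx(np.pi / 2, abs=0.05)


class TestQc:
    def test_constant_length_kept(self):
        keep, mean, rel = qc_contour_length([10.0, 10.0, 10.0])
        assert keep and mean == 10.0 and rel == 0.0

    @pytest.mark.parametrize("spread, expect_keep", [(0.05, True), (0.15, False)])
    def test_ten_percent_rule(self, spread, expect_keep):
        base = 40e-6
        series = [base * (1 - spread / 2), base, base * (1 + spread / 2)]
        keep, _, _ = qc_contour_length(series)
        assert keep is expect_keep

    def test_empty_series_raises(self):
        with pytest.raises(ValueError):
            qc_contour_length([40e-6])

    def test_focal_slab(self):
        z = np.array([0.0, 8e-6, -3e-6, 6e-6])
        mask = qc_focal_plane(z, slab_half_width=5e-6)
        assert mask.tolist() == [True, False, True, False]

    def test_focal_exclusion_count_matches_ground_truth(self):
        rng = np.random.default_rng(12)
        z = rng.uniform(-10e-6, 10e-6, size=200)
        mask = qc_focal_plane(z, slab_half_width=5e-6)
        assert (~mask).sum() == int(np.sum(np.abs(z) > 5e-6))


class TestRoundTripLength:
    @pytest.mark.parametrize("lp_um", [25.0, 50.0, 100.0])
    def test_rendered_wlc_length_within_three_percent(self, lp_um):
        """Rendering + extraction + spline fit recovers the generating
        contour length within 3% for gently curved filaments (strongly
        coiled chains self-overlap in the image and are a QC matter, not
        a length-accuracy one)."""
        p = WlcParameters(
            contour_length=30e-6, persistence_length=lp_um * 1e-6, arc_step=0.3e-6, seed=21
        )
        c = sample_wlc_contour(p)
        cfg = RenderConfig(noise="poisson", shape=(256, 256))
        img = render_filament_image(c, cfg, rng=np.random.default_rng(0))
        seg = SegmentationConfig(pixel_size=cfg.pixel_size)
        chain = extract_contour(img, seg)
        assert isinstance(chain, np.ndarray)
        fitted = fit_smooth_curve(chain)
        assert fitted.length == pytest.approx(c.length, rel=0.03)
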