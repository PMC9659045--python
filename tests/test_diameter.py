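"""Transverse profiles, FWHM diameters, and vessel classification."""

import numpy as np
import pytest

from microflow.diameter import (TransverseProfile, classify_vessel,
                                compute_normals, fwhm_diameter, sample_profile,
                                vessel_diameter)
from microflow.geometry import CenterlinePath
from microflow.synth import SceneSpec, VesselSpec, render_scene


def gaussian_dip(sigma, half=None, depth=1.0, shoulders=1.0):
    half = half or max(40, int(6 * sigma))
    pos = np.arange(-half, half + 1, dtype=float)
    vals = shoulders - depth * np.exp(-pos ** 2 / (2 * sigma ** 2))
    return TransverseProfile(pos, vals, half)


class TestComputeNormals:
    def test_horizontal_path_has_vertical_normals(self):
        path = CenterlinePath(np.column_stack([np.full(50, 7.0), np.arange(50.0)]))
        normals = compute_normals(path, interval_px=10)
        assert len(normals) == 5
        for _, n in normals:
            assert abs(n[0]) == pytest.approx(1.0) and n[1] == pytest.approx(0.0)

    def test_circle_arc_normals_are_radial(self):
        t = np.linspace(0, np.pi / 2, 200)
        r = 40.0
        pts = np.column_stack([50 + r * np.sin(t), 50 + r * np.cos(t)])
        path = CenterlinePath(pts)
        for (p, n) in compute_normals(path, interval_px=5)[2:-2]:
            radial = (p - [50, 50]) / np.linalg.norm(p - [50, 50])
            assert abs(np.dot(n, radial)) > 0.99

    def test_interval_equal_to_length(self):
        path = CenterlinePath(np.column_stack([np.full(21, 0.0), np.arange(21.0)]))
        assert len(compute_normals(path, interval_px=20)) == 2  # s = 0 and 20

    def test_too_short_rejected(self):
        path = CenterlinePath(np.array([[0.0, 0.0], [0.0, 3.0]]))
        with pytest.raises(ValueError, match="shorter"):
            compute_normals(path, interval_px=10)


class TestSampleProfile:
    def test_constant_image(self):
        img = np.full((40, 40), 0.3)
        prof = sample_profile(img, (20, 20), (1, 0), half_length_px=10)
        assert np.allclose(prof.values, 0.3)
        assert len(prof.values) == 21

    def test_dark_band_minimum_at_center(self):
        img = np.ones((40, 40))
        img[19:22] = 0.2
        prof = sample_profile(img, (20, 20), (1, 0), half_length_px=12)
        assert abs(int(np.argmin(prof.values)) - prof.center_index) <= 1

    def test_non_unit_normal_normalized(self):
        img = np.random.default_rng(0).uniform(size=(40, 40))
        a = sample_profile(img, (20, 20), (1, 0), half_length_px=8)
        b = sample_profile(img, (20, 20), (7, 0), half_length_px=8)
        assert np.array_equal(a.values, b.values)

    def test_out_of_frame_rejected(self):
        img = np.zeros((20, 20))
        with pytest.raises(ValueError, match="exits frame"):
            sample_profile(img, (10, 2), (0, 1), half_length_px=8)


class TestFwhm:
    def test_rectangular_dip_exact(self):
        for w in [5, 9, 21]:
            pos = np.arange(-30, 31, dtype=float)
            vals = np.where(np.abs(pos) <= (w - 1) / 2, 0.2, 0.9)
            est = fwhm_diameter(TransverseProfile(pos, vals, 30), 1.0)
            assert est.fwhm_px == pytest.approx(float(w), abs=1e-9)

    @pytest.mark.parametrize("sigma", [2, 4, 8, 16])
    def test_gaussian_dip_analytic(self, sigma):
        est = fwhm_diameter(gaussian_dip(sigma), 1.0)
        assert est.fwhm_px == pytest.approx(2 * np.sqrt(2 * np.log(2)) * sigma,
                                            abs=0.25)

    def test_asymmetric_shoulder_level(self):
        """p_L=100, p_R=80, m=40 -> level 40 + (90-40)/2 = 65."""
        pos = np.arange(-10, 11, dtype=float)
        vals = np.full(21, 80.0)
        vals[:5] = 100.0
        vals[8:13] = [60.0, 50.0, 40.0, 50.0, 60.0]
        est = fwhm_diameter(TransverseProfile(pos, vals, 10), 1.0)
        assert est.level_half_max == pytest.approx(65.0)

    def test_pixel_size_scales_micrometers(self):
        est = fwhm_diameter(gaussian_dip(4), 0.64)
        assert est.fwhm_um == pytest.approx(est.fwhm_px * 0.64)

    def test_monotone_profile_rejected(self):
        pos = np.arange(-10, 11, dtype=float)
        with pytest.raises(ValueError, match="dip"):
            fwhm_diameter(TransverseProfile(pos, pos * 0.1 + 5, 10), 1.0)

    def test_contrast_invariance_is_exact(self):
        """Affine intensity changes (a*I + b, a > 0) leave FWHM unchanged."""
        prof = gaussian_dip(5)
        base = fwhm_diameter(prof, 1.0).fwhm_px
        scaled = TransverseProfile(prof.positions, 3.7 * prof.values + 11.0,
                                   prof.center_index)
        assert fwhm_diameter(scaled, 1.0).fwhm_px == pytest.approx(base,
                                                                   rel=1e-12)

    def test_crossings_match_oversampled_oracle(self):
        """Linear-interpolated crossings vs 100x-oversampled brute force."""
        for sigma in [3, 6, 11]:
            prof = gaussian_dip(sigma)
            est = fwhm_diameter(prof, 1.0)
            fine = np.arange(prof.positions[0], prof.positions[-1], 0.01)
            vals = np.interp(fine, prof.positions, prof.values)
            below = fine[vals <= est.level_half_max]
            assert est.left_px == pytest.approx(below[0], abs=0.05)
            assert est.right_px == pytest.approx(below[-1], abs=0.05)


class TestClassify:
    @pytest.mark.parametrize("d,cls", [
        (19.9, "capillary"),
        (20.0, "arteriole_vein"),
        (100.0, "arteriole_vein"),
        (100.1, "out_of_range"),
        (150.0, "out_of_range"),
    ])
    def test_boundaries(self, d, cls):
        assert classify_vessel(d) == cls

    def test_nonpositive_rejected(self):
        with pytest.raises(ValueError):
            classify_vessel(0.0)


class TestVesselDiameter:
    @staticmethod
    def _scene(width_um, seed=3, angle_offset=30):
        return SceneSpec(
            height_px=160, width_px=200, noise_sd=0.01, jitter_px=0,
            vessels=[VesselSpec(polyline_points=[(10, 60), (190, 60 + angle_offset)],
                                width_um=width_um, velocity_um_s=100.0,
                                rbc_rate=10.0)],
            seed=seed)

    def test_30um_vessel_recovered(self):
        seq, truth = render_scene(self._scene(30.0))
        frame = np.median(seq.green(), axis=0)
        est = vessel_diameter(frame, truth.centerlines[0], interval_px=10,
                              half_length_px=55, pixel_size_um=0.64)
        assert est.fwhm_um == pytest.approx(30.0, abs=2.0)
        assert est.vessel_class == "arteriole_vein"

    def test_capillary_classified(self):
        seq, truth = render_scene(self._scene(12.0))
        frame = np.median(seq.green(), axis=0)
        est = vessel_diameter(frame, truth.centerlines[0], interval_px=10,
                              half_length_px=40, pixel_size_um=0.64)
        assert est.vessel_class == "capillary"

    def test_width_sweep_monotone(self):
        medians = []
        for wum in [8.0, 16.0, 30.0, 42.0]:
            seq, truth = render_scene(self._scene(wum))
            frame = np.median(seq.green(), axis=0)
            est = vessel_diameter(frame, truth.centerlines[0], interval_px=15,
                                  half_length_px=60, pixel_size_um=0.64)
            medians.append(est.fwhm_um)
        assert all(a < b for a, b in zip(medians, medians[1:]))

    def test_rotation_invariance(self):
        """A ~30-degree tilt changes the median FWHM by < 0.5 px."""
        flat = SceneSpec(height_px=160, width_px=200, noise_sd=0.01,
                         texture_sd=0.02,
                         vessels=[VesselSpec([(10, 80), (190, 80)], 25.0, 100.0,
                                             rbc_rate=10.0)], seed=3)
        tilted = SceneSpec(height_px=160, width_px=200, noise_sd=0.01,
                           texture_sd=0.02,
                           vessels=[VesselSpec([(10, 25), (190, 129)], 25.0, 100.0,
                                               rbc_rate=10.0)], seed=3)
        w = []
        for spec in (flat, tilted):
            seq, truth = render_scene(spec)
            w.append(vessel_diameter(np.median(seq.green(), axis=0),
                                     truth.centerlines[0], 5, 50, 1.0).fwhm_px)
        assert abs(w[0] - w[1]) < 0.5

    def test_all_failing_normals_is_error(self):
        img = np.full((60, 60), 0.5)
        path = CenterlinePath(np.column_stack([np.full(30, 30.0),
                                               np.arange(10.0, 40.0)]))
        with pytest.raises(ValueError, match="no valid"):
            vessel_diameter(img, path, 10, 15, 1.0)
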