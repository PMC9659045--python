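"""Vesselness, patch protocol, mask metrics, thinning and tracing."""

import numpy as np
import pytest
from hypothesis import given, settings
from hypothesis import strategies as st

from microflow.segment import (enhance_vessels, evaluate_segmentation,
                               extract_centerlines, extract_patches,
                               segment_vessels, skeletonize, stitch_patches,
                               trace_centerline)
from microflow.synth import SceneSpec, VesselSpec, render_scene


def _vessel_scene(width_um, seed=3):
    return SceneSpec(
        height_px=128, width_px=200, noise_sd=0.01, jitter_px=0,
        vessels=[VesselSpec(polyline_points=[(10, 40), (190, 70)],
                            width_um=width_um, velocity_um_s=100.0,
                            rbc_rate=10.0)],
        seed=seed)


class TestEnhanceVessels:
    def test_constant_image_gives_zeros(self):
        assert np.all(enhance_vessels(np.full((32, 32), 0.5)) == 0)

    def test_ridge_on_dark_vessel_centerline(self):
        """Response argmax per column sits within 1 px of the centerline."""
        spec = _vessel_scene(8.0)
        seq, truth = render_scene(spec)
        frame = np.median(seq.green(), axis=0)
        enh = enhance_vessels(frame, scales_px=(2, 4, 8))
        path = truth.centerlines[0]
        for s in np.linspace(20, path.length - 20, 9):
            y, x = path.point_at(s)
            col = int(round(x))
            assert abs(np.argmax(enh[:, col]) - y) <= 1.0

    def test_bright_vessel_suppressed(self):
        """Polarity contract: an inverted (bright) vessel barely responds."""
        spec = _vessel_scene(8.0)
        seq, truth = render_scene(spec)
        frame = np.median(seq.green(), axis=0)
        dark = enhance_vessels(frame, scales_px=(2, 4, 8))
        bright = enhance_vessels(frame.max() - frame, scales_px=(2, 4, 8))
        inside = truth.vessel_mask
        assert bright[inside].mean() < 0.1 * dark[inside].mean()

    def test_bad_scales_rejected(self):
        with pytest.raises(ValueError):
            enhance_vessels(np.zeros((8, 8)), scales_px=[])


class TestSegmentVessels:
    def test_zero_enhancement_empty_mask(self):
        assert segment_vessels(np.zeros((16, 16)), threshold=0.5).sum() == 0

    def test_threshold_above_max_empty(self):
        img = np.random.default_rng(0).uniform(0, 0.9, (16, 16))
        assert segment_vessels(img, threshold=1.0, min_object_px=0).sum() == 0

    @pytest.mark.parametrize("width_um", [3.2, 10.0, 30.0])
    def test_synthetic_scene_accuracy(self, width_um):
        seq, truth = render_scene(_vessel_scene(width_um))
        frame = np.median(seq.green(), axis=0)
        mask = segment_vessels(enhance_vessels(frame))
        m = evaluate_segmentation(mask, truth.vessel_mask)
        assert m.accuracy >= 0.95


class TestPatches:
    def test_single_patch_exact_fit(self):
        img = np.arange(256 * 256, dtype=float).reshape(256, 256)
        patches = extract_patches(img, 256, 256)
        assert len(patches) == 1 and patches[0][1] == (0, 0)

    def test_300_image_patch256_stride128_origins(self):
        img = np.zeros((300, 300))
        origins = {o for _, o in extract_patches(img, 256, 128)}
        assert origins == {(0, 0), (0, 44), (44, 0), (44, 44)}

    def test_stride_beyond_patch_rejected(self):
        with pytest.raises(ValueError):
            extract_patches(np.zeros((300, 300)), 64, 65)

    def test_two_overlapping_constants_average(self):
        patches = [(np.zeros((4, 4)), (0, 0)), (np.ones((4, 4)), (0, 2))]
        out = stitch_patches(patches, (4, 6))
        assert np.all(out[:, 2:4] == 0.5)

    def test_uncovered_pixel_rejected(self):
        with pytest.raises(ValueError, match="uncovered"):
            stitch_patches([(np.ones((2, 2)), (0, 0))], (4, 4))

    @settings(max_examples=25, deadline=None, derandomize=True)
    @given(h=st.integers(20, 60), w=st.integers(20, 60),
           patch=st.integers(8, 20), stride=st.integers(1, 20), seed=st.integers(0, 99))
    def test_extract_stitch_identity(self, h, w, patch, stride, seed):
        """extract -> stitch reproduces any image bit-exactly."""
        stride = min(stride, patch)
        patch = min(patch, h, w)
        stride = min(stride, patch)
        img = np.random.default_rng(seed).uniform(0, 1, (h, w)).astype(np.float32)
        out = stitch_patches(extract_patches(img, patch, stride), (h, w))
        assert np.array_equal(out, img.astype(np.float64))

    def test_random_patchset_matches_bruteforce(self):
        rng = np.random.default_rng(1)
        shape = (12, 15)
        patches = []
        for _ in range(12):
            ph, pw = rng.integers(2, 6, 2)
            oy = int(rng.integers(0, shape[0] - ph + 1))
            ox = int(rng.integers(0, shape[1] - pw + 1))
            patches.append((rng.uniform(0, 1, (ph, pw)), (oy, ox)))
        patches.append((np.ones(shape), (0, 0)))  # guarantee coverage
        acc = np.zeros(shape)
        cnt = np.zeros(shape)
        for p, (oy, ox) in patches:
            for i in range(p.shape[0]):
                for j in range(p.shape[1]):
                    acc[oy + i, ox + j] += p[i, j]
                    cnt[oy + i, ox + j] += 1
        assert np.array_equal(stitch_patches(patches, shape), acc / cnt)


class TestMetrics:
    def test_perfect_and_inverted(self):
        truth = np.array([[1, 0], [0, 1]])
        m = evaluate_segmentation(truth, truth)
        assert (m.accuracy, m.recall, m.specificity) == (1.0, 1.0, 1.0)
        m = evaluate_segmentation(1 - truth, truth)
        assert (m.accuracy, m.recall, m.specificity) == (0.0, 0.0, 0.0)

    def test_undefined_ratios_are_missing(self):
        empty = np.zeros((3, 3), dtype=bool)
        m = evaluate_segmentation(empty, empty)
        assert m.recall is None and m.accuracy == 1.0

    def test_shape_mismatch(self):
        with pytest.raises(ValueError):
            evaluate_segmentation(np.zeros((2, 2)), np.zeros((3, 3)))

    @settings(max_examples=60, deadline=None, derandomize=True)
    @given(pred=st.integers(0, 511), truth=st.integers(0, 511))
    def test_matches_bruteforce_confusion_on_3x3(self, pred, truth):
        p = np.array([(pred >> i) & 1 for i in range(9)]).reshape(3, 3)
        t = np.array([(truth >> i) & 1 for i in range(9)]).reshape(3, 3)
        tp = sum(int(p[i, j] and t[i, j]) for i in range(3) for j in range(3))
        tn = sum(int(not p[i, j] and not t[i, j]) for i in range(3) for j in range(3))
        fp = int(p.sum()) - tp
        fn = int(t.sum()) - tp
        m = evaluate_segmentation(p, t)
        assert m.accuracy == (tp + tn) / 9
        assert m.recall == (tp / (tp + fn) if tp + fn else None)
        assert m.specificity == (tn / (tn + fp) if tn + fp else None)


class TestSkeleton:
    def test_ribbon_thins_to_line(self):
        bar = np.zeros((9, 100), dtype=bool)
        bar[2:7] = True
        sk = skeletonize(bar)
        assert np.all(sk[:, 10:90].sum(axis=0) == 1)

    def test_empty_mask(self):
        assert skeletonize(np.zeros((5, 5), dtype=bool)).sum() == 0

    def test_skeleton_subset_and_idempotent(self):
        seq, truth = render_scene(_vessel_scene(10.0))
        mask = segment_vessels(enhance_vessels(np.median(seq.green(), axis=0)))
        sk = skeletonize(mask)
        assert np.all(mask[sk])
        assert np.array_equal(skeletonize(sk), sk)

    def test_skeleton_near_true_centerline(self):
        seq, truth = render_scene(_vessel_scene(10.0))
        sk = skeletonize(truth.vessel_mask)
        pts = np.argwhere(sk)
        path = truth.centerlines[0].resample(0.5)
        from scipy.spatial import cKDTree
        d, _ = cKDTree(path.points).query(pts)
        assert np.mean(d) <= 1.0


class TestTraceCenterline:
    def test_straight_line(self):
        line = np.zeros((5, 50), dtype=bool)
        line[2] = True
        p = trace_centerline(line, (2, 0))
        assert len(p.points) == 50
        assert p.length == 49.0
        assert np.allclose(p.tangents, [0.0, 1.0])

    def test_corner_stops_only_at_branch(self):
        """Degree decides: an L-corner with a diagonal-degree-3 pixel stops
        the walk there; a smooth diagonal continues to the far end."""
        L = np.zeros((20, 20), dtype=bool)
        L[2, 2:15] = True
        L[2:15, 2] = True
        p = trace_centerline(L, (2, 14))
        assert tuple(p.points[-1]) == (2.0, 3.0)  # (3,2) is 8-adjacent to (2,3)
        diag = np.zeros((20, 20), dtype=bool)
        for i in range(12):
            diag[2 + i, 2 + i] = True
        p = trace_centerline(diag, (2, 2))
        assert tuple(p.points[-1]) == (13.0, 13.0)

    def test_isolated_pixel_rejected(self):
        iso = np.zeros((5, 5), dtype=bool)
        iso[2, 2] = True
        with pytest.raises(ValueError, match="degree"):
            trace_centerline(iso, (2, 2))

    def test_interior_pixel_rejected(self):
        line = np.zeros((5, 50), dtype=bool)
        line[2] = True
        with pytest.raises(ValueError, match="degree"):
            trace_centerline(line, (2, 25))

    def test_extract_centerlines_on_scene(self):
        seq, truth = render_scene(_vessel_scene(10.0))
        mask = segment_vessels(enhance_vessels(np.median(seq.green(), axis=0)))
        paths = extract_centerlines(skeletonize(mask), min_length_px=30)
        assert len(paths) >= 1
        assert max(p.length for p in paths) > 100
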