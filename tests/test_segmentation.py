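"""Distance map, Roberts operator, blob counting — with brute-force oracles."""

import numpy as np
import pytest
from scipy import ndimage

from reefwatch.segmentation import (
    ROIPolygon,
    SegmentationParams,
    background_mean,
    distance_map,
    roberts_edges,
    segment_and_count,
)
from reefwatch.synthetic import render_scene, sample_fish


def roberts_oracle(f):
    """Roberts magnitude via explicit 2x2 kernel convolution."""
    k1 = np.array([[1.0, 0.0], [0.0, -1.0]])
    k2 = np.array([[0.0, 1.0], [-1.0, 0.0]])
    h, w = f.shape
    g1 = np.zeros((h - 1, w - 1))
    g2 = np.zeros((h - 1, w - 1))
    for i in range(h - 1):
        for j in range(w - 1):
            win = f[i:i + 2, j:j + 2]
            g1[i, j] = (win * k1).sum()
            g2[i, j] = (win * k2).sum()
    return np.sqrt(g1 ** 2 + g2 ** 2)


def flood_fill_components(mask):
    """8-connected component count by explicit stack-based flood fill."""
    mask = mask.copy()
    h, w = mask.shape
    count = 0
    for i0 in range(h):
        for j0 in range(w):
            if not mask[i0, j0]:
                continue
            count += 1
            stack = [(i0, j0)]
            mask[i0, j0] = False
            while stack:
                i, j = stack.pop()
                for di in (-1, 0, 1):
                    for dj in (-1, 0, 1):
                        ni, nj = i + di, j + dj
                        if 0 <= ni < h and 0 <= nj < w and mask[ni, nj]:
                            mask[ni, nj] = False
                            stack.append((ni, nj))
    return count


class TestBackgroundAndDistance:
    def test_constant_image(self):
        img = np.full((40, 40, 3), (10, 20, 30), dtype=np.uint8)
        assert np.array_equal(background_mean(img, (5, 5, 25, 25)), [10, 20, 30])

    def test_half_and_half_region(self):
        img = np.zeros((10, 10, 3))
        img[:5] = 40.0
        img[5:] = 80.0
        assert np.allclose(background_mean(img, (0, 0, 10, 10)), 60.0)

    def test_region_outside_rejected(self):
        with pytest.raises(ValueError, match="outside"):
            background_mean(np.zeros((5, 5, 3)), (0, 0, 10, 10))

    def test_distance_zero_at_background(self):
        img = np.full((4, 4, 3), 77.0)
        assert np.all(distance_map(img, [77, 77, 77]) == 0)

    def test_distance_black_to_white(self):
        img = np.full((2, 2, 3), 255.0)
        d = distance_map(img, [0, 0, 0])
        assert np.allclose(d, 255 * np.sqrt(3))

    def test_distance_hand_value(self):
        img = np.array([[[103, 104, 112]]], dtype=float)
        assert distance_map(img, [100, 100, 100])[0, 0] == pytest.approx(13.0)


class TestRoberts:
    def test_constant_field_is_flat(self):
        assert np.all(roberts_edges(np.full((8, 9), 3.7)) == 0)

    def test_vertical_step(self):
        h = 5.0
        f = np.zeros((4, 4))
        f[:, 2:] = h
        mag = roberts_edges(f)
        # diagonal pairs straddling the step see h on both kernels
        assert np.allclose(mag[:, 1], h * np.sqrt(2))
        assert np.all(mag[:, [0, 2]] == 0)

    def test_single_impulse(self):
        h = 4.0
        f = np.zeros((5, 5))
        f[2, 2] = h
        mag = roberts_edges(f)
        assert mag.max() == pytest.approx(h)  # each kernel sees the impulse once
        assert np.count_nonzero(mag) == 4    # its four 2x2 neighborhoods
        assert np.allclose(mag, roberts_oracle(f))

    @pytest.mark.parametrize("seed", range(5))
    def test_matches_convolution_oracle_on_random_fields(self, seed):
        rng = np.random.default_rng(seed)
        f = rng.uniform(0, 255, (12, 17))
        assert np.allclose(roberts_edges(f), roberts_oracle(f), atol=1e-12)

    def test_too_small_field_rejected(self):
        with pytest.raises(ValueError):
            roberts_edges(np.zeros((1, 5)))


class TestROIPolygon:
    def test_degenerate_rejected(self):
        with pytest.raises(ValueError):
            ROIPolygon(np.array([[0, 0], [1, 1], [2, 2]], float))

    def test_self_intersecting_rejected(self):
        bowtie = np.array([[0, 0], [10, 10], [0, 10], [10, 0]], float)
        with pytest.raises(ValueError, match="intersect"):
            ROIPolygon(bowtie)

    def test_contains_matches_mask(self):
        roi = ROIPolygon(np.array([[2, 3], [2, 17], [14, 17], [14, 3]], float))
        mask = roi.mask((20, 20))
        pts = np.array([[5.0, 5.0], [1.0, 1.0], [13.0, 16.0], [19.0, 19.0]])
        assert list(roi.contains(pts)) == [True, False, True, False]
        assert mask[5, 5] and not mask[1, 1]


class TestCounting:
    def test_blank_panel_counts_zero(self, small_scene, small_center):
        img, _ = render_scene(small_scene(noise_sigma=1.5, seed=2))
        res = segment_and_count(img, small_scene().roi, small_center)
        assert res.count == 0
        assert res.objects == []

    @pytest.mark.parametrize("k", [1, 3, 6, 8])
    def test_counts_k_disjoint_fish(self, small_scene, small_center, k):
        spec = small_scene(noise_sigma=2.0, seed=20 + k)
        fish = sample_fish(k, spec, np.random.default_rng(k), min_separation=55.0)
        img, note = render_scene(spec, fish)
        res = segment_and_count(img, spec.roi, small_center)
        assert res.count == note["true_count_in_roi"] == k
        for obj in res.objects:
            assert spec.roi.contains(np.array([obj.centroid]))[0]
            assert obj.area >= res.params.min_area

    def test_two_overlapping_fish_merge_into_one(self, small_scene, small_center):
        """Touching bodies merge into a single object — a known failure mode
        of edge-based counting."""
        from reefwatch.synthetic import FishBlob

        spec = small_scene(seed=5)
        rgb = (90.0, 20.0, 15.0)
        fish = [
            FishBlob((130.0, 150.0), (16.0, 8.0), 0.0, rgb),
            FishBlob((138.0, 162.0), (16.0, 8.0), 30.0, rgb),
        ]
        img, _ = render_scene(spec, fish)
        res = segment_and_count(img, spec.roi, small_center)
        assert res.count == 1

    def test_translation_equivariance(self, small_chart):
        """Shifting scene and ROI together leaves the count unchanged."""
        rng = np.random.default_rng(3)
        base = np.full((200, 260, 3), (168, 52, 44), dtype=float)
        base += rng.normal(0, 1.5, base.shape)
        for cr, cc in [(100, 80), (140, 170), (90, 200)]:
            rr, ccg = np.mgrid[0:200, 0:260]
            base[((rr - cr) / 12) ** 2 + ((ccg - cc) / 6) ** 2 <= 1] = (60, 10, 10)
        base = np.clip(np.round(base), 0, 255)
        roi = ROIPolygon(np.array([[60, 20], [60, 240], [190, 240], [190, 20]], float))
        res0 = segment_and_count(base, roi, (62, 22, 92, 52))
        dy, dx = 7, 9
        shifted = np.roll(np.roll(base, dy, axis=0), dx, axis=1)
        roi2 = ROIPolygon(roi.vertices + [dy, dx])
        res1 = segment_and_count(shifted, roi2, (62 + dy, 22 + dx, 92 + dy, 52 + dx))
        assert res0.count == 3
        assert res1.count == res0.count

    def test_count_monotone_in_min_area_and_threshold(self, small_scene, small_center):
        spec = small_scene(noise_sigma=2.0, seed=9)
        fish = sample_fish(5, spec, np.random.default_rng(9), min_separation=55.0)
        img, _ = render_scene(spec, fish)
        counts_area = [
            segment_and_count(img, spec.roi, small_center,
                              SegmentationParams(min_area=a)).count
            for a in (10, 30, 100, 400, 2000)
        ]
        assert counts_area == sorted(counts_area, reverse=True)
        base = segment_and_count(img, spec.roi, small_center)
        counts_thr = [
            segment_and_count(img, spec.roi, small_center,
                              SegmentationParams(edge_threshold=t)).count
            for t in (base.edge_threshold_used, base.edge_threshold_used * 4,
                      base.edge_threshold_used * 40)
        ]
        assert counts_thr == sorted(counts_thr, reverse=True)

    def test_connected_components_match_flood_fill(self):
        rng = np.random.default_rng(0)
        from skimage.measure import label

        for _ in range(50):
            mask = rng.random((32, 32)) < 0.35
            assert label(mask, connectivity=2).max() == flood_fill_components(mask)
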