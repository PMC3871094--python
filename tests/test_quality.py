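"""PCA ordination and frame selection against the good-visibility training set."""

import numpy as np
import pytest

from reefwatch.quality import (
    ImageFeature,
    build_feature_table,
    pca_ordinate,
    select_images,
)


def feats_from_rows(rows):
    return [ImageFeature(f"img{i:04d}", i, tuple(r)) for i, r in enumerate(rows)]


class TestFeatureTable:
    def test_identical_images_give_identical_rows(self):
        img = np.random.default_rng(0).integers(0, 255, (60, 80, 3)).astype(np.uint8)
        feats = build_feature_table({"a": img, "b": img.copy()}, (10, 10, 30, 30))
        assert feats[0].mean_rgb == feats[1].mean_rgb

    def test_constant_image_row_equals_fill(self):
        img = np.full((60, 80, 3), (12, 34, 56), dtype=np.uint8)
        feats = build_feature_table({"a": img}, (0, 0, 60, 80))
        assert feats[0].mean_rgb == (12.0, 34.0, 56.0)

    def test_region_outside_image_rejected(self):
        img = np.zeros((20, 20, 3), dtype=np.uint8)
        with pytest.raises(ValueError, match="outside"):
            build_feature_table({"a": img}, (0, 0, 30, 30))


class TestPCA:
    def test_collinear_features_explained_by_pc1(self):
        t = np.linspace(0, 1, 20)[:, None]
        rows = t * np.array([10.0, 20.0, 5.0]) + 100
        _, _, explained = pca_ordinate(feats_from_rows(rows))
        assert explained[0] == pytest.approx(1.0, abs=1e-12)

    def test_isotropic_cloud_splits_variance_evenly(self):
        rng = np.random.default_rng(7)
        rows = rng.normal(100, 1.0, (10_000, 3))
        _, _, explained = pca_ordinate(feats_from_rows(rows))
        assert np.all(np.abs(explained - 1 / 3) < 0.02)

    def test_reflection_leaves_explained_variance_unchanged(self):
        rng = np.random.default_rng(3)
        rows = rng.normal(100, [5, 2, 1], (200, 3))
        _, _, e1 = pca_ordinate(feats_from_rows(rows))
        mirrored = rows.mean(axis=0) - (rows - rows.mean(axis=0))
        _, _, e2 = pca_ordinate(feats_from_rows(mirrored))
        assert np.allclose(e1, e2, atol=1e-12)

    def test_sign_convention_is_deterministic(self):
        rng = np.random.default_rng(5)
        rows = rng.normal(100, [5, 2, 1], (50, 3))
        _, load1, _ = pca_ordinate(feats_from_rows(rows))
        _, load2, _ = pca_ordinate(feats_from_rows(rows))
        assert np.array_equal(load1, load2)
        for j in range(load1.shape[1]):
            assert load1[np.argmax(np.abs(load1[:, j])), j] > 0

    def test_degenerate_input_rejected(self):
        with pytest.raises(ValueError, match="degenerate"):
            pca_ordinate(feats_from_rows(np.full((10, 3), 7.0)))

    def test_too_few_images_rejected(self):
        with pytest.raises(ValueError, match="4"):
            pca_ordinate(feats_from_rows(np.eye(3)))


class TestSelection:
    def test_training_everything_at_full_coverage_selects_all(self):
        rng = np.random.default_rng(0)
        feats = feats_from_rows(rng.normal(100, 3, (40, 3)))
        res = select_images(feats, [f.image_id for f in feats], coverage=1.0)
        assert res.selected.all()
        assert res.rule == "mahalanobis"

    def test_separated_clusters_recovered(self):
        rng = np.random.default_rng(1)
        sigma = 1.0
        good = rng.normal(100, sigma, (300, 3))
        bad = rng.normal(100 + 10 * sigma, sigma, (150, 3))  # 10 sigma apart
        feats = feats_from_rows(np.vstack([good, bad]))
        training = [f.image_id for f in feats[:100]]
        res = select_images(feats, training)
        truth = np.r_[np.ones(300, bool), np.zeros(150, bool)]
        accuracy = (res.selected == truth).mean()
        assert accuracy >= 0.99

    def test_selection_permutation_invariant(self):
        rng = np.random.default_rng(2)
        rows = rng.normal(100, 2, (60, 3))
        rows[50:] += 15
        feats = feats_from_rows(rows)
        training = [f.image_id for f in feats[:20]]
        res = select_images(feats, training)
        perm = rng.permutation(60)
        res_p = select_images([feats[i] for i in perm], training)
        by_id = dict(zip([f.image_id for f in res_p.features], res_p.selected))
        assert all(by_id[f.image_id] == s
                   for f, s in zip(feats, res.selected))

    def test_mahalanobis_monotone_in_coverage(self):
        rng = np.random.default_rng(4)
        rows = rng.normal(100, 2, (80, 3))
        rows[60:] += rng.normal(0, 8, (20, 3))
        feats = feats_from_rows(rows)
        training = [f.image_id for f in feats[:30]]
        previous = None
        for coverage in (0.5, 0.9, 0.99, 0.999):
            sel = select_images(feats, training, coverage=coverage).selected
            if previous is not None:
                assert np.all(sel[previous])  # raising coverage never deselects
            previous = sel.copy()

    def test_training_frames_always_kept(self):
        rng = np.random.default_rng(6)
        rows = rng.normal(100, 2, (50, 3))
        rows[0] += 30  # an extreme training frame
        feats = feats_from_rows(rows)
        training = [f.image_id for f in feats[:10]]
        res = select_images(feats, training, coverage=0.5)
        assert res.selected[:10].all()

    def test_pc_sign_rule(self):
        rng = np.random.default_rng(8)
        rows = rng.normal(100, [8, 4, 2], (100, 3))
        feats = feats_from_rows(rows)
        res = select_images(feats, [f.image_id for f in feats[:5]], rule="pc_sign")
        expected = (res.scores[:, 0] > 0) & (res.scores[:, 2] > 0)
        assert np.array_equal(res.selected, expected)
        assert res.rule == "pc_sign"

    def test_unknown_training_id_rejected(self):
        feats = feats_from_rows(np.random.default_rng(9).normal(0, 1, (10, 3)))
        with pytest.raises(ValueError, match="training"):
            select_images(feats, ["nope1", "nope2", "nope3"])

    def test_report_frame_schema(self):
        rng = np.random.default_rng(10)
        feats = feats_from_rows(rng.normal(100, 2, (20, 3)))
        res = select_images(feats, [f.image_id for f in feats[:5]])
        df = res.to_frame()
        assert list(df.columns) == [
            "image_id", "timestamp", "pc1", "pc2", "pc3", "selected", "reason",
        ]
        assert df.selected.sum() + (~df.selected).sum() == 20


def test_screening_separates_turbid_frames(small_scene, small_chart, small_center):
    """End-to-end: calibrated turbid frames fall outside the training cloud."""
    from reefwatch.synthetic import render_scene
    from reefwatch.tps import apply_tps3d, extract_patch_means, fit_tps3d

    rng = np.random.default_rng(0)
    images, truth_good = [], []
    for i in range(48):
        turbid = i % 6 == 5  # 8 turbid frames
        spec = small_scene(
            gain=float(np.clip(rng.normal(1.0, 0.05), 0.8, 1.2)),
            turbidity=0.55 if turbid else 0.0,
            noise_sigma=2.0,
            seed=1000 + i,
        )
        img, _ = render_scene(spec)
        obs = extract_patch_means(img, small_chart)
        model = fit_tps3d(np.array([o.mean_rgb for o in obs]),
                          small_chart.srgb_array)
        images.append((f"f{i:03d}", i, apply_tps3d(model, img)))
        truth_good.append(not turbid)
    feats = build_feature_table(images, small_center)
    training = [f.image_id for f, g in zip(feats, truth_good) if g][:20]
    res = select_images(feats, training)
    truth_good = np.array(truth_good)
    recall = res.selected[truth_good].mean()
    precision = truth_good[res.selected].mean()
    assert recall >= 0.95
    assert precision >= 0.90
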