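"""Overlap/surface metrics vs brute-force oracles; GLCM texture features."""

import numpy as np
import pytest
from skimage.feature import graycomatrix, graycoprops

from oracles import assd_bruteforce, hausdorff_bruteforce
from pcgnet import metrics


def random_mask(rng, shape=(12, 12), max_pixels=100):
    mask = np.zeros(shape, bool)
    n = rng.integers(1, max_pixels + 1)
    idx = rng.choice(shape[0] * shape[1], size=min(n, shape[0] * shape[1]), replace=False)
    mask.ravel()[idx] = True
    return mask


class TestOverlap:
    def test_dsc_cases(self):
        a = np.zeros((2, 2), bool)
        a[0, 0] = a[0, 1] = True
        b = np.zeros((2, 2), bool)
        b[0, 1] = b[1, 1] = True
        assert metrics.dsc(a, b)[0] == pytest.approx(0.5)
        assert metrics.jaccard(a, b)[0] == pytest.approx(1 / 3)
        assert metrics.dsc(a, a) == (1.0, False)
        assert metrics.dsc(a, ~a)[0] == 0.0

    def test_both_empty_flagged(self):
        e = np.zeros((3, 3), bool)
        val, flag = metrics.dsc(e, e)
        assert val == 1.0 and flag
        val, flag = metrics.jaccard(e, e)
        assert val == 1.0 and flag

    def test_jaccard_dice_identity(self, rng):
        for _ in range(200):
            a, b = random_mask(rng), random_mask(rng)
            d, _ = metrics.dsc(a, b)
            j, _ = metrics.jaccard(a, b)
            assert abs(j - d / (2 - d)) < 1e-12

    def test_shape_mismatch(self):
        with pytest.raises(ValueError, match="mismatch"):
            metrics.dsc(np.zeros((2, 2), bool), np.zeros((3, 3), bool))


class TestSurfaceDistances:
    def test_identical_masks_are_zero(self, rng):
        m = random_mask(rng)
        assert metrics.hausdorff(m, m)[0] == 0.0
        assert metrics.assd(m, m)[0] == 0.0

    def test_single_pixel_pair(self):
        a = np.zeros((6, 6), bool)
        b = np.zeros((6, 6), bool)
        a[0, 0] = True
        b[3, 4] = True
        assert metrics.hausdorff(a, b)[0] == pytest.approx(5.0)
        assert metrics.assd(a, b)[0] == pytest.approx(5.0)

    def test_matches_bruteforce_oracle(self, rng):
        for _ in range(200):
            a, b = random_mask(rng), random_mask(rng)
            hd, _ = metrics.hausdorff(a, b)
            ad, _ = metrics.assd(a, b)
            assert hd == pytest.approx(hausdorff_bruteforce(a, b), abs=1e-9)
            assert ad == pytest.approx(assd_bruteforce(a, b), abs=1e-9)

    def test_scales_linearly_with_spacing(self, rng):
        a, b = random_mask(rng), random_mask(rng)
        assert metrics.hausdorff(a, b, 2.5)[0] == pytest.approx(2.5 * metrics.hausdorff(a, b)[0])
        assert metrics.assd(a, b, 0.5)[0] == pytest.approx(0.5 * metrics.assd(a, b)[0])

    def test_empty_mask_flagged_nan(self):
        m = np.zeros((4, 4), bool)
        n = m.copy()
        n[1, 1] = True
        val, flag = metrics.hausdorff(m, n)
        assert flag and np.isnan(val)

    def test_hd95_not_larger_than_hd(self, rng):
        a, b = random_mask(rng), random_mask(rng)
        assert metrics.hausdorff95(a, b)[0] <= metrics.hausdorff(a, b)[0] + 1e-12


class TestReports:
    def test_multiclass_equals_binary_per_class(self, rng):
        pred = rng.integers(0, 3, size=(10, 10))
        true = rng.integers(0, 3, size=(10, 10))
        rows = metrics.evaluate_label_map(pred, true, 3)
        for m in (1, 2):
            assert rows[m]["dsc"] == pytest.approx(metrics.dsc(pred == m, true == m)[0])

    def test_aggregate_excludes_empty_distances(self):
        full = {"dsc": 0.8, "jaccard": 0.7, "hd": 2.0, "assd": 1.0, "empty": False, "both_empty": False}
        empty = {"dsc": 0.0, "jaccard": 0.0, "hd": float("nan"), "assd": float("nan"), "empty": True, "both_empty": False}
        report = metrics.aggregate_reports(
            [{1: full, 2: empty}, {1: full, 2: full}], num_classes=3, small_structures=(2,)
        )
        name2 = "structure_2"
        assert report.empty_counts[name2] == 1
        assert report.per_structure[name2]["hd"] == pytest.approx(2.0)  # one sample excluded
        assert report.mean["dsc"] == pytest.approx((0.8 + 0.4) / 2)

    def test_report_writer_roundtrip(self, tmp_path, rng):
        pred = rng.integers(0, 3, size=(8, 8))
        rows = [metrics.evaluate_label_map(pred, pred, 3)]
        report = metrics.aggregate_reports(rows, 3, small_structures=(2,))
        data = metrics.write_report(report, json_path=tmp_path / "r.json", csv_path=tmp_path / "r.csv")
        assert (tmp_path / "r.json").exists() and (tmp_path / "r.csv").exists()
        assert data["mean"]["dsc"] == 1.0


class TestGLCM:
    def test_constant_image(self):
        feats = metrics.glcm_features(np.full((8, 8), 0.5))
        assert feats["contrast"] == 0.0
        assert feats["homogeneity"] == pytest.approx(1.0)
        assert np.isnan(feats["correlation"])

    def test_checkerboard_contrast_one(self):
        board = np.indices((8, 8)).sum(axis=0) % 2
        feats = metrics.glcm_features(board.astype(float), levels=2, offsets=((0, 1),))
        assert feats["contrast"] == pytest.approx(1.0)
        assert feats["homogeneity"] == pytest.approx(0.5)

    def test_transpose_invariance_with_symmetric_offsets(self, rng):
        img = rng.random((16, 16))
        f1 = metrics.glcm_features(img, offsets=((0, 1), (1, 0)))
        f2 = metrics.glcm_features(img.T, offsets=((0, 1), (1, 0)))
        for k in metrics.GLCM_FEATURES:
            assert f1[k] == pytest.approx(f2[k], abs=1e-10)

    def test_cross_site_heterogeneity_detected(self):
        """GLCM features + Mann-Whitney separate the multi-site pretraining
        pool from the single-site labeled split."""
        from pcgnet.phantoms import PhantomConfig, generate_dataset

        cfg = PhantomConfig(image_size=48, seed=31)
        pre = [s.image for s in generate_dataset(12, cfg, "pretrain")]
        tr = [s.image for s in generate_dataset(12, cfg, "train")]
        result = metrics.compare_texture_distributions(pre, tr)
        assert set(result) == set(metrics.GLCM_FEATURES)
        assert all(0.0 <= v["p_value"] <= 1.0 for v in result.values())
        # the site shifts are mostly a brightness offset at this sample size,
        # which the sum-average feature picks up
        assert result["sum_average"]["p_value"] < 0.05, result

    def test_agrees_with_skimage_props(self, rng):
        """contrast/homogeneity/correlation cross-checked against graycoprops."""
        img = (rng.random((20, 20)) * 15.99).astype(np.uint8)
        feats = metrics.glcm_features(img.astype(float), levels=16, offsets=((0, 1),))
        glcm = graycomatrix(img, [1], [0], levels=16, symmetric=True, normed=True)
        for mine, theirs in (
            ("contrast", "contrast"),
            ("homogeneity", "homogeneity"),
            ("correlation", "correlation"),
        ):
            assert feats[mine] == pytest.approx(float(graycoprops(glcm, theirs)[0, 0]), rel=1e-6)
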