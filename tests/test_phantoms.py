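"""Phantom generator: determinism, size calibration, splits, augmentation,
preprocessing."""

import numpy as np
import pytest

from pcgnet.phantoms import (
    SHIFT_TABLE,
    PhantomConfig,
    PhantomSample,
    augment,
    generate_dataset,
    generate_phantom,
    preprocess,
)


class TestGeneratePhantom:
    def test_seeded_determinism(self):
        cfg = PhantomConfig(seed=7)
        a, b = generate_phantom(cfg), generate_phantom(cfg)
        assert np.array_equal(a.image, b.image)
        assert np.array_equal(a.label, b.label)

    def test_label_values_complete(self, phantom_sample):
        assert set(np.unique(phantom_sample.label)) == set(range(6))

    def test_smallest_structure_pixel_band(self):
        """fraction 0.002 at 128^2 targets ~32.8 px; realised within +-30%."""
        cfg = PhantomConfig(seed=3)
        sample = generate_phantom(cfg)
        count = int((sample.label == 5).sum())
        assert 23 <= count <= 43

    def test_area_fraction_calibration_over_seeds(self):
        """Mean realised fraction per structure within +-10% of target (50 seeds)."""
        cfg0 = PhantomConfig()
        sums = np.zeros(cfg0.num_structures)
        n_seeds = 50
        for seed in range(n_seeds):
            s = generate_phantom(PhantomConfig(seed=seed))
            for m in range(1, 6):
                sums[m - 1] += (s.label == m).sum() / (128 * 128)
        means = sums / n_seeds
        for m, target in enumerate(cfg0.size_fractions):
            assert abs(means[m] - target) <= 0.1 * target, (m, means[m], target)

    def test_structures_nonoverlapping_and_nonempty(self, phantom_sample):
        counts = np.bincount(phantom_sample.label.ravel(), minlength=6)
        assert (counts[1:] >= 1).all()
        # non-overlap is implied by label uniqueness; check meta pixel counts agree
        for m, info in phantom_sample.meta["structures"].items():
            assert info["pixels"] == counts[int(m)]

    def test_no_structures_gives_pure_background(self):
        cfg = PhantomConfig(num_structures=0, size_fractions=(), intensity_means=(0.1,), seed=1)
        s = generate_phantom(cfg)
        assert (s.label == 0).all()
        assert 0 <= s.image.min() and s.image.max() <= 1

    def test_subpixel_fraction_names_structure(self):
        cfg = PhantomConfig(
            image_size=16, size_fractions=(0.04, 0.06, 0.03, 0.004, 0.002), seed=0
        )
        with pytest.raises(ValueError, match="structure 5"):
            generate_phantom(cfg)

    def test_invalid_fractions_rejected(self):
        with pytest.raises(ValueError, match="0, 0.25"):
            PhantomConfig(size_fractions=(0.3, 0.06, 0.03, 0.004, 0.002))
        with pytest.raises(ValueError, match="small"):
            PhantomConfig(size_fractions=(0.04, 0.06, 0.03, 0.02, 0.02))


class TestGenerateDataset:
    def test_empty(self):
        assert generate_dataset(0, PhantomConfig(), "train") == []

    def test_unknown_split(self):
        with pytest.raises(ValueError, match="split"):
            generate_dataset(1, PhantomConfig(), "holdout")

    def test_pretrain_withholds_labels_and_shifts_intensity(self):
        cfg = PhantomConfig(image_size=48, seed=5)
        pre = generate_dataset(10, cfg, "pretrain")
        tr = generate_dataset(10, cfg, "train")
        assert all(s.label is None for s in pre)
        assert all(s.label is not None for s in tr)
        with pytest.raises(ValueError, match="withheld"):
            pre[0].require_label()
        m_pre = np.mean([s.image.mean() for s in pre])
        m_tr = np.mean([s.image.mean() for s in tr])
        assert abs(m_pre - m_tr) > 0.02  # cross-site location shift is detectable

    def test_invariant_sweep(self):
        cfg = PhantomConfig(image_size=48, seed=9)
        samples = generate_dataset(30, cfg, "train")
        seeds = {s.meta["seed"] for s in samples}
        assert len(seeds) == 30
        for s in samples:
            assert set(np.unique(s.label)) == set(range(6))
            assert s.image.dtype == np.float32


class TestAugment:
    def test_mirror_involution(self, phantom_sample):
        once = augment(phantom_sample, [("mirror", {"axis": 1})])
        twice = augment(once, [("mirror", {"axis": 1})])
        assert np.array_equal(twice.image, phantom_sample.image)
        assert np.array_equal(twice.label, phantom_sample.label)

    def test_rot90_preserves_class_counts(self, phantom_sample):
        rotated = augment(phantom_sample, [("rotate", {"angle": 90})])
        assert np.array_equal(
            np.bincount(rotated.label.ravel(), minlength=6),
            np.bincount(phantom_sample.label.ravel(), minlength=6),
        )

    def test_gray_float_zero_sd_is_identity(self, phantom_sample):
        out = augment(phantom_sample, [("gray_float", {"sd": 0.0})])
        assert np.array_equal(out.image, phantom_sample.image)

    def test_label_values_never_grow(self, phantom_sample):
        before = set(np.unique(phantom_sample.label))
        ops = ["mirror", "rotate", "translate", "affine", "gray_float"]
        for seed in range(100):
            out = augment(phantom_sample, ops, seed=seed)
            assert set(np.unique(out.label)) <= before

    def test_geometry_moves_image_and_label_together(self, phantom_sample):
        out = augment(phantom_sample, [("translate", {"shift": (5, -3)})])
        # structure 2's bright pixels must still sit under label 2
        mask = out.label == 2
        assert mask.sum() > 0
        mean_in = out.image[mask].mean()
        mean_bg = out.image[out.label == 0].mean()
        assert abs(mean_in - PhantomConfig().intensity_means[2]) < 0.12
        assert abs(mean_in - mean_bg) > 0.2

    def test_unknown_op(self, phantom_sample):
        with pytest.raises(ValueError, match="unknown augmentation"):
            augment(phantom_sample, ["zoomblur"])


class TestPreprocess:
    def test_identity(self, rng):
        img = rng.random((64, 64)).astype(np.float32)
        assert np.array_equal(preprocess(img, 1.0, 1.0, 64), img)

    def test_resample_and_pad_arithmetic(self, rng):
        img = rng.random((256, 256)).astype(np.float32)
        out = preprocess(img, spacing=0.5, target_spacing=1.0, pad_to=512, pad_value=0.25)
        assert out.shape == (512, 512)
        # 256 * 0.5 / 1.0 = 128 px of content, centred
        content = out[192:320, 192:320]
        border = out[:192, :]
        assert np.allclose(border, 0.25)
        assert content.std() > 0.1

    def test_labels_keep_value_set(self, phantom_sample):
        out = preprocess(phantom_sample.label, 0.7, 1.0, 128, is_label=True)
        assert set(np.unique(out)) <= set(np.unique(phantom_sample.label))

    def test_oversize_content_cropped_with_warning(self, rng, caplog):
        img = rng.random((64, 64)).astype(np.float32)
        with caplog.at_level("WARNING"):
            out = preprocess(img, spacing=2.0, target_spacing=1.0, pad_to=96)
        assert out.shape == (96, 96)
        assert "cropping" in caplog.text

    def test_bad_spacing(self):
        with pytest.raises(ValueError, match="spacing"):
            preprocess(np.zeros((4, 4)), 0.0, 1.0, 8)
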