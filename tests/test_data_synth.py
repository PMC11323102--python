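"""Dataset I/O, preprocessing chain, augmentation and phantom generator."""

import imageio.v3 as iio
import nibabel as nib
import numpy as np
import pytest
from scipy import ndimage

from ccgan.data import (ImageSample, SynthConfig, augment, generate_synthetic,
                        load_dataset, preprocess, random_crop, rotate,
                        save_dataset, split_folds)


def _write_pair(root, stem, image, mask):
    iio.imwrite(root / f"{stem}.png", image.astype(np.uint8))
    iio.imwrite(root / f"{stem}_mask.png", mask.astype(np.uint8))


class TestLoadDataset:
    def test_png_pairs_count(self, tmp_path, rng):
        for i in range(3):
            _write_pair(tmp_path, f"s{i}", rng.integers(0, 255, (16, 16)),
                        rng.integers(0, 2, (16, 16)))
        samples = load_dataset(tmp_path, "png_pairs")
        assert len(samples) == 3
        assert all(np.issubdtype(s.mask.dtype, np.integer) for s in samples)

    def test_missing_mask_lists_stem(self, tmp_path, rng):
        _write_pair(tmp_path, "ok", rng.integers(0, 255, (8, 8)), np.zeros((8, 8)))
        iio.imwrite(tmp_path / "orphan.png", np.zeros((8, 8), dtype=np.uint8))
        with pytest.raises(FileNotFoundError, match="orphan"):
            load_dataset(tmp_path, "png_pairs")

    def test_shape_mismatch_names_both_shapes(self, tmp_path, rng):
        iio.imwrite(tmp_path / "a.png", np.zeros((64, 64), dtype=np.uint8))
        iio.imwrite(tmp_path / "a_mask.png", np.zeros((32, 32), dtype=np.uint8))
        with pytest.raises(ValueError, match=r"(?s)64.*32"):
            load_dataset(tmp_path, "png_pairs")

    def test_empty_masks_retained_and_flagged(self, tmp_path, rng):
        _write_pair(tmp_path, "blank", rng.integers(0, 255, (8, 8)), np.zeros((8, 8)))
        (sample,) = load_dataset(tmp_path, "png_pairs")
        assert sample.empty_mask

    def test_nifti_slices_match_volume(self, tmp_path, rng):
        vol = rng.random((16, 16, 10))
        mvol = (rng.random((16, 16, 10)) > 0.9).astype(np.int16)
        nib.save(nib.Nifti1Image(vol, np.eye(4)), tmp_path / "case.nii.gz")
        nib.save(nib.Nifti1Image(mvol, np.eye(4)), tmp_path / "case_mask.nii.gz")
        samples = load_dataset(tmp_path / "case.nii.gz", "nifti_slices")
        assert len(samples) == 10
        # per-slice foreground counts must equal the raw volume's counts
        for z, s in enumerate(samples):
            assert s.mask.sum() == mvol[..., z].sum()

    def test_nifti_shape_mismatch(self, tmp_path, rng):
        nib.save(nib.Nifti1Image(rng.random((8, 8, 4)), np.eye(4)), tmp_path / "v.nii")
        nib.save(nib.Nifti1Image(np.zeros((8, 8, 5)), np.eye(4)), tmp_path / "v_mask.nii")
        with pytest.raises(ValueError, match=r"(?s)8, 8, 4.*8, 8, 5"):
            load_dataset(tmp_path / "v.nii", "nifti_slices")


class TestPreprocess:
    def test_constant_image_all_zero(self):
        s = ImageSample("c", np.full((16, 16, 1), 7.0), np.zeros((16, 16), dtype=int))
        out = preprocess(s, target_size=16)
        np.testing.assert_array_equal(out.image, 0.0)

    def test_resize_keeps_mask_binary(self, rng):
        mask = (rng.random((128, 128)) > 0.95).astype(int)
        s = ImageSample("r", rng.random((128, 128, 1)), mask)
        out = preprocess(s, target_size=64)
        assert out.image.shape == (64, 64, 1)
        assert set(np.unique(out.mask)) <= {0, 1}

    def test_zscore_moments_with_clahe(self, checkerboard_sample):
        out = preprocess(checkerboard_sample, target_size=32, clahe=True)
        for ch in range(out.image.shape[2]):
            plane = out.image[:, :, ch]
            assert abs(plane.mean()) < 1e-6
            assert abs(plane.std() - 1.0) < 1e-6

    def test_nonfinite_rejected(self):
        img = np.ones((8, 8, 1))
        img[0, 0, 0] = np.nan
        s = ImageSample("n", img, np.zeros((8, 8), dtype=int))
        with pytest.raises(ValueError, match="non-finite"):
            preprocess(s, target_size=8)

    def test_normalisation_idempotent(self, checkerboard_sample):
        once = preprocess(checkerboard_sample, target_size=32)
        twice = preprocess(once, target_size=32)
        assert abs(twice.image.mean() - once.image.mean()) < 1e-6
        assert abs(twice.image.std() - once.image.std()) < 1e-6

    def test_replicate_channels(self, checkerboard_sample):
        out = preprocess(checkerboard_sample, target_size=32, replicate_channels=3)
        assert out.image.shape[2] == 3


class TestAugment:
    def test_zero_rotation_identity(self, checkerboard_sample):
        out = rotate(checkerboard_sample, 0)
        np.testing.assert_array_equal(out.image, checkerboard_sample.image)
        np.testing.assert_array_equal(out.mask, checkerboard_sample.mask)

    def test_four_quarter_turns_identity(self, checkerboard_sample):
        out = checkerboard_sample
        for _ in range(4):
            out = rotate(out, 90)
        np.testing.assert_array_equal(out.image, checkerboard_sample.image)
        np.testing.assert_array_equal(out.mask, checkerboard_sample.mask)

    def test_seeded_determinism(self, checkerboard_sample):
        a = augment(checkerboard_sample, {"random_crop", "rotation"}, rng_seed=5)
        b = augment(checkerboard_sample, {"random_crop", "rotation"}, rng_seed=5)
        np.testing.assert_array_equal(a.image, b.image)
        np.testing.assert_array_equal(a.mask, b.mask)

    def test_crop_too_large_rejected(self, checkerboard_sample, rng):
        with pytest.raises(ValueError, match="crop size"):
            random_crop(checkerboard_sample, 64, rng)

    def test_label_set_never_grows(self, checkerboard_sample):
        out = augment(checkerboard_sample, {"random_crop", "rotation"}, rng_seed=11)
        assert set(np.unique(out.mask)) <= set(np.unique(checkerboard_sample.mask))


class TestGenerateSynthetic:
    def test_seed_determinism(self):
        cfg = SynthConfig(n_samples=20, image_size=64, foreground_fraction=0.03, seed=7)
        a, b = generate_synthetic(cfg), generate_synthetic(cfg)
        for sa, sb in zip(a, b):
            np.testing.assert_array_equal(sa.image, sb.image)
            np.testing.assert_array_equal(sa.mask, sb.mask)

    def test_mean_foreground_fraction(self):
        cfg = SynthConfig(n_samples=200, image_size=64, foreground_fraction=0.03, seed=1)
        samples = generate_synthetic(cfg)
        frac = np.mean([s.mask.mean() for s in samples])
        assert 0.021 <= frac <= 0.039  # within 30% relative of the target

    def test_single_lesion_single_component(self):
        cfg = SynthConfig(n_samples=30, image_size=64, n_lesions_range=(1, 1), seed=3)
        for s in generate_synthetic(cfg):
            _, n = ndimage.label(s.mask)
            assert n == 1

    def test_majority_foreground_rejected(self):
        with pytest.raises(ValueError, match="minority-foreground"):
            generate_synthetic(SynthConfig(foreground_fraction=0.6))

    def test_disjoint_seeds_differ(self):
        a = generate_synthetic(SynthConfig(n_samples=5, image_size=32, seed=1))
        b = generate_synthetic(SynthConfig(n_samples=5, image_size=32, seed=2))
        assert any(not np.array_equal(sa.image, sb.image) for sa, sb in zip(a, b))


class TestSplitFolds:
    def test_even_split(self, small_dataset):
        out = split_folds(small_dataset[:10], k=5, seed=0)
        sizes = np.bincount([s.fold for s in out])
        assert list(sizes) == [2, 2, 2, 2, 2]

    def test_uneven_split_sizes(self, small_dataset):
        out = split_folds(small_dataset[:11], k=5, seed=0)
        sizes = sorted(np.bincount([s.fold for s in out]), reverse=True)
        assert sizes == [3, 2, 2, 2, 2]

    def test_determinism(self, small_dataset):
        a = split_folds(small_dataset, k=4, seed=9)
        b = split_folds(small_dataset, k=4, seed=9)
        assert [s.fold for s in a] == [s.fold for s in b]

    def test_too_many_folds(self, small_dataset):
        with pytest.raises(ValueError, match="folds"):
            split_folds(small_dataset[:3], k=5)


def test_save_dataset_roundtrip_layout(tmp_path, small_dataset):
    cfg = SynthConfig(n_samples=4, image_size=32, seed=5)
    samples = generate_synthetic(cfg)
    manifest = save_dataset(samples, tmp_path, cfg)
    assert manifest.exists()
    reloaded = load_dataset(tmp_path, "png_pairs")
    assert len(reloaded) == 4
    for orig, back in zip(samples, reloaded):
        np.testing.assert_array_equal(orig.mask, back.mask)  # masks are lossless
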