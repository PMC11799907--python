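"""Data loading, normalization, splits and the synthetic generator."""

import numpy as np
import pytest

import nibabel as nib
from PIL import Image

from lightawnet import generate_synthetic, load_image_pair, make_splits
from lightawnet.data import (SliceSample, load_npy_cache, load_volume_slices,
                             minmax_normalize, save_npy_cache, stack_batch)


def _write_nifti(path, arr):
    nib.save(nib.Nifti1Image(arr, affine=np.eye(4)), str(path))


class TestVolumeSlices:
    def test_four_slice_volume_yields_indexed_samples(self, tmp_path, rng):
        img = rng.random((6, 5, 4)).astype(np.float32)
        lab = (rng.random((6, 5, 4)) > 0.6).astype(np.int16)
        _write_nifti(tmp_path / "img.nii.gz", img)
        _write_nifti(tmp_path / "lab.nii.gz", lab)
        samples = load_volume_slices(tmp_path / "img.nii.gz",
                                     tmp_path / "lab.nii.gz")
        assert [s.slice_index for s in samples] == [0, 1, 2, 3]
        assert all(s.image.shape == (6, 5) for s in samples)

    def test_intensities_are_minmax_normalized_per_volume(self, tmp_path):
        img = np.array([[[0.0, 100.0]], [[200.0, 100.0]]], dtype=np.float32)
        lab = np.zeros_like(img, dtype=np.int16)
        _write_nifti(tmp_path / "i.nii", img)
        _write_nifti(tmp_path / "l.nii", lab)
        samples = load_volume_slices(tmp_path / "i.nii", tmp_path / "l.nii")
        got = np.stack([s.image for s in samples], axis=-1)
        np.testing.assert_allclose(got, img / 200.0)

    def test_constant_volume_maps_to_zeros(self, tmp_path):
        img = np.full((3, 3, 2), 7.0, dtype=np.float32)
        lab = np.zeros_like(img, dtype=np.int16)
        _write_nifti(tmp_path / "i.nii", img)
        _write_nifti(tmp_path / "l.nii", lab)
        for s in load_volume_slices(tmp_path / "i.nii", tmp_path / "l.nii"):
            assert not s.image.any()

    def test_multilabel_volumes_are_binarized(self, tmp_path):
        img = np.zeros((3, 3, 1), dtype=np.float32)
        lab = np.array([[[0], [1], [5]], [[2], [0], [7]],
                        [[0], [0], [0]]], dtype=np.int16)
        _write_nifti(tmp_path / "i.nii", img)
        _write_nifti(tmp_path / "l.nii", lab)
        (s,) = load_volume_slices(tmp_path / "i.nii", tmp_path / "l.nii")
        np.testing.assert_array_equal(np.unique(s.mask), [0, 1])
        assert s.mask.sum() == 4

    def test_shape_mismatch_names_the_files(self, tmp_path):
        _write_nifti(tmp_path / "i.nii", np.zeros((3, 3, 2), np.float32))
        _write_nifti(tmp_path / "l.nii", np.zeros((3, 3, 3), np.float32))
        with pytest.raises(ValueError, match="i.nii"):
            load_volume_slices(tmp_path / "i.nii", tmp_path / "l.nii")


class TestImagePairs:
    def test_full_scale_image_maps_to_one(self, tmp_path):
        Image.fromarray(np.full((8, 8), 255, np.uint8)).save(
            tmp_path / "im.png")
        Image.fromarray(np.full((8, 8), 255, np.uint8)).save(
            tmp_path / "m.png")
        s = load_image_pair(tmp_path / "im.png", tmp_path / "m.png")
        np.testing.assert_allclose(s.image, 1.0)
        assert s.mask.all()

    def test_mask_stays_binary_under_upscaling(self, tmp_path, rng):
        mask = (rng.random((8, 8)) > 0.5).astype(np.uint8) * 255
        Image.fromarray(np.zeros((8, 8), np.uint8)).save(tmp_path / "im.png")
        Image.fromarray(mask).save(tmp_path / "m.png")
        s = load_image_pair(tmp_path / "im.png", tmp_path / "m.png",
                            target_hw=(16, 16))
        assert set(np.unique(s.mask)) <= {0, 1}
        assert s.mask.shape == (16, 16)

    def test_checkerboard_downsampling_uses_nearest_neighbour(self, tmp_path):
        board = np.indices((8, 8)).sum(0) % 2
        Image.fromarray(np.zeros((8, 8), np.uint8)).save(tmp_path / "im.png")
        Image.fromarray((board * 255).astype(np.uint8)).save(
            tmp_path / "m.png")
        s = load_image_pair(tmp_path / "im.png", tmp_path / "m.png",
                            target_hw=(4, 4))
        assert set(np.unique(s.mask)) <= {0, 1}

    def test_missing_mask_raises(self, tmp_path):
        Image.fromarray(np.zeros((4, 4), np.uint8)).save(tmp_path / "im.png")
        with pytest.raises(FileNotFoundError):
            load_image_pair(tmp_path / "im.png", tmp_path / "nope.png")


class TestSplits:
    def test_five_folds_of_twenty_cases(self):
        manifest = make_splits([f"case{i}" for i in range(20)],
                               ("kfold", 5), seed=3)
        sizes = [len(v) for v in manifest.partitions.values()]
        assert sizes == [4, 4, 4, 4, 4]

    def test_same_seed_reproduces_the_manifest(self):
        ids = [f"c{i}" for i in range(17)]
        a = make_splits(ids, ("ratio", (8, 1, 1)), seed=11)
        b = make_splits(ids, ("ratio", (8, 1, 1)), seed=11)
        assert a.partitions == b.partitions

    def test_ratio_811_on_ten_ids(self):
        manifest = make_splits(list(range(10)), ("ratio", (8, 1, 1)), seed=0)
        assert [len(manifest.partitions[k])
                for k in ("train", "val", "test")] == [8, 1, 1]

    def test_partitions_are_disjoint_and_cover(self):
        ids = list(range(23))
        manifest = make_splits(ids, ("kfold", 4), seed=5)
        seen = sorted(i for v in manifest.partitions.values() for i in v)
        assert seen == ids

    def test_too_many_folds_is_an_error(self):
        with pytest.raises(ValueError):
            make_splits([1, 2, 3], ("kfold", 5), seed=0)

    def test_manifest_json_roundtrip(self, tmp_path):
        m = make_splits(list("abcdef"), ("ratio", (1, 1)), seed=2)
        m.to_json(tmp_path / "m.json")
        from lightawnet.data import SplitManifest
        again = SplitManifest.from_json(tmp_path / "m.json")
        assert again.partitions == m.partitions


class TestSyntheticGenerator:
    def test_fixed_seed_is_bit_identical(self):
        a = generate_synthetic(3, 64, 64, seed=9)
        b = generate_synthetic(3, 64, 64, seed=9)
        for sa, sb in zip(a, b):
            np.testing.assert_array_equal(sa.image, sb.image)
            np.testing.assert_array_equal(sa.mask, sb.mask)

    def test_masks_are_nonempty_with_sane_foreground_fraction(self):
        for s in generate_synthetic(10, 96, 96, seed=4):
            frac = s.mask.mean()
            assert 0.01 <= frac <= 0.5

    def test_mask_is_threshold_of_the_noiseless_blob_field(self):
        """With noise off, the image is an affine map of the blob field, so
        the mask must equal the image thresholded at the matching level."""
        for s in generate_synthetic(5, 64, 64, seed=2, noise_sd=0.0):
            img = s.image
            above = img > 0.55 + 1e-4
            below = img < 0.55 - 1e-4
            assert np.all(s.mask[above] == 1)
            assert np.all(s.mask[below] == 0)

    def test_samples_satisfy_invariants_across_sizes_and_channels(self):
        for H, W, C in [(64, 96, 1), (224, 224, 1), (64, 64, 3)]:
            for s in generate_synthetic(2, H, W, channels=C, seed=1):
                s.validate()
                assert s.image.shape[:2] == (H, W)
                if C > 1:
                    assert s.image.shape[2] == C


def test_npy_cache_roundtrip(tmp_path):
    samples = generate_synthetic(4, 32, 32, seed=8)
    save_npy_cache(samples, tmp_path)
    again = load_npy_cache(tmp_path)
    assert len(again) == 4
    for a, b in zip(samples, again):
        np.testing.assert_array_equal(a.image, b.image)
        np.testing.assert_array_equal(a.mask, b.mask)


def test_stack_batch_shapes():
    samples = generate_synthetic(3, 32, 48, seed=0)
    imgs, masks = stack_batch(samples)
    assert imgs.shape == (3, 1, 32, 48)
    assert masks.shape == (3, 1, 32, 48)
    assert imgs.dtype == np.float32


def test_minmax_normalize_degenerate_range():
    np.testing.assert_array_equal(minmax_normalize(np.full(5, 3.0)),
                                  np.zeros(5))
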