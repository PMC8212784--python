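"""I/O and preprocessing: z-score, stacking, one-hot, patch extraction."""

import numpy as np
import pytest
from hypothesis import given, settings
from hypothesis import strategies as st

from mtseg.brats_io import (
    MultimodalVolume,
    decode_onehot,
    encode_labels_onehot,
    extract_patches,
    grid_origins,
    read_case,
    stack_modalities,
    zscore_normalize,
)

rng = np.random.default_rng(42)


class TestZScore:
    def test_standardizes_to_zero_mean_unit_sd(self):
        vol = rng.normal(50, 7, size=(16, 16, 16))
        out = zscore_normalize(vol)
        assert abs(out.mean()) < 1e-6
        assert abs(out.std() - 1.0) < 1e-6
        # direct recomputation
        assert np.allclose(out, (vol - vol.mean()) / vol.std(), atol=1e-6)

    def test_constant_volume_returns_zeros_with_warning(self):
        with pytest.warns(UserWarning, match="constant"):
            out = zscore_normalize(np.full((4, 4, 4), 3.0))
        assert not out.any()

    def test_idempotent_on_standardized_input(self):
        vol = rng.normal(size=(12, 12, 12))
        once = zscore_normalize(vol)
        assert np.allclose(zscore_normalize(once), once, atol=1e-5)

    def test_nonzero_only_statistics(self):
        vol = np.zeros((10, 10, 10))
        vol[2:8, 2:8, 2:8] = rng.normal(100, 10, size=(6, 6, 6))
        out = zscore_normalize(vol, nonzero_only=True)
        inner = out[2:8, 2:8, 2:8]
        assert abs(inner.mean()) < 1e-6 and abs(inner.std() - 1) < 1e-6


class TestStacking:
    def test_four_volumes_stack_to_four_channels(self):
        vols = [np.full((5, 6, 7), k, dtype=float) for k in range(4)]
        out = stack_modalities(*vols)
        assert out.data.shape == (5, 6, 7, 4)
        for k in range(4):
            assert (out.data[..., k] == k).all()

    def test_shape_mismatch_reported(self):
        vols = [np.zeros((4, 4, 4))] * 3 + [np.zeros((4, 4, 5))]
        with pytest.raises(ValueError, match="differ"):
            stack_modalities(*vols)

    def test_channel_two_is_t1ce(self, small_case):
        image, _ = small_case
        restacked = stack_modalities(*(image.data[..., k] for k in range(4)))
        assert np.array_equal(restacked.data[..., 2], image.data[..., 2])


class TestOneHot:
    def test_all_zero_labels(self):
        oh = encode_labels_onehot(np.zeros((3, 3, 3), dtype=int))
        assert (oh[..., 0] == 1).all() and not oh[..., 1:].any()

    def test_label4_maps_to_channel3(self):
        lab = np.zeros((3, 3, 3), dtype=int)
        lab[1, 1, 1] = 4
        oh = encode_labels_onehot(lab)
        assert oh[1, 1, 1, 3] == 1 and oh[1, 1, 1, :3].sum() == 0

    def test_foreign_label_rejected(self):
        with pytest.raises(ValueError, match="3"):
            encode_labels_onehot(np.array([[[3]]]))

    @settings(deadline=None, derandomize=True, max_examples=25)
    @given(st.integers(0, 2**31 - 1))
    def test_roundtrip_and_partition(self, seed):
        lab = np.random.default_rng(seed).choice([0, 1, 2, 4], size=(6, 6, 6))
        oh = encode_labels_onehot(lab)
        assert (oh.sum(axis=-1) == 1).all()
        assert np.array_equal(decode_onehot(oh), lab)


class TestPatches:
    def test_whole_volume_patch_is_single_origin(self):
        img = rng.normal(size=(8, 8, 8, 4))
        pairs = extract_patches(img, None, (8, 8, 8), mode="grid")
        assert len(pairs) == 1 and pairs[0].origin == (0, 0, 0)

    def test_grid_covers_volume(self):
        img = rng.normal(size=(64, 64, 64, 4))
        pairs = extract_patches(img, None, (32, 32, 32), mode="grid")
        assert len(pairs) == 8
        cover = np.zeros((64, 64, 64), dtype=bool)
        for p in pairs:
            sl = tuple(slice(o, o + 32) for o in p.origin)
            cover[sl] = True
        assert cover.all()

    def test_grid_reassembly_reproduces_volume(self):
        img = rng.normal(size=(48, 32, 16, 4)).astype(np.float32)
        pairs = extract_patches(img, None, (16, 16, 16), mode="grid")
        rebuilt = np.zeros_like(img)
        for p in pairs:
            sl = tuple(slice(o, o + 16) for o in p.origin)
            rebuilt[sl] = p.image
        assert np.array_equal(rebuilt, img)

    def test_oversized_patch_rejected(self):
        with pytest.raises(ValueError, match="exceeds"):
            extract_patches(rng.normal(size=(8, 8, 8, 4)), None, (16, 8, 8))

    def test_tumor_forcing_fraction_one(self, small_case):
        image, labels = small_case
        mask = encode_labels_onehot(labels)
        pairs = extract_patches(
            image.data, mask, (16, 16, 16), mode="random", n_patches=20, tumor_fraction=1.0, seed=3
        )
        assert len(pairs) == 20
        for p in pairs:
            assert p.mask[..., 1:].sum() >= 1

    def test_random_mode_is_seeded(self, small_case):
        image, labels = small_case
        mask = encode_labels_onehot(labels)
        a = extract_patches(image.data, mask, (16, 16, 16), mode="random", n_patches=5, seed=9)
        b = extract_patches(image.data, mask, (16, 16, 16), mode="random", n_patches=5, seed=9)
        assert [p.origin for p in a] == [p.origin for p in b]

    def test_overlapping_grid_last_start_clamped(self):
        origins = grid_origins((10, 10, 10), (4, 4, 4), (4, 4, 4))
        starts = sorted({o[0] for o in origins})
        assert starts == [0, 4, 6]


class TestReadCase:
    def test_roundtrip_voxel_equality(self, phantom_dataset, small_spec):
        from mtseg.phantom import PhantomSpec, generate_case
        import dataclasses

        _, manifest = phantom_dataset
        entry = manifest[0]
        image, labels = read_case(entry["dir"])
        regenerated_img, regenerated_lab = generate_case(
            dataclasses.replace(small_spec, seed=entry["seed"])
        )
        assert np.allclose(image.data, regenerated_img.data, atol=1e-5)
        assert np.array_equal(labels, regenerated_lab)

    def test_missing_modality_named(self, phantom_dataset, tmp_path):
        import shutil

        _, manifest = phantom_dataset
        broken = tmp_path / "broken"
        shutil.copytree(manifest[0]["dir"], broken)
        t2 = next(broken.glob("*_t2.nii.gz"))
        t2.unlink()
        with pytest.raises(FileNotFoundError, match="t2"):
            read_case(broken)

    def test_segmentation_optional(self, phantom_dataset, tmp_path):
        import shutil

        _, manifest = phantom_dataset
        noseg = tmp_path / "noseg"
        shutil.copytree(manifest[0]["dir"], noseg)
        next(noseg.glob("*_seg.nii.gz")).unlink()
        image, labels = read_case(noseg)
        assert labels is None and image.data.shape[-1] == 4

    def test_invalid_label_value_rejected(self, tmp_path):
        import nibabel as nib

        case = tmp_path / "badlabels"
        case.mkdir()
        for mod in ("flair", "t1", "t1ce", "t2"):
            nib.save(nib.Nifti1Image(np.zeros((6, 6, 6), np.float32), np.eye(4)), str(case / f"x_{mod}.nii.gz"))
        nib.save(nib.Nifti1Image(np.full((6, 6, 6), 3, np.int16), np.eye(4)), str(case / "x_seg.nii.gz"))
        with pytest.raises(ValueError, match="3"):
            read_case(case)
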