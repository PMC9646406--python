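import numpy as np
import pytest

from longiseg.volume_io import (CropRecord, DegenerateInputError,
                                LongitudinalCase, RegistrationError, Volume,
                                concat_timepoints, crop_foreground, load_case,
                                preprocess_case, resample, restore_to_original,
                                save_volume, split_timepoints, znormalize)

from _oracles import bounding_box


def _vol(data, voxel=(1.0, 1.0, 1.0)):
    return Volume(np.asarray(data, dtype=np.float32),
                  np.diag(list(voxel) + [1.0]), voxel)


def _random_vol(rng, shape=(16, 16, 16), voxel=(1.0, 1.0, 1.0)):
    return _vol(rng.normal(1.0, 0.3, shape).astype(np.float32), voxel)


class TestLoadCase:
    def test_round_trip_preserves_grid_and_affine(self, tmp_path):
        rng = np.random.default_rng(0)
        b, f = _random_vol(rng), _random_vol(rng)
        save_volume(b, tmp_path / "b.nii.gz")
        save_volume(f, tmp_path / "f.nii.gz")
        case = load_case(tmp_path / "b.nii.gz", tmp_path / "f.nii.gz")
        np.testing.assert_allclose(case.baseline.data, b.data, rtol=1e-6)
        np.testing.assert_allclose(case.baseline.affine, b.affine)

    def test_shape_mismatch_is_a_registration_error(self, tmp_path):
        rng = np.random.default_rng(1)
        save_volume(_random_vol(rng), tmp_path / "b.nii.gz")
        save_volume(_random_vol(rng, shape=(16, 16, 12)), tmp_path / "f.nii.gz")
        with pytest.raises(RegistrationError):
            load_case(tmp_path / "b.nii.gz", tmp_path / "f.nii.gz")

    def test_mask_values_binarized(self, tmp_path):
        rng = np.random.default_rng(2)
        vol = _random_vol(rng)
        raw = np.zeros((16, 16, 16), dtype=np.float32)
        raw[4:8, 4:8, 4:8] = 255.0
        save_volume(vol, tmp_path / "b.nii.gz")
        save_volume(vol, tmp_path / "f.nii.gz")
        save_volume(_vol(raw), tmp_path / "m.nii.gz")
        case = load_case(tmp_path / "b.nii.gz", tmp_path / "f.nii.gz",
                         tmp_path / "m.nii.gz")
        # oracle: elementwise v > 0.5
        np.testing.assert_array_equal(case.mask.data[0], (raw > 0.5))


class TestConcat:
    def test_concat_shape_order_and_round_trip(self):
        rng = np.random.default_rng(3)
        b, f = _random_vol(rng), _random_vol(rng)
        case = LongitudinalCase("c", b, f)
        both = concat_timepoints(case)
        assert both.data.shape == (2, 16, 16, 16)
        np.testing.assert_array_equal(both.data[0], b.data[0])
        r_b, r_f = split_timepoints(both)
        np.testing.assert_array_equal(r_b.data, b.data)
        np.testing.assert_array_equal(r_f.data, f.data)


class TestCropForeground:
    def test_matches_brute_force_bounding_box(self):
        rng = np.random.default_rng(4)
        for _ in range(20):
            data = np.zeros((2, 12, 12, 12), dtype=np.float32)
            lo = rng.integers(0, 6, size=3)
            hi = lo + rng.integers(1, 6, size=3)
            data[:, lo[0]:hi[0], lo[1]:hi[1], lo[2]:hi[2]] = \
                rng.normal(1, 0.1, (2,) + tuple(hi - lo))
            cropped, _, rec = crop_foreground(_vol(data))
            ref_lo, ref_hi = bounding_box(data)
            assert rec.lower == ref_lo and rec.upper == ref_hi
            assert cropped.data.shape[1:] == tuple(h - l for l, h
                                                   in zip(ref_lo, ref_hi))

    def test_no_zeros_is_identity(self):
        vol = _random_vol(np.random.default_rng(5))
        vol.data += 10.0  # strictly positive
        cropped, _, rec = crop_foreground(vol)
        np.testing.assert_array_equal(cropped.data, vol.data)
        assert rec.lower == (0, 0, 0) and rec.upper == (16, 16, 16)

    def test_crop_then_restore_round_trip(self):
        data = np.zeros((1, 10, 10, 10), dtype=np.float32)
        data[0, 2:7, 3:8, 1:9] = 1.0
        vol = _vol(data)
        cropped, _, rec = crop_foreground(vol)
        restored = restore_to_original(cropped, rec, vol.voxel_size,
                                       vol.spatial_shape, mode="nearest")
        np.testing.assert_array_equal(restored.data, data)

    def test_all_zero_volume_rejected(self):
        with pytest.raises(DegenerateInputError):
            crop_foreground(_vol(np.zeros((1, 4, 4, 4))))


class TestZnormalize:
    def test_channels_standardized_independently(self):
        rng = np.random.default_rng(6)
        data = np.stack([rng.normal(5.0, 2.0, (16,) * 3),
                         rng.normal(-3.0, 0.5, (16,) * 3)]).astype(np.float32)
        out = znormalize(_vol(data))
        for c in range(2):
            # oracle: per-channel mean/std
            ref = (data[c] - data[c].mean()) / data[c].std()
            np.testing.assert_allclose(out.data[c], ref, atol=1e-5)
            assert abs(out.data[c].mean()) < 1e-5
            assert abs(out.data[c].var() - 1.0) < 1e-5

    def test_idempotent_to_float_tolerance(self):
        vol = _random_vol(np.random.default_rng(7))
        once = znormalize(vol)
        twice = znormalize(once)
        np.testing.assert_allclose(twice.data, once.data, atol=1e-5)

    def test_zero_variance_channel_rejected(self):
        with pytest.raises(DegenerateInputError):
            znormalize(_vol(np.full((1, 8, 8, 8), 3.0)))


class TestResample:
    def test_identity_spacing_is_identity(self):
        vol = _random_vol(np.random.default_rng(8))
        out = resample(vol, (1.0, 1.0, 1.0))
        np.testing.assert_array_equal(out.data, vol.data)

    def test_shape_formula_2mm_to_1mm(self):
        vol = _random_vol(np.random.default_rng(9), voxel=(2.0, 2.0, 2.0))
        out = resample(vol, (1.0, 1.0, 1.0))
        assert out.spatial_shape == (32, 32, 32)
        assert out.voxel_size == (1.0, 1.0, 1.0)

    def test_anisotropic_shape_rounding(self):
        # 16 * 0.6 / 1.0 = 9.6 -> 10; 16 * 0.98 = 15.68 -> 16
        vol = _random_vol(np.random.default_rng(10), voxel=(0.6, 0.98, 0.98))
        out = resample(vol, (1.0, 1.0, 1.0))
        assert out.spatial_shape == (10, 16, 16)

    def test_nearest_keeps_masks_binary(self):
        mask = np.zeros((1, 9, 9, 9), dtype=np.float32)
        mask[0, 2:6, 3:7, 2:8] = 1.0
        out = resample(_vol(mask), (0.7, 0.7, 0.7), mode="nearest")
        assert set(np.unique(out.data)) <= {0.0, 1.0}

    def test_affine_scaling_tracks_target_voxel(self):
        vol = _random_vol(np.random.default_rng(11), voxel=(2.0, 2.0, 2.0))
        out = resample(vol, (1.0, 1.0, 1.0))
        np.testing.assert_allclose(np.abs(np.diag(out.affine)[:3]), 1.0)


class TestRestore:
    def test_forward_then_restore_shape_identity(self):
        vol = _random_vol(np.random.default_rng(12))
        res = resample(vol, (0.5, 0.5, 0.5))
        back = restore_to_original(res, None, vol.voxel_size, vol.spatial_shape)
        assert back.spatial_shape == vol.spatial_shape
        assert back.voxel_size == vol.voxel_size

    def test_positive_volume_approximately_conserved(self):
        mask = np.zeros((1, 16, 16, 16), dtype=np.float32)
        mask[0, 4:12, 4:12, 4:12] = 1.0
        up = resample(_vol(mask), (0.5, 0.5, 0.5), mode="nearest")
        scale = 8  # 2^3 more voxels per mm^3
        assert abs(up.data.sum() / mask.sum() - scale) / scale < 0.2
        back = restore_to_original(up, None, (1, 1, 1), (16, 16, 16),
                                   mode="nearest")
        assert abs(back.data.sum() - mask.sum()) / mask.sum() < 0.2

    def test_outside_crop_box_is_zero(self):
        pred = _vol(np.ones((1, 4, 4, 4), dtype=np.float32))
        rec = CropRecord((2, 3, 4), (6, 7, 8), (12, 12, 12))
        out = restore_to_original(pred, rec, (1, 1, 1), (12, 12, 12),
                                  mode="nearest")
        inside = np.zeros((12, 12, 12), dtype=bool)
        inside[2:6, 3:7, 4:8] = True
        assert np.all(out.data[0][~inside] == 0)
        assert np.all(out.data[0][inside] == 1)

    def test_inconsistent_crop_record_rejected(self):
        pred = _vol(np.ones((1, 4, 4, 4), dtype=np.float32))
        rec = CropRecord((0, 0, 0), (4, 4, 4), (8, 8, 8))
        with pytest.raises(ValueError):
            restore_to_original(pred, rec, (1, 1, 1), (10, 10, 10))


def test_preprocess_chain_outputs_standardized_1mm(lesion_case):
    image, mask, record = preprocess_case(lesion_case)
    assert image.n_channels == 2
    assert image.voxel_size == (1.0, 1.0, 1.0)
    for c in range(2):
        assert abs(image.data[c].mean()) < 0.2  # resampling perturbs slightly
    assert set(np.unique(mask.data)) <= {0.0, 1.0}
    assert record is not None
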