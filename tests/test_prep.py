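"""Preprocessing geometry: crop, cube resampling, z-score, augmentation,
native-space inversion."""
import numpy as np
import pytest

from priorseg.grid import LabelMap, Volume
from priorseg.prep import (
    AffineAugmentParams,
    CropRecord,
    apply_affine_voxel,
    crop_foreground,
    random_affine_augment,
    resample_to_cube,
    to_native,
    zscore,
)


def _vol(data, affine=None):
    return Volume(np.asarray(data, dtype=np.float32),
                  np.eye(4) if affine is None else affine)


class TestCrop:
    def test_all_foreground_identity(self):
        v = _vol(np.ones((8, 9, 10)))
        out, _, rec = crop_foreground(v)
        assert out.shape == (8, 9, 10)
        assert rec.crop_bounds == ((0, 8), (0, 9), (0, 10))

    def test_single_voxel(self):
        data = np.zeros((20, 20, 20))
        data[10, 11, 12] = 5.0
        out, _, rec = crop_foreground(_vol(data))
        assert out.shape == (1, 1, 1)
        assert rec.crop_bounds == ((10, 11), (11, 12), (12, 13))

    def test_empty_foreground_raises(self):
        with pytest.raises(ValueError, match="empty foreground"):
            crop_foreground(_vol(np.zeros((5, 5, 5))))

    def test_crop_uncrop_roundtrip_exact(self, template64):
        vol, lab = template64
        _, clab, rec = crop_foreground(vol, lab)
        native = np.zeros(rec.original_shape, dtype=clab.data.dtype)
        sl = tuple(slice(lo, hi) for lo, hi in rec.crop_bounds)
        native[sl] = clab.data
        assert np.array_equal(native, lab.data)

    def test_crop_record_json_roundtrip(self):
        rec = CropRecord((10, 11, 12), ((1, 9), (0, 11), (2, 10)), (32, 32, 32),
                         [list(r) for r in np.eye(4).tolist()])
        rec2 = CropRecord.from_json(rec.to_json())
        assert rec2 == rec


class TestResample:
    def test_constant_volume_stays_constant(self):
        out = resample_to_cube(_vol(np.full((20, 24, 28), 3.5)), 16)
        assert out.shape == (16, 16, 16)
        assert np.allclose(out.data, 3.5)

    def test_label_closure(self, template64):
        _, lab = template64
        out = resample_to_cube(lab, 48)
        assert set(np.unique(out.data)) <= set(np.unique(lab.data))

    def test_world_coordinates_preserved_at_corners(self, template64):
        vol, _ = template64
        out = resample_to_cube(vol, 32)
        first = vol.affine @ np.array([0, 0, 0, 1.0])
        first2 = out.affine @ np.array([0, 0, 0, 1.0])
        last = vol.affine @ np.array([*(np.array(vol.shape) - 1), 1.0])
        last2 = out.affine @ np.array([31, 31, 31, 1.0])
        assert np.allclose(first, first2, atol=1e-6)
        assert np.allclose(last, last2, atol=1e-6)

    def test_identity_resample(self):
        rng = np.random.default_rng(0)
        v = _vol(rng.normal(size=(16, 16, 16)))
        out = resample_to_cube(v, 16)
        assert np.allclose(out.data, v.data, atol=1e-5)


class TestZscore:
    def test_normalizes_mean_and_sd(self, rng):
        v = _vol(rng.normal(5.0, 2.0, (20, 20, 20)))
        out = zscore(v)
        assert abs(out.data.mean()) < 1e-5
        assert abs(out.data.std() - 1.0) < 1e-5

    def test_linear_ramp_closed_form(self):
        # ramp 0..1: mean 1/2, SD of a uniform grid -> affine rescale
        n = 16
        ramp = np.tile(np.linspace(0, 1, n)[:, None, None], (1, n, n))
        out = zscore(_vol(ramp))
        expect = (ramp - ramp.mean()) / ramp.std()
        assert np.allclose(out.data, expect, atol=1e-5)

    def test_constant_input_raises(self):
        with pytest.raises(ValueError, match="constant"):
            zscore(_vol(np.full((6, 6, 6), 2.0)))

    def test_already_standardized_unchanged(self, rng):
        data = rng.normal(size=(12, 12, 12))
        data = (data - data.mean()) / data.std()
        out = zscore(_vol(data))
        assert np.allclose(out.data, data, atol=1e-5)


class TestAugment:
    def test_zero_amplitude_is_identity(self, template64):
        vol, lab = template64
        params = AffineAugmentParams(rotation_deg=0, scale=0, translation_vox=0, shear=0)
        ov, ol = random_affine_augment(vol, lab, params, seed=1)
        assert np.allclose(ov.data, vol.data, atol=1e-4)
        assert np.array_equal(ol.data, lab.data)

    def test_same_seed_identical(self, template64):
        vol, lab = template64
        a = random_affine_augment(vol, lab, seed=3)
        b = random_affine_augment(vol, lab, seed=3)
        assert np.array_equal(a[0].data, b[0].data)
        assert np.array_equal(a[1].data, b[1].data)

    def test_90_degree_rotation_conserves_class_volumes(self):
        # axis-aligned box phantom rotated by exactly 90 degrees about z
        data = np.zeros((24, 24, 24), dtype=np.int16)
        data[4:12, 6:18, 8:16] = 3
        mat = np.array([[0.0, -1.0, 0.0], [1.0, 0.0, 0.0], [0.0, 0.0, 1.0]])
        out = apply_affine_voxel(data, mat, np.zeros(3), order=1, is_labels=True)
        before = np.count_nonzero(data == 3)
        after = np.count_nonzero(out == 3)
        assert abs(after - before) / before < 0.02

    def test_label_closure(self, template64):
        vol, lab = template64
        _, ol = random_affine_augment(vol, lab, seed=11)
        assert set(np.unique(ol.data)) <= set(np.unique(lab.data))


class TestToNative:
    def test_all_background_prediction(self, template64):
        vol, _ = template64
        _, _, rec = crop_foreground(vol)
        rec.resample_target_shape = (32, 32, 32)
        pred = LabelMap(np.zeros((32, 32, 32), dtype=np.int16), np.eye(4))
        out = to_native(pred, rec, vol.shape, vol.affine)
        assert out.shape == vol.shape
        assert not out.data.any()

    def test_shape_mismatch_raises(self, template64):
        vol, _ = template64
        _, _, rec = crop_foreground(vol)
        pred = LabelMap(np.zeros((32, 32, 32), dtype=np.int16), np.eye(4))
        with pytest.raises(ValueError, match="does not match"):
            to_native(pred, rec, (10, 10, 10), vol.affine)
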