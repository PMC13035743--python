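"""Preprocessing pipeline and dataset IO."""

import numpy as np
import pytest

from cmapaug.io import (MissingMaskError, SliceCountMismatchError,
                        read_manifest, read_volume, write_manifest,
                        write_volume_nifti, write_volume_png_dir)
from cmapaug.preprocessing import (GrayVolume, MaskVolume,
                                   clip_hounsfield_outliers, minmax_normalize,
                                   preprocess_pair, resize_slices)


def _vol(values, **kw):
    arr = np.asarray(values, dtype=np.float64).reshape(1, 1, -1)
    return GrayVolume(voxels=arr, patient_id="p0", **kw)


class TestHounsfieldClip:
    def test_outlier_replaced_by_in_range_maximum(self):
        out = clip_hounsfield_outliers(_vol([100, 200, 5000]))
        assert out.voxels.ravel().tolist() == [100, 200, 200]

    def test_all_in_range_untouched(self):
        vol = _vol([0, 500, 3000])
        out = clip_hounsfield_outliers(vol)
        assert np.array_equal(out.voxels, vol.voxels)

    def test_boundary_value_is_in_range(self):
        out = clip_hounsfield_outliers(_vol([0, 3071, 4000]))
        assert out.voxels.ravel().tolist() == [0, 3071, 3071]

    def test_no_in_range_value_raises(self):
        with pytest.raises(ValueError):
            clip_hounsfield_outliers(_vol([4000, 5000]))


class TestMinMaxNormalize:
    def test_linear_map_endpoints(self):
        out = minmax_normalize(_vol([0, 5, 10]))
        assert out.voxels.ravel().tolist() == [0.0, 0.5, 1.0]

    def test_constant_volume_maps_to_zero(self):
        out = minmax_normalize(_vol([7, 7, 7]))
        assert np.array_equal(out.voxels, np.zeros((1, 1, 3)))

    def test_output_extrema(self, rng):
        vol = GrayVolume(voxels=rng.normal(50, 20, (4, 8, 8)), patient_id="p")
        out = minmax_normalize(vol)
        assert out.voxels.min() == 0.0
        assert out.voxels.max() == 1.0


class TestResize:
    def test_same_size_is_identity(self, rng):
        vol = GrayVolume(voxels=rng.random((3, 64, 64)), patient_id="p")
        mask = MaskVolume(voxels=(rng.random((3, 64, 64)) > 0.8).astype(np.uint8),
                          patient_id="p")
        out_vol, out_mask = resize_slices(vol, mask, target=64)
        assert np.array_equal(out_mask.voxels, mask.voxels)
        assert np.array_equal(out_vol.voxels, vol.voxels)

    def test_constant_slice_stays_constant(self):
        vol = GrayVolume(voxels=np.full((1, 32, 32), 0.4), patient_id="p")
        mask = MaskVolume(voxels=np.zeros((1, 32, 32), np.uint8), patient_id="p")
        out_vol, _ = resize_slices(vol, mask, target=16)
        assert np.allclose(out_vol.voxels, 0.4)
        assert out_vol.voxels.shape == (1, 16, 16)

    def test_downsampled_mask_stays_binary_nonempty(self):
        mask_arr = np.zeros((1, 32, 32), np.uint8)
        mask_arr[0, 10:14, 10:14] = 1
        vol = GrayVolume(voxels=np.zeros((1, 32, 32)), patient_id="p")
        mask = MaskVolume(voxels=mask_arr, patient_id="p")
        _, out_mask = resize_slices(vol, mask, target=16)
        assert set(np.unique(out_mask.voxels)) <= {0, 1}
        assert out_mask.voxels.sum() > 0

    def test_empty_volume_rejected(self):
        vol = GrayVolume(voxels=np.zeros((0, 8, 8)), patient_id="p")
        mask = MaskVolume(voxels=np.zeros((0, 8, 8), np.uint8), patient_id="p")
        with pytest.raises(ValueError):
            resize_slices(vol, mask)


def test_pipeline_is_idempotent_on_processed_data(rng):
    """Once a volume is at target size and normalized, re-running the
    pipeline changes nothing (within float tolerance)."""
    raw = GrayVolume(voxels=rng.normal(100, 900, (4, 40, 40)),
                     patient_id="p", modality_tag="CT")
    mask = MaskVolume(voxels=(rng.random((4, 40, 40)) > 0.7).astype(np.uint8),
                      patient_id="p")
    processed = preprocess_pair(*preprocess_pair(raw, mask, target=32),
                                target=32)
    again = preprocess_pair(*processed, target=32)
    assert np.allclose(processed[0].voxels, again[0].voxels, atol=1e-6)
    assert np.array_equal(processed[1].voxels, again[1].voxels)


class TestVolumeIO:
    def test_nifti_roundtrip_is_bit_exact(self, tmp_path, rng):
        voxels = rng.random((5, 16, 16)).astype(np.float32)
        mask_arr = (rng.random((5, 16, 16)) > 0.5).astype(np.uint8)
        vol = GrayVolume(voxels=voxels, patient_id="p7", modality_tag="MRI-T1")
        mask = MaskVolume(voxels=mask_arr, patient_id="p7")
        write_volume_nifti(vol, mask, tmp_path / "p7.nii.gz",
                           tmp_path / "p7_mask.nii.gz")
        out_vol, out_mask = read_volume(tmp_path / "p7.nii.gz",
                                        tmp_path / "p7_mask.nii.gz",
                                        modality_tag="MRI-T1")
        assert np.array_equal(out_vol.voxels, voxels)
        assert np.array_equal(out_mask.voxels, mask_arr)
        assert out_vol.patient_id == "p7"

    def test_png_directory_read_binarizes_255(self, tmp_path, rng):
        voxels = (rng.integers(0, 256, (3, 16, 16)) / 255.0).astype(np.float32)
        mask_arr = (rng.random((3, 16, 16)) > 0.6).astype(np.uint8)
        vol = GrayVolume(voxels=voxels, patient_id="case1")
        mask = MaskVolume(voxels=mask_arr, patient_id="case1")
        write_volume_png_dir(vol, mask, tmp_path / "case1")
        out_vol, out_mask = read_volume(tmp_path / "case1")
        assert out_vol.depth == 3
        assert np.array_equal(out_mask.voxels, mask_arr)  # 255 -> 1
        assert np.array_equal(out_vol.voxels,
                              np.rint(voxels * 255).astype(np.uint8))

    def test_png_slices_follow_natural_sort(self, tmp_path):
        import imageio.v3 as iio
        (tmp_path / "image").mkdir()
        (tmp_path / "mask").mkdir()
        for i, name in [(0, "slice_2.png"), (1, "slice_10.png")]:
            iio.imwrite(tmp_path / "image" / name,
                        np.full((4, 4), i, dtype=np.uint8))
            iio.imwrite(tmp_path / "mask" / name,
                        np.zeros((4, 4), dtype=np.uint8))
        vol, _ = read_volume(tmp_path)
        assert vol.voxels[0].max() == 0  # slice_2 before slice_10
        assert vol.voxels[1].max() == 1

    def test_missing_mask_raises(self, tmp_path, rng):
        vol = GrayVolume(voxels=rng.random((2, 8, 8)).astype(np.float32),
                         patient_id="p")
        mask = MaskVolume(voxels=np.zeros((2, 8, 8), np.uint8), patient_id="p")
        write_volume_nifti(vol, mask, tmp_path / "v.nii.gz",
                           tmp_path / "m.nii.gz")
        with pytest.raises(MissingMaskError):
            read_volume(tmp_path / "v.nii.gz", tmp_path / "absent.nii.gz")

    def test_slice_count_mismatch_raises(self, tmp_path, rng):
        vol = GrayVolume(voxels=rng.random((3, 8, 8)).astype(np.float32),
                         patient_id="p")
        short_mask = MaskVolume(voxels=np.zeros((2, 8, 8), np.uint8),
                                patient_id="p")
        write_volume_nifti(vol, MaskVolume(np.zeros((3, 8, 8), np.uint8), "p"),
                           tmp_path / "v.nii.gz", tmp_path / "unused.nii.gz")
        write_volume_nifti(
            GrayVolume(short_mask.voxels.astype(np.float32), "p"), short_mask,
            tmp_path / "unused2.nii.gz", tmp_path / "m.nii.gz")
        with pytest.raises(SliceCountMismatchError):
            read_volume(tmp_path / "v.nii.gz", tmp_path / "m.nii.gz")


def test_manifest_roundtrip(tmp_path):
    import pandas as pd
    frame = pd.DataFrame([{
        "patient_id": "a", "image_path": "a.nii.gz", "mask_path": "am.nii.gz",
        "modality_tag": "CT", "split": "source"}])
    write_manifest(frame, tmp_path / "manifest.csv")
    out = read_manifest(tmp_path / "manifest.csv")
    assert out.iloc[0]["patient_id"] == "a"
    with pytest.raises(ValueError):
        (tmp_path / "bad.csv").write_text("foo,bar\n1,2\n")
        read_manifest(tmp_path / "bad.csv")
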