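import numpy as np
import pydicom
import pytest
from pydicom.dataset import FileDataset, FileMetaDataset
from pydicom.uid import ExplicitVRLittleEndian, generate_uid

from petctseg.labels import SlicePair
from petctseg.volumes import (
    Volume,
    VolumeFormatError,
    export_slice_dataset,
    load_slice_dataset,
    read_volume,
    resample_to_reference,
    write_volume,
)
from tests.conftest import random_pair


def _random_volume(rng, shape=(5, 16, 16), spacing=(2.0, 1.5, 1.5), modality="CT"):
    data = rng.integers(-500, 1500, size=shape).astype(np.float32)
    if modality == "PET":
        data = np.abs(data)
    return Volume(data=data, spacing=spacing, origin=(1.0, -2.0, 3.0), modality=modality)


class TestVolumeContainer:
    def test_rejects_bad_inputs(self):
        with pytest.raises(ValueError):
            Volume(np.zeros((4, 4)), spacing=(1, 1, 1))
        with pytest.raises(ValueError):
            Volume(np.zeros((2, 4, 4)), spacing=(1, 0, 1))
        with pytest.raises(ValueError):
            Volume(np.full((2, 4, 4), -1.0), spacing=(1, 1, 1), modality="PET")

    def test_nifti_round_trip(self, rng, tmp_path):
        v = _random_volume(rng)
        write_volume(v, tmp_path / "v.nii.gz")
        back = read_volume(tmp_path / "v.nii.gz", "CT")
        np.testing.assert_allclose(back.data, v.data, rtol=1e-6)
        assert back.spacing == pytest.approx(v.spacing)
        assert back.origin == pytest.approx(v.origin)

    def test_spacing_metadata_passthrough(self, rng, tmp_path):
        v = _random_volume(rng, spacing=(4.0, 4.0, 4.0), modality="PET")
        write_volume(v, tmp_path / "pet.nii.gz")
        assert read_volume(tmp_path / "pet.nii.gz", "PET").spacing == pytest.approx((4.0, 4.0, 4.0))

    def test_unreadable_inputs_raise_format_error(self, tmp_path):
        empty = tmp_path / "series"
        empty.mkdir()
        with pytest.raises(VolumeFormatError):
            read_volume(empty, "CT")
        (empty / "junk.dcm").write_bytes(b"not a dicom")
        with pytest.raises(VolumeFormatError):
            read_volume(empty, "CT")
        with pytest.raises(VolumeFormatError):
            read_volume(tmp_path / "missing.nii", "CT")


def _write_dicom_slice(path, pixel_array, z, modality="CT", series_uid=None):
    meta = FileMetaDataset()
    meta.MediaStorageSOPClassUID = pydicom.uid.CTImageStorage
    meta.MediaStorageSOPInstanceUID = generate_uid()
    meta.TransferSyntaxUID = ExplicitVRLittleEndian
    ds = FileDataset(str(path), {}, file_meta=meta, preamble=b"\0" * 128)
    ds.Modality = modality
    ds.PatientID = "dcm-test"
    ds.SeriesInstanceUID = series_uid or generate_uid()
    ds.SOPInstanceUID = meta.MediaStorageSOPInstanceUID
    ds.ImagePositionPatient = [0.0, 0.0, float(z)]
    ds.PixelSpacing = [1.5, 1.5]
    ds.SliceThickness = 2.0
    ds.Rows, ds.Columns = pixel_array.shape
    ds.BitsAllocated = 16
    ds.BitsStored = 16
    ds.HighBit = 15
    ds.PixelRepresentation = 1
    ds.SamplesPerPixel = 1
    ds.PhotometricInterpretation = "MONOCHROME2"
    ds.RescaleSlope = 1.0
    ds.RescaleIntercept = 0.0
    ds.PixelData = pixel_array.astype(np.int16).tobytes()
    ds.save_as(str(path), enforce_file_format=True)


class TestDicomSeries:
    def test_series_read_sorted_ascending(self, rng, tmp_path):
        series = tmp_path / "ct"
        series.mkdir()
        uid = generate_uid()
        slices = [rng.integers(-100, 400, size=(8, 8)).astype(np.int16) for _ in range(3)]
        # write out of z order; reader must sort ascending along z
        for name, z, arr in [("b.dcm", 4.0, slices[2]), ("a.dcm", 0.0, slices[0]), ("c.dcm", 2.0, slices[1])]:
            _write_dicom_slice(series / name, arr, z={"a.dcm": 0.0, "b.dcm": 4.0, "c.dcm": 2.0}[name], series_uid=uid)
        v = read_volume(series, "CT")
        assert v.shape == (3, 8, 8)
        np.testing.assert_array_equal(v.data[0], slices[0])
        np.testing.assert_array_equal(v.data[1], slices[1])
        np.testing.assert_array_equal(v.data[2], slices[2])
        assert v.spacing == pytest.approx((2.0, 1.5, 1.5))
        assert v.patient_id == "dcm-test"

    def test_mixed_modality_series_rejected(self, rng, tmp_path):
        series = tmp_path / "mixed"
        series.mkdir()
        arr = rng.integers(0, 100, size=(4, 4)).astype(np.int16)
        _write_dicom_slice(series / "a.dcm", arr, z=0.0, modality="CT")
        _write_dicom_slice(series / "b.dcm", arr, z=2.0, modality="PT")
        with pytest.raises(VolumeFormatError, match="mixed-modality"):
            read_volume(series, "CT")


def _brute_force_trilinear(moving, point_mm):
    """Independent trilinear interpolation at one physical point."""
    u = (np.asarray(point_mm) - np.asarray(moving.origin)) / np.asarray(moving.spacing)
    lo = np.floor(u).astype(int)
    frac = u - lo
    acc = 0.0
    for dz in (0, 1):
        for dy in (0, 1):
            for dx in (0, 1):
                idx = lo + (dz, dy, dx)
                if np.any(idx < 0) or np.any(idx >= moving.shape):
                    continue
                w = ((1 - frac[0]) if dz == 0 else frac[0]) \
                    * ((1 - frac[1]) if dy == 0 else frac[1]) \
                    * ((1 - frac[2]) if dx == 0 else frac[2])
                acc += w * float(moving.data[tuple(idx)])
    return acc


class TestResample:
    def test_identity_grid_is_identity(self, rng):
        v = _random_volume(rng)
        out = resample_to_reference(v, v, "trilinear")
        np.testing.assert_allclose(out.data, v.data, atol=1e-4)

    def test_constant_volume_stays_constant(self):
        moving = Volume(np.full((6, 10, 10), 7.0), spacing=(2, 2, 2), origin=(0, 0, 0), modality="PET")
        ref = Volume(np.zeros((4, 8, 8)), spacing=(1, 1, 1), origin=(2, 2, 2))
        out = resample_to_reference(moving, ref, "trilinear")
        np.testing.assert_allclose(out.data, 7.0, atol=1e-5)

    def test_trilinear_matches_brute_force_oracle(self, rng, small_case):
        pet, ct = small_case.pet, small_case.ct
        out = resample_to_reference(pet, ct, "trilinear")
        idx = np.stack([rng.integers(1, s - 2, size=20) for s in ct.shape], axis=1)
        for i in idx:
            point = np.asarray(ct.origin) + i * np.asarray(ct.spacing)
            expected = _brute_force_trilinear(pet, point)
            assert out.data[tuple(i)] == pytest.approx(expected, abs=1e-6)

    def test_nearest_keeps_binary_volumes_binary(self, rng):
        data = (rng.random((5, 12, 12)) < 0.4).astype(np.float32)
        moving = Volume(data, spacing=(2, 2, 2))
        ref = Volume(np.zeros((8, 20, 20)), spacing=(1.3, 1.3, 1.3), origin=(0.4, 0.2, 0.1))
        out = resample_to_reference(moving, ref, "nearest")
        assert set(np.unique(out.data)) <= {0.0, 1.0}

    def test_disjoint_extents_warn_and_zero(self, caplog):
        moving = Volume(np.full((3, 4, 4), 5.0), spacing=(1, 1, 1), origin=(0, 0, 0))
        ref = Volume(np.zeros((3, 4, 4)), spacing=(1, 1, 1), origin=(100, 100, 100))
        with caplog.at_level("WARNING"):
            out = resample_to_reference(moving, ref, "trilinear")
        assert np.all(out.data == 0)
        assert any("overlap" in r.message for r in caplog.records)


class TestSliceExport:
    def test_export_and_lossless_round_trip(self, rng, tmp_path):
        pairs = [random_pair(rng, patient_id=f"p{i}") for i in range(3)]
        manifest = export_slice_dataset(pairs, tmp_path / "ds")
        assert len(manifest) == 3
        rasters = list((tmp_path / "ds").glob("*.png"))
        assert len(rasters) == 6
        back = load_slice_dataset(tmp_path / "ds")
        for orig, rt in zip(pairs, back):
            np.testing.assert_array_equal(rt.image, orig.image)
            np.testing.assert_array_equal(rt.mask, orig.mask)
            assert rt.patient_id == orig.patient_id
            assert rt.provenance == orig.provenance

    def test_empty_list_gives_empty_manifest(self, tmp_path):
        manifest = export_slice_dataset([], tmp_path / "empty")
        assert len(manifest) == 0
        assert list((tmp_path / "empty").glob("*.png")) == []

    def test_refuses_nonempty_dir_without_overwrite(self, rng, tmp_path):
        out = tmp_path / "busy"
        out.mkdir()
        (out / "junk.txt").write_text("x")
        with pytest.raises(FileExistsError):
            export_slice_dataset([random_pair(rng)], out)
        export_slice_dataset([random_pair(rng)], out, overwrite=True)  # explicit flag succeeds
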