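"""Volume IO and geometry.

Co-registered PET/CT pipelines need masks derived from PET to align
pixel-for-pixel with the CT slices used for training.  This module defines the
in-memory :class:`Volume` container, readers for DICOM series and NIfTI files,
a resampler that maps one volume onto the grid of another in physical (mm)
coordinates, and the exporter that writes 2D slice/label pairs to disk.

Conventions used everywhere in this package:

* array axes are ordered ``(slice, row, col)`` with 0-based indices;
* ``spacing`` and ``origin`` are ``(dz, dy, dx)`` / ``(z, y, x)`` in mm;
* physical coordinates refer to pixel *centers*: the center of voxel
  ``(i, j, k)`` sits at ``origin + index * spacing``.
"""

from __future__ import annotations

import logging
import os
from dataclasses import dataclass, field, replace
from pathlib import Path
from typing import Iterable, List, Literal, Sequence, Tuple

import numpy as np
import pydicom
import SimpleITK as sitk
from PIL import Image

logger = logging.getLogger(__name__)

Modality = Literal["PET", "CT"]


class VolumeFormatError(ValueError):
    """Raised for unreadable, empty or mixed-modality volume inputs."""


@dataclass
class Volume:
    """A 3D scalar image with grid metadata.

    Parameters
    ----------
    data : ndarray, shape (slices, rows, cols)
        Scalar intensities.  PET volumes are SUV-proportional and must be
        nonnegative; CT intensities (HU-like) are unrestricted.
    spacing : tuple of float
        Voxel spacing ``(dz, dy, dx)`` in mm, strictly positive.
    origin : tuple of float
        Physical position (mm) of the center of voxel ``(0, 0, 0)``.
    modality : {"PET", "CT"}
    patient_id : str
        Opaque identifier used for patient-level bookkeeping.
    """

    data: np.ndarray
    spacing: Tuple[float, float, float]
    origin: Tuple[float, float, float] = (0.0, 0.0, 0.0)
    modality: Modality = "CT"
    patient_id: str = "unknown"

    def __post_init__(self) -> None:
        self.data = np.asarray(self.data)
        if self.data.ndim != 3 or min(self.data.shape) < 1:
            raise ValueError(f"volume data must be 3D, got shape {self.data.shape}")
        self.spacing = tuple(float(s) for s in self.spacing)
        self.origin = tuple(float(o) for o in self.origin)
        if len(self.spacing) != 3 or any(s <= 0 for s in self.spacing):
            raise ValueError(f"spacing must be 3 positive floats, got {self.spacing}")
        if self.modality not in ("PET", "CT"):
            raise ValueError(f"modality must be 'PET' or 'CT', got {self.modality!r}")
        if self.modality == "PET" and float(self.data.min()) < 0:
            raise ValueError("PET intensities must be nonnegative (SUV-proportional)")

    @property
    def shape(self) -> Tuple[int, int, int]:
        return self.data.shape  # type: ignore[return-value]

    def copy(self) -> "Volume":
        return replace(self, data=self.data.copy())

    def to_sitk(self) -> sitk.Image:
        img = sitk.GetImageFromArray(np.ascontiguousarray(self.data, dtype=np.float64))
        img.SetSpacing(tuple(reversed(self.spacing)))  # sitk wants (x, y, z)
        img.SetOrigin(tuple(reversed(self.origin)))
        return img

    @classmethod
    def from_sitk(cls, img: sitk.Image, modality: Modality, patient_id: str = "unknown") -> "Volume":
        data = sitk.GetArrayFromImage(img).astype(np.float32)
        if data.ndim == 2:
            data = data[None]
        spacing = tuple(reversed(img.GetSpacing()))
        origin = tuple(reversed(img.GetOrigin()))
        if modality == "PET":
            # clip tiny negative interpolation/round-off residue
            data = np.maximum(data, 0.0)
        return cls(data=data, spacing=spacing, origin=origin, modality=modality, patient_id=patient_id)


# ---------------------------------------------------------------------------
# Reading / writing volumes
# ---------------------------------------------------------------------------

def _read_dicom_series(path: Path, modality: Modality) -> Volume:
    files = sorted(p for p in path.iterdir() if p.is_file())
    datasets = []
    for f in files:
        try:
            ds = pydicom.dcmread(str(f))
        except Exception:
            continue
        if not hasattr(ds, "PixelData"):
            continue
        datasets.append((f, ds))
    if not datasets:
        raise VolumeFormatError(f"no readable DICOM slices in {path}")

    modalities = {str(getattr(ds, "Modality", "")).upper() for _, ds in datasets}
    if len(modalities) > 1:
        offending = next(f for f, ds in datasets
                         if str(getattr(ds, "Modality", "")).upper() != str(getattr(datasets[0][1], "Modality", "")).upper())
        raise VolumeFormatError(f"mixed-modality DICOM series (offending file: {offending})")

    # ascending order along the patient axis
    def z_of(ds) -> float:
        ipp = getattr(ds, "ImagePositionPatient", None)
        if ipp is not None:
            return float(ipp[2])
        return float(getattr(ds, "InstanceNumber", 0))

    datasets.sort(key=lambda fd: z_of(fd[1]))
    first = datasets[0][1]
    slope = float(getattr(first, "RescaleSlope", 1.0))
    intercept = float(getattr(first, "RescaleIntercept", 0.0))
    try:
        arrays = [ds.pixel_array.astype(np.float32) * slope + intercept for _, ds in datasets]
        data = np.stack(arrays, axis=0)
    except Exception as exc:  # pragma: no cover - corrupt pixel data
        raise VolumeFormatError(f"cannot decode pixel data in {path}: {exc}") from exc

    ps = getattr(first, "PixelSpacing", [1.0, 1.0])
    if len(datasets) > 1:
        dz = abs(z_of(datasets[1][1]) - z_of(datasets[0][1])) or 1.0
    else:
        dz = float(getattr(first, "SliceThickness", 1.0) or 1.0)
    spacing = (dz, float(ps[0]), float(ps[1]))
    ipp = getattr(first, "ImagePositionPatient", [0.0, 0.0, 0.0])
    origin = (float(ipp[2]), float(ipp[1]), float(ipp[0]))
    pid = str(getattr(first, "PatientID", "unknown")) or "unknown"
    if modality == "PET":
        data = np.maximum(data, 0.0)
    return Volume(data=data, spacing=spacing, origin=origin, modality=modality, patient_id=pid)


def read_volume(path: os.PathLike | str, modality: Modality) -> Volume:
    """Read a DICOM series directory or a NIfTI file into a :class:`Volume`.

    Slice order is ascending along the patient (z) axis; spacing and origin
    are recovered from file metadata.
    """
    path = Path(path)
    if path.is_dir():
        return _read_dicom_series(path, modality)
    if not path.exists():
        raise VolumeFormatError(f"no such volume: {path}")
    try:
        img = sitk.ReadImage(str(path))
    except Exception as exc:
        raise VolumeFormatError(f"cannot read volume {path}: {exc}") from exc
    return Volume.from_sitk(img, modality=modality, patient_id=path.stem.split(".")[0])


def write_volume(volume: Volume, path: os.PathLike | str) -> None:
    """Write a volume to NIfTI (.nii / .nii.gz)."""
    path = Path(path)
    path.parent.mkdir(parents=True, exist_ok=True)
    sitk.WriteImage(volume.to_sitk(), str(path))


# ---------------------------------------------------------------------------
# Resampling
# ---------------------------------------------------------------------------

def _extent(v: Volume) -> Tuple[np.ndarray, np.ndarray]:
    lo = np.asarray(v.origin, dtype=float)
    hi = lo + (np.asarray(v.shape) - 1) * np.asarray(v.spacing)
    return lo, hi


def resample_to_reference(
    moving: Volume,
    reference: Volume,
    interpolation: Literal["nearest", "trilinear"] = "trilinear",
) -> Volume:
    """Resample ``moving`` onto the exact grid of ``reference``.

    Values are interpolated in physical coordinates (pixel-center convention);
    voxels of the reference grid outside the moving volume's field of view are
    set to 0.  The output keeps the moving volume's modality and patient id.
    """
    interp = {"nearest": sitk.sitkNearestNeighbor, "trilinear": sitk.sitkLinear}.get(interpolation)
    if interp is None:
        raise ValueError(f"unknown interpolation {interpolation!r}")
    lo_m, hi_m = _extent(moving)
    lo_r, hi_r = _extent(reference)
    if np.any(hi_m < lo_r) or np.any(lo_m > hi_r):
        logger.warning(
            "resample_to_reference: physical extents of moving (%s..%s) and reference "
            "(%s..%s) do not overlap; output is all zeros", lo_m, hi_m, lo_r, hi_r,
        )
    out = sitk.Resample(moving.to_sitk(), reference.to_sitk(), sitk.Transform(), interp, 0.0)
    res = Volume.from_sitk(out, modality=moving.modality, patient_id=moving.patient_id)
    return res


# ---------------------------------------------------------------------------
# Slice dataset export
# ---------------------------------------------------------------------------

MANIFEST_NAME = "manifest.tsv"
_MANIFEST_HEADER = ["image", "label", "patient_id", "source_slice", "angle_deg", "scale_x", "scale_y", "noise"]


@dataclass
class ManifestEntry:
    image_path: str
    label_path: str
    patient_id: str
    source_slice: int
    angle_deg: float
    scale_x: float
    scale_y: float
    noise: str  # "none" or e.g. "gaussian:5"


@dataclass
class SliceDatasetManifest:
    """Index of an exported 2D training dataset (image/label raster pairs)."""

    root: Path
    entries: List[ManifestEntry] = field(default_factory=list)

    def __len__(self) -> int:
        return len(self.entries)

    def save(self) -> Path:
        path = Path(self.root) / MANIFEST_NAME
        with open(path, "w") as fh:
            fh.write("\t".join(_MANIFEST_HEADER) + "\n")
            for e in self.entries:
                fh.write(
                    f"{e.image_path}\t{e.label_path}\t{e.patient_id}\t{e.source_slice}\t"
                    f"{e.angle_deg:g}\t{e.scale_x:g}\t{e.scale_y:g}\t{e.noise}\n"
                )
        return path

    @classmethod
    def load(cls, root: os.PathLike | str) -> "SliceDatasetManifest":
        root = Path(root)
        entries: List[ManifestEntry] = []
        with open(root / MANIFEST_NAME) as fh:
            header = fh.readline().rstrip("\n").split("\t")
            if header != _MANIFEST_HEADER:
                raise VolumeFormatError(f"unexpected manifest header in {root}: {header}")
            for line in fh:
                img, lab, pid, src, ang, sx, sy, noise = line.rstrip("\n").split("\t")
                entries.append(ManifestEntry(img, lab, pid, int(src), float(ang), float(sx), float(sy), noise))
        return cls(root=root, entries=entries)


def _write_image16(arr: np.ndarray, path: Path) -> None:
    """Store an integer-valued image as 16-bit grayscale PNG (offset +32768).

    The export contract is lossless for integer intensities in
    [-32768, 32767] (CT is integer HU in practice); fractional values are
    rounded at export time.
    """
    q = np.round(np.asarray(arr, dtype=np.float64))
    if q.min() < -32768 or q.max() > 32767:
        raise ValueError("image intensities outside the 16-bit export range [-32768, 32767]")
    u = (q + 32768.0).astype(np.uint16)
    Image.fromarray(u).save(path)  # uint16 -> 16-bit grayscale PNG


def _read_image16(path: Path) -> np.ndarray:
    u = np.asarray(Image.open(path), dtype=np.int32)
    return (u - 32768).astype(np.float32)


def _write_mask8(mask: np.ndarray, path: Path) -> None:
    m = np.asarray(mask)
    if not np.isin(m, (0, 1)).all():
        raise ValueError("mask values must be in {0, 1}")
    Image.fromarray((m * 255).astype(np.uint8), mode="L").save(path)


def _read_mask8(path: Path) -> np.ndarray:
    m = np.asarray(Image.open(path), dtype=np.uint8)
    return (m > 127).astype(np.uint8)


def export_slice_dataset(pairs: Sequence, out_dir: os.PathLike | str, overwrite: bool = False) -> SliceDatasetManifest:
    """Write image/label raster pairs plus a TSV manifest.

    Images go out as 16-bit PNG, masks as 8-bit {0, 255} PNG; reading back with
    :func:`load_slice_dataset` reproduces pixel values exactly (images are
    rounded to integers at export).  Refuses to write into an existing
    non-empty directory unless ``overwrite`` is set.
    """
    out_dir = Path(out_dir)
    if out_dir.exists() and any(out_dir.iterdir()) and not overwrite:
        raise FileExistsError(f"output directory {out_dir} is not empty (pass overwrite=True)")
    out_dir.mkdir(parents=True, exist_ok=True)
    manifest = SliceDatasetManifest(root=out_dir)
    for i, pair in enumerate(pairs):
        img_name = f"{i:06d}_img.png"
        lab_name = f"{i:06d}_lab.png"
        _write_image16(pair.image, out_dir / img_name)
        _write_mask8(pair.mask, out_dir / lab_name)
        p = pair.provenance
        manifest.entries.append(
            ManifestEntry(
                image_path=img_name,
                label_path=lab_name,
                patient_id=pair.patient_id,
                source_slice=pair.slice_index,
                angle_deg=p.angle_deg,
                scale_x=p.scale_x,
                scale_y=p.scale_y,
                noise=p.noise,
            )
        )
    manifest.save()
    return manifest


def load_slice_dataset(root: os.PathLike | str):
    """Read back an exported slice dataset as a list of ``SlicePair``."""
    from .labels import Provenance, SlicePair  # local import to avoid a cycle

    root = Path(root)
    manifest = SliceDatasetManifest.load(root)
    pairs = []
    for e in manifest.entries:
        image = _read_image16(root / e.image_path)
        mask = _read_mask8(root / e.label_path)
        pairs.append(
            SlicePair(
                image=image,
                mask=mask,
                patient_id=e.patient_id,
                slice_index=e.source_slice,
                provenance=Provenance(e.angle_deg, e.scale_x, e.scale_y, e.noise),
            )
        )
    return pairs
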