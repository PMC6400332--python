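"""Automatic ground-truth generation from PET.

The ¹⁸F-FDG radiotracer accumulates in the urinary bladder, so the bladder is
by far the brightest structure in an FDG-PET scan of the pelvis.  That makes a
fixed-fraction threshold of the per-dataset maximum SUV a usable automatic
segmenter: ``T = SUVmax * fraction`` (default fraction 0.2), with every voxel
*strictly above* T labelled foreground.  Applied to PET that has been resampled
onto the co-registered CT grid, this yields binary bladder masks aligned
pixel-for-pixel with CT slices — weak labels for training a CT segmentation
network without any manual delineation.
"""

from __future__ import annotations

import logging
from dataclasses import dataclass, field
from typing import List

import numpy as np

from .volumes import Volume, resample_to_reference

logger = logging.getLogger(__name__)


class DegenerateInputError(ValueError):
    """Raised when an input carries no usable signal (e.g. all-zero PET)."""


@dataclass(frozen=True)
class ThresholdRule:
    """Fraction of the dataset-wide SUV maximum used as the threshold."""

    fraction: float = 0.2

    def __post_init__(self) -> None:
        if not 0.0 < self.fraction < 1.0:
            raise ValueError(f"fraction must be in (0, 1), got {self.fraction}")


@dataclass(frozen=True)
class Provenance:
    """How a 2D slice was derived from its source volume."""

    angle_deg: float = 0.0
    scale_x: float = 1.0
    scale_y: float = 1.0
    noise: str = "none"

    @property
    def is_augmented(self) -> bool:
        return not (self.angle_deg == 0.0 and self.scale_x == 1.0 and self.scale_y == 1.0 and self.noise == "none")


@dataclass
class SlicePair:
    """One 2D CT slice with its aligned binary label mask."""

    image: np.ndarray
    mask: np.ndarray
    patient_id: str = "unknown"
    slice_index: int = 0
    provenance: Provenance = field(default_factory=Provenance)

    def __post_init__(self) -> None:
        self.image = np.asarray(self.image)
        self.mask = np.asarray(self.mask)
        if self.image.ndim != 2 or self.mask.ndim != 2:
            raise ValueError("image and mask must be 2D")
        if self.image.shape != self.mask.shape:
            raise ValueError(f"image shape {self.image.shape} != mask shape {self.mask.shape}")
        if not np.isin(self.mask, (0, 1)).all():
            raise ValueError("mask values must be in {0, 1}")


def compute_threshold(pet: Volume, rule: ThresholdRule = ThresholdRule()) -> float:
    """Return ``T = max(pet) * rule.fraction``.

    The maximum is taken over the whole 3D dataset, so one threshold applies
    to every slice of a patient (per-dataset, not per-slice thresholding).
    """
    if pet.modality != "PET":
        raise ValueError(f"expected a PET volume, got modality {pet.modality}")
    suv_max = float(pet.data.max())
    if suv_max <= 0:
        raise DegenerateInputError("PET volume has no positive uptake anywhere")
    return suv_max * rule.fraction


def binarize(pet_on_ct_grid: Volume, threshold: float) -> np.ndarray:
    """Threshold a PET volume: strictly above ``threshold`` -> 1, else 0.

    A voxel exactly equal to the threshold is background ("above" read
    strictly).
    """
    if threshold <= 0:
        raise ValueError(f"threshold must be positive, got {threshold}")
    return (pet_on_ct_grid.data > threshold).astype(np.uint8)


def extract_bladder_slices(ct: Volume, mask3d: np.ndarray, margin: int = 0) -> List[SlicePair]:
    """Extract CT slices around the bladder with their aligned 2D masks.

    Returns every slice whose mask has at least one foreground pixel, plus
    ``margin`` empty-mask context slices on each side of every foreground run,
    ordered by slice index.
    """
    mask3d = np.asarray(mask3d)
    if mask3d.shape != ct.shape:
        raise ValueError(f"ct shape {ct.shape} != mask shape {mask3d.shape}")
    if margin < 0:
        raise ValueError("margin must be >= 0")
    fg = np.flatnonzero(mask3d.reshape(mask3d.shape[0], -1).any(axis=1))
    if fg.size == 0:
        logger.warning("extract_bladder_slices: mask is empty for patient %s", ct.patient_id)
        return []
    keep: set[int] = set()
    for i in fg:
        keep.update(range(max(0, i - margin), min(ct.shape[0], i + margin + 1)))
    return [
        SlicePair(
            image=ct.data[i].astype(np.float32),
            mask=mask3d[i].astype(np.uint8),
            patient_id=ct.patient_id,
            slice_index=int(i),
        )
        for i in sorted(keep)
    ]


def make_labels(
    pet: Volume,
    ct: Volume,
    rule: ThresholdRule = ThresholdRule(),
    margin: int = 0,
) -> List[SlicePair]:
    """Full label-generation pipeline for one co-registered PET/CT pair.

    PET is resampled onto the CT grid (trilinear), the threshold is computed
    from the resampled volume's maximum (trilinear interpolation is
    max-bounded, so resampling cannot create values above the original max),
    the volume is binarized, and bladder-bearing slices are extracted.
    """
    pet_on_ct = resample_to_reference(pet, ct, interpolation="trilinear")
    t = compute_threshold(pet_on_ct, rule)
    mask3d = binarize(pet_on_ct, t)
    return extract_bladder_slices(ct, mask3d, margin=margin)
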