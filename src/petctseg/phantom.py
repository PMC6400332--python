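"""Synthetic PET/CT bladder phantoms.

The generator produces paired PET/CT volumes with a known ellipsoidal
"bladder" so that every pipeline stage — threshold labelling, augmentation,
network training, evaluation — can be exercised and validated without any
clinical image database.  The phantom emulates the imaging situation the
pipeline is designed for:

* PET: high-uptake bladder on a low background (FDG accumulates in the
  bladder), rendered at coarser in-plane resolution than CT and blurred
  in-plane to mimic PET partial-volume effects;
* CT: poor soft-tissue contrast (the bladder is only a few HU above
  background), a surrounding high-attenuation "pelvic ring", optional radial
  streak artifacts (beam hardening between dense bone), and additive Gaussian
  noise.

Geometry defaults are chosen so that the 20%-of-SUVmax rule recovers the true
mask with high Dice overlap: the bladder is large relative to the total PET
smoothing kernel, which is the regime in which fixed-fraction thresholding is
a valid weak labeller.
"""

from __future__ import annotations

from dataclasses import dataclass, field, replace
from typing import List, Sequence, Tuple

import numpy as np
from scipy.ndimage import gaussian_filter

from .volumes import Volume


class PhantomConfigError(ValueError):
    """Raised for phantom configurations that cannot be rendered."""


@dataclass(frozen=True)
class PhantomConfig:
    """Parameters of one synthetic PET/CT case.

    ``bladder_center`` is in fractional grid coordinates (slice, row, col);
    ``bladder_semiaxes_mm`` are the ellipsoid half-axes in mm along (z, y, x).
    ``uptake_ratio`` is the bladder-to-background PET intensity ratio; values
    above ~5 separate bladder from background under the 20% threshold rule.
    ``soft_tissue_contrast`` is the (small) CT intensity gap between bladder
    and surrounding soft tissue, in HU.
    """

    ct_shape: Tuple[int, int, int] = (12, 128, 128)
    ct_spacing: Tuple[float, float, float] = (4.0, 1.0, 1.0)
    pet_downsample_factor: int = 2
    bladder_center: Tuple[float, float, float] = (0.5, 0.5, 0.5)
    bladder_semiaxes_mm: Tuple[float, float, float] = (18.0, 40.0, 35.0)
    uptake_ratio: float = 15.0
    pet_background: float = 0.5
    ct_background: float = 40.0
    soft_tissue_contrast: float = 12.0
    bone_ring: bool = True
    bone_ring_intensity: float = 800.0
    streak_artifacts: bool = False
    streak_amplitude: float = 25.0
    noise_sd: float = 5.0
    pet_blur_sigma_mm: float = 0.7
    seed: int = 0

    def __post_init__(self) -> None:
        if self.pet_downsample_factor < 1:
            raise PhantomConfigError("pet_downsample_factor must be >= 1")
        if self.uptake_ratio <= 1:
            raise PhantomConfigError("uptake_ratio must be > 1")
        if any(n < 1 for n in self.ct_shape) or any(s <= 0 for s in self.ct_spacing):
            raise PhantomConfigError("invalid CT grid")
        if any(a < 0 for a in self.bladder_semiaxes_mm):
            raise PhantomConfigError("bladder semi-axes must be nonnegative")


@dataclass
class PhantomCase:
    """A rendered phantom: CT, PET and the true bladder mask on the CT grid."""

    ct: Volume
    pet: Volume
    true_mask: np.ndarray
    patient_id: str

    def __post_init__(self) -> None:
        if self.true_mask.shape != self.ct.shape:
            raise ValueError("true_mask must live on the CT grid")
        if not np.isin(self.true_mask, (0, 1)).all():
            raise ValueError("true_mask values must be in {0, 1}")
        if not self.true_mask.any():
            raise ValueError("true_mask must contain at least one foreground voxel")


def _grid_mm(shape: Tuple[int, int, int], spacing: Tuple[float, float, float]):
    axes = [np.arange(n, dtype=np.float64) * s for n, s in zip(shape, spacing)]
    return np.meshgrid(*axes, indexing="ij", sparse=True)


def rasterize_ellipsoid(
    shape: Tuple[int, int, int],
    spacing: Tuple[float, float, float],
    center_mm: Tuple[float, float, float],
    semiaxes_mm: Tuple[float, float, float],
) -> np.ndarray:
    """Binary ellipsoid on a voxel grid (pixel-center inclusion test).

    A voxel is foreground when its center satisfies the ellipsoid inequality
    ``sum(((x - c) / a)^2) <= 1``.  The voxel nearest the center is always
    included, so the small-semi-axis limit is a single-voxel bladder rather
    than an empty mask.
    """
    zz, yy, xx = _grid_mm(shape, spacing)
    semis = np.maximum(np.asarray(semiaxes_mm, dtype=np.float64), 1e-9)
    q = (
        ((zz - center_mm[0]) / semis[0]) ** 2
        + ((yy - center_mm[1]) / semis[1]) ** 2
        + ((xx - center_mm[2]) / semis[2]) ** 2
    )
    mask = (q <= 1.0).astype(np.uint8)
    nearest = tuple(int(np.clip(round(c / s), 0, n - 1)) for c, s, n in zip(center_mm, spacing, shape))
    mask[nearest] = 1
    return mask


def _block_mean_2d(stack: np.ndarray, f: int) -> np.ndarray:
    """In-plane f x f block average of a (z, y, x) stack (y, x divisible by f)."""
    z, y, x = stack.shape
    return stack.reshape(z, y // f, f, x // f, f).mean(axis=(2, 4))


def generate_phantom(config: PhantomConfig = PhantomConfig(), patient_id: str = "phantom-000") -> PhantomCase:
    """Render one phantom case from its configuration (deterministic in seed)."""
    shape, spacing = config.ct_shape, config.ct_spacing
    extent = tuple((n - 1) * s for n, s in zip(shape, spacing))
    center_mm = tuple(f * e for f, e in zip(config.bladder_center, extent))
    if any(c < 0 or c > e for c, e in zip(center_mm, extent)):
        raise PhantomConfigError(f"bladder center {center_mm} outside the field of view {extent}")

    rng = np.random.default_rng(config.seed)
    true_mask = rasterize_ellipsoid(shape, spacing, center_mm, config.bladder_semiaxes_mm)

    # --- CT -----------------------------------------------------------------
    ct = np.full(shape, config.ct_background, dtype=np.float64)
    ct += config.soft_tissue_contrast * true_mask
    zz, yy, xx = _grid_mm(shape, spacing)
    cy, cx = extent[1] / 2.0, extent[2] / 2.0
    r = np.sqrt((yy - cy) ** 2 + (xx - cx) ** 2) + 0.0 * zz
    r_ring = 0.42 * min(extent[1], extent[2])
    if config.bone_ring:
        ring = np.exp(-0.5 * ((r - r_ring) / (0.03 * min(extent[1], extent[2]))) ** 2)
        ct += config.bone_ring_intensity * ring
    if config.streak_artifacts:
        theta = np.arctan2(yy - cy, xx - cx) + 0.0 * zz
        # low-amplitude radial stripes inside the ring, strongest near the bone
        streaks = config.streak_amplitude * np.sin(16.0 * theta) * np.clip(r / r_ring, 0.0, 1.0)
        ct += np.where(r < r_ring, streaks, 0.0)
    if config.noise_sd > 0:
        ct += rng.normal(0.0, config.noise_sd, size=shape)

    # --- PET ----------------------------------------------------------------
    bg = config.pet_background
    uptake = config.uptake_ratio * bg
    pet_fine = bg + (uptake - bg) * true_mask.astype(np.float64)
    sig = config.pet_blur_sigma_mm
    if sig > 0:
        # in-plane partial-volume blur; PET slices share the CT slice grid
        pet_fine = gaussian_filter(pet_fine, sigma=(0.0, sig / spacing[1], sig / spacing[2]), mode="nearest")
    f = config.pet_downsample_factor
    if shape[1] % f or shape[2] % f:
        raise PhantomConfigError(f"in-plane CT shape {shape[1:]} not divisible by pet_downsample_factor {f}")
    pet_data = _block_mean_2d(pet_fine, f)
    pet_spacing = (spacing[0], spacing[1] * f, spacing[2] * f)
    pet_origin = (0.0, (f - 1) / 2.0 * spacing[1], (f - 1) / 2.0 * spacing[2])

    ct_vol = Volume(data=ct.astype(np.float32), spacing=spacing, origin=(0.0, 0.0, 0.0),
                    modality="CT", patient_id=patient_id)
    pet_vol = Volume(data=pet_data.astype(np.float32), spacing=pet_spacing, origin=pet_origin,
                     modality="PET", patient_id=patient_id)
    return PhantomCase(ct=ct_vol, pet=pet_vol, true_mask=true_mask, patient_id=patient_id)


def config_for_slice_count(base: PhantomConfig, n_bladder_slices: int, pad_slices: int = 3) -> PhantomConfig:
    """Derive a config whose true mask spans exactly ``n_bladder_slices`` slices.

    The bladder is centered along z and its z half-axis is set just under the
    half-extent of the requested slice run, so exactly that many slice planes
    intersect the ellipsoid.
    """
    if n_bladder_slices < 1:
        raise PhantomConfigError("n_bladder_slices must be >= 1")
    dz = base.ct_spacing[0]
    n_slices = n_bladder_slices + 2 * pad_slices
    semi_z = ((n_bladder_slices - 1) / 2.0 + 0.45) * dz
    center_z_frac = ((n_slices - 1) / 2.0) / (n_slices - 1) if n_slices > 1 else 0.0
    return replace(
        base,
        ct_shape=(n_slices, base.ct_shape[1], base.ct_shape[2]),
        bladder_center=(center_z_frac, base.bladder_center[1], base.bladder_center[2]),
        bladder_semiaxes_mm=(semi_z, base.bladder_semiaxes_mm[1], base.bladder_semiaxes_mm[2]),
    )


def generate_cohort(
    n_patients: int,
    per_patient_slices: int | Sequence[int],
    base_config: PhantomConfig = PhantomConfig(),
    seed: int = 0,
) -> List[PhantomCase]:
    """Generate a cohort of phantom patients with jittered anatomy.

    ``per_patient_slices`` fixes, per patient, the number of bladder-bearing
    slices of the true mask (an int applies to every patient; a sequence gives
    each patient its own count — with unequal counts any cohort total, e.g.
    the 845 slices of a 29-patient study, is reachable).  Bladder size,
    position, contrast and uptake are jittered per patient from a seeded RNG.
    """
    if n_patients < 1:
        raise PhantomConfigError("n_patients must be >= 1")
    if isinstance(per_patient_slices, (int, np.integer)):
        counts = [int(per_patient_slices)] * n_patients
    else:
        counts = [int(c) for c in per_patient_slices]
        if len(counts) != n_patients:
            raise PhantomConfigError("per_patient_slices sequence must have n_patients entries")
    rng = np.random.default_rng(seed)
    cases: List[PhantomCase] = []
    for i, k in enumerate(counts):
        jit_semi = (
            base_config.bladder_semiaxes_mm[0],
            base_config.bladder_semiaxes_mm[1] * float(rng.uniform(0.85, 1.1)),
            base_config.bladder_semiaxes_mm[2] * float(rng.uniform(0.85, 1.1)),
        )
        jit_center = (
            base_config.bladder_center[0],
            float(np.clip(base_config.bladder_center[1] + rng.uniform(-0.04, 0.04), 0.1, 0.9)),
            float(np.clip(base_config.bladder_center[2] + rng.uniform(-0.04, 0.04), 0.1, 0.9)),
        )
        cfg = replace(
            base_config,
            bladder_semiaxes_mm=jit_semi,
            bladder_center=jit_center,
            soft_tissue_contrast=base_config.soft_tissue_contrast * float(rng.uniform(0.7, 1.3)),
            uptake_ratio=max(6.0, base_config.uptake_ratio * float(rng.uniform(0.8, 1.2))),
            streak_artifacts=bool(rng.random() < 0.3),
            seed=int(rng.integers(0, 2**31 - 1)),
        )
        cfg = config_for_slice_count(cfg, k)
        cases.append(generate_phantom(cfg, patient_id=f"phantom-{i:03d}"))
    return cases
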