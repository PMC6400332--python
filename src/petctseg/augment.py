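"""Data augmentation with exact output-count accounting.

Training a segmentation network on a few hundred slices requires enlarging
the dataset.  The scheme here applies, to every slice/label pair, the full
cross-product of user-supplied rotation angles and x/y scale factors (the
identity transform is always a member), and then duplicates each transformed
pair with noise added to the *image only*.  The output size is therefore an
exact function of the configuration:

    variants per slice = |angles| * |scales_x| * |scales_y| * (1 + sum copies)

With the default configuration (3 angles x 3 x-scales x 3 y-scales, one
Gaussian copy) every slice yields 27 transformed variants and 54 total — the
magnification factors 27 and 54, so 630 input slices become 34,020.

Geometric transforms are applied identically to image and mask (bilinear for
the image, nearest-neighbour for the mask so labels stay binary); noise never
touches the mask.  A patient-level train/test splitter is included so that no
patient contributes slices to both sides.
"""

from __future__ import annotations

import itertools
from dataclasses import dataclass, field, replace
from typing import Dict, List, Sequence, Tuple

import numpy as np
from scipy import ndimage
from sklearn.base import BaseEstimator, TransformerMixin

from .labels import Provenance, SlicePair

#: Parameter bounds of the augmentation scheme (maximal rotation angle in
#: degrees, maximal |scale - 1|, maximal Gaussian sd, maximal uniform noise
#: amplitude, maximal salt-and-pepper density).
MAX_ROTATION_DEG = 180.0
MAX_SCALE_DELTA = 0.15
MAX_GAUSSIAN_SD = 10.0
MAX_UNIFORM_AMPLITUDE = 10.0
MAX_SALT_PEPPER_DENSITY = 0.5

NOISE_TYPES = ("gaussian", "uniform", "salt_pepper")


class AugmentationConfigError(ValueError):
    """Raised when an augmentation configuration violates the parameter bounds."""


@dataclass(frozen=True)
class NoiseSpec:
    """One noise augmentation: type, its parameter, copies per transformed slice.

    ``param`` is the standard deviation (gaussian), amplitude (uniform) or
    pixel density (salt_pepper).
    """

    type: str
    param: float
    copies: int = 1

    def __post_init__(self) -> None:
        if self.type not in NOISE_TYPES:
            raise AugmentationConfigError(f"unknown noise type {self.type!r} (one of {NOISE_TYPES})")
        limit = {"gaussian": MAX_GAUSSIAN_SD, "uniform": MAX_UNIFORM_AMPLITUDE,
                 "salt_pepper": MAX_SALT_PEPPER_DENSITY}[self.type]
        if not 0 <= self.param <= limit:
            raise AugmentationConfigError(f"{self.type} parameter {self.param} outside [0, {limit}]")
        if self.copies < 1:
            raise AugmentationConfigError("copies must be >= 1")

    @property
    def tag(self) -> str:
        return f"{self.type}:{self.param:g}"


@dataclass(frozen=True)
class AugmentationConfig:
    """Explicit transform lists; determines the exact output count."""

    rotation_angles: Tuple[float, ...] = (0.0,)
    scale_factors_x: Tuple[float, ...] = (1.0,)
    scale_factors_y: Tuple[float, ...] = (1.0,)
    noise_specs: Tuple[NoiseSpec, ...] = ()
    rng_seed: int = 0

    def __post_init__(self) -> None:
        object.__setattr__(self, "rotation_angles", tuple(float(a) for a in self.rotation_angles))
        object.__setattr__(self, "scale_factors_x", tuple(float(s) for s in self.scale_factors_x))
        object.__setattr__(self, "scale_factors_y", tuple(float(s) for s in self.scale_factors_y))
        object.__setattr__(self, "noise_specs", tuple(self.noise_specs))
        if 0.0 not in self.rotation_angles:
            raise AugmentationConfigError("rotation_angles must contain 0")
        if any(abs(a) > MAX_ROTATION_DEG for a in self.rotation_angles):
            raise AugmentationConfigError(f"|rotation angle| must be <= {MAX_ROTATION_DEG}")
        for name, scales in (("scale_factors_x", self.scale_factors_x), ("scale_factors_y", self.scale_factors_y)):
            if 1.0 not in scales:
                raise AugmentationConfigError(f"{name} must contain 1.0")
            if any(s <= 0 or abs(s - 1.0) > MAX_SCALE_DELTA + 1e-9 for s in scales):
                raise AugmentationConfigError(f"{name} entries must lie within 1 +/- {MAX_SCALE_DELTA}")

    @property
    def transformed_per_slice(self) -> int:
        return len(self.rotation_angles) * len(self.scale_factors_x) * len(self.scale_factors_y)

    @property
    def variants_per_slice(self) -> int:
        return self.transformed_per_slice * (1 + sum(s.copies for s in self.noise_specs))

    def to_dict(self) -> Dict:
        return {
            "rotation_angles": list(self.rotation_angles),
            "scale_factors_x": list(self.scale_factors_x),
            "scale_factors_y": list(self.scale_factors_y),
            "noise": [{"type": s.type, "param": s.param, "copies": s.copies} for s in self.noise_specs],
            "rng_seed": self.rng_seed,
        }

    @classmethod
    def from_dict(cls, d: Dict) -> "AugmentationConfig":
        return cls(
            rotation_angles=tuple(d.get("rotation_angles", (0.0,))),
            scale_factors_x=tuple(d.get("scale_factors_x", (1.0,))),
            scale_factors_y=tuple(d.get("scale_factors_y", (1.0,))),
            noise_specs=tuple(NoiseSpec(n["type"], float(n["param"]), int(n.get("copies", 1)))
                              for n in d.get("noise", [])),
            rng_seed=int(d.get("rng_seed", 0)),
        )


#: Default configuration: rotations {-45, 0, 45} deg, scales {0.9, 1.0, 1.1}
#: in x and y, one zero-mean Gaussian (sd 5) copy of every transformed slice.
#: Yields exactly 27 transformed and 54 total variants per input slice.
DEFAULT_AUG_CONFIG = AugmentationConfig(
    rotation_angles=(-45.0, 0.0, 45.0),
    scale_factors_x=(0.9, 1.0, 1.1),
    scale_factors_y=(0.9, 1.0, 1.1),
    noise_specs=(NoiseSpec("gaussian", 5.0, 1),),
)


# ---------------------------------------------------------------------------
# Geometric transforms
# ---------------------------------------------------------------------------

def _affine_matrix(angle_deg: float, sx: float, sy: float, shape: Tuple[int, int]):
    """Inverse (output -> input) matrix/offset for rotation+scaling about the center.

    Positive angles rotate content counter-clockwise in (row, col) display
    coordinates.  Coordinates are pixel-center based; the canvas size is
    unchanged.
    """
    theta = np.deg2rad(angle_deg)
    c, s = np.cos(theta), np.sin(theta)
    # forward map: p_out = S @ R @ (p_in - ctr) + ctr with p = (row, col)
    rot = np.array([[c, -s], [s, c]])
    scale = np.diag([sy, sx])
    fwd = scale @ rot
    inv = np.linalg.inv(fwd)
    ctr = (np.asarray(shape, dtype=float) - 1.0) / 2.0
    offset = ctr - inv @ ctr
    return inv, offset


def _transform_stack(stack: np.ndarray, angle_deg: float, sx: float, sy: float,
                     order: int, fill: np.ndarray) -> np.ndarray:
    """Apply one 2D affine to a (n, rows, cols) stack with per-image fill values."""
    inv, offset = _affine_matrix(angle_deg, sx, sy, stack.shape[1:])
    m3 = np.eye(3)
    m3[1:, 1:] = inv
    off3 = np.array([0.0, offset[0], offset[1]])
    fill = fill.reshape(-1, 1, 1)
    shifted = stack - fill  # out-of-bounds fill becomes the per-image fill value
    out = ndimage.affine_transform(shifted, m3, offset=off3, order=order,
                                   mode="constant", cval=0.0, prefilter=False)
    return out + fill


def apply_affine(pair: SlicePair, angle_deg: float, sx: float, sy: float) -> SlicePair:
    """Rotate/scale one slice pair about the image center.

    The image is interpolated bilinearly with out-of-bounds regions filled
    with the image minimum; the mask uses nearest-neighbour interpolation
    (stays binary) with 0 fill.  Output dimensions are unchanged.
    """
    if abs(sx - 1.0) > MAX_SCALE_DELTA + 1e-9 or abs(sy - 1.0) > MAX_SCALE_DELTA + 1e-9:
        raise AugmentationConfigError(f"scale factors ({sx}, {sy}) outside 1 +/- {MAX_SCALE_DELTA}")
    if abs(angle_deg) > MAX_ROTATION_DEG:
        raise AugmentationConfigError(f"|angle| {angle_deg} exceeds {MAX_ROTATION_DEG} degrees")
    img = np.asarray(pair.image, dtype=np.float32)[None]
    msk = np.asarray(pair.mask, dtype=np.uint8)[None]
    timg = _transform_stack(img, angle_deg, sx, sy, order=1, fill=np.array([img.min()], dtype=np.float32))[0]
    tmsk = _transform_stack(msk.astype(np.float32), angle_deg, sx, sy, order=0,
                            fill=np.zeros(1, dtype=np.float32))[0].astype(np.uint8)
    prov = replace(pair.provenance, angle_deg=float(angle_deg), scale_x=float(sx), scale_y=float(sy))
    return SlicePair(image=timg, mask=tmsk, patient_id=pair.patient_id,
                     slice_index=pair.slice_index, provenance=prov)


# ---------------------------------------------------------------------------
# Noise
# ---------------------------------------------------------------------------

def add_noise(pair: SlicePair, spec: NoiseSpec, rng: np.random.Generator) -> SlicePair:
    """Add noise to the image only; the mask is returned bit-identical."""
    img = np.asarray(pair.image, dtype=np.float32)
    if spec.type == "gaussian":
        noisy = img + rng.normal(0.0, spec.param, size=img.shape).astype(np.float32)
    elif spec.type == "uniform":
        noisy = img + rng.uniform(-spec.param, spec.param, size=img.shape).astype(np.float32)
    elif spec.type == "salt_pepper":
        noisy = img.copy()
        n_total = int(round(spec.param * img.size))
        idx = rng.choice(img.size, size=n_total, replace=False)
        n_salt = n_total // 2
        flat = noisy.reshape(-1)
        flat[idx[:n_salt]] = img.max()
        flat[idx[n_salt:]] = img.min()
    else:  # pragma: no cover - guarded by NoiseSpec
        raise AugmentationConfigError(f"unknown noise type {spec.type!r}")
    prov = replace(pair.provenance, noise=spec.tag)
    return SlicePair(image=noisy, mask=pair.mask.copy(), patient_id=pair.patient_id,
                     slice_index=pair.slice_index, provenance=prov)


# ---------------------------------------------------------------------------
# Dataset-level driver
# ---------------------------------------------------------------------------

def augment_dataset(pairs: Sequence[SlicePair], config: AugmentationConfig = DEFAULT_AUG_CONFIG) -> List[SlicePair]:
    """Emit the full augmentation cross-product for every input pair.

    For each input slice, every (angle, sx, sy) variant is produced, followed
    by ``copies`` noisy duplicates of each variant per noise spec.  The output
    is grouped by input slice and its length is exactly
    ``len(pairs) * config.variants_per_slice``.  Deterministic given
    ``config.rng_seed``.
    """
    if len(pairs) == 0:
        raise AugmentationConfigError("augment_dataset requires at least one input pair")
    combos = list(itertools.product(config.rotation_angles, config.scale_factors_x, config.scale_factors_y))

    # batch the affine transforms per canvas shape for speed
    by_shape: Dict[Tuple[int, int], List[int]] = {}
    for i, p in enumerate(pairs):
        by_shape.setdefault(p.image.shape, []).append(i)

    transformed: List[List[SlicePair]] = [[] for _ in pairs]
    for shape, idxs in by_shape.items():
        imgs = np.stack([np.asarray(pairs[i].image, dtype=np.float32) for i in idxs])
        msks = np.stack([np.asarray(pairs[i].mask, dtype=np.float32) for i in idxs])
        fills = imgs.reshape(len(idxs), -1).min(axis=1)
        zero_fill = np.zeros(len(idxs), dtype=np.float32)
        for angle, sx, sy in combos:
            if angle == 0.0 and sx == 1.0 and sy == 1.0:
                timgs, tmsks = imgs, msks  # identity member of the cross-product
            else:
                timgs = _transform_stack(imgs, angle, sx, sy, order=1, fill=fills)
                tmsks = _transform_stack(msks, angle, sx, sy, order=0, fill=zero_fill)
            for j, i in enumerate(idxs):
                p = pairs[i]
                prov = replace(p.provenance, angle_deg=float(angle), scale_x=float(sx), scale_y=float(sy))
                transformed[i].append(SlicePair(image=timgs[j].copy(), mask=tmsks[j].astype(np.uint8),
                                                patient_id=p.patient_id, slice_index=p.slice_index,
                                                provenance=prov))

    rng = np.random.default_rng(config.rng_seed)
    out: List[SlicePair] = []
    for variants in transformed:
        out.extend(variants)
        for spec in config.noise_specs:
            for _ in range(spec.copies):
                for v in variants:
                    out.append(add_noise(v, spec, rng))
    return out


def split_by_patient(pairs: Sequence[SlicePair], train_fraction: float = 0.8,
                     seed: int = 0) -> Tuple[List[SlicePair], List[SlicePair]]:
    """Patient-level train/test split (no patient appears on both sides).

    Patients are shuffled with the seeded RNG and greedily assigned to the
    training side until the training slice count first reaches
    ``train_fraction`` of the total; the remainder is the test side.
    """
    if not 0.0 < train_fraction < 1.0:
        raise ValueError(f"train_fraction must be in (0, 1), got {train_fraction}")
    by_patient: Dict[str, List[SlicePair]] = {}
    for p in pairs:
        by_patient.setdefault(p.patient_id, []).append(p)
    patients = sorted(by_patient)
    if len(patients) < 2:
        raise ValueError("cannot split a single patient without leakage")
    rng = np.random.default_rng(seed)
    order = [patients[i] for i in rng.permutation(len(patients))]
    target = train_fraction * len(pairs)
    train_patients: List[str] = []
    count = 0
    for pid in order:
        if count >= target:
            break
        train_patients.append(pid)
        count += len(by_patient[pid])
    if len(train_patients) == len(patients):  # keep the test side nonempty
        train_patients.pop()
    train_set = set(train_patients)
    train = [p for p in pairs if p.patient_id in train_set]
    test = [p for p in pairs if p.patient_id not in train_set]
    return train, test


class SliceAugmenter(BaseEstimator, TransformerMixin):
    """Transformer-style wrapper around :func:`augment_dataset`.

    Parameters mirror :class:`AugmentationConfig`; ``transform`` maps a list
    of slice pairs to the augmented list.  Stateless apart from the seed, so
    ``fit`` only validates the configuration.
    """

    def __init__(self, rotation_angles=(-45.0, 0.0, 45.0), scale_factors_x=(0.9, 1.0, 1.1),
                 scale_factors_y=(0.9, 1.0, 1.1), noise=({"type": "gaussian", "param": 5.0, "copies": 1},),
                 rng_seed=0):
        self.rotation_angles = rotation_angles
        self.scale_factors_x = scale_factors_x
        self.scale_factors_y = scale_factors_y
        self.noise = noise
        self.rng_seed = rng_seed

    def _config(self) -> AugmentationConfig:
        return AugmentationConfig.from_dict({
            "rotation_angles": self.rotation_angles,
            "scale_factors_x": self.scale_factors_x,
            "scale_factors_y": self.scale_factors_y,
            "noise": list(self.noise),
            "rng_seed": self.rng_seed,
        })

    def fit(self, X, y=None):
        self.config_ = self._config()
        return self

    def transform(self, X):
        if not hasattr(self, "config_"):
            self.fit(X)
        return augment_dataset(X, self.config_)
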