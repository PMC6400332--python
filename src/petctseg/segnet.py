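"""Semantic segmentation networks: FCN-8s and an atrous "upsampled ResNet".

Two architecture families for 2-class (background / bladder) segmentation of
CT slices:

* **FCN-8s** — a VGG-16-shaped convolutional backbone whose fully connected
  layers are realized as convolutions.  The stride-32 score map is upsampled
  x2 with a fixed bilinear transposed convolution and summed with 1x1 score
  maps from the fourth pooling stage, upsampled x2 again and summed with
  scores from the third pooling stage, then upsampled x8 to the input size.
* **Upsampled ResNet** — a residual backbone of four stages whose strides and
  atrous (dilated) rates are arranged so that the deepest feature map is 1/8
  of the input (strides 2, 2, 2, 1 with rate-2 atrous convolution in the last
  stage), followed by a 2-class score head and a fixed bilinear x8
  interpolation back to the input size.

Channel widths are scaled by ``width_scale`` so both families train from
scratch at desk scale on phantom data; all upsampling kernels are fixed
(never trained).  Training uses Adam at a fixed learning rate of 1e-4,
batch size 1 (hence no batch normalization), and pixelwise cross-entropy.

The sklearn-style estimators :class:`FCN8sSegmenter` and
:class:`UpsampledResNetSegmenter` wrap model building, training and
prediction behind ``fit``/``predict``.
"""

from __future__ import annotations

import json
from dataclasses import asdict, dataclass, field
from pathlib import Path
from typing import Dict, List, Optional, Sequence, Tuple

import numpy as np
from sklearn.base import BaseEstimator

from . import nn
from .labels import SlicePair
from .metrics import dsc
from .nn.autograd import Tensor, _corr2d_raw

__all__ = [
    "ModelSpec", "TrainSpec", "SegModel", "bilinear_kernel", "atrous_conv2d",
    "build_fcn8s", "build_upsampled_resnet", "build_model", "train", "predict",
    "FCN8sSegmenter", "UpsampledResNetSegmenter",
]

FAMILIES = ("fcn8s", "upsampled_resnet")


@dataclass(frozen=True)
class ModelSpec:
    """Architecture family, class count and width scaling."""

    family: str = "fcn8s"
    num_classes: int = 2
    input_size: Tuple[int, int] = (256, 256)
    width_scale: float = 1.0
    stage_depth: int = 1  # residual blocks per stage (upsampled_resnet only)
    upsample_kernels_fixed: bool = True

    def __post_init__(self) -> None:
        if self.family not in FAMILIES:
            raise ValueError(f"family must be one of {FAMILIES}, got {self.family!r}")
        if not 0 < self.width_scale <= 1:
            raise ValueError("width_scale must be in (0, 1]")
        if self.num_classes < 2:
            raise ValueError("num_classes must be >= 2")
        if not self.upsample_kernels_fixed:
            raise ValueError("upsampling kernels are always fixed in this implementation")


@dataclass(frozen=True)
class TrainSpec:
    """Optimization protocol: Adam, fixed lr 1e-4, batch size 1, cross-entropy."""

    iterations: int = 300
    learning_rate: float = 1e-4
    seed: int = 0

    def __post_init__(self) -> None:
        if self.iterations < 0:
            raise ValueError("iterations must be >= 0")
        if self.learning_rate <= 0:
            raise ValueError("learning_rate must be positive")


def bilinear_kernel(factor: int) -> np.ndarray:
    """Square separable bilinear (triangular) kernel, side ``2f - f mod 2``.

    Peak value 1 at the kernel center; used as the fixed filter of a
    transposed convolution with stride ``factor``, where it performs bilinear
    interpolation (and forms a partition of unity on the interior).
    """
    return nn.bilinear_kernel(factor)


def atrous_conv2d(image: np.ndarray, kernel: np.ndarray, rate: int = 1) -> np.ndarray:
    """Atrous (dilated) convolution of a 2D image with a 2D kernel.

    The kernel taps are spaced ``rate`` pixels apart; spatial size is
    preserved by same-padding.  Rate 1 is standard convolution.
    """
    if rate < 1:
        raise ValueError("rate must be >= 1")
    img = np.asarray(image, dtype=np.float64)
    ker = np.asarray(kernel, dtype=np.float64)
    if img.ndim != 2 or ker.ndim != 2:
        raise ValueError("atrous_conv2d expects 2D image and kernel")
    return _corr2d_raw(img[None], ker[None, None], rate)[0]


# ---------------------------------------------------------------------------
# Model container
# ---------------------------------------------------------------------------

def _width(base: int, scale: float) -> int:
    return max(2, int(round(base * scale)))


def _he_conv(rng: np.random.Generator, c_out: int, c_in: int, k: int) -> Tensor:
    std = np.sqrt(2.0 / (c_in * k * k))
    return nn.parameter(rng.normal(0.0, std, size=(c_out, c_in, k, k)))


def _zero_conv(c_out: int, c_in: int, k: int = 1) -> Tensor:
    return nn.parameter(np.zeros((c_out, c_in, k, k)))


def _bias(c_out: int) -> Tensor:
    return nn.parameter(np.zeros(c_out))


class SegModel:
    """A built network: parameter store plus a forward pass.

    Images are standardized per image inside ``forward`` using robust
    statistics (median / scaled MAD, clipped to ±20): CT intensity
    distributions are heavy-tailed — dense bone spans hundreds of HU while
    the bladder/soft-tissue contrast is on the order of 10 HU — and a robust
    scale keeps that low-contrast signal at order 1 instead of letting the
    bone dynamic range crush it.
    """

    def __init__(self, spec: ModelSpec, params: Dict[str, Tensor], forward_fn):
        self.spec = spec
        self.params = params
        self._forward_fn = forward_fn

    def parameters(self) -> List[Tensor]:
        return list(self.params.values())

    def forward(self, image: np.ndarray) -> Tensor:
        img = np.asarray(image, dtype=np.float64)
        if img.shape != tuple(self.spec.input_size):
            raise ValueError(f"image shape {img.shape} != model input size {self.spec.input_size}")
        med = np.median(img)
        mad = np.median(np.abs(img - med))
        img = np.clip((img - med) / (1.4826 * mad + 1e-6), -20.0, 20.0)
        return self._forward_fn(Tensor(img[None]), self.params)

    def state_dict(self) -> Dict[str, np.ndarray]:
        return {k: v.data.copy() for k, v in self.params.items()}

    def load_state_dict(self, state: Dict[str, np.ndarray]) -> None:
        for k, v in self.params.items():
            v.data = np.asarray(state[k], dtype=np.float64).copy()

    def save(self, path, train_spec: Optional["TrainSpec"] = None) -> None:
        """Write weights (.npz) plus a JSON sidecar with the model (and, if
        given, training) specification, so a run is reproducible from disk."""
        path = Path(path)
        path.parent.mkdir(parents=True, exist_ok=True)
        np.savez_compressed(path, **self.state_dict())
        meta = {"model_spec": asdict(self.spec)}
        if train_spec is not None:
            meta["train_spec"] = asdict(train_spec)
        with open(path.with_suffix(".json"), "w") as fh:
            json.dump(meta, fh, indent=2)

    @classmethod
    def load(cls, path) -> "SegModel":
        path = Path(path)
        with open(path.with_suffix(".json")) as fh:
            spec = ModelSpec(**{k: tuple(v) if isinstance(v, list) else v
                                for k, v in json.load(fh)["model_spec"].items()})
        model = build_model(spec)
        with np.load(path if path.suffix == ".npz" else path.with_suffix(".npz")) as data:
            model.load_state_dict({k: data[k] for k in data.files})
        return model


# ---------------------------------------------------------------------------
# FCN-8s
# ---------------------------------------------------------------------------

_VGG_WIDTHS = (64, 128, 256, 512, 512)
_VGG_DEPTHS = (2, 2, 3, 3, 3)
_FC_WIDTH = 4096


def build_fcn8s(spec: ModelSpec, seed: int = 0) -> SegModel:
    """FCN-8s: VGG-16-shaped backbone with skip fusion at pool3/pool4.

    Fully connected layers are realized as a 7x7 and a 1x1 convolution; the
    three upsampling steps (x2, x2, x8) use fixed bilinear kernels.  Skip
    score convolutions are zero-initialized so training starts from the
    coarse stride-32 prediction.  Input sides must be divisible by 32.
    """
    if spec.family != "fcn8s":
        raise ValueError("build_fcn8s requires family 'fcn8s'")
    h, w = spec.input_size
    if h % 32 or w % 32:
        raise ValueError(f"FCN-8s input size must be divisible by 32, got {spec.input_size}")
    rng = np.random.default_rng(seed)
    widths = [_width(b, spec.width_scale) for b in _VGG_WIDTHS]
    fc_w = _width(_FC_WIDTH, spec.width_scale)
    k = spec.num_classes

    params: Dict[str, Tensor] = {}
    c_in = 1
    for stage, (cw, depth) in enumerate(zip(widths, _VGG_DEPTHS), start=1):
        for i in range(1, depth + 1):
            params[f"conv{stage}_{i}_w"] = _he_conv(rng, cw, c_in, 3)
            params[f"conv{stage}_{i}_b"] = _bias(cw)
            c_in = cw
    params["fc6_w"] = _he_conv(rng, fc_w, widths[4], 7)
    params["fc6_b"] = _bias(fc_w)
    params["fc7_w"] = _he_conv(rng, fc_w, fc_w, 1)
    params["fc7_b"] = _bias(fc_w)
    params["score_fr_w"] = _he_conv(rng, k, fc_w, 1)
    params["score_fr_b"] = _bias(k)
    params["score_pool4_w"] = _zero_conv(k, widths[3])
    params["score_pool4_b"] = _bias(k)
    params["score_pool3_w"] = _zero_conv(k, widths[2])
    params["score_pool3_b"] = _bias(k)

    def forward(x: Tensor, p: Dict[str, Tensor]) -> Tensor:
        pools = {}
        h_ = x
        for stage, depth in enumerate(_VGG_DEPTHS, start=1):
            for i in range(1, depth + 1):
                h_ = nn.relu(nn.conv2d(h_, p[f"conv{stage}_{i}_w"], p[f"conv{stage}_{i}_b"]))
            h_ = nn.maxpool2(h_)
            pools[stage] = h_
        h_ = nn.relu(nn.conv2d(pools[5], p["fc6_w"], p["fc6_b"]))
        h_ = nn.relu(nn.conv2d(h_, p["fc7_w"], p["fc7_b"]))
        score = nn.conv2d(h_, p["score_fr_w"], p["score_fr_b"])            # stride 32
        up2 = nn.upsample_bilinear(score, 2)                                # stride 16
        s4 = nn.conv2d(pools[4], p["score_pool4_w"], p["score_pool4_b"])
        fuse4 = nn.add(up2, s4)
        up4 = nn.upsample_bilinear(fuse4, 2)                                # stride 8
        s3 = nn.conv2d(pools[3], p["score_pool3_w"], p["score_pool3_b"])
        fuse3 = nn.add(up4, s3)
        return nn.upsample_bilinear(fuse3, 8)                               # stride 1

    return SegModel(spec, params, forward)


# ---------------------------------------------------------------------------
# Upsampled ResNet (output stride 8 via atrous convolution)
# ---------------------------------------------------------------------------

_RES_WIDTHS = (64, 128, 256, 512)
_RES_STRIDES = (2, 2, 2, 1)   # stage strides; total downsampling 8
_RES_RATES = (1, 1, 1, 2)     # atrous rate per stage (dilated where stride stays 1)


def build_upsampled_resnet(spec: ModelSpec, seed: int = 0) -> SegModel:
    """Residual backbone with output stride 8 and fixed bilinear x8 upsampling.

    Four residual stages (width-/depth-scaled stand-in for a deep ResNet):
    the first three halve resolution, the last keeps it and dilates its
    convolutions with atrous rate 2 instead.  A 1x1 score head and a fixed
    bilinear x8 interpolation produce full-resolution logits.  Input sides
    must be divisible by 8.
    """
    if spec.family != "upsampled_resnet":
        raise ValueError("build_upsampled_resnet requires family 'upsampled_resnet'")
    h, w = spec.input_size
    if h % 8 or w % 8:
        raise ValueError(f"upsampled ResNet input size must be divisible by 8, got {spec.input_size}")
    rng = np.random.default_rng(seed)
    widths = [_width(b, spec.width_scale) for b in _RES_WIDTHS]
    k = spec.num_classes

    params: Dict[str, Tensor] = {}
    params["stem_w"] = _he_conv(rng, widths[0], 1, 3)
    params["stem_b"] = _bias(widths[0])
    c_in = widths[0]
    for s, cw in enumerate(widths):
        for blk in range(spec.stage_depth):
            pre = f"s{s}b{blk}"
            params[f"{pre}_conv1_w"] = _he_conv(rng, cw, c_in, 3)
            params[f"{pre}_conv1_b"] = _bias(cw)
            params[f"{pre}_conv2_w"] = _he_conv(rng, cw, cw, 3)
            params[f"{pre}_conv2_b"] = _bias(cw)
            if c_in != cw:
                params[f"{pre}_proj_w"] = _he_conv(rng, cw, c_in, 1)
                params[f"{pre}_proj_b"] = _bias(cw)
            c_in = cw
    params["score_w"] = _he_conv(rng, k, widths[3], 1)
    params["score_b"] = _bias(k)

    def block(x: Tensor, p: Dict[str, Tensor], pre: str, rate: int) -> Tensor:
        h_ = nn.relu(nn.conv2d(x, p[f"{pre}_conv1_w"], p[f"{pre}_conv1_b"], dilation=rate))
        h_ = nn.conv2d(h_, p[f"{pre}_conv2_w"], p[f"{pre}_conv2_b"], dilation=rate)
        if f"{pre}_proj_w" in p:
            x = nn.conv2d(x, p[f"{pre}_proj_w"], p[f"{pre}_proj_b"])
        return nn.relu(nn.add(h_, x))

    def forward(x: Tensor, p: Dict[str, Tensor]) -> Tensor:
        h_ = nn.relu(nn.conv2d(x, p["stem_w"], p["stem_b"]))
        for s in range(4):
            if _RES_STRIDES[s] == 2:
                h_ = nn.maxpool2(h_)
            for blk in range(spec.stage_depth):
                h_ = block(h_, p, f"s{s}b{blk}", _RES_RATES[s])
        score = nn.conv2d(h_, p["score_w"], p["score_b"])  # stride 8
        return nn.upsample_bilinear(score, 8)

    return SegModel(spec, params, forward)


def build_model(spec: ModelSpec, seed: int = 0) -> SegModel:
    if spec.family == "fcn8s":
        return build_fcn8s(spec, seed=seed)
    return build_upsampled_resnet(spec, seed=seed)


# ---------------------------------------------------------------------------
# Training / prediction
# ---------------------------------------------------------------------------

def train(model: SegModel, pairs: Sequence[SlicePair], spec: TrainSpec = TrainSpec()) -> Tuple[SegModel, List[float]]:
    """Train a model on slice pairs; returns the model and its loss trace.

    One image per step (batch size 1), pixelwise cross-entropy, Adam at the
    fixed learning rate.  The fixed bilinear upsampling kernels carry no
    parameters, so only backbone and score weights are updated.  Images are
    visited in cyclic order; the run is deterministic given the model's
    initialization seed.
    """
    if len(pairs) == 0:
        raise ValueError("train requires at least one pair")
    hw = tuple(model.spec.input_size)
    for i, p in enumerate(pairs):
        if p.image.shape != hw or p.mask.shape != hw:
            raise ValueError(f"pair {i}: image/mask shape {p.image.shape}/{p.mask.shape} "
                             f"does not match model input size {hw}")
    opt = nn.Adam(model.parameters(), lr=spec.learning_rate)
    trace: List[float] = []
    n = len(pairs)
    for t in range(spec.iterations):
        pair = pairs[t % n]
        opt.zero_grad()
        logits = model.forward(pair.image)
        loss = nn.softmax_cross_entropy(logits, pair.mask.astype(np.int64))
        loss.backward()
        opt.step()
        trace.append(float(loss.data))
    return model, trace


def predict(model: SegModel, image: np.ndarray) -> np.ndarray:
    """Per-pixel argmax over the 2-class logits; ties go to background."""
    logits = model.forward(image).data
    return (logits[1] > logits[0]).astype(np.uint8)


# ---------------------------------------------------------------------------
# Estimators
# ---------------------------------------------------------------------------

class _SegmenterBase(BaseEstimator):
    """Shared fit/predict logic for both architecture families."""

    _family = ""

    def __init__(self, width_scale: float = 0.125, iterations: int = 300,
                 learning_rate: float = 1e-4, stage_depth: int = 1, seed: int = 0):
        self.width_scale = width_scale
        self.iterations = iterations
        self.learning_rate = learning_rate
        self.stage_depth = stage_depth
        self.seed = seed

    @staticmethod
    def _as_stack(X) -> np.ndarray:
        arr = np.stack([np.asarray(x) for x in X]) if isinstance(X, (list, tuple)) else np.asarray(X)
        if arr.ndim != 3:
            raise ValueError(f"expected (n, H, W) images, got shape {arr.shape}")
        return arr

    def fit(self, X, y):
        """Train on images X (n, H, W) and binary masks y (n, H, W)."""
        X = self._as_stack(X)
        y = self._as_stack(y).astype(np.uint8)
        if X.shape != y.shape:
            raise ValueError(f"X shape {X.shape} != y shape {y.shape}")
        pairs = [SlicePair(image=xi.astype(np.float32), mask=yi) for xi, yi in zip(X, y)]
        self.model_spec_ = ModelSpec(family=self._family, input_size=X.shape[1:],
                                     width_scale=self.width_scale, stage_depth=self.stage_depth)
        self.train_spec_ = TrainSpec(iterations=self.iterations, learning_rate=self.learning_rate,
                                     seed=self.seed)
        self.model_ = build_model(self.model_spec_, seed=self.seed)
        self.model_, self.loss_trace_ = train(self.model_, pairs, self.train_spec_)
        self.n_iter_ = len(self.loss_trace_)
        return self

    def predict(self, X) -> np.ndarray:
        X = self._as_stack(X)
        return np.stack([predict(self.model_, xi) for xi in X])

    def score(self, X, y) -> float:
        """Mean Dice coefficient over the given images/masks."""
        y = self._as_stack(y).astype(np.uint8)
        preds = self.predict(X)
        vals = [dsc(p, g) for p, g in zip(preds, y)]
        vals = [v for v in vals if not np.isnan(v)]
        return float(np.mean(vals)) if vals else float("nan")


class FCN8sSegmenter(_SegmenterBase):
    """FCN-8s segmentation as a scikit-learn style estimator."""

    _family = "fcn8s"


class UpsampledResNetSegmenter(_SegmenterBase):
    """Atrous upsampled-ResNet segmentation as a scikit-learn style estimator."""

    _family = "upsampled_resnet"
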