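"""Minimal reverse-mode automatic differentiation on numpy arrays.

Just enough machinery for batch-size-1 fully convolutional segmentation
networks: stride-1 (optionally dilated/atrous) same-padded convolution,
2x2 max pooling, factor-2 subsampling, ReLU, elementwise addition,
fixed-kernel transposed convolution for bilinear upsampling, and a softmax
cross-entropy loss.  Downsampling by strided convolution is expressed as a
stride-1 convolution followed by :func:`subsample2`, which keeps every
convolution on the same fast im2col path.

All feature maps are ``(channels, height, width)`` float64 arrays; there is
no batch axis because the training protocol processes one image per step.
"""

from __future__ import annotations

from typing import Callable, List, Optional, Tuple

import numpy as np
from numpy.lib.stride_tricks import sliding_window_view


class Tensor:
    """A node in the computation graph."""

    __slots__ = ("data", "grad", "requires_grad", "_parents", "_backward")

    def __init__(self, data: np.ndarray, requires_grad: bool = False,
                 parents: Tuple["Tensor", ...] = (),
                 backward: Optional[Callable[[np.ndarray], None]] = None):
        self.data = np.asarray(data, dtype=np.float64)
        self.grad: Optional[np.ndarray] = None
        self.requires_grad = requires_grad
        self._parents = parents
        self._backward = backward

    @property
    def shape(self):
        return self.data.shape

    def _accumulate(self, g: np.ndarray) -> None:
        if self.grad is None:
            self.grad = g.copy()
        else:
            self.grad += g

    def backward(self) -> None:
        """Backpropagate from a scalar output through the graph."""
        if self.data.size != 1:
            raise ValueError("backward() must be called on a scalar tensor")
        topo: List[Tensor] = []
        seen = set()

        def visit(t: Tensor) -> None:
            if id(t) in seen:
                return
            seen.add(id(t))
            for p in t._parents:
                visit(p)
            topo.append(t)

        visit(self)
        self.grad = np.ones_like(self.data)
        for t in reversed(topo):
            if t._backward is not None and t.grad is not None:
                t._backward(t.grad)


def parameter(data: np.ndarray) -> Tensor:
    return Tensor(data, requires_grad=True)


def _needs_graph(*tensors: Tensor) -> bool:
    return any(t.requires_grad or t._parents for t in tensors)


# ---------------------------------------------------------------------------
# Convolution primitives (stride 1, same padding, odd kernels)
# ---------------------------------------------------------------------------

def _im2col(x: np.ndarray, kh: int, kw: int, dilation: int) -> np.ndarray:
    """Dilated sliding windows of a (C, H, W) array, same-padded.

    Returns an array of shape (C, H, W, kh, kw) where the window taps are
    spaced ``dilation`` pixels apart (atrous sampling).
    """
    d = dilation
    ph, pw = d * (kh - 1) // 2, d * (kw - 1) // 2
    xp = np.pad(x, ((0, 0), (ph, ph), (pw, pw)))
    eff_h, eff_w = d * (kh - 1) + 1, d * (kw - 1) + 1
    win = sliding_window_view(xp, (eff_h, eff_w), axis=(1, 2))
    return win[..., ::d, ::d]


def _corr2d_raw(x: np.ndarray, w: np.ndarray, dilation: int) -> np.ndarray:
    """Plain correlation: x (C,H,W), w (Co,C,kh,kw) -> (Co,H,W)."""
    win = _im2col(x, w.shape[2], w.shape[3], dilation)
    return np.einsum("chwij,ocij->ohw", win, w, optimize=True)


def conv2d(x: Tensor, w: Tensor, b: Optional[Tensor] = None, dilation: int = 1) -> Tensor:
    """Same-padded stride-1 (atrous) convolution.

    ``dilation`` (the atrous rate) spaces the kernel taps apart; rate 1 is
    standard convolution.  Kernel sides must be odd so "same" padding is
    symmetric.
    """
    kh, kw = w.shape[2], w.shape[3]
    if kh % 2 == 0 or kw % 2 == 0:
        raise ValueError("conv2d requires odd kernel sides")
    win = _im2col(x.data, kh, kw, dilation)
    y = np.einsum("chwij,ocij->ohw", win, w.data, optimize=True)
    if b is not None:
        y = y + b.data[:, None, None]

    parents = (x, w) + ((b,) if b is not None else ())
    if not _needs_graph(*parents):
        return Tensor(y)

    def backward(dy: np.ndarray) -> None:
        if w.requires_grad or w._parents:
            dw = np.einsum("chwij,ohw->ocij", win, dy, optimize=True)
            w._accumulate(dw)
        if b is not None and (b.requires_grad or b._parents):
            b._accumulate(dy.sum(axis=(1, 2)))
        if x.requires_grad or x._parents:
            # gradient wrt input = correlation of dy with the flipped,
            # channel-transposed kernel at the same dilation
            w_t = w.data[:, :, ::-1, ::-1].transpose(1, 0, 2, 3)
            x._accumulate(_corr2d_raw(dy, w_t, dilation))

    return Tensor(y, parents=parents, backward=backward)


def relu(x: Tensor) -> Tensor:
    y = np.maximum(x.data, 0.0)
    if not _needs_graph(x):
        return Tensor(y)

    def backward(dy: np.ndarray) -> None:
        x._accumulate(dy * (x.data > 0))

    return Tensor(y, parents=(x,), backward=backward)


def add(a: Tensor, b: Tensor) -> Tensor:
    if a.shape != b.shape:
        raise ValueError(f"add: shape mismatch {a.shape} vs {b.shape}")
    y = a.data + b.data
    if not _needs_graph(a, b):
        return Tensor(y)

    def backward(dy: np.ndarray) -> None:
        if a.requires_grad or a._parents:
            a._accumulate(dy)
        if b.requires_grad or b._parents:
            b._accumulate(dy)

    return Tensor(y, parents=(a, b), backward=backward)


def maxpool2(x: Tensor) -> Tensor:
    """2x2 max pooling with stride 2 (spatial dims must be even)."""
    c, h, w = x.data.shape
    if h % 2 or w % 2:
        raise ValueError(f"maxpool2 needs even spatial dims, got {(h, w)}")
    win = x.data.reshape(c, h // 2, 2, w // 2, 2).transpose(0, 1, 3, 2, 4).reshape(c, h // 2, w // 2, 4)
    idx = win.argmax(axis=-1)
    y = np.take_along_axis(win, idx[..., None], axis=-1)[..., 0]
    if not _needs_graph(x):
        return Tensor(y)

    def backward(dy: np.ndarray) -> None:
        dwin = np.zeros_like(win)
        np.put_along_axis(dwin, idx[..., None], dy[..., None], axis=-1)
        dx = dwin.reshape(c, h // 2, w // 2, 2, 2).transpose(0, 1, 3, 2, 4).reshape(c, h, w)
        x._accumulate(dx)

    return Tensor(y, parents=(x,), backward=backward)


def subsample2(x: Tensor) -> Tensor:
    """Keep every second pixel (the subsampling half of a stride-2 convolution)."""
    y = x.data[:, ::2, ::2]
    if not _needs_graph(x):
        return Tensor(y.copy())

    def backward(dy: np.ndarray) -> None:
        dx = np.zeros_like(x.data)
        dx[:, ::2, ::2] = dy
        x._accumulate(dx)

    return Tensor(y.copy(), parents=(x,), backward=backward)


# ---------------------------------------------------------------------------
# Fixed bilinear upsampling (transposed convolution)
# ---------------------------------------------------------------------------

def bilinear_kernel_1d(factor: int) -> np.ndarray:
    """Triangular weights of length ``2*factor - factor % 2`` peaking at 1."""
    if factor < 1:
        raise ValueError("factor must be >= 1")
    size = 2 * factor - factor % 2
    center = (size - 1) / 2.0
    i = np.arange(size, dtype=np.float64)
    return 1.0 - np.abs(i - center) / factor


def bilinear_kernel(factor: int) -> np.ndarray:
    """Separable 2D bilinear interpolation kernel for a transposed convolution."""
    k1 = bilinear_kernel_1d(factor)
    return np.outer(k1, k1)


def _convt_forward_1ch(x: np.ndarray, kernel: np.ndarray, f: int) -> np.ndarray:
    """Transposed convolution of one channel: (H, W) -> (f*H, f*W)."""
    k = kernel.shape[0]
    p = (k - f) // 2
    h, w = x.shape
    zs = np.zeros(((h - 1) * f + 1 + 2 * (k - 1 - p), (w - 1) * f + 1 + 2 * (k - 1 - p)))
    q = k - 1 - p
    zs[q:q + (h - 1) * f + 1:f, q:q + (w - 1) * f + 1:f] = x
    win = sliding_window_view(zs, (k, k))
    return np.einsum("hwij,ij->hw", win, kernel, optimize=True)


def _convt_backward_1ch(dy: np.ndarray, kernel: np.ndarray, f: int, h: int, w: int) -> np.ndarray:
    """Adjoint of the transposed convolution: strided correlation of dy."""
    k = kernel.shape[0]
    p = (k - f) // 2
    dyp = np.pad(dy, ((p, p), (p, p)))
    win = sliding_window_view(dyp, (k, k))[::f, ::f]
    return np.einsum("hwij,ij->hw", win[:h, :w], kernel, optimize=True)


def upsample_bilinear(x: Tensor, factor: int) -> Tensor:
    """Fixed-kernel transposed convolution performing bilinear upsampling.

    Applied per channel; the kernel carries no parameters and is never
    trained.  Output spatial size is exactly ``factor`` times the input.
    """
    if factor == 1:
        return x
    kernel = bilinear_kernel(factor)
    c, h, w = x.data.shape
    y = np.stack([_convt_forward_1ch(x.data[i], kernel, factor) for i in range(c)])
    if not _needs_graph(x):
        return Tensor(y)

    def backward(dy: np.ndarray) -> None:
        dx = np.stack([_convt_backward_1ch(dy[i], kernel, factor, h, w) for i in range(c)])
        x._accumulate(dx)

    return Tensor(y, parents=(x,), backward=backward)


# ---------------------------------------------------------------------------
# Loss
# ---------------------------------------------------------------------------

def softmax_cross_entropy(logits: Tensor, target: np.ndarray) -> Tensor:
    """Mean pixelwise cross-entropy between (K, H, W) logits and an integer mask."""
    k = logits.data.shape[0]
    t = np.asarray(target).astype(np.int64)
    if t.shape != logits.data.shape[1:]:
        raise ValueError(f"target shape {t.shape} != logits spatial shape {logits.data.shape[1:]}")
    z = logits.data - logits.data.max(axis=0, keepdims=True)
    logsumexp = np.log(np.exp(z).sum(axis=0)) + logits.data.max(axis=0)
    picked = np.take_along_axis(logits.data, t[None], axis=0)[0]
    n = t.size
    loss = float((logsumexp - picked).sum() / n)

    if not _needs_graph(logits):
        return Tensor(loss)

    def backward(dl: np.ndarray) -> None:
        soft = np.exp(z)
        soft /= soft.sum(axis=0, keepdims=True)
        onehot = np.zeros_like(soft)
        np.put_along_axis(onehot, t[None], 1.0, axis=0)
        logits._accumulate(float(dl) * (soft - onehot) / n)

    return Tensor(loss, parents=(logits,), backward=backward)
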