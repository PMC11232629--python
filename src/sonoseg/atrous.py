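"""Atrous (dilated) convolution and the normalise-then-convolve blocks.

The dilated convolution samples its input on a grid with spacing ``rate``:

    y[i] = sum_k x[i + r*k] w[k]        (per spatial axis, per channel pair)

so a K-tap kernel at rate ``r`` covers ``K + (K-1)(r-1)`` pixels per axis
while keeping exactly ``K*K`` weights — the field of view grows, the
parameter count does not.  ``rate=1`` is an ordinary convolution.

Convolutions here are "same"-padded with zeros, ``(K-1)*r/2`` pixels per
side, so the output spatial size always equals the input's; out-of-range
samples contribute zero.  Indexing is 0-based row-major (height, width).

The building block used throughout the segmentation network applies, in
order: batch normalisation, atrous convolution, activation.  Encoder
blocks default to ``rate=3``, decoder blocks to ``rate=1``.
"""

from __future__ import annotations

import math
from dataclasses import dataclass, field

import numpy as np

from .layers import ACTIVATIONS, BatchNorm2d, Layer, Parameter


def effective_field_of_view(K: int, r: int) -> int:
    """Span (pixels per axis) of a K-tap kernel dilated at rate ``r``.

    Dilation inserts ``r - 1`` zeros between consecutive taps, so the
    kernel covers ``K + (K - 1)(r - 1)`` pixels.
    """
    if not (isinstance(K, (int, np.integer)) and K >= 1):
        raise ValueError(f"kernel size must be a positive integer, got {K!r}")
    if not (isinstance(r, (int, np.integer)) and r >= 1):
        raise ValueError(f"dilation rate must be a positive integer, got {r!r}")
    return K + (K - 1) * (r - 1)


@dataclass
class AtrousKernel:
    """A dilated 2-D convolution kernel.

    Parameters
    ----------
    weights
        Array of shape ``(K, K, c_in, c_out)``; tap ``(0, 0)`` is the
        top-left corner of the (dilated) kernel footprint.
    rate
        Dilation rate ``r >= 1``; ``1`` reduces to standard convolution.
    bias
        Optional per-output-channel offset, shape ``(c_out,)``.
    """

    weights: np.ndarray
    rate: int = 1
    bias: np.ndarray | None = None

    def __post_init__(self):
        self.weights = np.asarray(self.weights)
        if self.weights.ndim != 4 or self.weights.shape[0] != self.weights.shape[1]:
            raise ValueError(
                "kernel weights must have shape (K, K, c_in, c_out), got "
                f"{self.weights.shape}")
        if self.weights.shape[0] % 2 == 0:
            raise ValueError("kernel size K must be odd for same-padding")
        if not (isinstance(self.rate, (int, np.integer)) and self.rate >= 1):
            raise ValueError(f"dilation rate must be a positive integer, got {self.rate!r}")
        if self.bias is not None:
            self.bias = np.asarray(self.bias)
            if self.bias.shape != (self.weights.shape[3],):
                raise ValueError("bias must have one entry per output channel")

    @property
    def size(self) -> int:
        return self.weights.shape[0]

    @property
    def in_channels(self) -> int:
        return self.weights.shape[2]

    @property
    def out_channels(self) -> int:
        return self.weights.shape[3]


def _same_pad(x: np.ndarray, K: int, rate: int) -> tuple[np.ndarray, int]:
    pad = (K - 1) * rate // 2
    if pad == 0:
        return x, 0
    return np.pad(x, ((0, 0), (pad, pad), (pad, pad), (0, 0))), pad


def _atrous_forward(xp: np.ndarray, weights: np.ndarray, rate: int,
                    out_hw: tuple[int, int]) -> np.ndarray:
    """Dilated correlation of a padded NHWC batch with (K,K,ci,co) weights."""
    K = weights.shape[0]
    h, w = out_hw
    n = xp.shape[0]
    y = np.zeros((n, h, w, weights.shape[3]), dtype=xp.dtype)
    for ki in range(K):
        for kj in range(K):
            patch = xp[:, ki * rate: ki * rate + h, kj * rate: kj * rate + w, :]
            y += patch @ weights[ki, kj]
    return y


def atrous_convolve(x: np.ndarray, kernel: AtrousKernel) -> np.ndarray:
    """Same-padded dilated convolution of a single (H, W, C) feature map.

    Each output position ``i`` sums ``x[i + r*k] * w[k]`` over the kernel
    taps ``k`` (both axes), with out-of-range samples taken as zero, plus
    the bias if present.
    """
    x = np.asarray(x)
    if x.ndim != 3:
        raise ValueError(f"feature map must be (H, W, C), got shape {x.shape}")
    if not np.all(np.isfinite(x)):
        raise ValueError("feature map contains non-finite values")
    if x.shape[2] != kernel.in_channels:
        raise ValueError(
            f"channel mismatch: map has {x.shape[2]} channels, kernel expects "
            f"{kernel.in_channels}")
    xb = x[None]
    xp, _ = _same_pad(xb, kernel.size, kernel.rate)
    y = _atrous_forward(xp, kernel.weights, kernel.rate, x.shape[:2])
    if kernel.bias is not None:
        y = y + kernel.bias
    return y[0]


class AtrousConv2d(Layer):
    """Trainable same-padded dilated convolution on NHWC batches."""

    def __init__(self, c_in: int, c_out: int, kernel_size: int = 3,
                 rate: int = 1, bias: bool = True,
                 rng: np.random.Generator | None = None,
                 dtype=np.float32, name: str = "conv"):
        if kernel_size < 1 or kernel_size % 2 == 0:
            raise ValueError("kernel size must be odd and positive")
        if rate < 1:
            raise ValueError("dilation rate must be >= 1")
        rng = rng or np.random.default_rng(0)
        scale = math.sqrt(2.0 / (kernel_size * kernel_size * c_in))
        self.weight = Parameter(
            rng.normal(0.0, scale, size=(kernel_size, kernel_size, c_in, c_out)
                       ).astype(dtype), f"{name}.w")
        self.bias = Parameter(np.zeros(c_out, dtype=dtype), f"{name}.b") if bias else None
        self.rate = int(rate)
        self._cache = None

    @property
    def kernel_size(self) -> int:
        return self.weight.value.shape[0]

    def forward(self, x, training=False):
        if x.shape[3] != self.weight.value.shape[2]:
            raise ValueError(
                f"channel mismatch: input has {x.shape[3]}, layer expects "
                f"{self.weight.value.shape[2]}")
        xp, pad = _same_pad(x, self.kernel_size, self.rate)
        self._cache = (xp, pad, x.shape)
        y = _atrous_forward(xp, self.weight.value, self.rate, x.shape[1:3])
        if self.bias is not None:
            y = y + self.bias.value
        return y

    def backward(self, grad):
        xp, pad, (n, h, w, c) = self._cache
        K, r = self.kernel_size, self.rate
        dxp = np.zeros_like(xp)
        for ki in range(K):
            for kj in range(K):
                patch = xp[:, ki * r: ki * r + h, kj * r: kj * r + w, :]
                self.weight.grad[ki, kj] += np.tensordot(
                    patch, grad, axes=([0, 1, 2], [0, 1, 2]))
                dxp[:, ki * r: ki * r + h, kj * r: kj * r + w, :] += (
                    grad @ self.weight.value[ki, kj].T)
        if self.bias is not None:
            self.bias.grad += grad.sum(axis=(0, 1, 2))
        if pad == 0:
            return dxp
        return dxp[:, pad:-pad, pad:-pad, :]


@dataclass
class ConvBlockSpec:
    """Configuration of one normalise -> dilated-conv -> activation block."""

    in_channels: int
    out_channels: int
    rate: int = 1
    kernel_size: int = 3
    normalize_first: bool = True
    activation: str = "relu"

    def __post_init__(self):
        if self.in_channels < 1 or self.out_channels < 1:
            raise ValueError("channel counts must be positive")
        if self.rate < 1:
            raise ValueError("dilation rate must be >= 1")
        if self.activation not in ACTIVATIONS:
            raise ValueError(f"unknown activation {self.activation!r}")


class ConvBlock(Layer):
    """Batch-norm placed *before* the dilated convolution, then activation.

    Normalising ahead of the convolution keeps the dilated taps operating
    on a standardised signal; with ``normalize_first=False`` the block
    degrades to plain conv -> activation.
    """

    def __init__(self, spec: ConvBlockSpec, rng: np.random.Generator | None = None,
                 dtype=np.float32, name: str = "block"):
        self.spec = spec
        self.bn = (BatchNorm2d(spec.in_channels, dtype=dtype, name=f"{name}.bn")
                   if spec.normalize_first else None)
        self.conv = AtrousConv2d(spec.in_channels, spec.out_channels,
                                 spec.kernel_size, spec.rate, rng=rng,
                                 dtype=dtype, name=f"{name}.conv")
        self.act = ACTIVATIONS[spec.activation]()

    def forward(self, x, training=False):
        if x.shape[3] != self.spec.in_channels:
            raise ValueError(
                f"block expects {self.spec.in_channels} channels, got {x.shape[3]}")
        h = self.bn.forward(x, training) if self.bn is not None else x
        h = self.conv.forward(h, training)
        return self.act.forward(h, training)

    def backward(self, grad):
        grad = self.act.backward(grad)
        grad = self.conv.backward(grad)
        if self.bn is not None:
            grad = self.bn.backward(grad)
        return grad


def conv_block(x: np.ndarray, spec: ConvBlockSpec, params: dict) -> np.ndarray:
    """Functional form of :class:`ConvBlock` on a single (H, W, C) map.

    ``params`` supplies explicit values: ``weights`` (K,K,ci,co), ``bias``
    (co,), and for the normalisation ``gamma``, ``beta``, ``mean``, ``var``
    (per input channel).  Normalisation uses the given statistics, i.e.
    inference behaviour.
    """
    block = ConvBlock(spec)
    block.conv.weight.value = np.asarray(params["weights"], dtype=np.float64)
    if "bias" in params and params["bias"] is not None:
        block.conv.bias.value = np.asarray(params["bias"], dtype=np.float64)
    if block.bn is not None:
        block.bn.gamma.value = np.asarray(params["gamma"], dtype=np.float64)
        block.bn.beta.value = np.asarray(params["beta"], dtype=np.float64)
        block.bn.running_mean = np.asarray(params["mean"], dtype=np.float64)
        block.bn.running_var = np.asarray(params["var"], dtype=np.float64)
    return block.forward(np.asarray(x, dtype=np.float64)[None], training=False)[0]
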