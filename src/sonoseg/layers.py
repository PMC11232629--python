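"""Reverse-mode neural-network primitives on plain numpy arrays.

All spatial tensors use NHWC layout (batch, height, width, channels);
token tensors use (batch, tokens, dim).  Every layer owns its
:class:`Parameter` objects and implements ``forward`` / ``backward``,
caching whatever the backward pass needs.  The graph is static (the
segmentation network wires layers explicitly), so a tape is unnecessary.

Gradients accumulate into ``Parameter.grad``; call
:meth:`Adam.zero_grad` between optimisation steps.
"""

from __future__ import annotations

import math

import numpy as np
from scipy.special import erf


class Parameter:
    """A trainable array together with its gradient accumulator."""

    __slots__ = ("value", "grad", "name")

    def __init__(self, value: np.ndarray, name: str = ""):
        self.value = np.asarray(value)
        self.grad = np.zeros_like(self.value)
        self.name = name

    @property
    def size(self) -> int:
        return self.value.size

    def __repr__(self) -> str:  # pragma: no cover - debug aid
        return f"Parameter({self.name or 'unnamed'}, shape={self.value.shape})"


class Layer:
    """Base class: recursive parameter/buffer discovery over attributes."""

    buffer_names: tuple[str, ...] = ()

    def parameters(self) -> list[Parameter]:
        found: list[Parameter] = []
        for value in self.__dict__.values():
            found.extend(_collect(value))
        return found

    def _child_layers(self) -> list["Layer"]:
        def walk(value):
            if isinstance(value, Layer):
                yield value
            elif isinstance(value, (list, tuple)):
                for item in value:
                    yield from walk(item)
        out: list[Layer] = []
        for value in self.__dict__.values():
            out.extend(walk(value))
        return out

    def buffers(self) -> list[tuple["Layer", str]]:
        """Non-trainable state (e.g. running statistics), as (owner, attr)."""
        found = [(self, name) for name in self.buffer_names]
        for child in self._child_layers():
            found.extend(child.buffers())
        return found

    def forward(self, x, training: bool = False):
        raise NotImplementedError

    def backward(self, grad):
        raise NotImplementedError

    def __call__(self, x, training: bool = False):
        return self.forward(x, training)


def _collect(value) -> list[Parameter]:
    if isinstance(value, Parameter):
        return [value]
    if isinstance(value, Layer):
        return value.parameters()
    if isinstance(value, (list, tuple)):
        out: list[Parameter] = []
        for item in value:
            out.extend(_collect(item))
        return out
    return []


# ---------------------------------------------------------------------------
# dense / norm / activation layers
# ---------------------------------------------------------------------------


class Linear(Layer):
    def __init__(self, d_in: int, d_out: int, rng: np.random.Generator,
                 dtype=np.float32, name: str = "linear"):
        scale = math.sqrt(2.0 / (d_in + d_out))
        self.weight = Parameter(
            rng.normal(0.0, scale, size=(d_in, d_out)).astype(dtype), f"{name}.w")
        self.bias = Parameter(np.zeros(d_out, dtype=dtype), f"{name}.b")
        self._x = None

    def forward(self, x, training=False):
        self._x = x
        return x @ self.weight.value + self.bias.value

    def backward(self, grad):
        x = self._x
        self.weight.grad += np.tensordot(x, grad, axes=(tuple(range(x.ndim - 1)),) * 2)
        self.bias.grad += grad.reshape(-1, grad.shape[-1]).sum(axis=0)
        return grad @ self.weight.value.T


class LayerNorm(Layer):
    """Per-token normalisation over the last axis with learned affine."""

    def __init__(self, dim: int, eps: float = 1e-5, dtype=np.float32,
                 name: str = "ln"):
        self.gamma = Parameter(np.ones(dim, dtype=dtype), f"{name}.gamma")
        self.beta = Parameter(np.zeros(dim, dtype=dtype), f"{name}.beta")
        self.eps = eps
        self._cache = None

    def forward(self, x, training=False):
        mu = x.mean(axis=-1, keepdims=True)
        var = x.var(axis=-1, keepdims=True)
        inv = 1.0 / np.sqrt(var + self.eps)
        xhat = (x - mu) * inv
        self._cache = (xhat, inv)
        return xhat * self.gamma.value + self.beta.value

    def backward(self, grad):
        xhat, inv = self._cache
        d = xhat.shape[-1]
        self.gamma.grad += (grad * xhat).reshape(-1, d).sum(axis=0)
        self.beta.grad += grad.reshape(-1, d).sum(axis=0)
        g = grad * self.gamma.value
        return (g - g.mean(axis=-1, keepdims=True)
                - xhat * (g * xhat).mean(axis=-1, keepdims=True)) * inv


class BatchNorm2d(Layer):
    """Channelwise batch normalisation for NHWC maps (running statistics
    for inference, batch statistics while training)."""

    buffer_names = ("running_mean", "running_var")

    def __init__(self, channels: int, eps: float = 1e-5, momentum: float = 0.1,
                 dtype=np.float32, name: str = "bn"):
        self.gamma = Parameter(np.ones(channels, dtype=dtype), f"{name}.gamma")
        self.beta = Parameter(np.zeros(channels, dtype=dtype), f"{name}.beta")
        self.running_mean = np.zeros(channels, dtype=dtype)
        self.running_var = np.ones(channels, dtype=dtype)
        self.eps = eps
        self.momentum = momentum
        self._cache = None

    def forward(self, x, training=False):
        if training:
            mu = x.mean(axis=(0, 1, 2))
            var = x.var(axis=(0, 1, 2))
            m = self.momentum
            self.running_mean = ((1 - m) * self.running_mean + m * mu).astype(
                self.running_mean.dtype)
            self.running_var = ((1 - m) * self.running_var + m * var).astype(
                self.running_var.dtype)
        else:
            mu, var = self.running_mean, self.running_var
        inv = 1.0 / np.sqrt(var + self.eps)
        xhat = (x - mu) * inv
        self._cache = (xhat, inv, training, x.shape)
        return xhat * self.gamma.value + self.beta.value

    def backward(self, grad):
        xhat, inv, training, shape = self._cache
        self.gamma.grad += (grad * xhat).sum(axis=(0, 1, 2))
        self.beta.grad += grad.sum(axis=(0, 1, 2))
        g = grad * self.gamma.value
        if not training:
            return g * inv
        m = shape[0] * shape[1] * shape[2]
        return (g - g.mean(axis=(0, 1, 2))
                - xhat * (g * xhat).mean(axis=(0, 1, 2))) * inv


_SQRT2 = math.sqrt(2.0)
_INV_SQRT_2PI = 1.0 / math.sqrt(2.0 * math.pi)


class GELU(Layer):
    """Exact (erf-based) Gaussian error linear unit."""

    def __init__(self):
        self._x = None

    def forward(self, x, training=False):
        self._x = x
        return 0.5 * x * (1.0 + erf(x / _SQRT2))

    def backward(self, grad):
        x = self._x
        cdf = 0.5 * (1.0 + erf(x / _SQRT2))
        pdf = _INV_SQRT_2PI * np.exp(-0.5 * x * x)
        return grad * (cdf + x * pdf)


class ReLU(Layer):
    def __init__(self):
        self._mask = None

    def forward(self, x, training=False):
        self._mask = x > 0
        return np.where(self._mask, x, 0.0)

    def backward(self, grad):
        return np.where(self._mask, grad, 0.0)


class Sigmoid(Layer):
    def __init__(self):
        self._y = None

    def forward(self, x, training=False):
        # numerically stable logistic
        y = np.empty_like(x)
        pos = x >= 0
        y[pos] = 1.0 / (1.0 + np.exp(-x[pos]))
        ex = np.exp(x[~pos])
        y[~pos] = ex / (1.0 + ex)
        self._y = y
        return y

    def backward(self, grad):
        y = self._y
        return grad * y * (1.0 - y)


class Identity(Layer):
    def forward(self, x, training=False):
        return x

    def backward(self, grad):
        return grad


ACTIVATIONS = {"relu": ReLU, "gelu": GELU, "sigmoid": Sigmoid, "linear": Identity}


# ---------------------------------------------------------------------------
# spatial layers
# ---------------------------------------------------------------------------


class MaxPool2d(Layer):
    """2x2 max-pooling with stride 2 (ties resolve to the first window
    position, row-major)."""

    def forward(self, x, training=False):
        n, h, w, c = x.shape
        if h % 2 or w % 2:
            raise ValueError(f"spatial dims must be even for 2x2 pooling, got {h}x{w}")
        windows = (x.reshape(n, h // 2, 2, w // 2, 2, c)
                    .transpose(0, 1, 3, 5, 2, 4)
                    .reshape(n, h // 2, w // 2, c, 4))
        idx = windows.argmax(axis=-1)
        self._cache = (idx, (n, h, w, c))
        return np.take_along_axis(windows, idx[..., None], axis=-1)[..., 0]

    def backward(self, grad):
        idx, (n, h, w, c) = self._cache
        scattered = np.zeros((n, h // 2, w // 2, c, 4), dtype=grad.dtype)
        np.put_along_axis(scattered, idx[..., None], grad[..., None], axis=-1)
        return (scattered.reshape(n, h // 2, w // 2, c, 2, 2)
                         .transpose(0, 1, 4, 2, 5, 3)
                         .reshape(n, h, w, c))


class ConvTranspose2x2(Layer):
    """2x2 transposed convolution with stride 2 (the channel-halving
    deconvolution of the decoder path)."""

    def __init__(self, c_in: int, c_out: int, rng: np.random.Generator,
                 dtype=np.float32, name: str = "deconv"):
        scale = math.sqrt(2.0 / c_in)
        self.weight = Parameter(
            rng.normal(0.0, scale, size=(2, 2, c_in, c_out)).astype(dtype),
            f"{name}.w")
        self.bias = Parameter(np.zeros(c_out, dtype=dtype), f"{name}.b")
        self._x = None

    def forward(self, x, training=False):
        self._x = x
        n, h, w, _ = x.shape
        c_out = self.weight.value.shape[-1]
        y = np.empty((n, 2 * h, 2 * w, c_out), dtype=x.dtype)
        for di in range(2):
            for dj in range(2):
                y[:, di::2, dj::2, :] = x @ self.weight.value[di, dj]
        return y + self.bias.value

    def backward(self, grad):
        x = self._x
        dx = np.zeros_like(x)
        for di in range(2):
            for dj in range(2):
                g = grad[:, di::2, dj::2, :]
                self.weight.grad[di, dj] += np.tensordot(
                    x, g, axes=([0, 1, 2], [0, 1, 2]))
                dx += g @ self.weight.value[di, dj].T
        self.bias.grad += grad.sum(axis=(0, 1, 2))
        return dx


# ---------------------------------------------------------------------------
# optimiser
# ---------------------------------------------------------------------------


class Adam:
    """Adam with the standard bias-corrected moment estimates."""

    def __init__(self, params: list[Parameter], lr: float = 1e-4,
                 betas: tuple[float, float] = (0.9, 0.999), eps: float = 1e-8):
        if lr < 0:
            raise ValueError("learning rate must be non-negative")
        self.params = list(params)
        self.lr = lr
        self.beta1, self.beta2 = betas
        self.eps = eps
        self.t = 0
        self._m = [np.zeros_like(p.value) for p in self.params]
        self._v = [np.zeros_like(p.value) for p in self.params]

    def zero_grad(self) -> None:
        for p in self.params:
            p.grad[...] = 0

    def step(self) -> None:
        self.t += 1
        b1c = 1.0 - self.beta1 ** self.t
        b2c = 1.0 - self.beta2 ** self.t
        for p, m, v in zip(self.params, self._m, self._v):
            g = p.grad
            m *= self.beta1
            m += (1 - self.beta1) * g
            v *= self.beta2
            v += (1 - self.beta2) * g * g
            update = (self.lr * (m / b1c)) / (np.sqrt(v / b2c) + self.eps)
            p.value -= update.astype(p.value.dtype)
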