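"""Vision-Transformer bottleneck: tokenisation, self-attention, blocks.

The deepest encoder feature map is flattened into a sequence of patch
tokens (row-major over the patch grid), each linearly embedded and offset
by a learned position embedding.  Two pre-norm transformer blocks then
mix the tokens:

    z_hat = MSA(LN(z_in)) + z_in
    z_out = MLP(LN(z_hat)) + z_hat

where MSA is multi-head scaled dot-product attention,

    Attention(Q, K, V) = softmax(Q K^T / sqrt(d) + B) V,

with a learned relative-position bias B indexed by the (dy, dx) offset
between token pairs on the patch grid, and the MLP is two linear layers
with a GELU between.  Detokenisation reshapes the sequence back to a
spatial map, so the bottleneck leaves spatial dims (and, with the default
patch size of 1 and embedding dim equal to the channel count, channels)
unchanged — the surrounding encoder/decoder wiring never sees it.
"""

from __future__ import annotations

from dataclasses import dataclass

import numpy as np

from .layers import GELU, Layer, LayerNorm, Linear, Parameter


# ---------------------------------------------------------------------------
# functional surface (single-sample, float64 — used directly in tests)
# ---------------------------------------------------------------------------


def tokenize(x: np.ndarray, patch_size: int, embed_params: dict) -> np.ndarray:
    """Flatten an (H, W, C) map into N = (H/p)(W/p) embedded tokens.

    Tokens are ordered row-major over the patch grid.  ``embed_params``
    holds ``weight`` of shape (p*p*C, D), optional ``bias`` (D,) and the
    learned position table ``positions`` (N, D) added after projection.
    """
    x = np.asarray(x)
    if x.ndim != 3:
        raise ValueError(f"feature map must be (H, W, C), got {x.shape}")
    h, w, c = x.shape
    p = int(patch_size)
    if p < 1 or h % p or w % p:
        raise ValueError(f"spatial dims {h}x{w} not divisible by patch size {p}")
    gh, gw = h // p, w // p
    patches = (x.reshape(gh, p, gw, p, c)
                .transpose(0, 2, 1, 3, 4)
                .reshape(gh * gw, p * p * c))
    tokens = patches @ np.asarray(embed_params["weight"])
    if embed_params.get("bias") is not None:
        tokens = tokens + np.asarray(embed_params["bias"])
    if embed_params.get("positions") is not None:
        pos = np.asarray(embed_params["positions"])
        if pos.shape != tokens.shape:
            raise ValueError(
                f"position table shape {pos.shape} != token shape {tokens.shape}")
        tokens = tokens + pos
    return tokens


@dataclass
class AttentionTensors:
    """Inputs of one scaled dot-product attention evaluation."""

    Q: np.ndarray
    K: np.ndarray
    V: np.ndarray
    d: int
    B: np.ndarray | None = None

    def __post_init__(self):
        self.Q, self.K, self.V = (np.asarray(a) for a in (self.Q, self.K, self.V))
        if self.d <= 0:
            raise ValueError("key dimension d must be positive")
        n = self.Q.shape[0]
        if self.K.shape[0] != n or self.V.shape[0] != n:
            raise ValueError("Q, K, V must share their leading (token) dimension")
        if self.B is not None:
            self.B = np.asarray(self.B)


def softmax(logits: np.ndarray, axis: int = -1) -> np.ndarray:
    if not np.all(np.isfinite(logits)):
        raise FloatingPointError("non-finite attention logits")
    shifted = logits - logits.max(axis=axis, keepdims=True)
    e = np.exp(shifted)
    return e / e.sum(axis=axis, keepdims=True)


def attention(at: AttentionTensors) -> np.ndarray:
    """softmax(Q K^T / sqrt(d) + B) V for one head."""
    logits = at.Q @ at.K.T / np.sqrt(float(at.d))
    if at.B is not None:
        logits = logits + at.B
    return softmax(logits, axis=-1) @ at.V


def transformer_block(z: np.ndarray, params: "TransformerBlock") -> np.ndarray:
    """Apply one pre-norm MSA + MLP block to an (N, D) token matrix."""
    return params.forward(np.asarray(z)[None])[0]


# ---------------------------------------------------------------------------
# trainable layers
# ---------------------------------------------------------------------------


def relative_position_index(grid: int) -> np.ndarray:
    """(L, L) table of flattened (dy, dx) offsets on a grid x grid of tokens.

    Offsets along each axis span 2*grid - 1 values, so the learned bias
    table has (2*grid - 1)**2 rows (one per distinct relative offset).
    """
    coords = np.stack(np.meshgrid(np.arange(grid), np.arange(grid),
                                  indexing="ij"), axis=-1).reshape(-1, 2)
    rel = coords[:, None, :] - coords[None, :, :] + (grid - 1)
    return rel[..., 0] * (2 * grid - 1) + rel[..., 1]


class MultiHeadSelfAttention(Layer):
    """Multi-head scaled dot-product self-attention with relative bias."""

    def __init__(self, dim: int, heads: int, grid: int,
                 rng: np.random.Generator, dtype=np.float32, name: str = "msa"):
        if dim % heads:
            raise ValueError(f"embedding dim {dim} not divisible by {heads} heads")
        self.dim, self.heads, self.grid = dim, heads, grid
        self.head_dim = dim // heads
        self.qkv = Linear(dim, 3 * dim, rng, dtype, f"{name}.qkv")
        self.proj = Linear(dim, dim, rng, dtype, f"{name}.proj")
        self.bias_table = Parameter(
            np.zeros(((2 * grid - 1) ** 2, heads), dtype=dtype), f"{name}.bias")
        self._rel_index = relative_position_index(grid)
        self._cache = None

    def forward(self, x, training=False):
        n, L, d = x.shape
        if L != self.grid * self.grid:
            raise ValueError(
                f"token count {L} does not match grid {self.grid}x{self.grid}")
        qkv = self.qkv.forward(x)  # (n, L, 3d)
        qkv = qkv.reshape(n, L, 3, self.heads, self.head_dim).transpose(2, 0, 3, 1, 4)
        q, k, v = qkv[0], qkv[1], qkv[2]          # each (n, h, L, dh)
        scale = 1.0 / np.sqrt(float(self.head_dim))
        logits = np.einsum("nhid,nhjd->nhij", q, k) * scale
        bias = self.bias_table.value[self._rel_index]          # (L, L, h)
        logits = logits + bias.transpose(2, 0, 1)[None]
        p = softmax(logits, axis=-1)
        out = np.einsum("nhij,nhjd->nhid", p, v)
        merged = out.transpose(0, 2, 1, 3).reshape(n, L, d)
        self._cache = (q, k, v, p, scale)
        self.last_attention = p
        return self.proj.forward(merged)

    def backward(self, grad):
        q, k, v, p, scale = self._cache
        n, h, L, dh = q.shape
        dmerged = self.proj.backward(grad)
        dout = dmerged.reshape(n, L, h, dh).transpose(0, 2, 1, 3)
        dp = np.einsum("nhid,nhjd->nhij", dout, v)
        dv = np.einsum("nhij,nhid->nhjd", p, dout)
        # softmax Jacobian, row-wise
        dlogits = p * (dp - (dp * p).sum(axis=-1, keepdims=True))
        bias_grad = dlogits.sum(axis=0).transpose(1, 2, 0)     # (L, L, h)
        np.add.at(self.bias_table.grad, self._rel_index.ravel(),
                  bias_grad.reshape(-1, h))
        dq = np.einsum("nhij,nhjd->nhid", dlogits, k) * scale
        dk = np.einsum("nhij,nhid->nhjd", dlogits, q) * scale
        dqkv = np.stack([dq, dk, dv])                           # (3, n, h, L, dh)
        dqkv = dqkv.transpose(1, 3, 0, 2, 4).reshape(n, L, 3 * self.dim)
        return self.qkv.backward(dqkv)


class TransformerBlock(Layer):
    """Pre-norm residual block: LN -> MSA -> add, LN -> MLP(GELU) -> add."""

    def __init__(self, dim: int, heads: int, mlp_hidden: int, grid: int,
                 rng: np.random.Generator | None = None, dtype=np.float32,
                 name: str = "tb"):
        rng = rng or np.random.default_rng(0)
        self.ln1 = LayerNorm(dim, dtype=dtype, name=f"{name}.ln1")
        self.msa = MultiHeadSelfAttention(dim, heads, grid, rng, dtype, f"{name}.msa")
        self.ln2 = LayerNorm(dim, dtype=dtype, name=f"{name}.ln2")
        self.fc1 = Linear(dim, mlp_hidden, rng, dtype, f"{name}.fc1")
        self.gelu = GELU()
        self.fc2 = Linear(mlp_hidden, dim, rng, dtype, f"{name}.fc2")

    def forward(self, x, training=False):
        attn = self.msa.forward(self.ln1.forward(x), training)
        z_hat = attn + x
        mlp = self.fc2.forward(self.gelu.forward(self.fc1.forward(
            self.ln2.forward(z_hat))))
        return mlp + z_hat

    def backward(self, grad):
        d_mlp = self.ln2.backward(self.fc1.backward(self.gelu.backward(
            self.fc2.backward(grad))))
        d_zhat = grad + d_mlp
        d_attn = self.ln1.backward(self.msa.backward(d_zhat))
        return d_zhat + d_attn


class VitBottleneck(Layer):
    """Tokenise -> ``depth`` transformer blocks -> reshape back to a map.

    The patch embedding projects each p x p x c_in patch to ``embed_dim``;
    detokenisation is a pure reshape, which requires ``embed_dim`` to be
    divisible by ``patch_size**2`` and yields ``embed_dim / p**2`` output
    channels (with the default p = 1: exactly ``embed_dim`` channels).
    """

    def __init__(self, in_channels: int, embed_dim: int, grid: int,
                 depth: int = 2, heads: int = 4, mlp_hidden: int | None = None,
                 patch_size: int = 1, rng: np.random.Generator | None = None,
                 dtype=np.float32, name: str = "vit"):
        rng = rng or np.random.default_rng(0)
        p = int(patch_size)
        if p < 1:
            raise ValueError("patch size must be >= 1")
        if embed_dim % (p * p):
            raise ValueError("embed_dim must be divisible by patch_size**2 "
                             "for projection-free detokenisation")
        self.patch_size = p
        self.grid = grid
        self.embed = Linear(p * p * in_channels, embed_dim, rng, dtype,
                            f"{name}.embed")
        self.positions = Parameter(
            (0.02 * rng.standard_normal((grid * grid, embed_dim))).astype(dtype),
            f"{name}.pos")
        self.blocks = [TransformerBlock(embed_dim, heads, mlp_hidden or 4 * embed_dim,
                                        grid, rng, dtype, f"{name}.b{i}")
                       for i in range(depth)]
        self.out_channels = embed_dim // (p * p)

    def forward(self, x, training=False):
        n, h, w, c = x.shape
        p = self.patch_size
        if h % p or w % p or (h // p) != self.grid or (w // p) != self.grid:
            raise ValueError(
                f"bottleneck map {h}x{w} incompatible with token grid "
                f"{self.grid} and patch size {p}")
        self._in_shape = x.shape
        patches = (x.reshape(n, self.grid, p, self.grid, p, c)
                    .transpose(0, 1, 3, 2, 4, 5)
                    .reshape(n, self.grid * self.grid, p * p * c))
        z = self.embed.forward(patches) + self.positions.value
        for block in self.blocks:
            z = block.forward(z, training)
        return z.reshape(n, self.grid, self.grid, p, p, self.out_channels) \
                .transpose(0, 1, 3, 2, 4, 5) \
                .reshape(n, h, w, self.out_channels)

    def backward(self, grad):
        n, h, w, c = self._in_shape
        p = self.patch_size
        dz = (grad.reshape(n, self.grid, p, self.grid, p, self.out_channels)
                  .transpose(0, 1, 3, 2, 4, 5)
                  .reshape(n, self.grid * self.grid, p * p * self.out_channels))
        for block in reversed(self.blocks):
            dz = block.backward(dz)
        self.positions.grad += dz.sum(axis=0)
        dpatches = self.embed.backward(dz)
        return (dpatches.reshape(n, self.grid, self.grid, p, p, c)
                        .transpose(0, 1, 3, 2, 4, 5)
                        .reshape(n, h, w, c))


def bottleneck_forward(x: np.ndarray, params: VitBottleneck) -> np.ndarray:
    """Run the full tokenise -> blocks -> detokenise stage on one (H, W, C) map."""
    return params.forward(np.asarray(x)[None])[0]
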