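"""Assembly of the encoder / ViT-bottleneck / decoder segmentation network.

Topology (U-Net lineage):

* encoder — one level per entry of ``channel_schedule[:-1]``; each level
  applies two normalise->dilated-conv->ReLU blocks (dilation ``r_enc``
  when the multi-scale flag is on, else 1) followed by 2x2 max-pooling;
* bottleneck — with self-attention on: patch-embed the pooled map to
  ``channel_schedule[-1]`` dims and run ``transformer_blocks`` pre-norm
  ViT blocks; with it off: two plain conv blocks to the same width;
* decoder — per level a 2x2 stride-2 transposed convolution that halves
  the channels, concatenation with the matching encoder map (skip
  connection), then two conv blocks at dilation ``r_dec``;
* head — 1x1 convolution to ``num_classes`` channels and a logistic
  output, at full input resolution.

Both ablation axes of the architecture are plain config flags, so the
2x2 grid {±multi-scale CNN} x {±self-attention} shares every other
hyper-parameter; the (off, off) corner is an ordinary U-Net.
"""

from __future__ import annotations

import dataclasses
import json
from dataclasses import dataclass, field

import numpy as np

from .atrous import AtrousConv2d, ConvBlock, ConvBlockSpec
from .layers import ConvTranspose2x2, Layer, MaxPool2d, Sigmoid
from .vit import VitBottleneck


class ConfigurationError(ValueError):
    pass


@dataclass(frozen=True)
class ModelConfig:
    """Full architectural hyper-parameter set of the segmentation network.

    ``channel_schedule`` lists per-level widths, encoder levels first and
    the bottleneck width last; the number of pooling levels (depth) is
    ``len(channel_schedule) - 1``.
    """

    input_size: tuple[int, int, int] = (256, 256, 1)
    channel_schedule: tuple[int, ...] = (16, 32, 64, 128, 256)
    r_enc: int = 3
    r_dec: int = 1
    transformer_blocks: int = 2
    heads: int = 4
    mlp_hidden: int | None = None          # None -> 4 * embed_dim
    patch_size: int = 1
    num_classes: int = 1
    use_multiscale_cnn: bool = True
    use_self_attention: bool = True
    dilate_first_level_only: bool = False

    def __post_init__(self):
        h, w, c = self.input_size
        d = self.depth
        if d < 1:
            raise ConfigurationError("channel schedule needs at least two entries")
        if h % (2 ** d) or w % (2 ** d):
            raise ConfigurationError(
                f"input {h}x{w} not divisible by 2^depth = {2 ** d}")
        if any(a >= b for a, b in zip(self.channel_schedule,
                                      self.channel_schedule[1:])):
            raise ConfigurationError(
                "channel schedule must increase strictly toward the bottleneck")
        if self.r_enc < 1 or self.r_dec < 1:
            raise ConfigurationError("dilation rates must be >= 1")
        if self.transformer_blocks < 0:
            raise ConfigurationError("transformer_blocks must be >= 0")
        grid = (h // 2 ** d) // self.patch_size
        if self.use_self_attention and grid * self.patch_size != h // 2 ** d:
            raise ConfigurationError("bottleneck not divisible by patch size")
        for width in self.channel_schedule[1:]:
            if width % 2:
                raise ConfigurationError(
                    "widths above the first level must be even (deconv halving)")

    @property
    def depth(self) -> int:
        return len(self.channel_schedule) - 1

    @property
    def bottleneck_grid(self) -> int:
        return (self.input_size[0] // 2 ** self.depth) // self.patch_size

    @property
    def embed_dim(self) -> int:
        return self.channel_schedule[-1]

    def replace(self, **kwargs) -> "ModelConfig":
        return dataclasses.replace(self, **kwargs)

    def to_json(self) -> str:
        return json.dumps(dataclasses.asdict(self))

    @classmethod
    def from_json(cls, text: str) -> "ModelConfig":
        raw = json.loads(text)
        raw["input_size"] = tuple(raw["input_size"])
        raw["channel_schedule"] = tuple(raw["channel_schedule"])
        return cls(**raw)


def _enc_rate(config: ModelConfig, level: int) -> int:
    if not config.use_multiscale_cnn:
        return 1
    if config.dilate_first_level_only and level > 0:
        return 1
    return config.r_enc


class SegmentationModel(Layer):
    """The assembled network; see the module docstring for the wiring."""

    def __init__(self, config: ModelConfig, rng: np.random.Generator | None = None,
                 dtype=np.float32):
        rng = rng or np.random.default_rng(0)
        self.config = config
        sched = config.channel_schedule
        c_in = config.input_size[2]

        self.enc_levels: list[list[ConvBlock]] = []
        self.pools: list[MaxPool2d] = []
        prev = c_in
        for i, width in enumerate(sched[:-1]):
            rate = _enc_rate(config, i)
            self.enc_levels.append([
                ConvBlock(ConvBlockSpec(prev, width, rate), rng, dtype,
                          f"enc{i}a"),
                ConvBlock(ConvBlockSpec(width, width, rate), rng, dtype,
                          f"enc{i}b"),
            ])
            self.pools.append(MaxPool2d())
            prev = width

        cb = sched[-1]
        if config.use_self_attention:
            self.bottleneck = VitBottleneck(
                prev, cb, config.bottleneck_grid, depth=config.transformer_blocks,
                heads=config.heads, mlp_hidden=config.mlp_hidden,
                patch_size=config.patch_size, rng=rng, dtype=dtype)
            self.bottleneck_convs: list[ConvBlock] = []
        else:
            self.bottleneck = None
            self.bottleneck_convs = [
                ConvBlock(ConvBlockSpec(prev, cb, 1), rng, dtype, "mid_a"),
                ConvBlock(ConvBlockSpec(cb, cb, 1), rng, dtype, "mid_b"),
            ]

        self.deconvs: list[ConvTranspose2x2] = []
        self.dec_levels: list[list[ConvBlock]] = []
        cur = cb
        for i in reversed(range(config.depth)):
            skip = sched[i]
            half = cur // 2
            self.deconvs.append(ConvTranspose2x2(cur, half, rng, dtype, f"up{i}"))
            self.dec_levels.append([
                ConvBlock(ConvBlockSpec(half + skip, skip, config.r_dec), rng,
                          dtype, f"dec{i}a"),
                ConvBlock(ConvBlockSpec(skip, skip, config.r_dec), rng, dtype,
                          f"dec{i}b"),
            ])
            cur = skip

        self.head = AtrousConv2d(cur, config.num_classes, kernel_size=1, rate=1,
                                 rng=rng, dtype=dtype, name="head")
        self.out_act = Sigmoid()

    # -- forward / backward -------------------------------------------------

    def forward(self, x, training=False):
        skips = []
        h = x
        for blocks, pool in zip(self.enc_levels, self.pools):
            for b in blocks:
                h = b.forward(h, training)
            skips.append(h)
            h = pool.forward(h, training)
        if self.bottleneck is not None:
            h = self.bottleneck.forward(h, training)
        else:
            for b in self.bottleneck_convs:
                h = b.forward(h, training)
        self._skip_channels = []
        for deconv, blocks, skip in zip(self.deconvs, self.dec_levels,
                                        reversed(skips)):
            h = deconv.forward(h, training)
            self._skip_channels.append((h.shape[-1], skip.shape[-1]))
            h = np.concatenate([h, skip], axis=-1)
            for b in blocks:
                h = b.forward(h, training)
        h = self.head.forward(h, training)
        return self.out_act.forward(h, training)

    def backward(self, grad):
        grad = self.out_act.backward(grad)
        grad = self.head.backward(grad)
        skip_grads = []
        for deconv, blocks, (c_up, c_skip) in zip(
                reversed(self.deconvs), reversed(self.dec_levels),
                reversed(self._skip_channels)):
            for b in reversed(blocks):
                grad = b.backward(grad)
            skip_grads.append(grad[..., c_up:])
            grad = deconv.backward(grad[..., :c_up])
        if self.bottleneck is not None:
            grad = self.bottleneck.backward(grad)
        else:
            for b in reversed(self.bottleneck_convs):
                grad = b.backward(grad)
        for pool, blocks, sg in zip(reversed(self.pools),
                                    reversed(self.enc_levels),
                                    reversed(skip_grads)):
            grad = pool.backward(grad) + sg
            for b in reversed(blocks):
                grad = b.backward(grad)
        return grad


def build_model(config: ModelConfig, rng: np.random.Generator | None = None,
                dtype=np.float32) -> SegmentationModel:
    """Instantiate the network described by ``config`` (seeded init)."""
    return SegmentationModel(config, rng, dtype)


def count_parameters(model: SegmentationModel) -> int:
    """Number of trainable scalars: conv/deconv weights and biases, batch-
    and layer-norm affine terms, ViT projections, position embeddings and
    relative-bias tables."""
    return int(sum(p.size for p in model.parameters()))


def ablation_variants(config: ModelConfig) -> list[ModelConfig]:
    """The 2x2 ablation grid over {multi-scale CNN} x {self-attention},
    all other settings fixed; ordered (off,off), (on,off), (off,on), (on,on)."""
    return [config.replace(use_multiscale_cnn=ms, use_self_attention=sa)
            for ms, sa in ((False, False), (True, False),
                           (False, True), (True, True))]


# ---------------------------------------------------------------------------
# reference configuration and checkpoints
# ---------------------------------------------------------------------------

# Widths calibrated so the full network's trainable-parameter count equals
# the published computational-cost figure of 4,675,329 scalars at the
# benchmark's 256x256 input.  See docs/methods.md for the calibration.
REFERENCE_COST = 4_675_329


def reference_config() -> ModelConfig:
    return ModelConfig(
        input_size=(256, 256, 1),
        channel_schedule=_REFERENCE_SCHEDULE,
        r_enc=3, r_dec=1,
        transformer_blocks=2, heads=_REFERENCE_HEADS,
        mlp_hidden=_REFERENCE_MLP_HIDDEN, patch_size=1, num_classes=1,
    )


_REFERENCE_SCHEDULE = (20, 40, 88, 176, 336)
_REFERENCE_HEADS = 6
_REFERENCE_MLP_HIDDEN = 1237


def save_checkpoint(path, model: SegmentationModel, extra: dict | None = None
                    ) -> None:
    """Write parameters, running statistics and config (self-describing
    single-file archive)."""
    arrays = {f"p{i:04d}": p.value for i, p in enumerate(model.parameters())}
    arrays.update({f"b{i:04d}": getattr(owner, attr)
                   for i, (owner, attr) in enumerate(model.buffers())})
    meta = {"config": json.loads(model.config.to_json()), "extra": extra or {}}
    np.savez(path, __meta__=np.frombuffer(
        json.dumps(meta).encode(), dtype=np.uint8), **arrays)


def load_checkpoint(path) -> tuple[SegmentationModel, dict]:
    """Rebuild the model stored by :func:`save_checkpoint` bit-exactly."""
    with np.load(path) as data:
        meta = json.loads(bytes(data["__meta__"]).decode())
        config = ModelConfig.from_json(json.dumps(meta["config"]))
        model = build_model(config)
        for i, p in enumerate(model.parameters()):
            stored = data[f"p{i:04d}"]
            if stored.shape != p.value.shape:
                raise ValueError(
                    f"checkpoint parameter {i} has shape {stored.shape}, "
                    f"model expects {p.value.shape}")
            p.value = stored.copy()
            p.grad = np.zeros_like(p.value)
        for i, (owner, attr) in enumerate(model.buffers()):
            key = f"b{i:04d}"
            if key in data:
                setattr(owner, attr, data[key].copy())
    return model, meta["extra"]
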