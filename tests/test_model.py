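"""Architecture contracts: shapes, parameter accounting, ablation grid."""

import numpy as np
import pytest

from sonoseg.atrous import AtrousConv2d
from sonoseg.model import (ConfigurationError, ModelConfig, REFERENCE_COST,
                           ablation_variants, build_model, count_parameters,
                           load_checkpoint, reference_config, save_checkpoint)


def test_lone_convolution_parameter_arithmetic():
    conv = AtrousConv2d(1, 2, kernel_size=3)
    assert conv.weight.size + conv.bias.size == 3 * 3 * 1 * 2 + 2 == 20


def test_two_level_toy_config_matches_hand_summed_ledger(tiny_config):
    """Every stage's weight shapes summed by hand, independently."""
    model = build_model(tiny_config)
    c1, cb = 4, 8          # schedule (4, 8); input 8x8x1; grid 4; heads 2
    h = 6                  # mlp hidden
    ledger = 0
    # encoder level: BN(1)+conv(1->4), BN(4)+conv(4->4)
    ledger += 2 * 1 + 9 * 1 * c1 + c1
    ledger += 2 * c1 + 9 * c1 * c1 + c1
    # bottleneck: embed 4->8 (+bias), positions 16x8, two transformer blocks
    ledger += c1 * cb + cb + 16 * cb
    per_block = (2 * cb                      # ln1
                 + cb * 3 * cb + 3 * cb     # qkv
                 + cb * cb + cb             # out proj
                 + (2 * 4 - 1) ** 2 * 2     # relative bias table, 2 heads
                 + 2 * cb                   # ln2
                 + cb * h + h + h * cb + cb)  # mlp
    ledger += 2 * per_block
    # decoder: deconv 8->4 (+bias), BN(8)+conv(8->4), BN(4)+conv(4->4)
    ledger += 4 * cb * c1 + c1
    ledger += 2 * (c1 + c1) + 9 * (c1 + c1) * c1 + c1
    ledger += 2 * c1 + 9 * c1 * c1 + c1
    # head: 1x1 conv 4->1
    ledger += c1 * 1 + 1
    assert count_parameters(model) == ledger


def test_reference_configuration_reproduces_published_cost():
    assert count_parameters(build_model(reference_config())) == REFERENCE_COST


@pytest.mark.parametrize("rate", [1, 2, 3, 4, 5, 6])
def test_parameter_count_invariant_across_dilation_rates(rate, small_config):
    base = count_parameters(build_model(small_config.replace(r_enc=1)))
    assert count_parameters(build_model(small_config.replace(r_enc=rate))) == base


@pytest.mark.parametrize("size", [32, 64])
@pytest.mark.parametrize("flags", [(False, False), (True, False),
                                   (False, True), (True, True)])
def test_resolution_conserved_for_every_variant(size, flags, rng):
    ms, sa = flags
    cfg = ModelConfig(input_size=(size, size, 1), channel_schedule=(4, 8, 16),
                      heads=2, mlp_hidden=8, use_multiscale_cnn=ms,
                      use_self_attention=sa)
    model = build_model(cfg, np.random.default_rng(0))
    x = rng.random((1, size, size, 1)).astype(np.float32)
    y = model.forward(x)
    assert y.shape == (1, size, size, 1)
    assert ((y >= 0) & (y <= 1)).all()


def test_deconvolutions_halve_channels(small_config):
    model = build_model(small_config)
    for deconv in model.deconvs:
        c_in = deconv.weight.value.shape[2]
        c_out = deconv.weight.value.shape[3]
        assert c_out * 2 == c_in


def test_ablation_grid_enumeration(small_config):
    variants = ablation_variants(small_config)
    assert len(variants) == 4
    flags = [(v.use_multiscale_cnn, v.use_self_attention) for v in variants]
    assert sorted(flags) == [(False, False), (False, True),
                             (True, False), (True, True)]
    assert sum(ms and sa for ms, sa in flags) == 1
    # all other settings fixed
    for v in variants:
        assert v.channel_schedule == small_config.channel_schedule
        assert v.input_size == small_config.input_size


def test_plain_unet_variant_has_no_transformer(small_config):
    plain = build_model(small_config.replace(use_multiscale_cnn=False,
                                             use_self_attention=False))
    assert plain.bottleneck is None
    names = [p.name for p in plain.parameters()]
    assert not any("vit" in n or "msa" in n for n in names)
    full = build_model(small_config)
    assert count_parameters(plain) < count_parameters(full)


def test_dilated_encoder_only_when_multiscale_enabled(small_config):
    dilated = build_model(small_config)
    assert all(b.conv.rate == 3 for lvl in dilated.enc_levels for b in lvl)
    assert all(b.conv.rate == 1 for lvl in dilated.dec_levels for b in lvl)
    off = build_model(small_config.replace(use_multiscale_cnn=False))
    assert all(b.conv.rate == 1 for lvl in off.enc_levels for b in lvl)
    first_only = build_model(small_config.replace(dilate_first_level_only=True))
    rates = [lvl[0].conv.rate for lvl in first_only.enc_levels]
    assert rates[0] == 3 and all(r == 1 for r in rates[1:])


def test_invalid_configurations_rejected():
    with pytest.raises(ConfigurationError, match="divisible"):
        ModelConfig(input_size=(50, 50, 1), channel_schedule=(4, 8, 16))
    with pytest.raises(ConfigurationError, match="increase"):
        ModelConfig(input_size=(64, 64, 1), channel_schedule=(8, 8, 16))
    with pytest.raises(ConfigurationError):
        ModelConfig(input_size=(64, 64, 1), channel_schedule=(4, 8),
                    transformer_blocks=-1)


def test_differentiable_end_to_end(tiny_config, rng):
    """A scalar loss has finite, generically nonzero gradients everywhere."""
    model = build_model(tiny_config, np.random.default_rng(0), dtype=np.float64)
    x = rng.random((2, 8, 8, 1))
    y = model.forward(x, training=True)
    model.backward(2 * y)           # d/dy of sum(y^2)
    groups = {"bn": 0, "conv": 0, "msa": 0, "fc": 0, "pos": 0, "up": 0,
              "head": 0}
    for p in model.parameters():
        assert np.isfinite(p.grad).all(), p.name
        for key in groups:
            if key in p.name:
                groups[key] += float(np.abs(p.grad).sum())
    assert all(v > 0 for v in groups.values()), groups


def test_checkpoint_round_trip_is_bitwise(tmp_path, tiny_config, rng):
    model = build_model(tiny_config, np.random.default_rng(42))
    path = tmp_path / "ckpt.npz"
    save_checkpoint(path, model, extra={"note": "test"})
    restored, extra = load_checkpoint(path)
    assert extra == {"note": "test"}
    for a, b in zip(model.parameters(), restored.parameters()):
        np.testing.assert_array_equal(a.value, b.value)
    x = rng.random((1, 8, 8, 1)).astype(np.float32)
    np.testing.assert_array_equal(model.forward(x), restored.forward(x))
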