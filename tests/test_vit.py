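"""Transformer bottleneck against independent step-by-step oracles."""

import numpy as np
import pytest

from sonoseg.vit import (AttentionTensors, TransformerBlock, VitBottleneck,
                         attention, bottleneck_forward, tokenize,
                         transformer_block)


# ---------------------------------------------------------------------------
# independent oracles (explicit loops, no shared code with the implementation)
# ---------------------------------------------------------------------------


def oracle_attention(Q, K, V, d, B=None):
    n = Q.shape[0]
    logits = np.zeros((n, n))
    for i in range(n):
        for j in range(n):
            logits[i, j] = float(np.dot(Q[i], K[j])) / np.sqrt(d)
            if B is not None:
                logits[i, j] += B[i, j]
    out = np.zeros((n, V.shape[1]))
    for i in range(n):
        exps = [np.exp(logits[i, j] - max(logits[i])) for j in range(n)]
        total = sum(exps)
        for j in range(n):
            out[i] += (exps[j] / total) * V[j]
    return out


def oracle_layernorm(x, gamma, beta, eps=1e-5):
    out = np.zeros_like(x)
    for i in range(x.shape[0]):
        mu = x[i].mean()
        var = x[i].var()
        out[i] = gamma * (x[i] - mu) / np.sqrt(var + eps) + beta
    return out


def oracle_gelu(x):
    from math import erf, sqrt
    return np.vectorize(lambda v: 0.5 * v * (1 + erf(v / sqrt(2))))(x)


def oracle_transformer_block(z, block: TransformerBlock):
    """Hand-stepped LN -> single-head attention -> residual -> LN -> MLP."""
    assert block.msa.heads == 1
    ln1 = oracle_layernorm(z, block.ln1.gamma.value, block.ln1.beta.value)
    qkv = ln1 @ block.msa.qkv.weight.value + block.msa.qkv.bias.value
    d = block.msa.head_dim
    Q, K, V = qkv[:, :d], qkv[:, d:2 * d], qkv[:, 2 * d:]
    bias = block.msa.bias_table.value[block.msa._rel_index][..., 0]
    att = oracle_attention(Q, K, V, d, bias)
    msa_out = att @ block.msa.proj.weight.value + block.msa.proj.bias.value
    z_hat = msa_out + z
    ln2 = oracle_layernorm(z_hat, block.ln2.gamma.value, block.ln2.beta.value)
    h = oracle_gelu(ln2 @ block.fc1.weight.value + block.fc1.bias.value)
    return h @ block.fc2.weight.value + block.fc2.bias.value + z_hat


def zero_block(dim, heads, hidden, grid):
    block = TransformerBlock(dim, heads, hidden, grid,
                             np.random.default_rng(0), dtype=np.float64)
    for p in (block.msa.qkv, block.msa.proj, block.fc1, block.fc2):
        p.weight.value[...] = 0
        p.bias.value[...] = 0
    return block


# ---------------------------------------------------------------------------
# attention
# ---------------------------------------------------------------------------


def test_attention_matches_dense_oracle():
    Q = np.array([[1.0, 2], [0, 1], [-1, 3]])
    K = np.array([[2.0, 0], [1, 1], [0, -1]])
    V = np.array([[1.0, 0], [0, 1], [2, 2]])
    B = np.array([[0.0, 1, 0], [0, 0, -1], [1, 0, 0]])
    got = attention(AttentionTensors(Q, K, V, d=2, B=B))
    np.testing.assert_allclose(got, oracle_attention(Q, K, V, 2, B), atol=1e-10)


def test_single_token_attention_returns_value():
    at = AttentionTensors(Q=np.array([[3.0]]), K=np.array([[2.0]]),
                          V=np.array([[7.5]]), d=1)
    np.testing.assert_allclose(attention(at), [[7.5]])


def test_zero_queries_give_uniform_attention(rng):
    V = rng.random((4, 3))
    at = AttentionTensors(Q=np.zeros((4, 2)), K=rng.random((4, 2)) * 0, V=V, d=2)
    out = attention(at)
    np.testing.assert_allclose(out, np.tile(V.mean(axis=0), (4, 1)), atol=1e-12)


def test_attention_rejects_bad_inputs(rng):
    with pytest.raises(ValueError):
        AttentionTensors(np.ones((2, 2)), np.ones((2, 2)), np.ones((2, 2)), d=0)
    at = AttentionTensors(np.full((2, 2), np.inf), np.ones((2, 2)),
                          np.ones((2, 2)), d=2)
    with pytest.raises(FloatingPointError):
        attention(at)


@pytest.mark.parametrize("n,d", [(2, 2), (4, 4), (3, 2)])
def test_softmax_rows_sum_to_one(n, d, rng):
    block = TransformerBlock(d, 1, 3 * d, 0, np.random.default_rng(7),
                             dtype=np.float64)
    # bypass the grid check: attention weights via direct MSA on n tokens
    block.msa.grid = int(np.sqrt(n)) if int(np.sqrt(n)) ** 2 == n else 0
    logits = rng.standard_normal((5, 3, n, n))
    from sonoseg.vit import softmax
    p = softmax(logits, axis=-1)
    np.testing.assert_allclose(p.sum(axis=-1), np.ones((5, 3, n)), atol=1e-6)


# ---------------------------------------------------------------------------
# tokenisation
# ---------------------------------------------------------------------------


@pytest.mark.parametrize("patch,expected", [(1, 256), (2, 64)])
def test_token_counts(patch, expected, rng):
    x = rng.random((16, 16, 3))
    d = 8
    params = {"weight": rng.standard_normal((patch * patch * 3, d)),
              "bias": np.zeros(d),
              "positions": np.zeros((expected, d))}
    tokens = tokenize(x, patch, params)
    assert tokens.shape == (expected, d)


def test_zero_projection_gives_zero_tokens(rng):
    x = rng.random((8, 8, 2))
    params = {"weight": np.zeros((2, 4)), "bias": np.zeros(4),
              "positions": np.zeros((64, 4))}
    assert not tokenize(x, 1, params).any()


def test_tokenize_row_major_ordering(rng):
    """Token k of a patch_size-1 grid is exactly pixel (k // W, k % W)."""
    x = rng.random((4, 6, 3))
    params = {"weight": np.eye(3), "bias": None, "positions": None}
    tokens = tokenize(x, 1, params)
    np.testing.assert_allclose(tokens, x.reshape(24, 3))


def test_tokenize_rejects_indivisible_dims(rng):
    with pytest.raises(ValueError, match="divisible"):
        tokenize(rng.random((9, 9, 1)), 2, {"weight": np.zeros((4, 2))})


# ---------------------------------------------------------------------------
# transformer block
# ---------------------------------------------------------------------------


def test_zero_weight_block_is_exact_identity(rng):
    block = zero_block(dim=4, heads=2, hidden=8, grid=2)
    z = rng.standard_normal((4, 4))
    np.testing.assert_array_equal(transformer_block(z, block), z)


def test_block_preserves_token_shape(rng):
    block = TransformerBlock(4, 2, 8, 2, np.random.default_rng(3),
                             dtype=np.float64)
    z = rng.standard_normal((4, 4))
    assert transformer_block(z, block).shape == (4, 4)


def test_block_matches_hand_stepped_oracle(rng):
    block = TransformerBlock(2, 1, 5, 2, np.random.default_rng(5),
                             dtype=np.float64)
    block.msa.bias_table.value = rng.standard_normal(
        block.msa.bias_table.value.shape)
    z = rng.standard_normal((4, 2))
    got = transformer_block(z, block)
    np.testing.assert_allclose(got, oracle_transformer_block(z, block),
                               atol=1e-10)


def test_permutation_equivariance_without_positions(rng):
    """With zero relative bias, permuting tokens permutes outputs."""
    block = TransformerBlock(4, 2, 8, 2, np.random.default_rng(9),
                             dtype=np.float64)
    assert not block.msa.bias_table.value.any()
    z = rng.standard_normal((4, 4))
    perm = np.array([2, 0, 3, 1])
    out = transformer_block(z, block)
    out_perm = transformer_block(z[perm], block)
    np.testing.assert_allclose(out_perm, out[perm], atol=1e-5)


# ---------------------------------------------------------------------------
# full bottleneck
# ---------------------------------------------------------------------------


def test_identity_calibrated_bottleneck_passes_input_through(rng):
    c = 4
    vb = VitBottleneck(c, c, grid=4, depth=2, heads=2, mlp_hidden=8,
                       rng=np.random.default_rng(0), dtype=np.float64)
    vb.embed.weight.value = np.eye(c)
    vb.embed.bias.value[...] = 0
    vb.positions.value[...] = 0
    for block in vb.blocks:
        for lin in (block.msa.qkv, block.msa.proj, block.fc1, block.fc2):
            lin.weight.value[...] = 0
            lin.bias.value[...] = 0
    x = rng.random((4, 4, c))
    np.testing.assert_array_equal(bottleneck_forward(x, vb), x)


def test_bottleneck_preserves_shape(rng):
    vb = VitBottleneck(32, 32, grid=8, depth=2, heads=4,
                       rng=np.random.default_rng(1), dtype=np.float64)
    x = rng.random((8, 8, 32))
    assert bottleneck_forward(x, vb).shape == (8, 8, 32)


def test_reference_bottleneck_has_two_blocks():
    from sonoseg.model import build_model, reference_config
    model = build_model(reference_config())
    assert len(model.bottleneck.blocks) == 2


def test_gradient_flows_through_both_residual_branches(rng):
    """Finite-difference check of one MSA weight and one MLP weight."""
    vb = VitBottleneck(3, 3, grid=2, depth=1, heads=1, mlp_hidden=4,
                       rng=np.random.default_rng(2), dtype=np.float64)
    x = rng.random((1, 2, 2, 3))

    def loss():
        return float((vb.forward(x) ** 2).sum())

    for param in (vb.blocks[0].msa.qkv.weight, vb.blocks[0].fc1.weight):
        base = loss()
        for p in vb.parameters():
            p.grad[...] = 0
        y = vb.forward(x)
        vb.backward(2 * y)
        eps = 1e-6
        old = param.value[0, 0]
        param.value[0, 0] = old + eps
        fd = (loss() - base) / eps
        param.value[0, 0] = old
        assert np.isfinite(param.grad[0, 0]) and param.grad[0, 0] != 0
        assert param.grad[0, 0] == pytest.approx(fd, rel=1e-3, abs=1e-8)
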