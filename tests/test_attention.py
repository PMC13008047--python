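"""EMA, MCA and MMSA contracts, including an independent EMA reference."""

import numpy as np
import pytest
from scipy.signal import correlate2d
from scipy.special import expit, softmax

from lmunet.attention import EMA, MCA, MMSA
from lmunet.tensor import Tensor


# ---------------------------------------------------------------------------
# EMA


def test_ema_requires_divisible_groups():
    with pytest.raises(ValueError, match="divide"):
        EMA(10, np.random.default_rng(0), groups=4)


def test_ema_shape_preserving(rng):
    ema = EMA(16, np.random.default_rng(1), groups=8)
    x = Tensor(rng.standard_normal((2, 16, 6, 7)).astype(np.float32))
    assert ema(x).shape == x.shape


def test_ema_constant_input_directional_descriptors_equal(rng):
    """For a constant map, width- and height-pooled descriptors coincide."""
    x = np.full((1, 8, 4, 4), 2.5, np.float32)
    ph = x.mean(axis=3)
    pw = x.mean(axis=2)
    np.testing.assert_array_equal(ph, pw)
    ema = EMA(8, np.random.default_rng(2), groups=2)
    out = ema(Tensor(x)).data
    assert out.shape == x.shape and np.isfinite(out).all()


def _ema_reference(module, x):
    """Step-by-step numpy re-derivation of the EMA contract (independent path)."""
    b, c, h, w = x.shape
    g = module.groups
    cg = c // g
    gx = x.reshape(b * g, cg, h, w).astype(np.float64)
    w1 = module.conv1x1.weight.data.astype(np.float64)
    b1 = module.conv1x1.bias.data.astype(np.float64)
    w3 = module.conv3x3.weight.data.astype(np.float64)
    b3 = module.conv3x3.bias.data.astype(np.float64)

    # (a)+(b): directional pooling, shared 1x1 mix, sigmoid gates
    ph = gx.mean(axis=3)                      # (bg, cg, h)
    pw = gx.mean(axis=2)                      # (bg, cg, w)
    pooled = np.concatenate([ph, pw], axis=2)  # (bg, cg, h+w)
    mixed = np.einsum("oi,bil->bol", w1[:, :, 0, 0], pooled) + b1[None, :, None]
    gate_h = expit(mixed[:, :, :h])[:, :, :, None]
    gate_w = expit(mixed[:, :, h:])[:, :, None, :]
    weighted = gx * gate_h * gate_w

    # (c): per-channel group normalisation of the weighted map
    mu = weighted.mean(axis=(2, 3), keepdims=True)
    var = weighted.var(axis=(2, 3), keepdims=True)
    x1 = (weighted - mu) / np.sqrt(var + module.gn.eps)
    x1 = x1 * module.gn.weight.data[None, :, None, None] \
        + module.gn.bias.data[None, :, None, None]

    # (d): 3x3 local path
    x2 = np.empty_like(gx)
    for n in range(b * g):
        for o in range(cg):
            acc = np.zeros((h, w))
            for i in range(cg):
                acc += correlate2d(gx[n, i], w3[o, i], mode="same")
            x2[n, o] = acc + b3[o]

    # (e): cross-spatial matmuls in both directions, sum, sigmoid, gate
    d1 = softmax(x1.mean(axis=(2, 3)), axis=1)[:, None, :]
    d2 = softmax(x2.mean(axis=(2, 3)), axis=1)[:, None, :]
    logits = d1 @ x2.reshape(b * g, cg, h * w) + d2 @ x1.reshape(b * g, cg, h * w)
    weights = expit(logits.reshape(b * g, 1, h, w))
    return (gx * weights).reshape(b, c, h, w)


def test_ema_matches_independent_reference(rng):
    ema = EMA(8, np.random.default_rng(3), groups=2)
    x = rng.standard_normal((2, 8, 4, 4)).astype(np.float32)
    out = ema(Tensor(x)).data
    ref = _ema_reference(ema, x)
    np.testing.assert_allclose(out, ref, atol=1e-6)


def test_ema_ungrouping_conserves_channels(rng):
    ema = EMA(24, np.random.default_rng(4), groups=8)
    x = Tensor(rng.standard_normal((1, 24, 5, 5)).astype(np.float32))
    assert ema(x).shape[1] == 24


# ---------------------------------------------------------------------------
# MCA


def _stages(rng, channels=(8, 12, 16), size=16, b=2):
    maps = []
    s = size
    for c in channels:
        maps.append(Tensor(rng.standard_normal((b, c, s, s)).astype(np.float32)))
        s //= 2
    return maps


def test_mca_rejects_empty():
    mca = MCA((8, 16), np.random.default_rng(0))
    with pytest.raises(ValueError, match="empty"):
        mca([])


def test_mca_gap_of_constant_stage(rng):
    stages = _stages(rng)
    stages[1] = Tensor(np.full((2, 12, 8, 8), 3.0, np.float32))
    desc = stages[1].mean(axis=(2, 3)).data
    np.testing.assert_allclose(desc, 3.0)


def test_mca_attention_strictly_in_unit_interval_and_shapes(rng):
    mca = MCA((8, 12, 16), np.random.default_rng(1))
    stages = _stages(rng)
    outs = mca(stages)
    for t_in, t_out, fc in zip(stages, outs, mca.fcs):
        assert t_out.shape == t_in.shape
        att = fc(mca.conv1d(
            Tensor(np.concatenate([s.mean(axis=(2, 3)).data for s in stages], axis=1))
        )).sigmoid().data
        assert np.all(att > 0) and np.all(att < 1)


def test_mca_forced_half_attention_scales_by_1p5(rng):
    """Zero FC weights and bias give sigmoid(0) = 0.5, so Out = 1.5 * t."""
    mca = MCA((8, 12, 16), np.random.default_rng(2))
    for fc in mca.fcs:
        fc.weight.data[:] = 0.0
        fc.bias.data[:] = 0.0
    stages = _stages(rng)
    outs = mca(stages)
    for t_in, t_out in zip(stages, outs):
        np.testing.assert_allclose(t_out.data, 1.5 * t_in.data, rtol=1e-6)


def test_mca_zero_attention_limit_returns_input(rng):
    """As the attention weights approach 0, the residual floor keeps Out = t."""
    mca = MCA((8, 12), np.random.default_rng(3))
    for fc in mca.fcs:
        fc.weight.data[:] = 0.0
        fc.bias.data[:] = -40.0  # sigmoid -> 0
    stages = _stages(rng, channels=(8, 12))
    for t_in, t_out in zip(stages, mca(stages)):
        np.testing.assert_allclose(t_out.data, t_in.data, rtol=1e-5)


# ---------------------------------------------------------------------------
# MMSA


def test_mmsa_constant_input_mean_equals_max():
    x = np.full((1, 6, 5, 5), 1.75, np.float32)
    assert np.array_equal(x.mean(axis=1), x.max(axis=1))


def test_mmsa_shape_and_attention_range(rng):
    mmsa = MMSA(np.random.default_rng(0))
    x = Tensor(rng.standard_normal((2, 6, 9, 9)).astype(np.float32))
    out = mmsa(x)
    assert out.shape == x.shape
    att = mmsa.conv(Tensor(np.concatenate(
        [x.data.mean(axis=1, keepdims=True), x.data.max(axis=1, keepdims=True)],
        axis=1))).sigmoid().data
    assert np.all(att > 0) and np.all(att < 1)


def test_mmsa_zero_weights_closed_form(rng):
    """Zero conv weights with bias b give F_out = F * (1 + sigmoid(b)) exactly."""
    mmsa = MMSA(np.random.default_rng(1))
    mmsa.conv.weight.data[:] = 0.0
    bval = 0.37
    mmsa.conv.bias.data[:] = bval
    x = rng.standard_normal((2, 4, 8, 8)).astype(np.float32)
    out = mmsa(Tensor(x)).data
    np.testing.assert_allclose(out, x * (1 + 1 / (1 + np.exp(-bval))), rtol=1e-6)


def test_mmsa_zero_attention_limit_returns_input(rng):
    mmsa = MMSA(np.random.default_rng(2))
    mmsa.conv.weight.data[:] = 0.0
    mmsa.conv.bias.data[:] = -40.0
    x = rng.standard_normal((1, 3, 6, 6)).astype(np.float32)
    np.testing.assert_allclose(mmsa(Tensor(x)).data, x, rtol=1e-5)
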