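"""Network assembly: shape table, seeding, toggles, accounting, checkpoints."""

import numpy as np
import pytest

from lmunet import nn
from lmunet.network import (LMUNet, ModelConfig, build_model, count_flops,
                            count_parameters, encoder_shapes, load_checkpoint,
                            save_checkpoint)
from lmunet.tensor import Tensor, mac_counter


EXPECTED_TABLE = [
    (1, (-1, 3, 224, 224), (-1, 8, 224, 224), 50176),
    (2, (-1, 8, 224, 224), (-1, 16, 112, 112), 12544),
    (3, (-1, 16, 112, 112), (-1, 24, 56, 56), 3136),
    (4, (-1, 24, 56, 56), (-1, 32, 28, 28), 784),
    (5, (-1, 32, 28, 28), (-1, 48, 14, 14), 196),
    (6, (-1, 48, 14, 14), (-1, 64, 7, 7), 49),
]


def test_encoder_shape_table_exact():
    rows = encoder_shapes(ModelConfig())
    got = [(r.stage, r.input_dims, r.output_dims, r.sequence_length) for r in rows]
    assert got == EXPECTED_TABLE


def test_sequence_length_is_output_area():
    for r in encoder_shapes(ModelConfig()):
        assert r.sequence_length == r.output_dims[2] * r.output_dims[3]


def test_config_validation_errors():
    with pytest.raises(ValueError, match="six"):
        ModelConfig(stage_channels=(8, 16, 24))
    with pytest.raises(ValueError, match="divisible"):
        ModelConfig(image_size=100)
    with pytest.raises(ValueError, match="use_efe"):
        ModelConfig(use_eff=True, use_efe=False)


def test_same_seed_bit_identical_weights(small_model_cfg):
    a = LMUNet(small_model_cfg).state_dict()
    b = LMUNet(small_model_cfg).state_dict()
    assert a.keys() == b.keys()
    for k in a:
        np.testing.assert_array_equal(a[k], b[k])


def test_different_seed_different_weights(small_model_cfg):
    from dataclasses import replace
    a = LMUNet(small_model_cfg).state_dict()
    b = LMUNet(replace(small_model_cfg, seed=small_model_cfg.seed + 1)).state_dict()
    assert any(not np.array_equal(a[k], b[k]) for k in a)


def test_forward_shape_and_determinism(small_model_cfg, rng):
    model = LMUNet(small_model_cfg).eval()
    x = Tensor(rng.standard_normal((2, 3, 64, 64)).astype(np.float32))
    y1 = model(x)
    assert y1.shape == (2, 1, 64, 64)
    assert np.isfinite(y1.data).all()
    np.testing.assert_array_equal(y1.data, model(x).data)


def test_forward_rejects_wrong_input(small_model_cfg):
    model = LMUNet(small_model_cfg)
    with pytest.raises(ValueError, match="expected input"):
        model(Tensor(np.zeros((1, 3, 32, 32), np.float32)))
    with pytest.raises(ValueError, match="expected input"):
        model(Tensor(np.zeros((1, 1, 64, 64), np.float32)))


def test_toggles_reduce_to_baseline_topology(small_model_cfg):
    from dataclasses import replace
    base = LMUNet(replace(small_model_cfg, use_ema=False, use_efe=False,
                          use_eff=False, use_mmsc=False))
    assert base.efe is None and base.eff is None
    assert base.mca is None and base.mmsa is None
    assert all(s.ema is None for s in base.encoder)
    x = Tensor(np.zeros((1, 3, 64, 64), np.float32))
    assert base.eval()(x).shape == (1, 1, 64, 64)


def test_each_toggle_strictly_adds_parameters(small_model_cfg):
    from dataclasses import replace
    full = count_parameters(LMUNet(small_model_cfg))
    for off in ({"use_ema": False}, {"use_mmsc": False},
                {"use_eff": False}, {"use_efe": False, "use_eff": False}):
        reduced = count_parameters(LMUNet(replace(small_model_cfg, **off)))
        assert reduced < full, f"disabling {off} did not remove parameters"


def test_count_parameters_single_conv_example():
    conv = nn.Conv2d(8, 16, 3, np.random.default_rng(0), bias=True)
    assert sum(p.size for p in conv.parameters()) == 3 * 3 * 8 * 16 + 16  # 1168


def test_count_parameters_frozen_model(small_model_cfg):
    model = LMUNet(small_model_cfg)
    for p in model.parameters():
        p.requires_grad = False
    assert count_parameters(model) == 0


def test_flops_single_conv_closed_form():
    conv = nn.Conv2d(8, 16, 3, np.random.default_rng(0), padding=1)
    with mac_counter() as c:
        conv(Tensor(np.zeros((1, 8, 112, 112), np.float32)))
    assert c.total == 9 * 8 * 16 * 112 * 112


def test_flops_per_sample_batch_invariant(small_model_cfg):
    model = LMUNet(small_model_cfg).eval()
    totals = {}
    for b in (1, 2):
        with mac_counter() as c:
            model(Tensor(np.zeros((b, 3, 64, 64), np.float32)))
        totals[b] = c.total
    assert totals[2] == 2 * totals[1]


def test_gradient_reaches_every_parameter(small_model_cfg, rng):
    """One backward pass leaves no named parameter with an all-zero gradient."""
    model = LMUNet(small_model_cfg)
    x = Tensor(rng.standard_normal((2, 3, 64, 64)).astype(np.float32))
    from lmunet.losses import combined_loss
    y = Tensor((rng.uniform(size=(2, 1, 64, 64)) > 0.7).astype(np.float32))
    loss = combined_loss(model(x), y)
    loss.backward()
    dead = [name for name, p in model.named_parameters()
            if p.grad is None or not np.any(p.grad != 0)]
    assert not dead, f"dead parameters: {dead}"


def test_checkpoint_round_trip(tmp_path, small_model_cfg, rng):
    model = LMUNet(small_model_cfg).eval()
    path = tmp_path / "model.npz"
    save_checkpoint(path, model, extra={"note": "unit"})
    loaded = load_checkpoint(path).eval()
    assert loaded.cfg == model.cfg
    x = Tensor(rng.standard_normal((1, 3, 64, 64)).astype(np.float32))
    np.testing.assert_array_equal(model(x).data, loaded(x).data)


def test_default_build_smoke():
    model = build_model()
    assert count_parameters(model) > 0
    assert len(model.encoder) == 6 and len(model.decoder) == 5
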