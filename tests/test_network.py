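"""Model assembly: registry, ablation flags, shapes, gradients, counting,
checkpointing and translation equivariance."""

import numpy as np
import pytest

from dgfinet import (ModelConfig, PhantomSpec, ablation_variant, build_model,
                     count_mult_adds, count_parameters, dice_loss,
                     load_checkpoint, make_phantom, save_checkpoint)
from dgfinet import autodiff as ad
from dgfinet import nn


def test_ablation_variant_flag_table():
    flags = lambda c: (c.use_ecrb, c.use_agfrb, c.use_dgfi, c.use_lrm)
    assert flags(ablation_variant("baseline")) == (False, False, False, False)
    assert flags(ablation_variant("ecrb")) == (True, False, False, False)
    assert flags(ablation_variant("agfrb")) == (False, True, False, False)
    assert flags(ablation_variant("ecrb_agfrb_dgfi")) == (True, True, True,
                                                          False)
    assert flags(ablation_variant("full")) == (True, True, True, True)
    with pytest.raises(ValueError, match="baseline.*full"):
        ablation_variant("bogus")


def test_baseline_registry_has_no_auxiliary_or_bottleneck_extras(tiny_model_cfg):
    m = build_model(tiny_model_cfg, seed=0)
    names = [k for k, _ in m.named_parameters()]
    assert names, "registry must not be empty"
    assert not any(n.startswith(("aux", "lrm", "guide", "fuse"))
                   for n in names)


def test_full_registry_contains_every_component(tiny_model_cfg):
    cfg = ablation_variant("full", tiny_model_cfg)
    names = [k for k, _ in build_model(cfg, seed=0).named_parameters()]
    for prefix in ("aux_encoder", "aux_decoder_up", "lrm", "guide", "fuse",
                   "encoder", "bottleneck", "head"):
        assert any(n.startswith(prefix) for n in names), prefix


def test_build_is_deterministic_in_config_and_seed(tiny_model_cfg):
    cfg = ablation_variant("full", tiny_model_cfg)
    a, b = build_model(cfg, seed=5), build_model(cfg, seed=5)
    for (ka, pa), (kb, pb) in zip(a.named_parameters(), b.named_parameters()):
        assert ka == kb
        np.testing.assert_array_equal(pa.data, pb.data)
    c = build_model(cfg, seed=6)
    assert any(not np.array_equal(p.data, q.data)
               for p, q in zip(a.parameters(), c.parameters()))


def test_parameter_counts_grow_along_the_ablation_ladder():
    counts = {v: count_parameters(build_model(ablation_variant(v), 0))
              for v in ("baseline", "ecrb", "full")}
    assert counts["baseline"] < counts["ecrb"] < counts["full"]


def test_parameter_count_matches_layer_walking_oracle(tiny_model_cfg):
    """Closed-form per-layer count of the plain U-Net, derived independently
    from the architecture definition."""
    cfg = tiny_model_cfg
    w = cfg.stage_widths

    def double_conv(cin, cout):
        # two 3x3 bias-free convs, each with BN gamma+beta
        return 9 * cin * cout + 2 * cout + 9 * cout * cout + 2 * cout

    expected = 0
    chans = [cfg.in_channels] + w
    for cin, cout in zip(chans[:-1], chans[1:]):          # encoder
        expected += double_conv(cin, cout)
    expected += double_conv(w[-1], cfg.bottleneck_width)  # bottleneck
    above = [cfg.bottleneck_width] + w[:0:-1]
    for d, src in zip(range(cfg.num_stages - 1, -1, -1), above):  # decoder
        expected += src * w[d] + 2 * w[d]                 # 1x1 up-conv + BN
        expected += double_conv(2 * w[d], w[d])
    expected += w[0] * 1 + 1                              # sigmoid head
    assert count_parameters(build_model(cfg, 0)) == expected


def test_single_conv_parameter_closed_forms():
    r = np.random.default_rng(0)
    assert sum(p.size for p in nn.Conv2d(r, 4, 8, 1).parameters()) == 40
    dw = nn.Conv2d(r, 16, 16, 3, groups=16)
    assert sum(p.size for p in dw.parameters()) == 9 * 16 + 16


def test_mult_adds_scale_quadratically_with_input_side(tiny_model_cfg):
    # exactly x4 for the purely convolutional baseline; the full variant adds
    # ECA channel-descriptor convs whose cost is resolution-independent
    base = build_model(tiny_model_cfg, 0)
    assert count_mult_adds(base, 32) == 4 * count_mult_adds(base, 16)
    m = build_model(ablation_variant("full", tiny_model_cfg), 0)
    params_before = count_parameters(m)
    m16, m32 = count_mult_adds(m, 16), count_mult_adds(m, 32)
    assert abs(m32 - 4 * m16) / m32 < 1e-4
    assert count_parameters(m) == params_before


def test_forward_shape_range_and_divisibility(tiny_model_cfg):
    cfg = ablation_variant("full", tiny_model_cfg)
    m = build_model(cfg, 1).eval()
    x = np.random.default_rng(0).random((2, 1, 16, 16)).astype(np.float32)
    with ad.no_grad():
        y = m(x).data
    assert y.shape == (2, 1, 16, 16)
    assert np.all((y > 0) & (y < 1))
    with pytest.raises(ValueError, match="multiple of 4"):
        m(np.zeros((1, 1, 10, 10), dtype=np.float32))


def test_zeroed_head_outputs_exactly_half(tiny_model_cfg):
    m = build_model(tiny_model_cfg, 2).eval()
    m.head.weight.data = np.zeros_like(m.head.weight.data)
    m.head.bias.data = np.zeros_like(m.head.bias.data)
    with ad.no_grad():
        y = m(np.zeros((1, 1, 16, 16), dtype=np.float32)).data
    np.testing.assert_array_equal(y, 0.5)


def test_every_parameter_gets_gradient_from_dice_backward(tiny_model_cfg):
    cfg = ablation_variant("full", tiny_model_cfg)
    m = build_model(cfg, 3)
    rng = np.random.default_rng(4)
    x = rng.random((2, 1, 16, 16)).astype(np.float32)
    t = (rng.random((2, 1, 16, 16)) > 0.5).astype(np.float32)
    loss = dice_loss(m(x), t)
    loss.backward()
    dead = [k for k, p in m.named_parameters()
            if p.grad is None or np.linalg.norm(p.grad) == 0]
    assert dead == []


def test_checkpoint_roundtrip_restores_forward_exactly(tmp_path,
                                                       tiny_model_cfg):
    cfg = ablation_variant("full", tiny_model_cfg)
    m = build_model(cfg, 7)
    x = np.random.default_rng(1).random((1, 1, 16, 16)).astype(np.float32)
    # perturb running stats so buffers are exercised too
    m.train()
    m(x)
    before = m.predict(x)
    path = tmp_path / "ck.npz"
    save_checkpoint(m, path)
    loaded = load_checkpoint(path)
    assert loaded.cfg == cfg
    np.testing.assert_array_equal(loaded.predict(x), before)


def test_thresholded_output_is_translation_equivariant():
    # a compact phantom on a uniform canvas, far from the borders, shifted by
    # one pooling period; only the border halo and the global ECA descriptor
    # break equivariance, so thresholded maps must agree on >= 95% of the
    # interior
    cfg = ModelConfig(stage_widths=[8, 16, 32, 64], bottleneck_width=128,
                      use_ecrb=True, use_agfrb=True, use_dgfi=True,
                      use_lrm=True)
    m = build_model(cfg, 9).eval()
    period = 2 ** cfg.num_stages
    s = make_phantom(PhantomSpec(image_size=64, seed=3))
    canvas = np.full((128, 128), 0.03, dtype=np.float32)
    shifted = canvas.copy()
    canvas[32:96, 16:80] = s.image
    shifted[32:96, 16 + period : 80 + period] = s.image
    with ad.no_grad():
        y = m(canvas[None, None]).data[0, 0] >= 0.5
        y_shift = m(shifted[None, None]).data[0, 0] >= 0.5
    interior = (slice(8, 120), slice(40, 112))
    agree = (np.roll(y, period, axis=1)[interior]
             == y_shift[interior]).mean()
    assert agree >= 0.95
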