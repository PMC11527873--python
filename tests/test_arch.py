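"""Structural and contract tests of the network and its ablation variants.

Heavy checks run at channel_scale 0.25 and 64x64 inputs; the full-scale
512x512 contracts live in the acceptance suite.
"""

import numpy as np
import pytest

from reflexseg.arch import (AblationVariant, ConvUNeXtBlock, NetworkConfig,
                            ReflexNet, VARIANTS, build_variant,
                            make_conv_block, make_initial_stage_proposed,
                            make_initial_stage_segnet, summarize_architecture)
from reflexseg.nn import Tensor, no_grad
from reflexseg.nn import functional as F

SCALE = 0.25


def _x(n=1, size=64, seed=0):
    return np.random.default_rng(seed).uniform(
        0, 1, (n, size, size, 3)).astype("f4")


class TestNetworkConfig:
    def test_variant_mapping(self):
        assert VARIANTS == {
            "proposed": ("proposed", "all"),
            "A": ("proposed", "no_initial"),
            "B": ("proposed", "initial_only"),
            "C": ("segnet", "all"),
            "D": ("segnet", "none"),
        }

    def test_default_channel_schedules(self):
        cfg = NetworkConfig()
        assert cfg.encoder_channels == (64, 128, 256, 512, 512)
        assert cfg.decoder_channels == (512, 512, 256, 128, 64)

    @pytest.mark.parametrize("kwargs", [
        dict(encoder_channels=(64, 128)),
        dict(initial_stage="resnet"),
        dict(skip_mode="some"),
        dict(convunext_kernels=(4, 7, 9)),
        dict(channel_scale=0.0),
    ])
    def test_invalid_configs_rejected(self, kwargs):
        with pytest.raises(ValueError):
            NetworkConfig(**kwargs)

    def test_unknown_variant_rejected(self):
        with pytest.raises(ValueError, match="unknown variant"):
            AblationVariant("E")

    def test_json_roundtrip(self):
        cfg = NetworkConfig(channel_scale=0.5, skip_mode="none")
        assert NetworkConfig.from_json(cfg.to_json()) == cfg


class TestConvBlock:
    def test_preserves_spatial_size_and_nonnegative(self, rng):
        block = make_conv_block(3, 8, rng=rng)
        out = block(Tensor(_x(2, 64)))
        assert out.shape == (2, 64, 64, 8)
        assert (out.data >= 0).all()

    def test_small_channel_block(self, rng):
        block = make_conv_block(8, 8, rng=rng)
        out = block(Tensor(rng.uniform(0, 1, (1, 16, 16, 8)).astype("f4")))
        assert out.shape == (1, 16, 16, 8)


class TestInitialStages:
    def test_proposed_exposes_four_full_resolution_taps(self, rng):
        cfg = NetworkConfig(channel_scale=SCALE)
        stage = make_initial_stage_proposed(cfg, rng)
        out, taps = stage(Tensor(_x()))
        c1 = cfg.scaled_encoder()[0]
        assert len(taps) == 4 and stage.num_taps == 4
        for tap in taps:
            assert tap.shape == (1, 64, 64, c1)
        assert out is taps[-1]

    def test_segnet_exposes_single_tap(self, rng):
        cfg = NetworkConfig(channel_scale=SCALE, initial_stage="segnet")
        stage = make_initial_stage_segnet(cfg, rng)
        out, taps = stage(Tensor(_x()))
        assert stage.num_taps == 1 and len(taps) == 1
        assert out.shape == (1, 64, 64, cfg.scaled_encoder()[0])

    def test_residual_block_is_identity_when_projection_zeroed(self, rng):
        block = ConvUNeXtBlock(8, 32, kernel=7, momentum=0.1, rng=rng)
        block.pw2.weight.data[:] = 0.0
        block.pw2.bias.data[:] = 0.0
        x = Tensor(rng.normal(size=(1, 16, 16, 8)).astype("f4"))
        out = block(x)
        np.testing.assert_array_equal(out.data, x.data)

    def test_convunext_parameter_count_closed_form(self, rng):
        # dw 64*7*7 (no bias) + BN 2*64 + 1x1 64->256 (+bias) + 1x1 256->64 (+bias)
        block = ConvUNeXtBlock(64, 256, kernel=7, momentum=0.1, rng=rng)
        expected = 64 * 49 + 2 * 64 + 64 * 256 + 256 + 256 * 64 + 64
        assert block.num_parameters() == expected


def propagate_channels(cfg: NetworkConfig) -> list[int]:
    """Independent symbolic propagation of decoder concat widths.

    Index-based unpooling pins the tensor entering decoder stage j to the
    channel count of the encoder map whose pool indices it reuses; the
    skip concat then adds that encoder map's width (or the initial-stage
    taps for stage 5).
    """
    enc = cfg.scaled_encoder()
    n_taps = 4 if cfg.initial_stage == "proposed" else 1
    widths = []
    for j in range(1, 6):
        unpooled = enc[5 - j]  # == enc[4] for j=1
        if cfg.skip_active(j):
            skip = enc[0] * n_taps if j == 5 else enc[5 - j]
        else:
            skip = 0
        widths.append(unpooled + skip)
    return widths


class TestEncoderDecoder:
    def test_encoder_schedule_and_spatial_halving(self):
        net = build_variant("proposed", channel_scale=SCALE, seed=0)
        outs = net.encode(_x())
        enc = net.cfg.scaled_encoder()
        for i, (pre, pooled) in enumerate(zip(outs.pre_pool, outs.pooled)):
            side = 64 // 2 ** i
            assert pre.shape == (1, side, side, enc[i])
            assert pooled.values.shape == (1, side // 2, side // 2, enc[i])
            assert pooled.indices.shape == tuple(pooled.values.shape)
            assert pooled.indices.min() >= 0 and pooled.indices.max() <= 3

    def test_final_pooled_map_is_1x1_on_32px_input(self):
        net = build_variant("proposed", channel_scale=0.05, seed=0)
        outs = net.encode(_x(size=32))
        assert outs.pooled[-1].values.shape[1:3] == (1, 1)

    def test_indivisible_input_rejected(self):
        net = build_variant("proposed", channel_scale=SCALE, seed=0)
        with pytest.raises(ValueError, match="divisible by 32"):
            net.encode(np.zeros((1, 48, 48, 3), "f4"))

    @pytest.mark.parametrize("variant", sorted(VARIANTS))
    def test_concat_widths_match_symbolic_oracle(self, variant):
        net = build_variant(variant, channel_scale=1.0, seed=0)
        expected = propagate_channels(net.cfg)
        got = [net.decoder.concat_width(j) for j in range(1, 6)]
        assert got == expected

    def test_proposed_full_width_concats(self):
        net = build_variant("proposed", channel_scale=1.0, seed=0)
        assert [net.decoder.concat_width(j) for j in range(1, 6)] == \
            [1024, 1024, 512, 256, 320]

    @pytest.mark.parametrize("variant,junctions", [
        ("proposed", 5), ("A", 4), ("B", 1), ("C", 5), ("D", 0)])
    def test_concat_junction_counts(self, variant, junctions):
        net = build_variant(variant, channel_scale=SCALE, seed=0)
        assert net.concat_junctions == junctions

    @pytest.mark.parametrize("variant", sorted(VARIANTS))
    def test_forward_shape_and_sigmoid_range(self, variant):
        net = build_variant(variant, channel_scale=SCALE, seed=0)
        with no_grad():
            out = net(_x(2))
        assert out.shape == (2, 64, 64, 1)
        assert (out.data > 0).all() and (out.data < 1).all()

    def test_eval_mode_forward_is_bit_deterministic(self):
        net = build_variant("proposed", channel_scale=SCALE, seed=0).eval()
        x = _x()
        with no_grad():
            a = net(x).data.copy()
            b = net(x).data.copy()
        np.testing.assert_array_equal(a, b)

    def test_zero_input_gives_bias_driven_deterministic_response(self):
        net = build_variant("proposed", channel_scale=SCALE, seed=0).eval()
        z = np.zeros((1, 64, 64, 3), "f4")
        with no_grad():
            o1 = net.encode(z)
            o2 = net.encode(z)
        for a, b in zip(o1.pre_pool, o2.pre_pool):
            np.testing.assert_array_equal(a.data, b.data)

    def test_decode_requires_taps_when_initial_skip_active(self):
        net = build_variant("proposed", channel_scale=SCALE, seed=0)
        outs = net.encode(_x())
        outs.initial_block_outputs = []
        with pytest.raises(ValueError, match="taps"):
            net.decode(outs)

    def test_seeded_build_is_deterministic(self):
        a = build_variant("B", channel_scale=SCALE, seed=7)
        b = build_variant("B", channel_scale=SCALE, seed=7)
        for (n1, p1), (_, p2) in zip(a.named_parameters(),
                                     b.named_parameters()):
            np.testing.assert_array_equal(p1.data, p2.data)

    def test_proposed_vs_a_differ_only_in_last_decoder_stage_input(self):
        shapes_p = {n: p.data.shape for n, p in
                    build_variant("proposed", channel_scale=SCALE,
                                  seed=0).named_parameters()}
        shapes_a = {n: p.data.shape for n, p in
                    build_variant("A", channel_scale=SCALE,
                                  seed=0).named_parameters()}
        diffs = {n for n in shapes_p if shapes_p[n] != shapes_a[n]}
        assert diffs == {"decoder.stage5._0.conv.weight"}

    def test_unpooling_inverse_property_inside_network(self):
        net = build_variant("proposed", channel_scale=SCALE, seed=0)
        outs = net.encode(_x())
        # stage 1 ends in a residual add, so values may be negative; the
        # scatter contract holds regardless of sign
        pf = outs.pooled[0]
        restored = F.max_unpool2d(pf.values, pf.indices)
        flat = restored.data.reshape(*pf.values.shape[:1],
                                     pf.values.shape[1], 2,
                                     pf.values.shape[2], 2,
                                     pf.values.shape[3])
        gathered = np.take_along_axis(
            flat.transpose(0, 1, 3, 2, 4, 5).reshape(
                *pf.values.shape[:3], 4, pf.values.shape[3]),
            pf.indices[:, :, :, None, :].astype(np.int64), axis=3)
        np.testing.assert_array_equal(gathered[:, :, :, 0, :],
                                      pf.values.data)
        assert (restored.data != 0).sum() <= pf.values.data.size
        # ReLU-terminated stages additionally satisfy the repool identity
        pf2 = outs.pooled[1]
        repooled, _ = F.max_pool2d(F.max_unpool2d(pf2.values, pf2.indices))
        np.testing.assert_array_equal(repooled.data, pf2.values.data)


class TestGradientFlow:
    def test_every_parameter_receives_gradient(self):
        from reflexseg.losses import focal_tversky_loss
        from reflexseg.nn import AdamW
        net = build_variant("proposed", channel_scale=0.1, seed=0)
        x = _x(2, 64, seed=3)
        y = np.zeros((2, 64, 64, 1), "f4")
        y[:, 30:33, 30:33, 0] = 1.0
        pred = net(Tensor(x))
        loss = focal_tversky_loss(pred, y)
        loss.backward()
        missing = [n for n, p in net.named_parameters() if p.grad is None]
        assert missing == []
        zero_frac = np.mean([float((p.grad == 0).all())
                             for _, p in net.named_parameters()])
        assert zero_frac < 0.1  # BN betas etc. may start at exact zero grad

    def test_optimizer_step_changes_parameters(self):
        from reflexseg.losses import focal_tversky_loss
        from reflexseg.nn import AdamW
        net = build_variant("D", channel_scale=0.1, seed=0)
        before = {n: p.data.copy() for n, p in net.named_parameters()}
        opt = AdamW(net.parameters(), lr=1e-2)
        pred = net(Tensor(_x(1, 64, seed=5)))
        y = np.zeros((1, 64, 64, 1), "f4")
        y[0, 10:12, 10:12, 0] = 1.0
        loss = focal_tversky_loss(pred, y)
        opt.zero_grad()
        loss.backward()
        opt.step()
        changed = sum(not np.array_equal(before[n], p.data)
                      for n, p in net.named_parameters())
        assert changed == len(before)


class TestPersistenceAndSummary:
    def test_save_load_roundtrip(self, tmp_path):
        net = build_variant("C", channel_scale=0.1, seed=1)
        path = tmp_path / "net.npz"
        net.save(path)
        loaded = ReflexNet.load(path)
        x = _x(1, 64, seed=2)
        with no_grad():
            np.testing.assert_array_equal(net.eval()(x).data,
                                          loaded.eval()(x).data)

    def test_channel_scale_quarter_runs_end_to_end(self):
        net = build_variant("proposed", channel_scale=0.25, seed=0)
        assert net.cfg.scaled_encoder() == (16, 32, 64, 128, 128)
        with no_grad():
            out = net(_x())
        assert out.shape == (1, 64, 64, 1)

    def test_summary_table_lists_all_stages(self):
        df = summarize_architecture("proposed", channel_scale=0.25)
        assert len(df) == 11  # 5 encoder + 5 decoder + head
        assert df.attrs["concat_junctions"] == 5
        assert df.attrs["total_params"] > 0
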