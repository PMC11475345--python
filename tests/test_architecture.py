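"""Structural probes of the network modules: shape contracts, receptive
fields, weight sharing, connectivity and symbolic parameter counts."""

import numpy as np
import pytest

from cattledet.attention import LSKA, LSKAConfig, SPPFLSKA, lska_param_count
from cattledet.backbone import StarBlock, StarNet, StarNetConfig, star_block_param_count
from cattledet.head import LMFDConfig, LMFDHead, RawPrediction, decode, lmfd_param_count
from cattledet.neck import ADown, InceptionContext, MCFP, MCFPConfig, adown_param_count
from cattledet.nn import ConvBNAct, Tensor, trace_flops


def feat(rng, c, h, w, n=1):
    return Tensor(rng.normal(0, 1, (n, c, h, w)).astype(np.float32))


class TestStarNet:
    def test_stride_contract_640_and_64(self, rng):
        net = StarNet().eval()
        # trace mode propagates real shapes without the arithmetic
        shapes = {}

        def run(x):
            p3, p4, p5 = net(x)
            shapes.update(p3=p3.shape, p4=p4.shape, p5=p5.shape)
            return p3

        trace_flops(run, (1, 3, 640, 640))
        c3, c4, c5 = net.cfg.pyramid_channels
        assert shapes["p3"] == (1, c3, 80, 80)
        assert shapes["p4"] == (1, c4, 40, 40)
        assert shapes["p5"] == (1, c5, 20, 20)
        p3, p4, p5 = net(feat(rng, 3, 64, 64, n=2))
        assert p3.shape[:1] == (2,) and p3.shape[2:] == (8, 8) and p5.shape[2:] == (2, 2)

    def test_indivisible_input_rejected(self, rng):
        with pytest.raises(ValueError, match="divisible by 32"):
            StarNet().eval()(feat(rng, 3, 60, 64))

    def test_star_block_preserves_shape_and_residual_identity_at_init(self, rng):
        blk = StarBlock(16, rng=rng).eval()
        x = feat(rng, 16, 10, 10)
        y = blk(x)
        assert y.shape == x.shape
        # trailing BN has zero-init scale: the block starts as the identity
        assert np.allclose(y.data, x.data, atol=1e-6)

    def test_star_product_differs_from_additive_block(self, rng):
        g1, g2 = np.random.default_rng(0), np.random.default_rng(0)
        star = StarBlock(8, rng=g1, star=True).train()
        plain = StarBlock(8, rng=g2, star=False).train()
        for blk in (star, plain):  # open the zero-init residual gate
            blk.bn2.gamma.data[:] = 1.0
        x = feat(rng, 8, 6, 6)
        assert not np.allclose(star(x).data, plain(x).data)

    def test_symbolic_block_count_matches_framework(self, rng):
        for width, e in ((16, 4), (32, 4), (24, 2)):
            blk = StarBlock(width, expansion=e, rng=rng)
            assert blk.num_params() == star_block_param_count(width, e)

    def test_backbone_count_is_pure_function_of_config(self):
        a = StarNet(StarNetConfig(), rng=np.random.default_rng(1))
        b = StarNet(StarNetConfig(), rng=np.random.default_rng(99))
        assert a.num_params() == b.num_params()

    def test_deterministic_forward(self, rng):
        net = StarNet().eval()
        x = feat(rng, 3, 32, 32)
        y1 = net(x)[0].data
        y2 = net(x)[0].data
        assert np.array_equal(y1, y2)


class TestLSKA:
    def test_config_kernels_odd_and_support_equals_k(self):
        cfg = LSKAConfig(k=11, d=3)
        assert cfg.k_local % 2 == 1 and cfg.k_dilated % 2 == 1
        assert cfg.receptive_field == 11

    def test_impulse_response_support(self, rng):
        c = 4
        lska = LSKA(c, LSKAConfig(k=11, d=3), rng=rng)
        # make every depthwise tap positive the full support is exercised
        for conv in (lska.conv_h, lska.conv_v, lska.conv_h_d, lska.conv_v_d):
            conv.weight.data = np.abs(conv.weight.data) + 0.1
            conv.bias.data[:] = 0.0
        x = np.zeros((1, c, 31, 31), dtype=np.float32)
        x[0, :, 15, 15] = 1.0
        z = lska.conv_v_d(lska.conv_h_d(lska.conv_v(lska.conv_h(Tensor(x)))))
        ys, xs = np.where(np.abs(z.data[0, 0]) > 1e-8)
        assert ys.max() - ys.min() + 1 == 11
        assert xs.max() - xs.min() + 1 == 11

    def test_zero_input_maps_to_zero(self, rng):
        lska = LSKA(8, rng=rng)
        out = lska(Tensor(np.zeros((1, 8, 9, 9), dtype=np.float32)))
        assert np.array_equal(out.data, np.zeros_like(out.data))

    def test_attention_neutral_when_map_is_one(self, rng):
        lska = LSKA(8, rng=rng)
        for conv in (lska.conv_h, lska.conv_v, lska.conv_h_d, lska.conv_v_d, lska.proj):
            conv.weight.data[:] = 0.0
            conv.bias.data[:] = 0.0
        lska.proj.bias.data[:] = 1.0  # A == 1 everywhere
        x = feat(rng, 8, 7, 7)
        assert np.allclose(lska(x).data, x.data, atol=1e-6)

    def test_symbolic_param_count(self):
        cfg = LSKAConfig(k=11, d=3)
        for c in (32, 256):
            assert LSKA(c, cfg).num_params() == lska_param_count(c, cfg)
        # depthwise part linear in C, pointwise quadratic
        dw = lambda c: lska_param_count(c, cfg) - c * c - c
        assert dw(256) == 8 * dw(32)

    def test_channel_mismatch_rejected(self, rng):
        with pytest.raises(ValueError, match="channels"):
            LSKA(8, rng=rng)(feat(rng, 4, 5, 5))


class TestSPPFLSKA:
    def test_shape_preserved(self, rng):
        m = SPPFLSKA(32, 32, rng=rng).eval()
        x = feat(rng, 32, 8, 8)
        assert m(x).shape == (1, 32, 8, 8)

    def test_without_lska_is_standard_sppf_graph(self, rng):
        g1, g2 = np.random.default_rng(4), np.random.default_rng(4)
        with_ = SPPFLSKA(16, 16, use_lska=True, rng=g1)
        without = SPPFLSKA(16, 16, use_lska=False, rng=g2)
        from cattledet.baseline import SPPF

        ref = SPPF(16, 16, rng=np.random.default_rng(4))
        assert without.num_params() == ref.num_params()
        assert with_.num_params() == without.num_params() + lska_param_count(32, with_.lska.cfg)

    def test_gradient_reaches_all_pooled_branches(self, rng):
        m = SPPFLSKA(8, 8, rng=rng).train()
        x = Tensor(rng.normal(0, 1, (1, 8, 8, 8)).astype(np.float32), requires_grad=True)
        (m(x) * Tensor(rng.normal(size=(1, 8, 8, 8)))).sum().backward()
        assert x.grad is not None and np.abs(x.grad).max() > 0
        for conv in (m.cv1.conv, m.cv2.conv):
            assert conv.weight.grad is not None and np.abs(conv.weight.grad).sum() > 0


class TestADownAndContext:
    def test_halves_resolution(self, rng):
        m = ADown(8, 8, rng=rng).eval()
        assert m(feat(rng, 8, 12, 12)).shape == (1, 8, 6, 6)

    def test_odd_dims_rejected(self, rng):
        with pytest.raises(ValueError, match="even"):
            ADown(8, 8, rng=rng).eval()(feat(rng, 8, 7, 8))

    def test_cheaper_than_plain_stride2_conv(self, rng):
        for c in (32, 76, 128):
            plain = ConvBNAct(c, c, 3, 2, rng=rng).num_params()
            assert ADown(c, c, rng=rng).num_params() == adown_param_count(c, c) < plain

    def test_constant_input_yields_constant_branches(self, rng):
        m = ADown(4, 4, rng=rng).eval()
        out = m(Tensor(np.full((1, 4, 8, 8), 3.0, dtype=np.float32))).data
        interior = out[:, :, 1:-1, 1:-1]  # borders see conv zero-padding
        assert np.allclose(interior, interior[:, :, :1, :1], atol=1e-5)

    def test_inception_context_residual_identity_at_zero_init(self, rng):
        m = InceptionContext(8, rng=rng)
        for conv in (m.dw_square, m.dw_band_h, m.dw_band_v, m.pw):
            conv.weight.data[:] = 0.0
            conv.bias.data[:] = 0.0
        x = feat(rng, 8, 6, 6)
        assert np.allclose(m(x).data, x.data)

    def test_inception_impulse_support_is_union_of_branches(self, rng):
        m = InceptionContext(4, band_kernel=7, rng=rng)
        for conv in (m.dw_square, m.dw_band_h, m.dw_band_v):
            conv.weight.data = np.abs(conv.weight.data) + 0.1
            conv.bias.data[:] = 0.0
        m.pw.weight.data = np.abs(m.pw.weight.data) + 0.1
        m.pw.bias.data[:] = 0.0
        x = np.zeros((1, 4, 21, 21), dtype=np.float32)
        x[0, :, 10, 10] = 1.0
        y = m(Tensor(x)).data[0, 0]
        ys, xs = np.where(np.abs(y) > 1e-8)
        # band pair spans 7 in each axis (cross), square 3x3, identity 1x1
        assert xs.max() - xs.min() + 1 == 7
        assert ys.max() - ys.min() + 1 == 7


class TestMCFP:
    def _neck(self, rng):
        return MCFP((40, 80, 160), MCFPConfig(neck_width=76), rng=rng)

    def _pyramid(self, rng, n=1, s=32):
        return (feat(rng, 40, s, s, n), feat(rng, 80, s // 2, s // 2, n), feat(rng, 160, s // 4, s // 4, n))

    def test_output_strides_and_common_width(self, rng):
        neck = self._neck(rng).eval()
        n3, n4, n5 = neck(self._pyramid(rng))
        assert n3.shape == (1, 76, 32, 32) and n4.shape == (1, 76, 16, 16) and n5.shape == (1, 76, 8, 8)

    def test_zeroed_p5_still_feeds_n5_through_diffusion(self, rng):
        neck = self._neck(rng).eval()
        p3, p4, p5 = self._pyramid(rng)
        zero5 = Tensor(np.zeros_like(p5.data))
        n5 = neck((p3, p4, zero5))[2]
        assert np.abs(n5.data).max() > 1e-4

    def test_every_input_level_influences_every_output(self, rng):
        neck = self._neck(rng).eval()
        base = self._pyramid(rng)
        ref = [o.data.copy() for o in neck(base)]
        for i in range(3):
            bumped = list(base)
            bumped[i] = Tensor(base[i].data + rng.normal(0, 0.5, base[i].shape).astype(np.float32))
            out = neck(tuple(bumped))
            for j in range(3):
                assert np.abs(out[j].data - ref[j]).max() > 1e-5, f"P{i+3} does not reach N{j+3}"

    def test_deterministic_under_fixed_weights(self, rng):
        neck = self._neck(rng).eval()
        p = self._pyramid(rng)
        assert np.array_equal(neck(p)[0].data, neck(p)[0].data)


class TestLMFDHead:
    def _feats(self, rng, n=1):
        return [feat(rng, 76, s, s, n) for s in (8, 4, 2)]

    def test_output_channel_contract(self, rng):
        head = LMFDHead(rng=rng)
        raw = head(self._feats(rng))
        assert len(raw.box) == len(raw.cls) == 3
        for b, c, s in zip(raw.box, raw.cls, (8, 4, 2)):
            assert b.shape == (1, 64, s, s) and c.shape == (1, 4, s, s)

    def test_shared_conv_affects_all_levels_stems_only_theirs(self, rng):
        head = LMFDHead(rng=rng)
        feats = self._feats(rng)
        ref = [b.data.copy() for b in head(feats).box]
        head.shared.conv.weight.data += 0.05
        after_shared = head(feats).box
        assert all(np.abs(a.data - r).max() > 1e-6 for a, r in zip(after_shared, ref))
        head2 = LMFDHead(rng=np.random.default_rng(0))
        ref2 = [b.data.copy() for b in head2(feats).box]
        head2.stems[0].conv.weight.data += 0.05
        after_stem = head2(feats).box
        assert np.abs(after_stem[0].data - ref2[0]).max() > 1e-6
        assert np.array_equal(after_stem[1].data, ref2[1])
        assert np.array_equal(after_stem[2].data, ref2[2])

    def test_scale_is_neutral_at_init(self, rng):
        head = LMFDHead(rng=rng)
        feats = self._feats(rng)
        ref = [b.data.copy() for b in head(feats).box]
        for s in head.scales:
            s.s.data[:] = 1.0
        again = head(feats).box
        assert all(np.array_equal(a.data, r) for a, r in zip(again, ref))
        head.scales[1].s.data[:] = 2.0
        scaled = head(feats).box
        assert np.allclose(scaled[1].data, 2 * ref[1], atol=1e-6)
        assert np.array_equal(scaled[0].data, ref[0])

    def test_batch_independence_of_group_normalized_head(self, rng):
        head = LMFDHead(rng=rng)
        f1 = self._feats(np.random.default_rng(5))
        f2 = self._feats(np.random.default_rng(6))
        both = head([Tensor(np.concatenate([a.data, b.data])) for a, b in zip(f1, f2)])
        solo = head(f1)
        for lvl in range(3):
            assert np.allclose(both.cls[lvl].data[0], solo.cls[lvl].data[0], atol=1e-5)

    def test_symbolic_param_count_matches_framework(self, rng):
        for cfg, ins in ((LMFDConfig(), None), (LMFDConfig(hidden=64, gn_groups=8), (64, 128, 256))):
            head = LMFDHead(cfg, in_channels=ins, rng=rng)
            assert head.num_params() == lmfd_param_count(cfg, ins)

    def test_channel_mismatch_rejected(self, rng):
        with pytest.raises(ValueError, match="channels"):
            LMFDHead(rng=rng)([feat(rng, 40, s, s) for s in (8, 4, 2)])

    def test_hidden_must_divide_into_gn_groups(self):
        with pytest.raises(ValueError, match="divisible"):
            LMFDConfig(hidden=90, gn_groups=16)


class TestDecode:
    def _empty_raw(self, nc=4, reg_max=16):
        box = [Tensor(np.zeros((1, 4 * reg_max, s, s), dtype=np.float32)) for s in (8, 4, 2)]
        cls = [Tensor(np.full((1, nc, s, s), -40.0, dtype=np.float32)) for s in (8, 4, 2)]
        return RawPrediction(box=box, cls=cls, reg_max=reg_max)

    def test_all_background_decodes_to_nothing(self):
        assert decode(self._empty_raw(), (64, 64), conf_thr=0.25) == []

    def test_delta_distribution_decodes_to_bin_times_stride(self):
        raw = self._empty_raw()
        b = 3  # peaked bin
        cell = (4, 4)
        for side in range(4):
            raw.box[0].data[0, side * 16 + b, cell[0], cell[1]] = 40.0
        raw.cls[0].data[0, 2, cell[0], cell[1]] = 5.0
        (det,) = decode(raw, (64, 64), conf_thr=0.5)
        assert det.cls == 2
        cx, cy = (cell[1] + 0.5) * 8, (cell[0] + 0.5) * 8
        x1, y1, x2, y2 = det.to_xyxy(64, 64)
        assert (x1, y1, x2, y2) == pytest.approx((cx - b * 8, cy - b * 8, cx + b * 8, cy + b * 8), abs=1e-3)

    def test_nms_suppresses_duplicate(self):
        raw = self._empty_raw()
        for cell, logit in (((2, 2), 3.0), ((2, 3), 2.0)):  # adjacent cells, same box shape
            for side in range(4):
                raw.box[0].data[0, side * 16 + 6, cell[0], cell[1]] = 40.0
            raw.cls[0].data[0, 1, cell[0], cell[1]] = logit
        dets = decode(raw, (64, 64), conf_thr=0.1, nms_iou=0.45)
        assert len(dets) == 1 and dets[0].score == pytest.approx(1 / (1 + np.exp(-3.0)))
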