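"""Dual-branch network components: windows, attention, HMSPE, assembly."""

import numpy as np
import pytest

import hmcformer.nn.functional as F
from conftest import micro_config
from hmcformer.config import ModelConfig, desk_config
from hmcformer.model import (AttentionBlock, CnnDownsample, CnnFusion,
                             ConvBlock, HMSPE, HMSPEUp, PatchMerging, PEM,
                             SqueezeExcite, WindowAttention, build_model,
                             channel_shuffle, count_flops, count_parameters,
                             relative_position_index, window_departition,
                             window_partition)
from hmcformer.nn import Tensor, no_grad
from hmcformer.nn.functional import cross_entropy
from reference_impl import ref_window_attention


def t(arr):
    return Tensor(np.asarray(arr, dtype=np.float32))


class TestWindows:
    def test_partition_departition_roundtrip(self, rng):
        x = t(rng.standard_normal((2, 8, 12, 5)))
        back = window_departition(window_partition(x, 4), 4, 8, 12)
        np.testing.assert_array_equal(back.numpy(), x.numpy())

    def test_relative_index_symmetry(self):
        idx = relative_position_index(4)
        # zero displacement maps to one table entry on the diagonal
        assert np.unique(np.diag(idx)).size == 1


class TestWindowAttention:
    def _module(self, rng, dim=12, heads=1, window=4, qkv_bias=True):
        return WindowAttention(dim, heads, window, rng, qkv_bias=qkv_bias)

    @pytest.mark.parametrize("heads", [1, 3])
    def test_matches_dense_oracle(self, rng, heads):
        attn = self._module(rng, dim=12, heads=heads)
        x = rng.standard_normal((1, 16, 12)).astype(np.float32)
        with no_grad():
            out = attn(t(x)).numpy()[0]
        ref = ref_window_attention(
            x[0].astype(np.float64), attn.qkv.weight.data.astype(np.float64),
            attn.qkv.bias.data.astype(np.float64),
            attn.proj.weight.data.astype(np.float64),
            attn.proj.bias.data.astype(np.float64), heads,
            attn.bias_table.data.astype(np.float64),
            relative_position_index(4))
        np.testing.assert_allclose(out, ref, atol=1e-4)

    def test_fused_matches_dense_oracle(self, rng):
        attn = self._module(rng, dim=8, heads=2)
        x = rng.standard_normal((1, 16, 8)).astype(np.float32)
        y = rng.standard_normal((1, 16, 8)).astype(np.float32)
        with no_grad():
            out = attn(t(x), yw=t(y)).numpy()[0]
        ref = ref_window_attention(
            x[0].astype(np.float64), attn.qkv.weight.data.astype(np.float64),
            attn.qkv.bias.data.astype(np.float64),
            attn.proj.weight.data.astype(np.float64),
            attn.proj.bias.data.astype(np.float64), 2,
            attn.bias_table.data.astype(np.float64),
            relative_position_index(4), y=y[0].astype(np.float64))
        np.testing.assert_allclose(out, ref, atol=1e-4)

    def test_zero_cnn_input_reduces_to_plain_attention(self, rng):
        attn = self._module(rng, dim=16, heads=4)
        x = t(rng.standard_normal((3, 16, 16)))
        with no_grad():
            plain = attn(x).numpy()
            fused = attn(x, yw=t(np.zeros((3, 16, 16)))).numpy()
        assert np.abs(plain - fused).max() < 1e-5

    def test_zero_transformer_input_gives_pure_cnn_attention(self, rng):
        # bias-free instance: X=0 must route only CNN-derived q/k/v
        attn = self._module(rng, dim=8, heads=1, qkv_bias=False)
        y = rng.standard_normal((1, 16, 8)).astype(np.float32)
        with no_grad():
            out = attn(t(np.zeros((1, 16, 8))), yw=t(y)).numpy()[0]
        ref = ref_window_attention(
            np.zeros((16, 8)), attn.qkv.weight.data.astype(np.float64), None,
            attn.proj.weight.data.astype(np.float64),
            attn.proj.bias.data.astype(np.float64), 1,
            attn.bias_table.data.astype(np.float64),
            relative_position_index(4), y=y[0].astype(np.float64))
        np.testing.assert_allclose(out, ref, atol=1e-4)

    def test_uniform_tokens_mean_pool(self, rng):
        # identical tokens -> uniform attention -> every output identical
        attn = self._module(rng, dim=8, heads=1)
        x = np.tile(rng.standard_normal((1, 1, 8)), (1, 16, 1))
        with no_grad():
            out = attn(t(x)).numpy()[0]
        assert np.abs(out - out[0]).max() < 1e-5


class TestAttentionBlock:
    def test_shifted_block_preserves_shape_and_grads(self, rng):
        blk = AttentionBlock(8, 2, 4, "sw", rng)
        x = Tensor(rng.standard_normal((2, 8, 8, 8)).astype(np.float32),
                   requires_grad=True)
        out = blk(x)
        assert out.shape == (2, 8, 8, 8)
        out.sum().backward()
        assert np.abs(x.grad).max() > 0

    def test_window_clamps_to_small_maps(self, rng):
        blk = AttentionBlock(8, 2, 7, "w", rng)
        x = t(rng.standard_normal((1, 4, 4, 8)))
        assert blk(x).shape == (1, 4, 4, 8)

    def test_padding_path_for_non_divisible_maps(self, rng):
        blk = AttentionBlock(8, 2, 4, "sw", rng)
        x = t(rng.standard_normal((1, 6, 10, 8)))
        assert blk(x).shape == (1, 6, 10, 8)

    def test_fusion_block_requires_cnn_features(self, rng):
        blk = AttentionBlock(8, 2, 4, "wm", rng)
        with pytest.raises(ValueError):
            blk(t(np.zeros((1, 4, 4, 8))))


class TestConvBlocks:
    def test_output_shape_and_zero_weight_residual(self, rng):
        blk = ConvBlock(4, 5, rng)
        for p in blk.parameters():
            p.data[:] = 0
        x = t(rng.standard_normal((2, 4, 9, 9)))
        np.testing.assert_array_equal(blk(x).numpy(), x.numpy())

    @pytest.mark.parametrize("dilated,stack,field", [
        (False, 1, 5),       # one 5x5 block
        (True, 2, 9),        # two stacked dilated 3x3 blocks
    ])
    def test_receptive_field_support(self, rng, dilated, stack, field):
        kernel = 3 if dilated else 5
        blocks = [ConvBlock(2, kernel, rng, dilated=dilated)
                  for _ in range(stack)]
        for blk in blocks:
            blk.expand.bias.data[:] = 0
            blk.compress.bias.data[:] = 0
        x = np.zeros((1, 2, 17, 17), dtype=np.float32)
        x[0, :, 8, 8] = 1.0
        out = t(x)
        with no_grad():
            for blk in blocks:
                out = blk(out)
        resp = np.abs(out.numpy() - x).max(axis=(0, 1))
        ys, xs = np.nonzero(resp)
        half = field // 2
        assert ys.min() >= 8 - half and ys.max() <= 8 + half
        assert xs.min() >= 8 - half and xs.max() <= 8 + half
        assert resp[8 - half, 8 - half] != 0 or resp[8 + half, 8 + half] != 0


class TestPEM:
    def test_shape_preserved(self, rng):
        pem = PEM(6, rng)
        x = t(np.random.default_rng(0).standard_normal((2, 6, 5, 5)))
        assert pem(x).shape == (2, 6, 5, 5)

    def test_saturated_gate_passes_normalised_input(self, rng):
        pem = PEM(4, rng)
        pem.fc2.weight.data[:] = 0
        pem.fc2.bias.data[:] = 50.0          # sigmoid -> 1
        x = t(np.random.default_rng(1).standard_normal((1, 4, 3, 3)))
        with no_grad():
            out = pem(x).numpy()
            expected = pem.norm(x).numpy()
        np.testing.assert_allclose(out, expected, atol=1e-6)

    def test_gradient_reaches_every_pixel(self, rng):
        pem = PEM(4, rng)
        r2 = np.random.default_rng(2)
        x = Tensor(r2.standard_normal((1, 4, 3, 3)).astype(np.float32),
                   requires_grad=True)
        weights = r2.standard_normal((1, 4, 3, 3)).astype(np.float32)
        (pem(x) * Tensor(weights)).sum().backward()
        assert np.all(np.abs(x.grad).sum(axis=1) > 0)


class TestHMSPE:
    def test_output_shape(self, rng):
        blk = HMSPE(16, rng)
        x = t(np.random.default_rng(0).standard_normal((2, 16, 8, 8)))
        assert blk(x).shape == (2, 16, 8, 8)

    def test_channel_split_must_divide(self, rng):
        with pytest.raises(AssertionError):
            HMSPE(6, rng)

    def test_zero_weights_reduce_to_identity(self, rng):
        blk = HMSPE(8, rng)
        for name, p in blk.named_parameters():
            if "norm" not in name:
                p.data[:] = 0
        x = t(np.random.default_rng(1).standard_normal((1, 8, 6, 6)))
        with no_grad():
            np.testing.assert_allclose(blk(x).numpy(), x.numpy(), atol=1e-6)

    def test_parameter_count_closed_form(self, rng):
        C = 64
        q = C // 4
        conv5 = 25 * q * 2 * q + 2 * q + 2 * q * q + q      # expand+compress
        conv3 = 9 * q * 2 * q + 2 * q + 2 * q * q + q
        pem = 2 * ((2 * q) ** 2 + 2 * q) + 2 * (2 * q)      # convs + LN
        expected = (C * C + C) + conv5 + 6 * conv3 + 4 * pem
        assert HMSPE(C, rng).num_parameters() == expected


class TestFusionAndDownsampling:
    def test_hmspe_up_aligns_channels(self, rng):
        up = HMSPEUp(16, 32, rng)
        x = t(np.random.default_rng(0).standard_normal((1, 16, 6, 6)))
        assert up(x).shape == (1, 32, 6, 6)

    def test_se_unit_gate_passes_through(self, rng):
        se = SqueezeExcite(8, rng)
        se.fc2.weight.data[:] = 0
        se.fc2.bias.data[:] = 50.0
        x = t(np.random.default_rng(1).standard_normal((1, 8, 4, 4)))
        with no_grad():
            np.testing.assert_allclose(se(x).numpy(), x.numpy(), rtol=1e-5)

    def test_channel_shuffle_is_permutation(self, rng):
        x = t(np.random.default_rng(2).standard_normal((2, 8, 3, 3)))
        out = channel_shuffle(x, 2).numpy()
        np.testing.assert_array_equal(np.sort(out, axis=1),
                                      np.sort(x.numpy(), axis=1))

    def test_cnn_fusion_shapes(self, rng):
        fus = CnnFusion(8, rng)
        y = t(np.random.default_rng(0).standard_normal((2, 8, 6, 6)))
        xt = t(np.random.default_rng(1).standard_normal((2, 6, 6, 8)))
        assert fus(y, xt).shape == (2, 8, 6, 6)

    def test_downsample_halves_and_doubles(self, rng):
        ds = CnnDownsample(8, rng)
        x = t(np.random.default_rng(0).standard_normal((1, 8, 14, 14)))
        assert ds(x).shape == (1, 16, 7, 7)
        pm = PatchMerging(8, rng)
        xt = t(np.random.default_rng(1).standard_normal((1, 14, 14, 8)))
        assert pm(xt).shape == (1, 7, 7, 16)


class TestModelAssembly:
    def test_stage_resolution_pipeline(self):
        # 224 input: stage resolutions 56/28/14/7, dims C*(1,2,4,8)
        assert [224 // 4 // (2 ** s) for s in range(4)] == [56, 28, 14, 7]
        cfg = ModelConfig()
        assert [cfg.embed_dim << s for s in range(4)] == [32, 64, 128, 256]

    def test_config_validation(self):
        with pytest.raises(ValueError):
            ModelConfig(embed_dim=30).validate()
        with pytest.raises(ValueError):
            ModelConfig(heads=(3, 6, 12, 24)).validate()
        with pytest.raises(ValueError):
            ModelConfig(transformer_depths=(1, 2, 6, 2)).validate()

    def test_logits_shape_and_gradient_connectivity(self, micro_model):
        m = micro_model
        rng = np.random.default_rng(0)
        rgb = t(rng.standard_normal((2, 3, 56, 56)))
        eg = t(rng.standard_normal((2, 1, 56, 56)))
        logits = m(rgb, eg)
        assert logits.shape == (2, m.cfg.num_classes)
        loss = cross_entropy(logits, np.array([0, 1]))
        m.zero_grad()
        loss.backward()
        # fusion must not sever either branch
        assert np.abs(m.patch_embed.proj.weight.grad).max() > 0
        assert np.abs(m.stem.proj.weight.grad).max() > 0

    def test_forward_deterministic_in_eval(self, micro_model):
        m = micro_model
        m.eval()
        rng = np.random.default_rng(5)
        rgb = t(rng.standard_normal((1, 3, 56, 56)))
        eg = t(rng.standard_normal((1, 1, 56, 56)))
        with no_grad():
            a = m(rgb, eg).numpy()
            b = m(rgb, eg).numpy()
        np.testing.assert_array_equal(a, b)

    def test_same_seed_same_weights(self):
        cfg = micro_config()
        m1 = build_model(cfg, seed=11)
        m2 = build_model(cfg, seed=11)
        for (n1, p1), (_, p2) in zip(m1.named_parameters(),
                                     m2.named_parameters()):
            np.testing.assert_array_equal(p1.data, p2.data, err_msg=n1)

    def test_desk_profile_counts(self):
        m = build_model(desk_config(), seed=0)
        assert 0 < count_parameters(m) < 5
        assert 0 < count_flops(m) < 1
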