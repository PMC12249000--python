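"""Forward passes of every network stage against explicit-loop oracles."""

import numpy as np
import pytest
from hypothesis import given, settings
from hypothesis import strategies as st

import oracles
from cellsage import ModelConfig, build_model
from cellsage.model import (FeatureMap, channel_attention, dwb_forward,
                            mscfe_forward, spatial_attention)
from cellsage.nn import BatchNorm2d, Conv2d, sigmoid
from conftest import tiny_config

TOL = 1e-5


def rel_err(a, b):
    denom = max(np.abs(b).max(), 1e-12)
    return np.abs(a - b).max() / denom


class TestConv2dAgainstLoops:
    @pytest.mark.parametrize("cin,cout,k,stride,groups", [
        (1, 1, 3, 1, 1), (2, 3, 5, 1, 1), (3, 2, 3, 2, 1),
        (4, 4, 3, 1, 4), (4, 8, 1, 1, 1), (2, 2, 7, 2, 2),
    ])
    def test_matches_loop_oracle(self, cin, cout, k, stride, groups, rng):
        conv = Conv2d(cin, cout, k, stride=stride, groups=groups)
        conv.params["weight"] = rng.standard_normal(
            conv.params["weight"].shape).astype(np.float32)
        conv.params["bias"] = rng.standard_normal(cout).astype(np.float32)
        x = rng.standard_normal((2, cin, 9, 9)).astype(np.float32)
        expected = oracles.conv2d_loops(x, conv.params["weight"],
                                        conv.params["bias"], stride, groups)
        assert rel_err(conv.forward(x), expected) < TOL

    @given(st.integers(1, 3), st.integers(1, 3), st.sampled_from([1, 3, 5]),
           st.integers(1, 2), st.integers(0, 10_000))
    @settings(max_examples=25, deadline=None)
    def test_random_shapes(self, cin, cout, k, stride, seed):
        rng = np.random.default_rng(seed)
        conv = Conv2d(cin, cout, k, stride=stride)
        conv.params["weight"] = rng.standard_normal(
            conv.params["weight"].shape).astype(np.float32)
        x = rng.standard_normal((1, cin, 7, 7)).astype(np.float32)
        expected = oracles.conv2d_loops(x, conv.params["weight"],
                                        np.zeros(cout), stride)
        assert rel_err(conv.forward(x), expected) < TOL


class TestMSCFE:
    def test_channel_and_stride_arithmetic(self):
        cfg = ModelConfig()  # reference: branch 32, stride 2
        model = build_model(cfg, seed=0)
        x = FeatureMap(np.zeros((1, 3, 224, 224), dtype=np.float32), "input_x")
        out = mscfe_forward(x, model)
        assert out.values.shape == (1, 96, 112, 112)
        assert out.role == "f_mscfe"

    def test_zero_input_zero_bias_gives_zero(self, tiny_model):
        x = FeatureMap(np.zeros((1, 3, 16, 16), dtype=np.float32), "input_x")
        out = mscfe_forward(x, tiny_model)  # biases are zero-initialized
        assert np.all(out.values == 0.0)

    def test_all_ones_kernels_equal_window_sums(self):
        """1x8x8 input, branch width 1, stride 1: pure sliding-window sums."""
        cfg = ModelConfig(input_channels=1, input_size=8, mscfe_branch_channels=1,
                          mscfe_stride=1, stage_widths=(4, 8), blocks_per_stage=1,
                          cbam_reduction_ratio=4, dropout_rate=0.0)
        model = build_model(cfg, seed=0)
        for branch in model.mscfe.branches:
            branch.params["weight"] = np.ones_like(branch.params["weight"])
            branch.params["bias"][:] = 0.0
        rng = np.random.default_rng(0)
        x = rng.uniform(0.0, 1.0, (1, 1, 8, 8)).astype(np.float32)  # >= 0: ReLU inert
        out = mscfe_forward(FeatureMap(x, "input_x"), model).values
        for i, k in enumerate(cfg.mscfe_kernels):
            expected = oracles.conv2d_loops(x, np.ones((1, 1, k, k)), np.zeros(1))
            assert rel_err(out[:, i:i + 1], expected) < TOL

    def test_concat_order_follows_kernel_order(self, rng):
        model = build_model(tiny_config(), seed=3)
        x = rng.standard_normal((2, 3, 16, 16)).astype(np.float32)
        out = model.mscfe.forward(x)
        weights = [b.params["weight"] for b in model.mscfe.branches]
        biases = [b.params["bias"] for b in model.mscfe.branches]
        expected = oracles.mscfe_loops(x, weights, biases, stride=2)
        assert rel_err(out, expected) < TOL

    def test_channel_mismatch_raises(self, tiny_model):
        bad = FeatureMap(np.zeros((1, 5, 16, 16), dtype=np.float32), "input_x")
        with pytest.raises(ValueError, match="channel"):
            mscfe_forward(bad, tiny_model)


class TestDWBlock:
    def _fresh_blocks_model(self):
        # never-trained model: batch norm running stats are identity
        return build_model(tiny_config(), seed=5)

    def test_identity_composition(self):
        """Centered-impulse depthwise + identity pointwise = identity."""
        model = build_model(tiny_config(stage_widths=(6,), blocks_per_stage=2,
                                        cbam_reduction_ratio=3), seed=5)
        block = next(b for b in model.blocks if b.dw.stride == 1
                     and b.dw.cin == b.pw.cout)
        c = block.dw.cin
        w = np.zeros_like(block.dw.params["weight"])
        w[:, 0, 1, 1] = 1.0  # centered unit impulse
        block.dw.params["weight"] = w
        block.dw.params["bias"][:] = 0.0
        block.pw.params["weight"] = np.eye(c, dtype=np.float32)[:, :, None, None]
        block.pw.params["bias"][:] = 0.0
        x = np.random.default_rng(0).uniform(0, 1, (1, c, 5, 5)).astype(np.float32)
        out = block.forward(x, train=False)
        assert np.allclose(out, x, atol=1e-5)

    def test_matches_loop_oracle(self, rng):
        model = self._fresh_blocks_model()
        block = model.blocks[0]
        cin, cout = block.dw.cin, block.pw.cout
        block.dw.params["weight"] = rng.standard_normal(
            block.dw.params["weight"].shape).astype(np.float32) * 0.5
        block.dw.params["bias"] = rng.standard_normal(cin).astype(np.float32) * 0.1
        block.pw.params["weight"] = rng.standard_normal(
            block.pw.params["weight"].shape).astype(np.float32) * 0.5
        block.pw.params["bias"] = rng.standard_normal(cout).astype(np.float32) * 0.1
        x = rng.standard_normal((2, cin, 3, 3)).astype(np.float32)
        expected = oracles.dwb_loops(
            x, block.dw.params["weight"], block.dw.params["bias"],
            block.pw.params["weight"], block.pw.params["bias"],
            stride=block.dw.stride)
        assert rel_err(block.forward(x, train=False), expected) < TOL

    def test_output_width_contract(self, tiny_model, rng):
        for spatial in (6, 10):
            x = rng.standard_normal((1, 6, spatial, spatial)).astype(np.float32)
            out = tiny_model.stack.forward(x)
            assert out.shape[1] == tiny_model.config.stage_widths[-1]

    def test_typed_wrapper_checks_channels(self, tiny_model):
        bad = FeatureMap(np.zeros((1, 7, 8, 8), dtype=np.float32), "f_mscfe")
        with pytest.raises(ValueError, match="channel"):
            dwb_forward(bad, tiny_model)


class TestChannelAttention:
    def test_identical_channels_equal_weights(self, tiny_model, rng):
        # symmetry requires a channel-symmetric MLP (constant weights)
        cam = tiny_model.cbam.cam
        cam.fc1.params["weight"][:] = 0.3
        cam.fc1.params["bias"][:] = 0.05
        cam.fc2.params["weight"][:] = -0.2
        cam.fc2.params["bias"][:] = 0.1
        base = rng.standard_normal((1, 1, 4, 4)).astype(np.float32)
        x = np.repeat(base, tiny_model.config.stage_widths[-1], axis=1)
        maps, _ = channel_attention(FeatureMap(x, "f_dwb"), tiny_model)
        assert np.allclose(maps.channel_map, maps.channel_map[:, :1], atol=1e-6)

    def test_zero_mlp_gives_half(self, tiny_model, rng):
        cam = tiny_model.cbam.cam
        for fc in (cam.fc1, cam.fc2):
            fc.params["weight"][:] = 0.0
            fc.params["bias"][:] = 0.0
        x = rng.standard_normal(
            (2, tiny_model.config.stage_widths[-1], 3, 3)).astype(np.float32)
        maps, fprime = channel_attention(FeatureMap(x, "f_dwb"), tiny_model)
        assert np.allclose(maps.channel_map, 0.5, atol=1e-7)
        assert np.allclose(fprime.values, 0.5 * x, atol=1e-6)

    def test_hand_written_two_channel_oracle(self):
        cfg = tiny_config(stage_widths=(4, 2), cbam_reduction_ratio=2)
        model = build_model(cfg, seed=0)
        cam = model.cbam.cam
        w1 = np.array([[0.5, -0.25]], dtype=np.float32)       # 2 -> 1
        b1 = np.array([0.1], dtype=np.float32)
        w2 = np.array([[1.5], [-0.75]], dtype=np.float32)     # 1 -> 2
        b2 = np.array([-0.2, 0.3], dtype=np.float32)
        cam.fc1.params["weight"], cam.fc1.params["bias"] = w1, b1
        cam.fc2.params["weight"], cam.fc2.params["bias"] = w2, b2
        x = np.array([[[[1.0, -2.0], [0.5, 3.0]],
                       [[0.0, 4.0], [-1.0, 2.0]]]], dtype=np.float32)
        att_exp, out_exp = oracles.channel_attention_scalars(x, w1, b1, w2, b2)
        maps, fprime = channel_attention(FeatureMap(x, "f_dwb"), model)
        assert rel_err(maps.channel_map, att_exp) < TOL
        assert rel_err(fprime.values, out_exp) < TOL

    def test_indivisible_reduction_rejected(self):
        with pytest.raises(Exception, match="divide"):
            tiny_config(stage_widths=(8, 10), cbam_reduction_ratio=4)


class TestSpatialAttention:
    def test_constant_input_constant_interior(self, tiny_model):
        c = tiny_model.config.stage_widths[-1]
        x = np.full((1, c, 11, 11), 2.5, dtype=np.float32)
        maps, _ = spatial_attention(FeatureMap(x, "f_prime"), tiny_model)
        interior = maps.spatial_map[0, 3:-3, 3:-3]  # beyond the 7x7 halo
        assert np.allclose(interior, interior.flat[0], atol=1e-6)

    def test_bounded_open_interval_and_shape(self, tiny_model, rng):
        c = tiny_model.config.stage_widths[-1]
        x = (rng.standard_normal((2, c, 5, 9)) * 50).astype(np.float32)
        maps, out = spatial_attention(FeatureMap(x, "f_prime"), tiny_model)
        assert maps.spatial_map.shape == (2, 5, 9)
        assert np.all(maps.spatial_map > 0) and np.all(maps.spatial_map < 1)
        assert out.values.shape == x.shape

    def test_matches_loop_oracle(self, rng):
        model = build_model(tiny_config(stage_widths=(4, 8),
                                        cbam_reduction_ratio=4), seed=9)
        sam = model.cbam.sam
        sam.conv.params["weight"] = rng.standard_normal(
            sam.conv.params["weight"].shape).astype(np.float32)
        sam.conv.params["bias"] = rng.standard_normal(1).astype(np.float32)
        x = rng.standard_normal((1, 3, 9, 9)).astype(np.float32)
        att_exp, out_exp = oracles.spatial_attention_loops(
            x, sam.conv.params["weight"], sam.conv.params["bias"])
        att, out = sam.attend(x)
        assert rel_err(att, att_exp) < TOL
        assert rel_err(out, out_exp) < TOL


class TestAttenuationProperty:
    def test_attention_attenuates_sup_norm(self, tiny_model, rng):
        c = tiny_model.config.stage_widths[-1]
        f_dwb = np.abs(rng.standard_normal((2, c, 6, 6))).astype(np.float32)
        maps_c, f_prime = channel_attention(FeatureMap(f_dwb, "f_dwb"), tiny_model)
        maps_s, f_second = spatial_attention(f_prime, tiny_model)
        assert np.abs(f_prime.values).max() <= np.abs(f_dwb).max() + 1e-7
        assert np.abs(f_second.values).max() <= np.abs(f_prime.values).max() + 1e-7

    @given(st.integers(0, 10_000))
    @settings(max_examples=20, deadline=None)
    def test_channel_attention_bounded(self, seed):
        model = build_model(tiny_config(), seed=1)
        rng = np.random.default_rng(seed)
        x = (rng.standard_normal((1, model.config.stage_widths[-1], 4, 4))
             * rng.uniform(0.1, 100)).astype(np.float32)
        att, _ = model.cbam.cam.attend(x)
        assert np.all(att > 0) and np.all(att < 1)


class TestBatchNorm:
    def test_eval_mode_is_identity_when_fresh(self, rng):
        bn = BatchNorm2d(4)
        x = rng.standard_normal((2, 4, 3, 3)).astype(np.float32)
        assert np.allclose(bn.forward(x, train=False), x, atol=1e-3)

    def test_train_mode_normalizes_batch(self, rng):
        bn = BatchNorm2d(3)
        x = (rng.standard_normal((8, 3, 5, 5)) * 4 + 2).astype(np.float32)
        out = bn.forward(x, train=True)
        assert np.allclose(out.mean(axis=(0, 2, 3)), 0, atol=1e-5)
        assert np.allclose(out.std(axis=(0, 2, 3)), 1, atol=1e-3)
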