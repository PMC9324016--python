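"""Pyramid construction, attention, PPM wiring and the ICN losses."""

import numpy as np
import pytest

from eien.autodiff import Tensor
from eien.illumination import (AttentionModule, ICNConfig, IlluminationCorrectionNet,
                               PyramidPoolingModule, ResidualBlock, attention_weight_map,
                               build_pyramid, correct_illumination, loss_icn_recon,
                               loss_icn_smooth, loss_icn_total)
from eien.imaging import gradient_map

from test_decomposition import loop_mean_l1, loop_smoothness


class TestPyramid:
    def test_level_sizes_from_224(self):
        levels = build_pyramid(np.random.default_rng(0).uniform(0, 1, (224, 224, 1)))
        assert [lv.shape[:2] for lv in levels] == [(224, 224), (112, 112), (56, 56)]

    def test_odd_sizes_floor_halve(self):
        levels = build_pyramid(np.zeros((25, 37, 1)))
        assert [lv.shape[:2] for lv in levels] == [(25, 37), (12, 18), (6, 9)]

    def test_constant_map_stays_constant(self):
        levels = build_pyramid(np.full((16, 16, 1), 0.42))
        for lv in levels:
            np.testing.assert_allclose(lv, 0.42)

    def test_block_maxima(self, rng):
        x = rng.uniform(0, 1, (8, 8, 1))
        _, half, _ = build_pyramid(x)
        for bi in range(4):
            for bj in range(4):
                assert half[bi, bj, 0] == x[2 * bi:2 * bi + 2, 2 * bj:2 * bj + 2].max()


class TestAttention:
    def test_zero_weights_give_half(self, rng):
        net = IlluminationCorrectionNet(seed=0)
        for conv in net.attention.convs:
            conv.weight.data[:] = 0.0
            conv.bias.data[:] = 0.0
        att = attention_weight_map(rng.uniform(0, 1, (8, 8, 1)),
                                   rng.uniform(0, 1, (8, 8, 3)), net)
        np.testing.assert_allclose(att, 0.5, atol=1e-7)

    def test_strictly_inside_unit_interval(self, rng):
        net = IlluminationCorrectionNet(seed=1)
        att = attention_weight_map(rng.uniform(0, 1, (12, 10, 1)),
                                   rng.uniform(0, 1, (12, 10, 3)), net)
        assert att.shape == (12, 10, 1)
        assert 0.0 < att.min() and att.max() < 1.0

    def test_dark_regions_receive_more_attention(self):
        # With positive centre-tap kernels on the [1-I, G, B] stack, large
        # illumination lowers the pre-sigmoid response, so bright halves
        # get smaller weights than dark halves.
        net = IlluminationCorrectionNet(seed=0)
        for conv in net.attention.convs:
            conv.weight.data[:] = 0.0
            conv.weight.data[0, 0, 1, 1] = 1.0  # unit impulse on the 1-I channel
            conv.bias.data[:] = 0.0
        i = np.full((8, 8, 1), 0.9)
        i[:, 4:] = 0.1
        s = np.full((8, 8, 3), 0.5)
        att = attention_weight_map(i, s, net)
        assert att[:, 4:].mean() > att[:, :4].mean()

    def test_shape_mismatch_rejected(self):
        net = IlluminationCorrectionNet(seed=0)
        with pytest.raises(ValueError):
            attention_weight_map(np.zeros((8, 8, 1)), np.zeros((8, 9, 3)), net)


class TestBlocks:
    def test_residual_block_zero_weights_is_identity(self, rng):
        block = ResidualBlock(4, np.random.default_rng(0))
        for conv in (block.conv1, block.conv2):
            conv.weight.data[:] = 0.0
            conv.bias.data[:] = 0.0
        x = rng.normal(size=(1, 4, 6, 6))
        np.testing.assert_array_equal(block(Tensor(x)).data, x)

    def test_residual_block_preserves_channels_and_is_finite(self, rng):
        block = ResidualBlock(8, np.random.default_rng(1))
        out = block(Tensor(rng.normal(size=(2, 8, 7, 9)).astype(np.float32))).data
        assert out.shape == (2, 8, 7, 9)
        assert np.isfinite(out).all()

    def test_ppm_preserves_channels(self, rng):
        ppm = PyramidPoolingModule(8, (1, 2, 3, 6), np.random.default_rng(2))
        out = ppm(Tensor(rng.normal(size=(1, 8, 12, 10)).astype(np.float32))).data
        assert out.shape == (1, 8, 12, 10)

    def test_ppm_zeroed_convs_reduce_to_residual_path(self, rng):
        ppm = PyramidPoolingModule(8, (1, 2, 3, 6), np.random.default_rng(3))
        for conv in ppm.branch_convs + [ppm.project]:
            conv.weight.data[:] = 0.0
            conv.bias.data[:] = 0.0
        x = rng.normal(size=(1, 8, 8, 8))
        np.testing.assert_array_equal(ppm(Tensor(x)).data, x)

    def test_ppm_rejects_too_small_input(self, rng):
        ppm = PyramidPoolingModule(4, (1, 2, 3, 6), np.random.default_rng(4))
        with pytest.raises(ValueError, match="bin"):
            ppm(Tensor(rng.normal(size=(1, 4, 5, 5))))


class TestCorrectIllumination:
    @pytest.mark.parametrize("shape", [(64, 64), (100, 150)])
    def test_output_shape_and_range(self, rng, shape):
        net = IlluminationCorrectionNet(ICNConfig(base_channels=8), seed=0)
        out = correct_illumination(rng.uniform(0, 1, shape + (1,)),
                                   rng.uniform(0, 1, shape + (3,)), net)
        assert out.shape == shape + (1,)
        assert 0.0 <= out.min() and out.max() <= 1.0

    def test_224_size_contract(self, rng):
        net = IlluminationCorrectionNet(ICNConfig(base_channels=4,
                                                  residual_blocks_per_branch=1), seed=0)
        out = correct_illumination(rng.uniform(0, 1, (224, 224, 1)),
                                   rng.uniform(0, 1, (224, 224, 3)), net)
        assert out.shape == (224, 224, 1)

    def test_no_attention_equals_all_ones_attention(self, rng):
        net = IlluminationCorrectionNet(ICNConfig(base_channels=8), seed=5)
        i = rng.uniform(0, 1, (16, 16, 1))
        s = rng.uniform(0, 1, (16, 16, 3))
        without = correct_illumination(i, s, net, use_attention=False)

        original = AttentionModule.__call__
        AttentionModule.__call__ = lambda self, stack: Tensor(
            np.ones((1, 1) + tuple(stack.shape[-2:]), dtype=np.float32))
        try:
            forced_ones = correct_illumination(i, s, net, use_attention=True)
        finally:
            AttentionModule.__call__ = original
        np.testing.assert_array_equal(without, forced_ones)

    def test_attention_changes_the_output(self, rng):
        net = IlluminationCorrectionNet(ICNConfig(base_channels=8), seed=6)
        i = rng.uniform(0, 1, (16, 16, 1))
        s = rng.uniform(0, 1, (16, 16, 3))
        with_att = correct_illumination(i, s, net, use_attention=True)
        without = correct_illumination(i, s, net, use_attention=False)
        assert np.abs(with_att - without).max() > 0.0

    def test_shape_mismatch_rejected(self, rng):
        net = IlluminationCorrectionNet(ICNConfig(base_channels=8), seed=0)
        with pytest.raises(ValueError):
            correct_illumination(np.zeros((16, 16, 1)), np.zeros((16, 18, 3)), net)


class TestICNLosses:
    def test_exact_reconstruction_zero(self, rng):
        r = rng.uniform(0.1, 1, (4, 4, 3))
        i_hat = rng.uniform(0.1, 1, (4, 4, 1))
        assert loss_icn_recon(i_hat, r, r * i_hat) == pytest.approx(0.0)

    def test_scalar_worked_example(self):
        val = loss_icn_recon(0.4 * np.ones((1, 1, 1)), 0.5 * np.ones((1, 1, 3)),
                             0.3 * np.ones((1, 1, 3)))
        assert val == pytest.approx(0.1)

    def test_lipschitz_in_i_hat(self, rng):
        # For R <= 1, |loss(I1) - loss(I2)| <= mean|I1 - I2|.
        r = rng.uniform(0, 1, (6, 6, 3))
        s = rng.uniform(0, 1, (6, 6, 3))
        i1 = rng.uniform(0, 1, (6, 6, 1))
        i2 = rng.uniform(0, 1, (6, 6, 1))
        lhs = abs(loss_icn_recon(i1, r, s) - loss_icn_recon(i2, r, s))
        assert lhs <= np.abs(i1 - i2).mean() + 1e-12

    def test_smooth_constant_zero(self, rng):
        assert loss_icn_smooth(np.full((5, 5, 1), 0.3), rng.uniform(0, 1, (5, 5, 3))) == 0.0

    def test_smooth_step_flat_reflectance(self):
        i = np.zeros((4, 4, 1))
        i[2:, :] = 1.0
        r = np.full((4, 4, 3), 0.5)
        assert loss_icn_smooth(i, r) == pytest.approx(gradient_map(i).mean())

    def test_smooth_colocated_edge_shrinks(self):
        i = np.zeros((4, 4, 1))
        i[2:, :] = 1.0
        edged = np.full((4, 4, 3), 0.2)
        edged[2:, :] = 0.8
        assert loss_icn_smooth(i, edged) < loss_icn_smooth(i, np.full((4, 4, 3), 0.5))

    def test_loop_oracles(self, rng):
        i_hat = rng.uniform(0, 1, (4, 4, 1))
        r = rng.uniform(0, 1, (4, 4, 3))
        s = rng.uniform(0, 1, (4, 4, 3))
        assert loss_icn_recon(i_hat, r, s) == pytest.approx(
            loop_mean_l1(r * i_hat, s), abs=1e-6)
        assert loss_icn_smooth(i_hat, r) == pytest.approx(
            loop_smoothness(i_hat, r), abs=1e-6)

    def test_total(self):
        assert loss_icn_total(0.0, 0.0) == 0.0
        assert loss_icn_total(0.1, 0.2) == pytest.approx(0.12)
        assert loss_icn_total(0.3, 0.4) >= 0.3
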