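"""Decomposition network architecture and loss correctness.

Loss values are cross-checked against deliberately unvectorised
straight-loop reference implementations on small random fixtures.
"""

import numpy as np
import pytest

from eien.autodiff import Tensor
from eien.decomposition import (DecompositionNet, decompose, loss_decom_total,
                                loss_illumination_smoothness,
                                loss_illumination_smoothness_pair,
                                loss_invariable_reflectance, loss_reconstruction,
                                model_storage_megabytes)


# -- straight-loop oracles (no vectorisation) -----------------------------


def loop_mean_l1(a, b):
    total, count = 0.0, 0
    for i in range(a.shape[0]):
        for j in range(a.shape[1]):
            for c in range(a.shape[2]):
                total += abs(a[i, j, c] - b[i, j, c])
                count += 1
    return total / count


def loop_gradient(x):
    h, w = x.shape[:2]
    out = np.zeros_like(x)
    for i in range(h):
        for j in range(w):
            for c in range(x.shape[2]):
                dh = abs(x[i + 1, j, c] - x[i, j, c]) if i + 1 < h else 0.0
                dv = abs(x[i, j + 1, c] - x[i, j, c]) if j + 1 < w else 0.0
                out[i, j, c] = dh + dv
    return out


def loop_smoothness(i_map, r_map, lambda_g=10.0):
    r_bar = np.zeros(r_map.shape[:2] + (1,))
    for y in range(r_map.shape[0]):
        for x in range(r_map.shape[1]):
            r_bar[y, x, 0] = (r_map[y, x, 0] + r_map[y, x, 1] + r_map[y, x, 2]) / 3.0
    gi = loop_gradient(i_map)
    gr = loop_gradient(r_bar)
    total, count = 0.0, 0
    for y in range(i_map.shape[0]):
        for x in range(i_map.shape[1]):
            total += gi[y, x, 0] * np.exp(-lambda_g * gr[y, x, 0])
            count += 1
    return total / count


def loop_reconstruction(r_ab, i_ab, r_n, i_n, s_ab, s_n, lam_cross=0.1):
    total = 0.0
    for r, r_name in ((r_ab, "ab"), (r_n, "n")):
        for i, s, s_name in ((i_ab, s_ab, "ab"), (i_n, s_n, "n")):
            lam = 1.0 if r_name == s_name else lam_cross
            total += lam * loop_mean_l1(r * i, s)
    return total


@pytest.fixture
def fixture_4x4(rng):
    r_ab = rng.uniform(0, 1, (4, 4, 3))
    r_n = rng.uniform(0, 1, (4, 4, 3))
    i_ab = rng.uniform(0, 1, (4, 4, 1))
    i_n = rng.uniform(0, 1, (4, 4, 1))
    s_ab = rng.uniform(0, 1, (4, 4, 3))
    s_n = rng.uniform(0, 1, (4, 4, 3))
    return r_ab, i_ab, r_n, i_n, s_ab, s_n


class TestArchitecture:
    def test_parameter_count_and_storage(self):
        net = DecompositionNet(seed=0)
        assert net.parameter_count() == 207_748
        assert round(model_storage_megabytes(net), 3) == 0.831

    def test_zero_output_layer_gives_sigmoid_midpoint(self, rng):
        net = DecompositionNet(seed=0)
        net.out.weight.data[:] = 0.0
        net.out.bias.data[:] = 0.0
        r, i = decompose(rng.uniform(0, 1, (8, 8, 3)), net)
        np.testing.assert_allclose(r, 0.5, atol=1e-7)
        np.testing.assert_allclose(i, 0.5, atol=1e-7)

    @pytest.mark.parametrize("shape", [(8, 8), (17, 23)])
    def test_output_splits_three_plus_one_in_unit_range(self, rng, shape):
        net = DecompositionNet(seed=1)
        r, i = decompose(rng.uniform(0, 1, shape + (3,)), net)
        assert r.shape == shape + (3,)
        assert i.shape == shape + (1,)
        assert 0.0 <= r.min() and r.max() <= 1.0
        assert 0.0 <= i.min() and i.max() <= 1.0

    def test_distinct_inputs_give_distinct_outputs(self, rng):
        net = DecompositionNet(seed=2)
        r1, _ = decompose(rng.uniform(0, 1, (8, 8, 3)), net)
        r2, _ = decompose(rng.uniform(0, 1, (8, 8, 3)), net)
        assert np.abs(r1 - r2).max() > 0.0

    def test_forward_is_deterministic(self, rng):
        net = DecompositionNet(seed=3)
        s = rng.uniform(0, 1, (8, 8, 3))
        r1, i1 = decompose(s, net)
        r2, i2 = decompose(s, net)
        np.testing.assert_array_equal(r1, r2)
        np.testing.assert_array_equal(i1, i2)

    def test_small_image_rejected(self):
        with pytest.raises(ValueError):
            decompose(np.full((4, 4, 3), 0.5), DecompositionNet(seed=0))


class TestInvariableReflectanceLoss:
    def test_identical_maps_zero(self, rng):
        r = rng.uniform(0, 1, (4, 4, 3))
        assert loss_invariable_reflectance(r, r) == 0.0

    def test_scalar_case(self):
        a = np.full((1, 1, 1), 0.2)
        b = np.full((1, 1, 1), 0.5)
        assert loss_invariable_reflectance(a, b) == pytest.approx(0.3)

    def test_two_pixel_case(self):
        a = np.array([[[0.0], [1.0]]])
        b = np.array([[[1.0], [0.0]]])
        assert loss_invariable_reflectance(a, b) == pytest.approx(1.0)

    def test_symmetry_and_oracle(self, fixture_4x4):
        r_ab, _, r_n, _, _, _ = fixture_4x4
        val = loss_invariable_reflectance(r_ab, r_n)
        assert val == pytest.approx(loss_invariable_reflectance(r_n, r_ab))
        assert val == pytest.approx(loop_mean_l1(r_ab, r_n), abs=1e-6)

    def test_shape_mismatch(self):
        with pytest.raises(ValueError):
            loss_invariable_reflectance(np.ones((2, 2, 3)), np.ones((3, 2, 3)))


class TestIlluminationSmoothnessLoss:
    def test_constant_illumination_zero(self, rng):
        i = np.full((4, 4, 1), 0.7)
        r = rng.uniform(0, 1, (4, 4, 3))
        assert loss_illumination_smoothness(i, r) == 0.0

    def test_step_with_constant_reflectance(self):
        # With flat R the exp weight is 1 and the loss is the mean |grad I|.
        i = np.zeros((4, 4, 1))
        i[:, 2:] = 1.0
        r = np.full((4, 4, 3), 0.5)
        from eien.imaging import gradient_map
        assert loss_illumination_smoothness(i, r) == pytest.approx(gradient_map(i).mean())

    def test_colocated_edge_reduces_loss(self):
        i = np.zeros((4, 4, 1))
        i[:, 2:] = 1.0
        flat = np.full((4, 4, 3), 0.5)
        edged = np.full((4, 4, 3), 0.2)
        edged[:, 2:] = 0.8
        assert (loss_illumination_smoothness(i, edged)
                < loss_illumination_smoothness(i, flat))

    def test_oracle_agreement(self, fixture_4x4):
        r_ab, i_ab = fixture_4x4[0], fixture_4x4[1]
        assert loss_illumination_smoothness(i_ab, r_ab) == pytest.approx(
            loop_smoothness(i_ab, r_ab), abs=1e-6)

    def test_pair_version_sums_members(self, fixture_4x4):
        r_ab, i_ab, r_n, i_n, _, _ = fixture_4x4
        assert loss_illumination_smoothness_pair(i_ab, r_ab, i_n, r_n) == pytest.approx(
            loss_illumination_smoothness(i_ab, r_ab)
            + loss_illumination_smoothness(i_n, r_n))


class TestReconstructionLoss:
    def test_perfect_shared_decomposition_zero(self):
        r = np.full((2, 2, 3), 1.0)
        i_ab = np.full((2, 2, 1), 0.2)
        i_n = np.full((2, 2, 1), 0.8)
        s_ab = r * i_ab
        s_n = r * i_n
        assert loss_reconstruction(r, i_ab, r, i_n, s_ab, s_n) == pytest.approx(0.0)

    def test_four_term_worked_example(self):
        # 1|0.1-0.2| + 0.1|0.4-0.8| + 0.1|0.2-0.2| + 1|0.8-0.8| = 0.14
        one = np.ones((1, 1, 1))
        val = loss_reconstruction(0.5 * np.ones((1, 1, 3)), 0.2 * one,
                                  1.0 * np.ones((1, 1, 3)), 0.8 * one,
                                  0.2 * np.ones((1, 1, 3)), 0.8 * np.ones((1, 1, 3)))
        assert val == pytest.approx(0.14)

    def test_oracle_agreement(self, fixture_4x4):
        assert loss_reconstruction(*fixture_4x4) == pytest.approx(
            loop_reconstruction(*fixture_4x4), abs=1e-6)


class TestTotalLoss:
    def test_zero_components(self):
        assert loss_decom_total(0.0, 0.0, 0.0) == 0.0

    def test_weighted_sum(self):
        assert loss_decom_total(0.14, 0.2, 0.3) == pytest.approx(0.163)

    def test_total_at_least_reconstruction(self, rng):
        recon, smooth, invariable = rng.uniform(0, 1, 3)
        assert loss_decom_total(recon, smooth, invariable) >= recon
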