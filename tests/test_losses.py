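"""Objective functions and metrics against closed forms and independent
oracles (scikit-image SSIM, elementwise NumPy recomputations)."""

import numpy as np
import pytest
from hypothesis import given, settings
from hypothesis import strategies as st
from skimage.metrics import structural_similarity as sk_ssim

from virtualstain.losses import (LossConfig, MaskWeightSchedule,
                                 adversarial_losses, conventional_loss,
                                 mask_loss, mask_weight, metrics, ssim,
                                 total_generator_loss)


class TestAdversarial:
    def test_chance_level_closed_form(self):
        zeros = np.zeros((3, 3))
        loss_d, loss_g = adversarial_losses(zeros, zeros)
        assert loss_d == pytest.approx(-2 * np.log(0.5), rel=1e-6)
        assert loss_g == pytest.approx(-np.log(0.5), rel=1e-6)

    def test_saturated_optimum(self):
        loss_d, _ = adversarial_losses(np.full((2, 2), 40.0), np.full((2, 2), -40.0))
        assert loss_d == pytest.approx(0.0, abs=1e-6)

    def test_matches_elementwise_bce_oracle(self, rng):
        real = rng.standard_normal((4, 4)) * 3
        fake = rng.standard_normal((4, 4)) * 3

        def sig(z):
            return 1 / (1 + np.exp(-z))

        oracle_d = np.mean([-np.log(sig(v)) for v in real.ravel()]) + \
            np.mean([-np.log(1 - sig(v)) for v in fake.ravel()])
        oracle_g = np.mean([-np.log(sig(v)) for v in fake.ravel()])
        loss_d, loss_g = adversarial_losses(real, fake)
        assert loss_d == pytest.approx(oracle_d, rel=1e-5)
        assert loss_g == pytest.approx(oracle_g, rel=1e-5)


class TestSSIM:
    def test_self_similarity_is_one(self, rng):
        x = rng.random((32, 32))
        assert ssim(x, x) == pytest.approx(1.0, abs=1e-6)

    def test_symmetry(self, rng):
        x, y = rng.random((24, 24)), rng.random((24, 24))
        assert ssim(x, y) == pytest.approx(ssim(y, x), rel=1e-6)

    def test_constant_images(self):
        a = np.full((16, 16), 0.5)
        assert ssim(a, a.copy()) == pytest.approx(1.0, abs=1e-6)
        # different constants: zero-variance windows, luminance term only
        from virtualstain.autograd import use_dtype

        b = np.full((16, 16), 0.9)
        cfg = LossConfig(data_range=1.0)
        expected = (2 * 0.5 * 0.9 + cfg.c1) / (0.5**2 + 0.9**2 + cfg.c1)
        with use_dtype(np.float64):
            assert ssim(a, b, cfg) == pytest.approx(expected, rel=1e-6)

    def test_global_window_matches_handrolled_statistics(self):
        """Window = full image ⇒ plain means/variances reproduce the score."""
        x = np.linspace(0, 1, 256).reshape(16, 16)
        y = x**2
        cfg = LossConfig(data_range=1.0, ssim_window=None)
        mx, my = x.mean(), y.mean()
        vx, vy = x.var(), y.var()
        cxy = ((x - mx) * (y - my)).mean()
        expected = ((2 * mx * my + cfg.c1) * (2 * cxy + cfg.c2)) / \
            ((mx**2 + my**2 + cfg.c1) * (vx + vy + cfg.c2))
        assert ssim(x, y, cfg) == pytest.approx(expected, rel=1e-5)

    def test_matches_skimage_oracle(self, rng):
        """Independent implementation check: 11×11 Gaussian window, σ=1.5."""
        x = rng.random((48, 48))
        y = np.clip(x + rng.normal(0, 0.1, x.shape), 0, 1)
        ours = ssim(x, y, LossConfig(data_range=1.0))
        ref = sk_ssim(x, y, data_range=1.0, gaussian_weights=True, sigma=1.5,
                      win_size=11, use_sample_covariance=False)
        assert ours == pytest.approx(ref, abs=2e-3)

    def test_shape_mismatch_rejected(self):
        with pytest.raises(ValueError):
            ssim(np.zeros((4, 4)), np.zeros((5, 5)))


class TestConventionalLoss:
    def test_zero_iff_identical(self, rng):
        x = rng.random((16, 16))
        assert conventional_loss(x, x.copy()) == pytest.approx(0.0, abs=1e-6)
        y = x.copy()
        y[0, 0] += 0.2
        assert conventional_loss(x, y) > 1e-5

    def test_alpha_one_reduces_to_mae(self, rng):
        x, y = rng.random((8, 8)), rng.random((8, 8))
        cfg = LossConfig(alpha=1.0)
        assert conventional_loss(x, y, cfg) == pytest.approx(
            np.abs(x - y).mean(), rel=1e-5)

    def test_combines_l1_and_ssim_oracles(self, rng):
        x, y = rng.random((8, 8)), rng.random((8, 8))
        cfg = LossConfig(alpha=0.5, data_range=1.0)
        expected = 0.5 * np.abs(x - y).mean() + 0.5 * (1 - ssim(x, y, cfg))
        assert conventional_loss(x, y, cfg) == pytest.approx(expected, rel=1e-5)


class TestMaskLoss:
    def test_perfect_prediction_is_zero(self):
        labels = np.array([[0, 1], [2, 1]])
        mask = np.zeros((3, 2, 2))
        for c in range(3):
            mask[c][labels == c] = 1.0
        assert mask_loss(mask, labels) == pytest.approx(0.0, abs=1e-6)

    def test_uniform_mask_gives_ln3(self, rng):
        mask = np.full((3, 4, 4), 1 / 3)
        labels = rng.integers(0, 3, (4, 4))
        assert mask_loss(mask, labels) == pytest.approx(np.log(3), rel=1e-5)

    def test_matches_elementwise_oracle(self, rng):
        logits = rng.standard_normal((3, 4, 4))
        mask = np.exp(logits) / np.exp(logits).sum(axis=0)
        labels = rng.integers(0, 3, (4, 4))
        oracle = np.mean([-np.log(mask[labels[i, j], i, j])
                          for i in range(4) for j in range(4)])
        assert mask_loss(mask, labels) == pytest.approx(oracle, rel=1e-5)

    def test_out_of_range_label_rejected(self):
        with pytest.raises(ValueError):
            mask_loss(np.full((3, 2, 2), 1 / 3), np.array([[0, 3], [1, 2]]))


class TestMaskWeightSchedule:
    def test_initial_weight(self):
        assert mask_weight(0) == 250.0

    def test_first_decay_boundary(self):
        assert mask_weight(1499) == 250.0
        assert mask_weight(1500) == pytest.approx(225.0)

    def test_floor(self):
        assert mask_weight(10**6) == 2.5

    @settings(max_examples=60, derandomize=True)
    @given(st.integers(0, 10**6), st.integers(0, 10**6))
    def test_non_increasing_and_floored(self, e1, e2):
        lo, hi = sorted((e1, e2))
        assert mask_weight(hi) <= mask_weight(lo)
        assert mask_weight(hi) >= 2.5

    def test_invalid_schedules_rejected(self):
        with pytest.raises(ValueError):
            MaskWeightSchedule(initial=1.0, floor=2.5)
        with pytest.raises(ValueError):
            MaskWeightSchedule(decay=1.5)


class TestTotalLoss:
    def test_zero_components(self):
        assert total_generator_loss(0.0, 0.0, 0.0, 0) == 0.0

    def test_default_weights_at_epoch_zero(self):
        assert total_generator_loss(1.0, 1.0, 1.0, 0) == pytest.approx(351.0)

    def test_mask_weight_after_two_decays(self):
        # at epoch 3000 the mask term contributes 250·0.9² = 202.5 per unit
        assert total_generator_loss(0.0, 0.0, 1.0, 3000) == pytest.approx(202.5)

    def test_linear_in_each_component(self):
        base = total_generator_loss(1.0, 2.0, 3.0, 0)
        assert total_generator_loss(2.0, 2.0, 3.0, 0) - base == pytest.approx(1.0)
        assert total_generator_loss(1.0, 3.0, 3.0, 0) - base == pytest.approx(100.0)
        assert total_generator_loss(1.0, 2.0, 4.0, 0) - base == pytest.approx(250.0)


class TestMetrics:
    def test_identity(self, rng):
        x = rng.random((16, 16))
        m = metrics(x, x.copy())
        assert m["mae"] == 0.0
        assert m["ssim"] == pytest.approx(1.0, abs=1e-6)
        assert np.isinf(m["psnr"])

    def test_constant_offset_closed_forms(self, rng):
        x = rng.random((32, 32))
        m = metrics(x + 0.1, x, data_range=1.0)
        assert m["mae"] == pytest.approx(0.1, rel=1e-6)
        assert m["psnr"] == pytest.approx(20.0, rel=1e-6)

    def test_matches_scalar_oracles(self, rng):
        p, t = rng.random((8, 8)), rng.random((8, 8))
        m = metrics(p, t)
        assert m["mae"] == pytest.approx(np.abs(p - t).mean(), rel=1e-6)
        mse = ((p - t) ** 2).mean()
        assert m["psnr"] == pytest.approx(10 * np.log10(1 / mse), rel=1e-6)

    def test_mae_symmetry(self, rng):
        p, t = rng.random((8, 8)), rng.random((8, 8))
        assert metrics(p, t)["mae"] == pytest.approx(metrics(t, p)["mae"])
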