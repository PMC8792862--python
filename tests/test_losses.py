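"""Loss formulas against closed forms and a per-pixel double-loop oracle."""

import math

import numpy as np
import pytest

from ushapegan import losses
from ushapegan.losses import (BACKGROUND, FAKE, LUNG, discriminator_loss,
                              fake_loss, generator_loss, original_gan_loss,
                              supervised_loss, unsupervised_real_loss)

from conftest import random_prob_maps

EPS = losses.SAFE_LOG_EPS


def oracle_losses(probs, masks):
    """Independent double-loop implementation of all pixel losses."""
    n, _, h, w = probs.shape
    L_l = L_u = L_g = L_G = 0.0
    for i in range(n):
        for r in range(h):
            for c in range(w):
                p_lung, p_back, p_fake = probs[i, :, r, c]
                correct = p_lung if masks[i, r, c] == 1 else p_back
                L_l += -math.log(max(correct, EPS))
                L_u += -math.log(max(1.0 - p_fake, EPS))
                L_g += -math.log(max(p_fake, EPS))
                L_G += math.log(max(p_fake, EPS))
    npx = n * h * w
    return L_l / npx, L_u / npx, L_g / npx, L_G / npx


def uniform_maps(n=2, h=4, w=4):
    return np.full((n, 3, h, w), 1.0 / 3.0)


class TestClosedForms:
    def test_uniform_probabilities(self):
        probs = uniform_maps()
        masks = np.zeros((2, 4, 4), dtype=int)
        masks[0, :2] = 1
        assert supervised_loss(probs, masks) == pytest.approx(math.log(3), abs=1e-12)
        assert unsupervised_real_loss(probs) == pytest.approx(-math.log(2 / 3), abs=1e-12)
        assert fake_loss(probs) == pytest.approx(math.log(3), abs=1e-12)
        assert generator_loss(probs) == pytest.approx(-math.log(3), abs=1e-12)

    def test_perfect_predictions_give_zero(self):
        n, h, w = 2, 4, 4
        masks = np.zeros((n, h, w), dtype=int)
        masks[:, :2] = 1
        probs = np.zeros((n, 3, h, w))
        probs[:, LUNG][masks == 1] = 1.0
        probs[:, BACKGROUND][masks == 0] = 1.0
        assert supervised_loss(probs, masks) == pytest.approx(0.0, abs=1e-12)
        assert unsupervised_real_loss(probs) == pytest.approx(0.0, abs=1e-12)
        all_fake = np.zeros((n, 3, h, w))
        all_fake[:, FAKE] = 1.0
        assert fake_loss(all_fake) == pytest.approx(0.0, abs=1e-12)

    def test_original_gan_loss(self):
        assert original_gan_loss(np.array([1.0, 0.0]),
                                 np.array([1, 0])) == pytest.approx(0.0, abs=1e-6)
        assert original_gan_loss(np.full(4, 0.5),
                                 np.array([1, 0, 1, 0])) == pytest.approx(
            math.log(2), abs=1e-12)


class TestOracleEquivalence:
    def test_matches_double_loop_on_random_batches(self, rng):
        for trial in range(100):
            probs = random_prob_maps(rng, n=3, h=8, w=8)
            masks = rng.integers(0, 2, size=(3, 8, 8))
            o_l, o_u, o_g, o_G = oracle_losses(probs, masks)
            assert supervised_loss(probs, masks) == pytest.approx(o_l, abs=1e-6)
            assert unsupervised_real_loss(probs) == pytest.approx(o_u, abs=1e-6)
            assert fake_loss(probs) == pytest.approx(o_g, abs=1e-6)
            assert generator_loss(probs) == pytest.approx(o_G, abs=1e-6)

    def test_decomposition_and_bundle(self, rng):
        probs_a = random_prob_maps(rng)
        probs_u = random_prob_maps(rng)
        probs_g = random_prob_maps(rng)
        masks = rng.integers(0, 2, size=(3, 8, 8))
        bundle = discriminator_loss((probs_a, masks), probs_u, probs_g)
        assert bundle.L_D == pytest.approx(bundle.L_l + bundle.L_u + bundle.L_g,
                                           rel=1e-6)
        assert bundle.L_l == pytest.approx(supervised_loss(probs_a, masks), abs=1e-12)
        assert bundle.L_u == pytest.approx(unsupervised_real_loss(probs_u), abs=1e-12)
        assert bundle.L_g == pytest.approx(fake_loss(probs_g), abs=1e-12)
        assert all(v >= 0 for v in (bundle.L_l, bundle.L_u, bundle.L_g))

    def test_generator_loss_is_negated_fake_loss(self, rng):
        probs = random_prob_maps(rng)
        assert generator_loss(probs) == pytest.approx(-fake_loss(probs), abs=1e-12)


class TestModesAndValidation:
    def test_supervised_only_bundle(self, rng):
        probs = random_prob_maps(rng)
        masks = rng.integers(0, 2, size=(3, 8, 8))
        bundle = discriminator_loss(annotated=(probs, masks))
        assert bundle.L_D == pytest.approx(bundle.L_l, abs=1e-12)
        assert bundle.L_u == 0.0 and bundle.L_g == 0.0

    def test_all_empty_rejected(self):
        with pytest.raises(ValueError):
            discriminator_loss()

    def test_shape_mismatch_rejected(self, rng):
        probs = random_prob_maps(rng)
        with pytest.raises(ValueError):
            supervised_loss(probs, np.zeros((3, 4, 4), dtype=int))

    def test_nonbinary_mask_rejected(self, rng):
        probs = random_prob_maps(rng)
        with pytest.raises(ValueError):
            supervised_loss(probs, np.full((3, 8, 8), 2))


class TestStability:
    def test_one_hot_maps_stay_finite(self):
        n, h, w = 2, 4, 4
        for hot in (LUNG, BACKGROUND, FAKE):
            probs = np.zeros((n, 3, h, w))
            probs[:, hot] = 1.0
            masks = np.zeros((n, h, w), dtype=int)
            vals = [supervised_loss(probs, masks), unsupervised_real_loss(probs),
                    fake_loss(probs), generator_loss(probs)]
            assert np.isfinite(vals).all()

    def test_gradient_step_reduces_fake_probability(self, rng):
        """One small generator-style step on L_G lowers mean P(fake)."""
        logits = rng.normal(size=(2, 3, 6, 6))

        def softmax(z):
            e = np.exp(z - z.max(axis=1, keepdims=True))
            return e / e.sum(axis=1, keepdims=True)

        probs = softmax(logits)
        before = probs[:, FAKE].mean()
        _, dprobs = generator_loss(probs, return_grad=True)
        dlogits = probs * (dprobs - (dprobs * probs).sum(axis=1, keepdims=True))
        probs2 = softmax(logits - 1e-3 * dlogits / np.abs(dlogits).max())
        assert probs2[:, FAKE].mean() < before

    def test_supervised_minimum_recovers_class_frequencies(self):
        """On a 2-pixel problem with one lung and one background pixel, the
        constant prediction minimizing L_l is the empirical frequency 1/2."""
        masks = np.array([[[1, 0]]])

        def L(p_lung):
            probs = np.zeros((1, 3, 1, 2))
            probs[:, LUNG] = p_lung
            probs[:, BACKGROUND] = 1.0 - p_lung
            return supervised_loss(probs, masks)

        grid = np.linspace(0.01, 0.99, 197)
        vals = [L(p) for p in grid]
        assert grid[int(np.argmin(vals))] == pytest.approx(0.5, abs=0.006)
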