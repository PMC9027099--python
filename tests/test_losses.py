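"""Tri-axial slicing, perceptual loss, adversarial and combined losses."""

import math

import numpy as np
import pytest

from thinsr.losses import (
    LossBundle,
    RandomConvFeatureExtractor,
    adversarial_losses,
    extract_triaxial_slices,
    perceptual_batch_with_grad,
    perceptual_loss_3d,
    perceptual_loss_3d_with_grad,
    total_generator_loss,
)


@pytest.fixture(scope="module")
def extractor():
    return RandomConvFeatureExtractor(seed=0)


class TestTriaxialSlices:
    def test_slice_count_is_three_n(self, rng):
        patch = rng.uniform(size=(32, 32, 32))
        assert extract_triaxial_slices(patch).shape == (96, 32, 32)
        assert extract_triaxial_slices(rng.uniform(size=(8, 8, 8))).shape == (24, 8, 8)

    def test_unit_patch_gives_three_identical_slices(self):
        patch = np.full((1, 1, 1), 5.0)
        stack = extract_triaxial_slices(patch)
        assert stack.shape == (3, 1, 1)
        assert np.all(stack == 5.0)

    def test_slice_ordering_axial_sagittal_coronal(self, rng):
        patch = rng.uniform(size=(4, 4, 4))
        stack = extract_triaxial_slices(patch)
        assert np.array_equal(stack[1], patch[:, :, 1])  # axial, z ascending
        assert np.array_equal(stack[4 + 2], patch[2, :, :])  # sagittal, x ascending
        assert np.array_equal(stack[8 + 3], patch[:, 3, :])  # coronal, y ascending

    def test_transposition_symmetry(self, rng):
        # a patch invariant under x<->z swap has equal axial/sagittal slice
        # sets after in-plane transposition
        base = rng.uniform(size=(6, 6, 6))
        patch = base + base.transpose(2, 1, 0)
        stack = extract_triaxial_slices(patch)
        axial, sagittal = stack[:6], stack[6:12]
        assert np.allclose(np.transpose(sagittal, (0, 2, 1)), axial)

    def test_non_cubic_rejected(self, rng):
        with pytest.raises(ValueError):
            extract_triaxial_slices(rng.uniform(size=(4, 4, 5)))

    def test_extractor_normalization_applied(self, rng, extractor):
        patch = rng.uniform(0, 10000, size=(4, 4, 4))
        out = extract_triaxial_slices(patch, extractor)
        assert out.shape == (12, 3, 4, 4)
        assert out.max() <= 1.0 and out.min() >= 0.0
        assert np.array_equal(out[:, 0], out[:, 1])


class TestPerceptualLoss:
    def test_zero_for_identical_inputs(self, rng, extractor):
        patch = rng.uniform(0, 10000, size=(8, 8, 8))
        assert perceptual_loss_3d(patch, patch.copy(), extractor) == 0.0

    def test_symmetric(self, rng, extractor):
        a = rng.uniform(0, 10000, size=(8, 8, 8))
        b = rng.uniform(0, 10000, size=(8, 8, 8))
        assert perceptual_loss_3d(a, b, extractor) == pytest.approx(
            perceptual_loss_3d(b, a, extractor), rel=1e-9
        )

    def test_positive_and_deterministic_on_distinct_patches(self, rng, extractor):
        a = rng.uniform(0, 10000, size=(8, 8, 8))
        b = rng.uniform(0, 10000, size=(8, 8, 8))
        l1 = perceptual_loss_3d(a, b, extractor)
        l2 = perceptual_loss_3d(a, b, RandomConvFeatureExtractor(seed=0))
        assert l1 > 0
        assert l1 == pytest.approx(l2, rel=1e-12)

    def test_batched_equals_per_slice_loop(self, rng, extractor):
        a = rng.uniform(0, 10000, size=(8, 8, 8))
        b = rng.uniform(0, 10000, size=(8, 8, 8))
        batched = perceptual_loss_3d(a, b, extractor)
        # oracle: push each slice through the extractor separately
        sa = extract_triaxial_slices(a, extractor)
        sb = extract_triaxial_slices(b, extractor)
        per_slice = []
        for i in range(sa.shape[0]):
            fa = extractor.apply(sa[i : i + 1])
            fb = extractor.apply(sb[i : i + 1])
            per_slice.append(np.mean((fa.astype(np.float64) - fb) ** 2))
        assert batched == pytest.approx(float(np.mean(per_slice)), rel=1e-5)

    def test_gradient_matches_finite_differences(self, rng):
        extractor = RandomConvFeatureExtractor(seed=3)
        a = rng.uniform(0, 10000, size=(6, 6, 6))
        b = rng.uniform(0, 10000, size=(6, 6, 6))
        loss, grad = perceptual_loss_3d_with_grad(a, b, extractor)
        eps = 1.0
        for idx in [(0, 0, 0), (3, 2, 1), (5, 5, 5)]:
            ap = a.copy()
            ap[idx] += eps
            am = a.copy()
            am[idx] -= eps
            num = (
                perceptual_loss_3d(ap, b, extractor)
                - perceptual_loss_3d(am, b, extractor)
            ) / (2 * eps)
            assert grad[idx] == pytest.approx(num, rel=1e-2, abs=1e-12)

    def test_batch_version_matches_single(self, rng, extractor):
        a = rng.uniform(0, 10000, size=(3, 6, 6, 6))
        b = rng.uniform(0, 10000, size=(3, 6, 6, 6))
        loss_b, grad_b = perceptual_batch_with_grad(a, b, extractor)
        singles = [perceptual_loss_3d_with_grad(a[i], b[i], extractor) for i in range(3)]
        assert loss_b == pytest.approx(np.mean([s[0] for s in singles]), rel=1e-6)
        for i in range(3):
            assert np.allclose(grad_b[i], singles[i][1] / 3.0, rtol=1e-4, atol=1e-12)

    def test_finite_on_many_random_pairs(self, rng, extractor):
        for _ in range(25):
            a = rng.uniform(0, 10000, size=(4, 4, 4))
            b = rng.uniform(0, 10000, size=(4, 4, 4))
            assert math.isfinite(perceptual_loss_3d(a, b, extractor))


class TestAdversarialLosses:
    def test_coin_flip_discriminator_analytic_values(self):
        half = np.full(8, 0.5)
        g_loss, d_loss = adversarial_losses(half, half)
        assert d_loss == pytest.approx(2 * math.log(2), abs=1e-9)
        assert g_loss == pytest.approx(math.log(2), abs=1e-9)

    def test_perfect_discriminator_limit(self):
        g_loss, d_loss = adversarial_losses(np.full(4, 1.0 - 1e-9), np.full(4, 1e-9))
        assert d_loss == pytest.approx(0.0, abs=1e-5)

    def test_generator_loss_decreasing_in_fake_scores(self):
        losses = [
            adversarial_losses(np.array([0.5]), np.array([f]))[0]
            for f in (0.1, 0.3, 0.5, 0.7, 0.9)
        ]
        assert all(a > b for a, b in zip(losses, losses[1:]))

    def test_out_of_range_scores_rejected(self):
        with pytest.raises(ValueError):
            adversarial_losses(np.array([1.2]), np.array([0.5]))
        with pytest.raises(ValueError):
            adversarial_losses(np.array([0.5]), np.array([-0.1]))


class TestTotalGeneratorLoss:
    def test_unit_terms_with_default_weights(self):
        bundle = total_generator_loss(1.0, 1.0, 1.0)
        assert bundle.l_total == pytest.approx(1.011, abs=1e-12)

    def test_mse_only(self):
        assert total_generator_loss(0, 0, 7.0).l_total == pytest.approx(0.007)

    def test_zero_weights_leave_perceptual_term(self):
        assert total_generator_loss(3.25, 9, 9, 0.0, 0.0).l_total == 3.25

    def test_negative_weights_rejected(self):
        with pytest.raises(ValueError):
            total_generator_loss(1, 1, 1, lambda_w=-0.1)

    def test_bundle_invariant(self):
        b = LossBundle(l_mse=2.0, l_per=1.0, l_gan=3.0, lambda_w=0.01, mu_w=0.001)
        assert b.l_total == pytest.approx(1.0 + 0.01 * 3.0 + 0.001 * 2.0)
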