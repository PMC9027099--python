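"""Loss functions: voxelwise MSE, tri-axial 3D perceptual loss, GAN losses.

A 2D feature extractor cannot see a volume, so the perceptual distance is
computed *tri-axially*: every axial, sagittal and coronal plane of both
volumes is pushed through the extractor and the squared feature differences
are averaged over all 3n slice pairs (for an n^3 patch).  This resolves the
volume perceptually along the three principal directions while reusing a
plain 2D embedding.

The feature extractor sits behind a small contract (:class:`FeatureExtractor`)
so any deterministic 2D embedding can be plugged in.  The package default,
:class:`RandomConvFeatureExtractor`, is a fixed-seed, untrained two-layer
convolutional embedding: random deep features define a perfectly valid
perceptual metric (zero iff feature maps agree, symmetric, deterministic)
and require no external weights.

The adversarial objective is the vanilla GAN: a sigmoid discriminator with
log losses.  The generator side uses the non-saturating form -log D(G(y)),
which has the same fixed points as the min-max form but healthier gradients
early in training.
"""

from __future__ import annotations

from dataclasses import dataclass
from typing import List, Optional, Tuple

import numpy as np

from .nn import Conv, relu, relu_grad

__all__ = [
    "FeatureExtractor",
    "RandomConvFeatureExtractor",
    "LossBundle",
    "extract_triaxial_slices",
    "perceptual_loss_3d",
    "perceptual_loss_3d_with_grad",
    "adversarial_losses",
    "total_generator_loss",
    "DEFAULT_LAMBDA",
    "DEFAULT_MU",
]

DEFAULT_LAMBDA = 0.01  # weight of the adversarial term
DEFAULT_MU = 0.001  # weight of the pixel-wise MSE term
_EPS = 1e-7  # internal clamp for log arguments

#: intensity ceiling assumed by the extractor normalization
_STANDARD_CEILING = 10000.0


class FeatureExtractor:
    """Contract for deterministic 2D feature embeddings.

    ``apply`` maps a batch of three-channel images (B, 3, h, w) to feature
    maps (B, c, h', w'); ``normalize`` maps raw standardized-intensity
    slices onto the input range the embedding expects.  ``apply_backward``
    propagates a feature-space gradient back to the (normalized) input and
    is required only for training.
    """

    layer_tag: str = "abstract"
    min_input: int = 1

    def normalize(self, slices: np.ndarray) -> np.ndarray:
        raise NotImplementedError

    def apply(self, images: np.ndarray) -> np.ndarray:
        raise NotImplementedError

    def apply_backward(self, gfeat: np.ndarray) -> np.ndarray:
        raise NotImplementedError


class RandomConvFeatureExtractor(FeatureExtractor):
    """Untrained convolutional embedding with frozen, seeded weights.

    Two 3x3 convolution + ReLU stages (the second strided) computed before
    the final activation, loosely mirroring the shape of deep pre-activation
    feature stacks.  Weights are drawn once from a seeded generator and
    never updated, so the embedding is deterministic and identical across
    processes.
    """

    def __init__(self, seed: int = 0, channels: int = 8):
        rng = np.random.default_rng(seed)
        self.layer_tag = f"random-conv-2L (seed {seed})"
        self.min_input = 4
        self.conv1 = Conv(3, channels, 3, ndim=2, padding=1, rng=rng)
        self.conv2 = Conv(channels, 2 * channels, 3, ndim=2, stride=2, padding=1, rng=rng)
        self._a1: Optional[np.ndarray] = None

    def normalize(self, slices: np.ndarray) -> np.ndarray:
        """(B, h, w) standardized intensities -> (B, 3, h, w) in [0, 1]."""
        x = np.asarray(slices, dtype=np.float32) / _STANDARD_CEILING
        return np.repeat(x[:, None], 3, axis=1)

    def apply(self, images: np.ndarray) -> np.ndarray:
        if images.ndim != 4 or images.shape[1] != 3:
            raise ValueError(f"expected (B, 3, h, w), got {images.shape}")
        if min(images.shape[2:]) < self.min_input:
            raise ValueError(
                f"slices must be at least {self.min_input} px for this extractor"
            )
        a1 = self.conv1.forward(images.astype(np.float32))
        self._a1 = a1
        # pre-activation features of the second stage
        return self.conv2.forward(relu(a1))

    def apply_backward(self, gfeat: np.ndarray) -> np.ndarray:
        assert self._a1 is not None, "apply_backward before apply"
        g = self.conv2.backward(gfeat.astype(np.float32))
        return self.conv1.backward(relu_grad(self._a1, g))


def extract_triaxial_slices(
    patch: np.ndarray, extractor: Optional[FeatureExtractor] = None
) -> np.ndarray:
    """All axial, sagittal and coronal planes of a cubic patch.

    Returns the 3n slices of an n^3 patch as one (3n, n, n) stack, ordered
    axial (z ascending), then sagittal (x ascending), then coronal
    (y ascending).  If an extractor is given, each slice is replicated to
    three channels and passed through the extractor's normalization,
    yielding (3n, 3, n, n).
    """
    patch = np.asarray(patch)
    if patch.ndim != 3 or len(set(patch.shape)) != 1:
        raise ValueError(f"expected a cubic patch, got shape {patch.shape}")
    axial = np.moveaxis(patch, 2, 0)  # (z, x, y)
    sagittal = patch  # (x, y, z) indexed by x
    coronal = np.moveaxis(patch, 1, 0)  # (y, x, z)
    stack = np.concatenate([axial, sagittal, coronal], axis=0)
    if extractor is None:
        return stack
    return extractor.normalize(stack)


def _slice_batches(
    pred: np.ndarray, truth: np.ndarray, extractor: FeatureExtractor
) -> Tuple[np.ndarray, np.ndarray]:
    if pred.shape != truth.shape:
        raise ValueError(f"shape mismatch: {pred.shape} vs {truth.shape}")
    return (
        extract_triaxial_slices(pred, extractor),
        extract_triaxial_slices(truth, extractor),
    )


def perceptual_loss_3d(
    pred: np.ndarray, truth: np.ndarray, extractor: FeatureExtractor
) -> float:
    """Tri-axial perceptual distance between two cubic volumes.

    Mean over the 3n slice pairs of the per-slice squared feature
    difference averaged over height x width x channels; zero iff the
    feature maps agree, in particular for identical volumes.
    """
    ps, ts = _slice_batches(pred, truth, extractor)
    fp = extractor.apply(ps)
    ft = extractor.apply(ts)
    diff = fp.astype(np.float64) - ft.astype(np.float64)
    return float(np.mean(diff**2))


def perceptual_loss_3d_with_grad(
    pred: np.ndarray, truth: np.ndarray, extractor: FeatureExtractor
) -> Tuple[float, np.ndarray]:
    """Perceptual loss and its gradient with respect to ``pred``.

    Each voxel belongs to exactly one axial, one sagittal and one coronal
    slice, so slice-space gradients are scattered back and added.
    """
    n = pred.shape[0]
    ps, ts = _slice_batches(pred, truth, extractor)
    ft = extractor.apply(ts)
    fp = extractor.apply(ps)  # extractor caches this forward
    diff = fp - ft
    loss = float(np.mean(diff.astype(np.float64) ** 2))
    gfeat = (2.0 / diff.size) * diff
    gslices = extractor.apply_backward(gfeat)  # (3n, 3, n, n)
    # undo channel replication and intensity normalization
    gs = gslices.sum(axis=1) / _STANDARD_CEILING
    gpred = np.zeros_like(pred, dtype=np.float64)
    gpred += np.moveaxis(gs[:n], 0, 2)  # axial
    gpred += gs[n : 2 * n]  # sagittal
    gpred += np.moveaxis(gs[2 * n :], 0, 1)  # coronal
    return loss, gpred


def perceptual_batch_with_grad(
    pred_b: np.ndarray, truth_b: np.ndarray, extractor: FeatureExtractor
) -> Tuple[float, np.ndarray]:
    """Batch version of :func:`perceptual_loss_3d_with_grad`.

    ``pred_b``/``truth_b`` are (B, n, n, n) stacks of cubic patches.  All
    B*3n slices go through the extractor in one pass (much better BLAS
    utilization during training); the returned loss is the mean of the
    per-patch losses and the gradient has the batch's shape.
    """
    if pred_b.shape != truth_b.shape:
        raise ValueError(f"shape mismatch: {pred_b.shape} vs {truth_b.shape}")
    b, n = pred_b.shape[0], pred_b.shape[1]
    ps = np.concatenate(
        [extract_triaxial_slices(p, extractor) for p in pred_b]
    )
    ts = np.concatenate(
        [extract_triaxial_slices(t, extractor) for t in truth_b]
    )
    ft = extractor.apply(ts)
    fp = extractor.apply(ps)  # cached for the backward pass
    diff = fp - ft
    loss = float(np.mean(diff.astype(np.float64) ** 2))
    gslices = extractor.apply_backward((2.0 / diff.size) * diff)
    gs = gslices.sum(axis=1) / _STANDARD_CEILING
    gpred = np.zeros_like(pred_b, dtype=np.float64)
    for i in range(b):
        block = gs[i * 3 * n : (i + 1) * 3 * n]
        gpred[i] += np.moveaxis(block[:n], 0, 2)
        gpred[i] += block[n : 2 * n]
        gpred[i] += np.moveaxis(block[2 * n :], 0, 1)
    return loss, gpred


def adversarial_losses(
    d_real: np.ndarray, d_fake: np.ndarray
) -> Tuple[float, float]:
    """Vanilla-GAN losses from discriminator scores.

    ``d_loss = -mean log D(x) - mean log(1 - D(G(y)))`` and the
    non-saturating generator loss ``g_loss = -mean log D(G(y))``.  Scores
    must lie in (0, 1); they are clamped at 1e-7 from the boundaries before
    taking logs.
    """
    d_real = np.asarray(d_real, dtype=np.float64).ravel()
    d_fake = np.asarray(d_fake, dtype=np.float64).ravel()
    for name, arr in (("d_real", d_real), ("d_fake", d_fake)):
        if np.any(arr < 0) or np.any(arr > 1):
            raise ValueError(f"{name} scores must lie in (0, 1)")
    dr = np.clip(d_real, _EPS, 1 - _EPS)
    df = np.clip(d_fake, _EPS, 1 - _EPS)
    d_loss = float(-np.mean(np.log(dr)) - np.mean(np.log(1 - df)))
    g_loss = float(-np.mean(np.log(df)))
    return g_loss, d_loss


@dataclass(frozen=True)
class LossBundle:
    """The generator's loss terms and their combination.

    ``l_total = l_per + lambda_w * l_gan + mu_w * l_mse`` with default
    weights lambda_w = 0.01 and mu_w = 0.001 balancing the adversarial and
    pixel-wise terms against the perceptual term.
    """

    l_mse: float
    l_per: float
    l_gan: float
    lambda_w: float = DEFAULT_LAMBDA
    mu_w: float = DEFAULT_MU

    @property
    def l_total(self) -> float:
        return self.l_per + self.lambda_w * self.l_gan + self.mu_w * self.l_mse


def total_generator_loss(
    l_per: float,
    l_gan: float,
    l_mse: float,
    lambda_w: float = DEFAULT_LAMBDA,
    mu_w: float = DEFAULT_MU,
) -> LossBundle:
    """Combine the generator's three loss terms with their weights."""
    if lambda_w < 0 or mu_w < 0:
        raise ValueError("loss weights must be non-negative")
    return LossBundle(
        l_mse=float(l_mse),
        l_per=float(l_per),
        l_gan=float(l_gan),
        lambda_w=float(lambda_w),
        mu_w=float(mu_w),
    )
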