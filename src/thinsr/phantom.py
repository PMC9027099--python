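"""Procedural 3D phantoms: self-contained HR ground truth for the pipeline.

Real training data for this task are near-isotropic clinical volumes,
which cannot ship with a package.  The phantoms combine the three kinds of
content that make super-resolution measurably different from interpolation:

* a smooth low-order polynomial background (easy for any interpolator,
  anchors the intensity scale),
* randomly placed ellipsoids with constant interiors and *sharp* borders
  (step edges through-plane, the structure cubic interpolation blurs), and
* band-limited random texture (fine detail with energy above the
  decimation Nyquist, the structure interpolation cannot recover at all).

Everything is deterministic per seed and standardized to (0, 10000).
"""

from __future__ import annotations

from dataclasses import dataclass
from typing import List, Sequence, Tuple

import numpy as np
from scipy.ndimage import gaussian_filter

from .dataset import (
    PatchPair,
    SplitAssignment,
    cubic_upsample_z,
    make_patch_pairs,
    shuffle_patches,
    split_patients,
)
from .degrade import DegradationSpec, degrade
from .volume_io import DEFAULT_RANGE, Volume, standardize

__all__ = ["PhantomSpec", "generate_phantom", "generate_training_fixture"]


@dataclass(frozen=True)
class PhantomSpec:
    """Parameters of one procedural phantom volume."""

    shape: Tuple[int, int, int] = (64, 64, 64)
    n_ellipsoids: int = 6
    texture_amplitude: float = 0.15
    background_gradient: bool = True
    seed: int = 0

    def __post_init__(self) -> None:
        if len(self.shape) != 3 or any(int(n) < 8 for n in self.shape):
            raise ValueError(f"phantom shape must be >= 8 per axis, got {self.shape}")
        if not (0.0 <= self.texture_amplitude <= 1.0):
            raise ValueError("texture_amplitude must be in [0, 1]")
        if self.n_ellipsoids < 0:
            raise ValueError("n_ellipsoids must be >= 0")


def _background(shape: Tuple[int, int, int], rng: np.random.Generator) -> np.ndarray:
    """Random quadratic polynomial over normalized coordinates in [-1, 1]."""
    u, v, w = np.meshgrid(
        *(np.linspace(-1.0, 1.0, n) for n in shape), indexing="ij"
    )
    terms = [np.ones(shape), u, v, w, u * v, u * w, v * w, u**2, v**2, w**2]
    coefs = rng.uniform(-1.0, 1.0, size=len(terms))
    coefs[0] = rng.uniform(2.0, 4.0)  # keep the field positive-ish
    return sum(c * t for c, t in zip(coefs, terms))


def _ellipsoids(
    shape: Tuple[int, int, int], n: int, rng: np.random.Generator
) -> np.ndarray:
    x, y, z = np.meshgrid(*(np.arange(s, dtype=np.float64) for s in shape), indexing="ij")
    field = np.zeros(shape, dtype=np.float64)
    for _ in range(n):
        center = [rng.uniform(0.25 * s, 0.75 * s) for s in shape]
        radii = [rng.uniform(0.08 * s, 0.2 * s) for s in shape]
        intensity = rng.uniform(1.0, 3.0) * rng.choice([-1.0, 1.0])
        mask = (
            ((x - center[0]) / radii[0]) ** 2
            + ((y - center[1]) / radii[1]) ** 2
            + ((z - center[2]) / radii[2]) ** 2
        ) <= 1.0
        field[mask] += intensity
    return field


def _texture(
    shape: Tuple[int, int, int], amplitude: float, rng: np.random.Generator
) -> np.ndarray:
    if amplitude == 0.0:
        return np.zeros(shape)
    noise = rng.standard_normal(shape)
    smooth = gaussian_filter(noise, sigma=1.0, mode="reflect")
    smooth /= max(smooth.std(), 1e-12)
    return amplitude * smooth


def generate_phantom(spec: PhantomSpec) -> Volume:
    """Deterministic phantom volume standardized to (0, 10000)."""
    rng = np.random.default_rng(spec.seed)
    shape = tuple(int(n) for n in spec.shape)
    field = np.zeros(shape, dtype=np.float64)
    if spec.background_gradient:
        field += _background(shape, rng)
    else:
        # consume the same draws so toggling content stays comparable
        _background(shape, rng)
    field += _ellipsoids(shape, spec.n_ellipsoids, rng)
    field += _texture(shape, spec.texture_amplitude, rng)
    if field.max() <= field.min():
        # no content requested at all; provide a deterministic ramp
        field = np.linspace(0, 1, shape[2])[None, None, :] * np.ones(shape)
    vol = Volume(field.astype(np.float32), spacing=(1.0, 1.0, 1.0))
    return standardize(vol, *DEFAULT_RANGE)


def generate_training_fixture(
    n_volumes: int,
    spec: PhantomSpec,
    factors: Sequence[int] = (4,),
    mode: str = "thick",
    seed: int = 0,
    patch_size: int = 32,
    ratios: Tuple[float, float, float] = (0.8, 0.1, 0.1),
) -> Tuple[List[PatchPair], SplitAssignment]:
    """A miniature of the full data pipeline on phantoms.

    Generates ``n_volumes`` phantoms (per-volume seeds ``spec.seed + i``),
    degrades each by every factor under ``mode``, cubically pre-upsamples
    back to the HR grid, splits at the phantom level by ``ratios`` and
    returns the shuffled patch pairs together with the split.
    """
    if n_volumes < 3:
        raise ValueError("need at least 3 phantoms to form a split")
    pairs: List[PatchPair] = []
    ids = [f"phantom-{i:03d}" for i in range(n_volumes)]
    for i, pid in enumerate(ids):
        vspec = PhantomSpec(
            shape=spec.shape,
            n_ellipsoids=spec.n_ellipsoids,
            texture_amplitude=spec.texture_amplitude,
            background_gradient=spec.background_gradient,
            seed=spec.seed + i,
        )
        hr = generate_phantom(vspec)
        for s in factors:
            dspec = DegradationSpec(mode=mode, factor_s=int(s))
            lr = degrade(hr, dspec)
            lr_up = cubic_upsample_z(lr, hr.shape[2], ratio=float(s))
            pairs.extend(
                make_patch_pairs(
                    lr_up, hr, patch_size=patch_size, scale_s=int(s), patient_id=pid
                )
            )
    split = split_patients(ids, ratios=ratios, seed=seed)
    return shuffle_patches(pairs, seed=seed), split
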