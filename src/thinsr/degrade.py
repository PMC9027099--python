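"""Acquisition-motivated degradation: synthesize low-resolution volumes.

Supervised training needs matched (LR, HR) pairs; clinical archives only
hold one of the two.  The encoder that turns a high-resolution volume into
its low-resolution counterpart is therefore simulated, and *how* it is
simulated must mirror the acquisition protocol or the learned inverse will
not transfer:

``thick``
    Same z coverage, thicker slices.  Each output slice averages ``s``
    consecutive thin slices - a length-``s`` moving-average (FIR) kernel
    with coefficients ``1/s`` followed by s-fold decimation.  This mimics
    the partial-volume averaging of a thick-slice scan and is intrinsically
    anti-aliased.

``sparse``
    Same in-plane resolution, slices acquired far apart.  Every ``s``-th
    slice is kept with *no* filtering, so perpendicular reformats alias -
    exactly as sparsely stacked clinical 2D acquisitions do.

``gaussian``
    Anything in between: a tunable Gaussian slice profile followed by
    decimation.

All decimation is phase-0: the first output slice coincides with the first
input slice/block, which keeps retained sparse slices exactly on the HR
grid (the inference stage relies on this alignment).
"""

from __future__ import annotations

from dataclasses import dataclass
from typing import Optional

import numpy as np
from scipy.ndimage import convolve1d

from ._exceptions import InsufficientSlicesError
from .volume_io import Volume

__all__ = [
    "DegradationSpec",
    "degrade",
    "thick_to_thin_degrade",
    "sparse_to_thin_degrade",
    "gaussian_degrade",
]

_MODES = ("thick", "sparse", "gaussian")


@dataclass(frozen=True)
class DegradationSpec:
    """Parameters of the simulated low-resolution acquisition.

    ``factor_s`` is the through-plane down-sampling factor (>= 2 for
    training corpora; 1 is allowed and is the identity for sparse mode).
    ``noise_sigma`` adds zero-mean Gaussian measurement noise after
    decimation; the default 0 keeps degradation deterministic.
    """

    mode: str
    factor_s: int
    gaussian_sigma: Optional[float] = None
    noise_sigma: float = 0.0

    def __post_init__(self) -> None:
        if self.mode not in _MODES:
            raise ValueError(f"mode must be one of {_MODES}, got {self.mode!r}")
        if int(self.factor_s) != self.factor_s or self.factor_s < 1:
            raise ValueError(f"factor_s must be a positive integer, got {self.factor_s}")
        if self.mode == "gaussian":
            if self.gaussian_sigma is None or self.gaussian_sigma < 0:
                raise ValueError("gaussian mode requires gaussian_sigma >= 0")
        elif self.gaussian_sigma is not None:
            raise ValueError(f"gaussian_sigma is only valid in gaussian mode")
        if self.noise_sigma < 0:
            raise ValueError("noise_sigma must be >= 0")


def _check_extent(volume: Volume, s: int) -> None:
    if volume.shape[2] < s:
        raise InsufficientSlicesError(
            f"volume has {volume.shape[2]} slices, need at least {s}"
        )


def _add_noise(
    voxels: np.ndarray, sigma: float, seed: Optional[int]
) -> np.ndarray:
    if sigma <= 0:
        return voxels
    rng = np.random.default_rng(seed)
    return voxels + rng.normal(0.0, sigma, size=voxels.shape).astype(np.float32)


def thick_to_thin_degrade(
    volume: Volume, spec: DegradationSpec, seed: Optional[int] = None
) -> Volume:
    """Thick-slice simulation: block means of ``s`` consecutive slices.

    Equivalent to convolving along z with the uniform FIR kernel of length
    ``s`` (each coefficient ``1/s``) and decimating at phase 0.  Trailing
    slices that do not fill a block are dropped rather than padded, so no
    tissue is fabricated at the volume edge.
    """
    if spec.mode != "thick":
        raise ValueError(f"spec mode is {spec.mode!r}, expected 'thick'")
    s = int(spec.factor_s)
    _check_extent(volume, s)
    nx, ny, nz = volume.shape
    nblocks = nz // s
    v = volume.voxels[:, :, : nblocks * s].astype(np.float64)
    out = v.reshape(nx, ny, nblocks, s).mean(axis=3).astype(np.float32)
    out = _add_noise(out, spec.noise_sigma, seed)
    return volume.with_voxels(out, z_spacing=volume.spacing[2] * s)


def sparse_to_thin_degrade(
    volume: Volume, spec: DegradationSpec, seed: Optional[int] = None
) -> Volume:
    """Sparse-stack simulation: keep slices ``0, s, 2s, ...`` unfiltered."""
    if spec.mode != "sparse":
        raise ValueError(f"spec mode is {spec.mode!r}, expected 'sparse'")
    s = int(spec.factor_s)
    _check_extent(volume, s)
    out = np.ascontiguousarray(volume.voxels[:, :, ::s])
    out = _add_noise(out, spec.noise_sigma, seed)
    return volume.with_voxels(out, z_spacing=volume.spacing[2] * s)


def gaussian_kernel(sigma: float) -> np.ndarray:
    """Symmetric Gaussian kernel truncated at 4 sigma, renormalized to sum 1."""
    if sigma <= 0:
        return np.array([1.0])
    radius = int(np.ceil(4.0 * sigma))
    x = np.arange(-radius, radius + 1, dtype=np.float64)
    k = np.exp(-0.5 * (x / sigma) ** 2)
    return k / k.sum()


def gaussian_degrade(
    volume: Volume, spec: DegradationSpec, seed: Optional[int] = None
) -> Volume:
    """Gaussian slice-profile simulation: filter along z, then decimate."""
    if spec.mode != "gaussian":
        raise ValueError(f"spec mode is {spec.mode!r}, expected 'gaussian'")
    s = int(spec.factor_s)
    _check_extent(volume, s)
    kernel = gaussian_kernel(float(spec.gaussian_sigma))
    filtered = convolve1d(
        volume.voxels.astype(np.float64), kernel, axis=2, mode="reflect"
    )
    out = np.ascontiguousarray(filtered[:, :, ::s]).astype(np.float32)
    out = _add_noise(out, spec.noise_sigma, seed)
    return volume.with_voxels(out, z_spacing=volume.spacing[2] * s)


_DISPATCH = {
    "thick": thick_to_thin_degrade,
    "sparse": sparse_to_thin_degrade,
    "gaussian": gaussian_degrade,
}


def degrade(
    volume: Volume, spec: DegradationSpec, seed: Optional[int] = None
) -> Volume:
    """Apply the degradation selected by ``spec.mode``."""
    return _DISPATCH[spec.mode](volume, spec, seed)
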