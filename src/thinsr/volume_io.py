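"""Volume container, NIfTI input/output and intensity standardization.

A :class:`Volume` is the currency of the whole pipeline: a 3D float32 grid
indexed ``(x, y, z)`` with ``z`` the through-plane (slice) axis, physical
voxel spacing in millimetres, and an optional record of the intensity window
the voxels were standardized into.  One network serves several modalities
(T1/FLAIR MRI, CT, ...) only because every input is first mapped onto a
common intensity range; the default window is ``(0, 10000)``.
"""

from __future__ import annotations

import os
from dataclasses import dataclass, field, replace
from typing import Optional, Tuple

import nibabel as nib
import numpy as np

from ._exceptions import (
    DegenerateRangeError,
    DimensionalityError,
    VolumeFormatError,
)

DEFAULT_RANGE: Tuple[float, float] = (0.0, 10000.0)

__all__ = [
    "Volume",
    "DEFAULT_RANGE",
    "read_volume",
    "write_volume",
    "standardize",
    "unstandardize",
]


@dataclass
class Volume:
    """3D intensity grid plus geometry and intensity metadata.

    Attributes
    ----------
    voxels:
        float32 array indexed ``(x, y, z)``; ``z`` is through-plane.
    spacing:
        physical voxel size per axis, mm, strictly positive.
    intensity_range:
        the ``(low, high)`` standardization window the voxels currently
        live in, or ``None`` if the volume has raw scanner intensities.
    affine:
        4x4 voxel-to-physical mapping.
    """

    voxels: np.ndarray
    spacing: Tuple[float, float, float]
    intensity_range: Optional[Tuple[float, float]] = None
    affine: np.ndarray = field(default=None)  # type: ignore[assignment]

    def __post_init__(self) -> None:
        self.voxels = np.asarray(self.voxels, dtype=np.float32)
        if self.voxels.ndim != 3:
            raise DimensionalityError(
                f"expected a 3D grid, got {self.voxels.ndim}D"
            )
        if not np.all(np.isfinite(self.voxels)):
            raise ValueError("voxel values must all be finite")
        self.spacing = tuple(float(s) for s in self.spacing)  # type: ignore[assignment]
        if len(self.spacing) != 3 or any(s <= 0 for s in self.spacing):
            raise ValueError(f"spacing must be 3 positive values, got {self.spacing}")
        if self.affine is None:
            self.affine = np.diag(list(self.spacing) + [1.0])
        self.affine = np.asarray(self.affine, dtype=np.float64)

    @property
    def shape(self) -> Tuple[int, int, int]:
        return self.voxels.shape  # type: ignore[return-value]

    def with_voxels(
        self,
        voxels: np.ndarray,
        z_spacing: Optional[float] = None,
        intensity_range: Optional[Tuple[float, float]] = "unset",  # type: ignore[assignment]
    ) -> "Volume":
        """Copy of this volume with new voxels and (optionally) new z spacing."""
        spacing = self.spacing
        affine = self.affine.copy()
        if z_spacing is not None:
            spacing = (spacing[0], spacing[1], float(z_spacing))
            # rescale the z direction column, preserving orientation
            col = affine[:3, 2]
            norm = np.linalg.norm(col)
            if norm > 0:
                affine[:3, 2] = col / norm * z_spacing
        irange = self.intensity_range if intensity_range == "unset" else intensity_range
        return Volume(np.asarray(voxels, dtype=np.float32), spacing, irange, affine)


def _encode_range(intensity_range: Optional[Tuple[float, float]]) -> bytes:
    if intensity_range is None:
        return b""
    lo, hi = intensity_range
    return f"irange={lo:g}:{hi:g}".encode("ascii")[:80]


def _decode_range(descrip: bytes) -> Optional[Tuple[float, float]]:
    try:
        text = bytes(descrip).split(b"\x00", 1)[0].decode("ascii")
    except UnicodeDecodeError:
        return None
    if not text.startswith("irange="):
        return None
    try:
        lo, hi = text[len("irange="):].split(":")
        return float(lo), float(hi)
    except ValueError:
        return None


def read_volume(path: os.PathLike | str) -> Volume:
    """Read a NIfTI file into the internal ``(x, y, z)`` convention.

    The image is reoriented to the closest RAS-canonical axes so the third
    array axis is the through-plane direction of the stored volume.  No
    intensity rescaling beyond the NIfTI slope/intercept is applied.
    """
    try:
        img = nib.load(str(path))
    except Exception as exc:  # nibabel raises several unrelated types
        raise VolumeFormatError(f"cannot read {path!r}: {exc}") from exc
    if img.ndim != 3:
        raise DimensionalityError(
            f"{path!r} is {img.ndim}D; only 3D volumes are supported"
        )
    img = nib.as_closest_canonical(img)
    data = np.asanyarray(img.dataobj).astype(np.float32)
    if not np.all(np.isfinite(data)):
        raise VolumeFormatError(f"{path!r} contains non-finite voxels")
    spacing = tuple(float(z) for z in img.header.get_zooms()[:3])
    irange = _decode_range(img.header["descrip"].tobytes())
    return Volume(data, spacing, irange, np.asarray(img.affine))


def write_volume(volume: Volume, path: os.PathLike | str) -> None:
    """Write a NIfTI file whose header matches the volume's geometry.

    The standardization window, if any, is stored in the header ``descrip``
    field so a write/read round trip preserves it.
    """
    img = nib.Nifti1Image(volume.voxels, volume.affine)
    img.header.set_zooms(volume.spacing)
    img.header["descrip"] = _encode_range(volume.intensity_range)
    parent = os.path.dirname(os.path.abspath(str(path)))
    if not os.access(parent, os.W_OK):
        raise IOError(f"directory not writable: {parent}")
    nib.save(img, str(path))


def standardize(
    volume: Volume,
    out_low: float = DEFAULT_RANGE[0],
    out_high: float = DEFAULT_RANGE[1],
) -> Volume:
    """Affinely map the volume's intensity extrema onto ``[out_low, out_high]``.

    Min-max standardization onto a uniform window makes one trained model
    usable across modalities with very different native scales (MRI arbitrary
    units vs. CT Hounsfield units).  The mapping is strictly monotone, hence
    idempotent, and the window is recorded in ``intensity_range`` so it can
    be inverted on output.
    """
    if out_high <= out_low:
        raise ValueError("out_high must exceed out_low")
    lo = float(volume.voxels.min())
    hi = float(volume.voxels.max())
    if hi <= lo:
        raise DegenerateRangeError("constant-valued volume cannot be standardized")
    scaled = (volume.voxels.astype(np.float64) - lo) / (hi - lo)
    scaled = scaled * (out_high - out_low) + out_low
    return replace(
        volume,
        voxels=scaled.astype(np.float32),
        intensity_range=(float(out_low), float(out_high)),
    )


def unstandardize(volume: Volume, original_range: Tuple[float, float]) -> Volume:
    """Invert :func:`standardize`, mapping the window back onto a native range."""
    if volume.intensity_range is None:
        raise ValueError("volume has no recorded standardization window")
    lo, hi = volume.intensity_range
    olo, ohi = original_range
    scaled = (volume.voxels.astype(np.float64) - lo) / (hi - lo) * (ohi - olo) + olo
    return replace(volume, voxels=scaled.astype(np.float32), intensity_range=None)
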