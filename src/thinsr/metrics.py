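"""Full-reference quality metrics for volumes: RMSE, PSNR, SSIM.

PSNR and SSIM are computed against a fixed data range - for standardized
volumes the standardization window width (10000) - rather than a per-pair
intensity spread, so scores are comparable across volumes and factors.
SSIM defaults to true 3D windows (Gaussian, sigma = 1.5, Wang constants
C1 = (0.01 R)^2, C2 = (0.03 R)^2); a slice-wise 2D mode is available for
comparability with slice-based reports.
"""

from __future__ import annotations

import math
from dataclasses import dataclass
from typing import Union

import numpy as np
from skimage.metrics import structural_similarity

from .volume_io import Volume

__all__ = [
    "MetricsReport",
    "rmse",
    "psnr",
    "ssim",
    "evaluate",
    "paired_comparison",
]

DEFAULT_DATA_RANGE = 10000.0

#: PSNR reported for a perfect reconstruction (rmse == 0)
PSNR_PERFECT = math.inf


def _voxels(v: Union[Volume, np.ndarray]) -> np.ndarray:
    return v.voxels if isinstance(v, Volume) else np.asarray(v)


def _check_shapes(a: np.ndarray, b: np.ndarray) -> None:
    if a.shape != b.shape:
        raise ValueError(f"shape mismatch: {a.shape} vs {b.shape}")


@dataclass(frozen=True)
class MetricsReport:
    rmse: float
    psnr: float
    ssim: float
    data_range: float
    n_voxels: int

    def as_row(self, patient_id: str = "", s: float = 0.0, method: str = "") -> dict:
        return {
            "patient_id": patient_id,
            "s": s,
            "method": method,
            "rmse": self.rmse,
            "psnr": self.psnr,
            "ssim": self.ssim,
        }


def rmse(a: Union[Volume, np.ndarray], b: Union[Volume, np.ndarray]) -> float:
    """Root mean squared voxel difference."""
    av, bv = _voxels(a).astype(np.float64), _voxels(b).astype(np.float64)
    _check_shapes(av, bv)
    return float(np.sqrt(np.mean((av - bv) ** 2)))


def psnr(
    a: Union[Volume, np.ndarray],
    b: Union[Volume, np.ndarray],
    data_range: float = DEFAULT_DATA_RANGE,
) -> float:
    """Peak signal-to-noise ratio, ``20 log10(R / rmse)`` in dB.

    Identical volumes return ``math.inf`` (documented sentinel).
    """
    if data_range <= 0:
        raise ValueError("data_range must be positive")
    r = rmse(a, b)
    if r == 0.0:
        return PSNR_PERFECT
    return float(20.0 * math.log10(data_range / r))


def ssim(
    a: Union[Volume, np.ndarray],
    b: Union[Volume, np.ndarray],
    data_range: float = DEFAULT_DATA_RANGE,
    mode: str = "3d",
) -> float:
    """Mean structural similarity.

    ``mode='3d'`` uses volumetric Gaussian windows; ``mode='slicewise'``
    averages 2D SSIM over axial slices.
    """
    av, bv = _voxels(a).astype(np.float64), _voxels(b).astype(np.float64)
    _check_shapes(av, bv)
    kwargs = dict(
        data_range=data_range,
        gaussian_weights=True,
        sigma=1.5,
        use_sample_covariance=False,
    )
    if mode == "3d":
        if min(av.shape) < 11:
            raise ValueError(
                f"volume extent {av.shape} smaller than the 11-voxel SSIM window"
            )
        return float(structural_similarity(av, bv, **kwargs))
    if mode == "slicewise":
        if min(av.shape[:2]) < 11:
            raise ValueError("in-plane extent smaller than the SSIM window")
        vals = [
            structural_similarity(av[:, :, k], bv[:, :, k], **kwargs)
            for k in range(av.shape[2])
        ]
        return float(np.mean(vals))
    raise ValueError(f"unknown ssim mode {mode!r}")


def paired_comparison(scores_a, scores_b) -> float:
    """Two-sided p-value for paired per-volume scores of two methods.

    Wilcoxon signed-rank test across test volumes (each volume scored by
    both methods).  Returns 1.0 when every pair ties.
    """
    from scipy.stats import wilcoxon

    a = np.asarray(scores_a, dtype=np.float64)
    b = np.asarray(scores_b, dtype=np.float64)
    if a.shape != b.shape or a.ndim != 1 or len(a) < 2:
        raise ValueError("need two equal-length 1D score arrays (>= 2 volumes)")
    if np.allclose(a, b):
        return 1.0
    return float(wilcoxon(a, b, alternative="two-sided").pvalue)


def evaluate(
    a: Union[Volume, np.ndarray],
    b: Union[Volume, np.ndarray],
    data_range: float = DEFAULT_DATA_RANGE,
    ssim_mode: str = "3d",
) -> MetricsReport:
    """All three metrics in one report."""
    av = _voxels(a)
    return MetricsReport(
        rmse=rmse(a, b),
        psnr=psnr(a, b, data_range),
        ssim=ssim(a, b, data_range, ssim_mode),
        data_range=float(data_range),
        n_voxels=int(av.size),
    )
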