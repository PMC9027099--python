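"""Training-corpus construction: splits, pre-upsampling, patch pairing.

The training unit is a matched pair of 32^3 patches: the low-resolution
patch comes from the LR volume *after* cubic interpolation back onto the
high-resolution grid (pre-upsampling residual learning), the ground-truth
patch from the original HR volume at the same location.  Whole volumes are
interpolated before patching so patch content never suffers boundary
interpolation artifacts, and every patch records which degradation factor
produced it (the scale-attention model needs that at training time).

Splits are at the patient level - every patch of a patient lives in exactly
one of train/validation/test - which is what prevents leakage between the
groups; the default ratio is 8:1:1.
"""

from __future__ import annotations

import json
import os
from dataclasses import dataclass, field
from typing import List, Optional, Sequence, Tuple

import numpy as np
from scipy.interpolate import CubicSpline

from ._exceptions import InsufficientSlicesError, PairingError, SplitError
from .volume_io import Volume

__all__ = [
    "PatchPair",
    "SplitAssignment",
    "split_patients",
    "cubic_upsample_z",
    "make_patch_pairs",
    "shuffle_patches",
    "save_corpus",
    "load_corpus",
]

DEFAULT_PATCH = 32
DEFAULT_RATIOS = (0.8, 0.1, 0.1)


@dataclass
class PatchPair:
    """Matched LR (pre-upsampled) / HR patch with provenance."""

    lr_patch: np.ndarray
    hr_patch: np.ndarray
    scale_s: int
    patient_id: str
    corner: Tuple[int, int, int]

    def __post_init__(self) -> None:
        self.lr_patch = np.asarray(self.lr_patch, dtype=np.float32)
        self.hr_patch = np.asarray(self.hr_patch, dtype=np.float32)
        if self.lr_patch.shape != self.hr_patch.shape:
            raise PairingError(
                f"patch shapes differ: {self.lr_patch.shape} vs {self.hr_patch.shape}"
            )


@dataclass(frozen=True)
class SplitAssignment:
    """Disjoint, jointly exhaustive patient-level split."""

    train_ids: Tuple[str, ...]
    val_ids: Tuple[str, ...]
    test_ids: Tuple[str, ...]
    seed: int

    def group_of(self, patient_id: str) -> str:
        if patient_id in self.train_ids:
            return "train"
        if patient_id in self.val_ids:
            return "val"
        if patient_id in self.test_ids:
            return "test"
        raise KeyError(patient_id)


def split_patients(
    patient_ids: Sequence[str],
    ratios: Tuple[float, float, float] = DEFAULT_RATIOS,
    seed: int = 0,
) -> SplitAssignment:
    """Deterministically shuffle patients and split them by ratio.

    Group sizes are the floor of the cumulative ratios, which makes the
    groups jointly exhaustive; with at least three patients every group is
    guaranteed at least one member.
    """
    ids = [str(p) for p in patient_ids]
    if len(set(ids)) != len(ids):
        raise SplitError("patient ids must be unique")
    if len(ids) < 3:
        raise SplitError(f"need at least 3 patients, got {len(ids)}")
    r = np.asarray(ratios, dtype=np.float64)
    if r.shape != (3,) or np.any(r <= 0) or abs(r.sum() - 1.0) > 1e-9:
        raise SplitError(f"ratios must be 3 positive values summing to 1, got {ratios}")
    rng = np.random.default_rng(seed)
    order = rng.permutation(len(ids))
    shuffled = [ids[i] for i in order]
    n = len(ids)
    bounds = np.floor(np.cumsum(r) * n + 1e-9).astype(int)
    bounds[2] = n
    sizes = np.diff(np.concatenate([[0], bounds]))
    # guarantee non-empty groups by borrowing from the largest
    while np.any(sizes == 0):
        sizes[int(np.argmin(sizes))] += 1
        sizes[int(np.argmax(sizes))] -= 1
    b1, b2 = int(sizes[0]), int(sizes[0] + sizes[1])
    return SplitAssignment(
        train_ids=tuple(shuffled[:b1]),
        val_ids=tuple(shuffled[b1:b2]),
        test_ids=tuple(shuffled[b2:]),
        seed=int(seed),
    )


def cubic_upsample_z(
    volume: Volume, target_z: int, ratio: Optional[float] = None
) -> Volume:
    """Cubic interpolation along z onto ``target_z`` uniformly spaced slices.

    Two grid anchors are supported.  Without ``ratio`` the target grid is
    endpoint-aligned: its first sample coincides with the first input
    slice and its last with the last.  With ``ratio`` r (the degradation
    or super-resolution factor) the grid is *phase-0*: output slice p sits
    at input coordinate p / r, so input slices reappear exactly at output
    indices 0, r, 2r, ... - the alignment the degradation operators
    produce and the inference pipeline expects.  Any residual systematic
    offset is then constant along z (translation-invariant), which is what
    lets a convolutional model correct it.  The last few phase-0 samples
    may extrapolate by less than one input spacing.

    Not-a-knot cubic splines are used, which reproduce cubic polynomials
    exactly everywhere, including at the boundaries and in the short
    extrapolation range.
    """
    nz = volume.shape[2]
    if nz < 4:
        raise InsufficientSlicesError(
            f"cubic interpolation needs >= 4 slices, got {nz}"
        )
    target_z = int(target_z)
    if target_z < nz:
        raise ValueError("target_z must be >= current z extent")
    if ratio is None and target_z == nz:
        return volume.with_voxels(volume.voxels.copy())
    spline = CubicSpline(np.arange(nz), volume.voxels.astype(np.float64), axis=2)
    if ratio is None:
        t = np.linspace(0.0, nz - 1, target_z)
        new_dz = volume.spacing[2] * (nz - 1) / (target_z - 1)
    else:
        ratio = float(ratio)
        if ratio <= 0:
            raise ValueError("ratio must be positive")
        t = np.arange(target_z) / ratio
        new_dz = volume.spacing[2] / ratio
    out = spline(t).astype(np.float32)
    return volume.with_voxels(out, z_spacing=new_dz)


def make_patch_pairs(
    lr_up: Volume,
    hr: Volume,
    patch_size: int = DEFAULT_PATCH,
    stride: Optional[int] = None,
    scale_s: int = 0,
    patient_id: str = "",
) -> List[PatchPair]:
    """Tile a pre-upsampled LR volume and its HR twin into aligned patches.

    The default stride equals the patch size (non-overlapping tiling);
    partial tiles at the far edges are discarded.
    """
    if lr_up.shape != hr.shape:
        raise PairingError(
            f"volumes must share a grid: {lr_up.shape} vs {hr.shape}"
        )
    p = int(patch_size)
    if stride is None:
        stride = p
    stride = int(stride)
    if stride < 1 or p < 1:
        raise ValueError("patch_size and stride must be positive")
    if any(ext < p for ext in hr.shape):
        raise PairingError(
            f"patch size {p} exceeds volume extent {hr.shape}"
        )
    pairs: List[PatchPair] = []
    nx, ny, nz = hr.shape
    for x0 in range(0, nx - p + 1, stride):
        for y0 in range(0, ny - p + 1, stride):
            for z0 in range(0, nz - p + 1, stride):
                pairs.append(
                    PatchPair(
                        lr_patch=lr_up.voxels[x0 : x0 + p, y0 : y0 + p, z0 : z0 + p].copy(),
                        hr_patch=hr.voxels[x0 : x0 + p, y0 : y0 + p, z0 : z0 + p].copy(),
                        scale_s=int(scale_s),
                        patient_id=str(patient_id),
                        corner=(x0, y0, z0),
                    )
                )
    return pairs


def shuffle_patches(pairs: Sequence[PatchPair], seed: int = 0) -> List[PatchPair]:
    """Deterministic permutation of the patch list under ``seed``."""
    rng = np.random.default_rng(seed)
    order = rng.permutation(len(pairs))
    return [pairs[i] for i in order]


# -- on-disk corpus ---------------------------------------------------------
#
# One compressed array container per group (train/val/test) plus a JSON
# manifest describing records and provenance; arrays are stacked patch
# tensors so the corpus loads in a handful of reads.


def save_corpus(
    out_dir,
    pairs: Sequence[PatchPair],
    split: SplitAssignment,
) -> None:
    os.makedirs(out_dir, exist_ok=True)
    manifest = {"format": 1, "seed": split.seed, "groups": {}}
    for group in ("train", "val", "test"):
        ordered = getattr(split, f"{group}_ids")
        ids = set(ordered)
        members = [pp for pp in pairs if pp.patient_id in ids]
        manifest["groups"][group] = {
            "n_pairs": len(members),
            "patients": list(ordered),
            "records": [
                {
                    "patient_id": pp.patient_id,
                    "scale_s": pp.scale_s,
                    "corner": list(pp.corner),
                }
                for pp in members
            ],
        }
        if members:
            lr = np.stack([pp.lr_patch for pp in members])
            hr = np.stack([pp.hr_patch for pp in members])
        else:
            lr = hr = np.zeros((0,), dtype=np.float32)
        np.savez_compressed(os.path.join(out_dir, f"{group}.npz"), lr=lr, hr=hr)
    with open(os.path.join(out_dir, "manifest.json"), "w") as fh:
        json.dump(manifest, fh, indent=1, sort_keys=True)


def load_corpus(out_dir) -> Tuple[dict, SplitAssignment]:
    """Load a saved corpus; returns ({group: [PatchPair]}, SplitAssignment)."""
    with open(os.path.join(out_dir, "manifest.json")) as fh:
        manifest = json.load(fh)
    groups = {}
    patients = {}
    for group in ("train", "val", "test"):
        info = manifest["groups"][group]
        patients[group] = tuple(info["patients"])
        pairs: List[PatchPair] = []
        if info["n_pairs"]:
            with np.load(os.path.join(out_dir, f"{group}.npz")) as data:
                lr, hr = data["lr"], data["hr"]
            for rec, l, h in zip(info["records"], lr, hr):
                pairs.append(
                    PatchPair(
                        lr_patch=l,
                        hr_patch=h,
                        scale_s=int(rec["scale_s"]),
                        patient_id=rec["patient_id"],
                        corner=tuple(rec["corner"]),
                    )
                )
        groups[group] = pairs
    split = SplitAssignment(
        train_ids=patients["train"],
        val_ids=patients["val"],
        test_ids=patients["test"],
        seed=int(manifest["seed"]),
    )
    return groups, split
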