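"""Preprocessing for head CT: skull removal, z-score normalization, padding.

Skull stripping here is threshold-and-topology based: bone is everything at
or above a HU threshold, the brain is the largest connected component of
tissue enclosed by the bone shell. That is adequate for phantoms and clean
CT; it is not a clinical-grade brain extractor.
"""
from __future__ import annotations

from dataclasses import dataclass
from typing import Tuple

import numpy as np
from scipy import ndimage

from .grids import HU, ZSCORED, LabelMask, Volume

__all__ = [
    "NoSkullFoundError",
    "strip_skull",
    "zscore",
    "pad_to_multiple",
    "CropRecord",
    "BONE_THRESHOLD_HU",
]

BONE_THRESHOLD_HU = 300.0
FILL_HU = -1000.0


class NoSkullFoundError(ValueError):
    """Raised when no bone shell is present in the volume."""


def strip_skull(v: Volume, bone_threshold: float = BONE_THRESHOLD_HU) -> Tuple[Volume, LabelMask]:
    """Remove bone and everything outside it; return the brain-only volume.

    The brain mask is the largest connected component enclosed by the bone
    shell (morphological closing with a 1-voxel radius bridges small shell
    gaps before the topology analysis). Voxels outside the mask are set to
    -1000 HU.
    """
    if v.intensity_domain != HU:
        raise ValueError("strip_skull expects HU-valued input")
    bone = v.values >= bone_threshold
    if not bone.any():
        raise NoSkullFoundError(
            f"no voxel reaches the bone threshold of {bone_threshold} HU"
        )
    structure = ndimage.generate_binary_structure(v.ndim, 1)
    closed = ndimage.binary_closing(bone, structure=structure, iterations=1)
    enclosed = ndimage.binary_fill_holes(closed) & ~closed
    labels, n = ndimage.label(enclosed, structure=structure)
    if n == 0:
        raise NoSkullFoundError("bone shell encloses no tissue")
    sizes = ndimage.sum_labels(np.ones_like(labels), labels, index=np.arange(1, n + 1))
    brain = labels == (1 + int(np.argmax(sizes)))
    out = np.where(brain, v.values, FILL_HU)
    return v.with_values(out), LabelMask(brain.astype(np.uint8), v.spacing, v.origin)


def zscore(v: Volume, mask: LabelMask) -> Volume:
    """Z-score normalize over the mask (population sd); zero outside the mask."""
    if mask.shape != v.shape:
        raise ValueError("mask shape must match the volume")
    inside = mask.values.astype(bool)
    if inside.sum() < 2:
        raise ValueError("mask must select at least 2 voxels")
    vals = v.values[inside]
    mu = float(vals.mean())
    sd = float(vals.std())  # population convention (ddof=0)
    if sd == 0:
        raise ValueError("zero variance inside the mask; cannot z-score")
    out = np.zeros_like(v.values, dtype=float)
    out[inside] = (vals - mu) / sd
    return v.with_values(out, intensity_domain=ZSCORED)


@dataclass(frozen=True)
class CropRecord:
    """Inverse of :func:`pad_to_multiple`."""

    original_shape: Tuple[int, ...]

    def crop(self, values: np.ndarray) -> np.ndarray:
        return values[tuple(slice(0, n) for n in self.original_shape)]

    def crop_volume(self, v: Volume) -> Volume:
        return v.with_values(self.crop(v.values))


def pad_to_multiple(v: Volume, k: int) -> Tuple[Volume, CropRecord]:
    """Zero-pad each axis up to the next multiple of ``k`` (at the high end)."""
    if k < 1:
        raise ValueError("k must be >= 1")
    pads = [(0, (-n) % k) for n in v.shape]
    out = np.pad(v.values, pads)
    return v.with_values(out), CropRecord(tuple(v.shape))
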