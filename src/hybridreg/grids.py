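"""Core spatial containers: volumes, label masks, displacement fields, landmarks.

Conventions used throughout the package:

* Voxel indices are 0-based; the physical (mm) coordinate of voxel ``i``
  along an axis is ``i * spacing + origin``.
* Displacement fields are stored in **voxel units** with the spacing carried
  alongside; physical statements convert per-axis via the spacing.
* Warping is backward: the warped image reads the source at ``x + u(x)``.

All containers work in 2-D and 3-D; the dimensionality is inferred from the
array shape and every spacing/origin tuple must match it.
"""
from __future__ import annotations

from dataclasses import dataclass, replace
from typing import Optional, Sequence

import numpy as np

__all__ = [
    "Volume",
    "LabelMask",
    "DisplacementField",
    "LandmarkSet",
]

HU = "HU"
ZSCORED = "zscored"


def _as_tuple(x: Sequence[float], ndim: int, name: str) -> tuple:
    t = tuple(float(v) for v in np.atleast_1d(x))
    if len(t) != ndim:
        raise ValueError(f"{name} must have length {ndim}, got {len(t)}")
    return t


@dataclass
class Volume:
    """A scalar image grid with physical spacing and origin (mm)."""

    values: np.ndarray
    spacing: tuple
    origin: tuple = None
    intensity_domain: str = HU

    def __post_init__(self):
        self.values = np.asarray(self.values)
        if self.values.ndim not in (2, 3):
            raise ValueError(f"Volume must be 2-D or 3-D, got {self.values.ndim}-D")
        if any(n < 2 for n in self.values.shape):
            raise ValueError(f"Volume needs >= 2 voxels per axis, got shape {self.values.shape}")
        nd = self.values.ndim
        if self.origin is None:
            self.origin = (0.0,) * nd
        self.spacing = _as_tuple(self.spacing, nd, "spacing")
        self.origin = _as_tuple(self.origin, nd, "origin")
        if any(s <= 0 for s in self.spacing):
            raise ValueError(f"spacing components must be > 0, got {self.spacing}")
        if self.intensity_domain not in (HU, ZSCORED):
            raise ValueError(f"unknown intensity_domain {self.intensity_domain!r}")

    @property
    def ndim(self) -> int:
        return self.values.ndim

    @property
    def shape(self) -> tuple:
        return self.values.shape

    def with_values(self, values: np.ndarray, intensity_domain: Optional[str] = None) -> "Volume":
        return replace(
            self,
            values=values,
            intensity_domain=intensity_domain or self.intensity_domain,
        )


@dataclass
class LabelMask:
    """A binary mask sharing the grid of a companion :class:`Volume`."""

    values: np.ndarray
    spacing: tuple
    origin: tuple = None

    def __post_init__(self):
        arr = np.asarray(self.values)
        if not np.isin(arr, (0, 1)).all():
            raise ValueError("mask values must be 0/1")
        self.values = arr.astype(np.uint8)
        nd = self.values.ndim
        if nd not in (2, 3):
            raise ValueError(f"LabelMask must be 2-D or 3-D, got {nd}-D")
        if self.origin is None:
            self.origin = (0.0,) * nd
        self.spacing = _as_tuple(self.spacing, nd, "spacing")
        self.origin = _as_tuple(self.origin, nd, "origin")

    @property
    def ndim(self) -> int:
        return self.values.ndim

    @property
    def shape(self) -> tuple:
        return self.values.shape

    def volume_mm(self) -> float:
        """Total physical volume (mm^ndim) of the set voxels."""
        return float(self.values.sum()) * float(np.prod(self.spacing))


@dataclass
class DisplacementField:
    """Per-voxel displacement vectors in voxel units (last axis = components)."""

    vectors: np.ndarray
    spacing: tuple

    def __post_init__(self):
        self.vectors = np.asarray(self.vectors, dtype=float)
        nd = self.vectors.ndim - 1
        if nd not in (2, 3) or self.vectors.shape[-1] != nd:
            raise ValueError(
                "field must have shape (*spatial, d) with d == number of "
                f"spatial axes; got {self.vectors.shape}"
            )
        if not np.isfinite(self.vectors).all():
            raise ValueError("displacement field contains non-finite values")
        self.spacing = _as_tuple(self.spacing, nd, "spacing")

    @property
    def ndim(self) -> int:
        return self.vectors.ndim - 1

    @property
    def spatial_shape(self) -> tuple:
        return self.vectors.shape[:-1]

    @classmethod
    def zeros(cls, shape: Sequence[int], spacing: Sequence[float]) -> "DisplacementField":
        shape = tuple(int(n) for n in shape)
        return cls(np.zeros(shape + (len(shape),)), tuple(spacing))

    def magnitude_mm(self) -> np.ndarray:
        """Per-voxel vector magnitude in mm."""
        mm = self.vectors * np.asarray(self.spacing)
        return np.sqrt((mm**2).sum(axis=-1))


@dataclass
class LandmarkSet:
    """Named points in physical mm, optionally with gold displacement vectors.

    ``gold_vectors_mm`` are sparse gold-standard displacements (mm, one per
    point) used for endpoint-error evaluation. ``in_bounds`` is filled by
    point transforms that detect samples outside the field extent.
    """

    names: list
    points_mm: np.ndarray
    gold_vectors_mm: Optional[np.ndarray] = None
    in_bounds: Optional[np.ndarray] = None

    def __post_init__(self):
        self.names = list(self.names)
        if len(set(self.names)) != len(self.names):
            raise ValueError("landmark names must be unique")
        self.points_mm = np.asarray(self.points_mm, dtype=float)
        if self.points_mm.ndim != 2 or self.points_mm.shape[0] != len(self.names):
            raise ValueError("points_mm must be (n_points, ndim) matching names")
        if self.gold_vectors_mm is not None:
            self.gold_vectors_mm = np.asarray(self.gold_vectors_mm, dtype=float)
            if self.gold_vectors_mm.shape != self.points_mm.shape:
                raise ValueError("gold_vectors_mm must match points_mm in shape")
        if self.in_bounds is not None:
            self.in_bounds = np.asarray(self.in_bounds, dtype=bool)

    def __len__(self) -> int:
        return len(self.names)

    @property
    def ndim(self) -> int:
        return self.points_mm.shape[1]
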