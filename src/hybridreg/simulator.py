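"""Random gold-standard deformation fields: multiscale affine + elastic.

The simulator manufactures supervision for registration training: it draws a
random affine transform and a multiscale elastic perturbation, composes them
into one displacement field, and (with a configurable probability) switches
to a "large deformation" regime so the network sees displacement scales
comparable to real intersubject anatomical variation.

Conventions: fields are stored in voxel units with spacing carried
alongside; all magnitude statements are in mm. Composition is backward-map:
``compose(outer, inner)(x) = inner(x) + outer(x + inner(x))``, and the
elastic part is applied after (outside) the affine part.
"""
from __future__ import annotations

import math
from dataclasses import dataclass, field
from typing import List, Optional, Sequence, Tuple

import numpy as np
from scipy import ndimage

from .grids import DisplacementField

__all__ = [
    "AffineParams",
    "AffineRanges",
    "ElasticSpec",
    "Regime",
    "SimulatorConfig",
    "desk_simulator",
    "sample_affine",
    "affine_to_field",
    "sample_elastic",
    "compose_fields",
    "sample_deformation",
]


@dataclass
class AffineParams:
    """Affine transform parameters about a centre point (mm).

    ``rotation`` is one angle (degrees) in 2-D and three (about axes 0,1,2)
    in 3-D; ``shear`` has one (2-D) or three (3-D, upper-triangular xy/xz/yz)
    components. The map is translate . rotate . shear . scale about
    ``center``.
    """

    rotation: Tuple[float, ...]
    scale: Tuple[float, ...]
    shear: Tuple[float, ...]
    translation: Tuple[float, ...]
    center: Tuple[float, ...]

    def __post_init__(self):
        if any(s <= 0 for s in self.scale):
            raise ValueError("scale components must be > 0")
        d = len(self.translation)
        if d not in (2, 3) or len(self.scale) != d or len(self.center) != d:
            raise ValueError("inconsistent affine parameter dimensions")
        nrot = 1 if d == 2 else 3
        if len(self.rotation) != nrot or len(self.shear) != nrot:
            raise ValueError(f"rotation/shear must have {nrot} components in {d}-D")

    @property
    def ndim(self) -> int:
        return len(self.translation)

    @classmethod
    def identity(cls, ndim: int, center: Sequence[float] = None) -> "AffineParams":
        nrot = 1 if ndim == 2 else 3
        center = tuple(center) if center is not None else (0.0,) * ndim
        return cls((0.0,) * nrot, (1.0,) * ndim, (0.0,) * nrot, (0.0,) * ndim, center)

    def matrix(self) -> np.ndarray:
        """Linear part: rotation @ shear @ scale."""
        d = self.ndim
        sc = np.diag(self.scale)
        sh = np.eye(d)
        if d == 2:
            sh[0, 1] = self.shear[0]
            a = math.radians(self.rotation[0])
            rot = np.array([[math.cos(a), -math.sin(a)], [math.sin(a), math.cos(a)]])
        else:
            sh[0, 1], sh[0, 2], sh[1, 2] = self.shear
            rot = np.eye(3)
            for axis, ang in enumerate(self.rotation):
                a = math.radians(ang)
                c, s = math.cos(a), math.sin(a)
                r = np.eye(3)
                i, j = [k for k in range(3) if k != axis]
                r[i, i], r[i, j], r[j, i], r[j, j] = c, -s, s, c
                rot = r @ rot  # axis-0 rotation applied first
        return rot @ sh @ sc

    def apply(self, points_mm: np.ndarray) -> np.ndarray:
        c = np.asarray(self.center)
        t = np.asarray(self.translation)
        return (points_mm - c) @ self.matrix().T + c + t


@dataclass
class AffineRanges:
    """Uniform sampling intervals for each affine parameter group."""

    rotation_deg: Tuple[float, float] = (-10.0, 10.0)
    scale: Tuple[float, float] = (0.9, 1.1)
    shear: Tuple[float, float] = (-0.05, 0.05)
    translation_mm: Tuple[float, float] = (-10.0, 10.0)

    def __post_init__(self):
        for name in ("rotation_deg", "scale", "shear", "translation_mm"):
            lo, hi = (float(x) for x in getattr(self, name))
            if not (np.isfinite(lo) and np.isfinite(hi)):
                raise ValueError(f"{name} interval must be finite")
            if lo > hi:
                raise ValueError(f"{name} interval is inverted: ({lo}, {hi})")
            setattr(self, name, (lo, hi))

    @classmethod
    def identity(cls) -> "AffineRanges":
        return cls((0, 0), (1, 1), (0, 0), (0, 0))


@dataclass
class ElasticSpec:
    """Multiscale smooth random displacement specification.

    ``control_spacings`` are coarse-grid node spacings in voxels (one field
    per scale, summed); ``max_displacement`` is the mm magnitude the summed
    field is rescaled to; ``smoothness_sigma`` is the Gaussian smoothing
    width in voxels applied at full resolution.
    """

    control_spacings: List[int] = field(default_factory=lambda: [8, 16, 32])
    max_displacement: float = 5.0
    smoothness_sigma: float = 2.0

    def __post_init__(self):
        if not self.control_spacings:
            raise ValueError("control_spacings must be nonempty")
        if any(s < 2 for s in self.control_spacings):
            raise ValueError("control spacings must be >= 2 voxels")
        if self.max_displacement < 0:
            raise ValueError("max_displacement must be >= 0")


@dataclass
class Regime:
    affine: AffineRanges = field(default_factory=AffineRanges)
    elastic: ElasticSpec = field(default_factory=ElasticSpec)


def _default_large() -> Regime:
    return Regime(
        affine=AffineRanges((-20, 20), (0.8, 1.25), (-0.05, 0.05), (-20, 20)),
        elastic=ElasticSpec(max_displacement=15.0),
    )


@dataclass
class SimulatorConfig:
    """Small/large deformation regimes and the large-regime probability."""

    small: Regime = field(default_factory=Regime)
    large: Regime = field(default_factory=_default_large)
    large_fraction: float = 0.2

    def __post_init__(self):
        if not (0.0 <= self.large_fraction <= 1.0):
            raise ValueError("large_fraction must be in [0, 1]")
        if self.large.elastic.max_displacement < self.small.elastic.max_displacement:
            raise ValueError(
                "large regime max_displacement must be >= small regime's"
            )


def desk_simulator(mm_scale: float = 0.3) -> SimulatorConfig:
    """Deformation regimes scaled to desk-size phantom geometry.

    The default regimes describe head-size (~85 mm brain radius) anatomy; on
    a desk-scale grid (~25 mm brain radius) the same millimetre translations
    and elastic magnitudes would be proportionally far larger than the
    intersubject variation they model, so mm-valued ranges shrink by the
    radius ratio (~0.3). Angles, scales and shears are dimensionless and
    stay unchanged.
    """

    def shrink(r: Regime) -> Regime:
        lo, hi = r.affine.translation_mm
        return Regime(
            affine=AffineRanges(
                rotation_deg=r.affine.rotation_deg,
                scale=r.affine.scale,
                shear=r.affine.shear,
                translation_mm=(lo * mm_scale, hi * mm_scale),
            ),
            elastic=ElasticSpec(
                control_spacings=list(r.elastic.control_spacings),
                max_displacement=r.elastic.max_displacement * mm_scale,
                smoothness_sigma=r.elastic.smoothness_sigma,
            ),
        )

    base = SimulatorConfig()
    return SimulatorConfig(
        small=shrink(base.small), large=shrink(base.large),
        large_fraction=base.large_fraction,
    )


# ---------------------------------------------------------------------------


def sample_affine(
    ranges: AffineRanges,
    rng: np.random.Generator,
    ndim: int = 3,
    center: Optional[Sequence[float]] = None,
) -> AffineParams:
    """Draw affine parameters uniformly from the configured intervals."""
    nrot = 1 if ndim == 2 else 3
    center = tuple(center) if center is not None else (0.0,) * ndim
    return AffineParams(
        rotation=tuple(rng.uniform(*ranges.rotation_deg, nrot)),
        scale=tuple(rng.uniform(*ranges.scale, ndim)),
        shear=tuple(rng.uniform(*ranges.shear, nrot)),
        translation=tuple(rng.uniform(*ranges.translation_mm, ndim)),
        center=center,
    )


def _mm_coords(shape, spacing) -> np.ndarray:
    axes = [np.arange(n) * s for n, s in zip(shape, spacing)]
    return np.stack(np.meshgrid(*axes, indexing="ij"), axis=-1)


def affine_to_field(p: AffineParams, shape, spacing) -> DisplacementField:
    """Dense displacement u(x) = A(x_mm) - x_mm, stored in voxel units."""
    x = _mm_coords(shape, spacing)
    u_mm = p.apply(x.reshape(-1, p.ndim)).reshape(x.shape) - x
    return DisplacementField(u_mm / np.asarray(spacing), tuple(spacing))


def sample_elastic(
    spec: ElasticSpec, shape, spacing, rng: np.random.Generator
) -> DisplacementField:
    """Smooth multiscale random field rescaled to ``max_displacement`` mm.

    Per control spacing, i.i.d. standard-normal per-axis displacements are
    drawn on a coarse node grid, cubically interpolated to full resolution
    and Gaussian-smoothed; scales are summed and the result rescaled so the
    maximum vector magnitude equals ``max_displacement`` exactly (zero input
    magnitude gives the zero field).
    """
    shape = tuple(int(n) for n in shape)
    d = len(shape)
    total_mm = np.zeros(shape + (d,))
    for s in spec.control_spacings:
        coarse = tuple(max(int(math.ceil((n - 1) / s)) + 1, 2) for n in shape)
        noise = rng.standard_normal(coarse + (d,))
        coords = np.meshgrid(
            *[np.arange(n) / s for n in shape], indexing="ij"
        )
        for k in range(d):
            comp = ndimage.map_coordinates(
                noise[..., k], np.stack(coords), order=3, mode="nearest"
            )
            if spec.smoothness_sigma > 0:
                comp = ndimage.gaussian_filter(comp, spec.smoothness_sigma)
            total_mm[..., k] += comp
    mags = np.sqrt((total_mm**2).sum(axis=-1))
    peak = float(mags.max())
    if peak > 0 and spec.max_displacement > 0:
        total_mm *= spec.max_displacement / peak
    else:
        total_mm[:] = 0.0
    return DisplacementField(total_mm / np.asarray(spacing, dtype=float), tuple(spacing))


def compose_fields(outer: DisplacementField, inner: DisplacementField) -> DisplacementField:
    """Backward-map composition: u(x) = inner(x) + outer(x + inner(x)).

    Sequential warping with (outer, then inner) equals a single warp with
    the composed field. ``outer`` is sampled with linear interpolation,
    border-clamped.
    """
    if outer.spatial_shape != inner.spatial_shape or outer.spacing != inner.spacing:
        raise ValueError("fields must share shape and spacing to compose")
    shape = inner.spatial_shape
    grid = np.stack(
        np.meshgrid(*[np.arange(n, dtype=float) for n in shape], indexing="ij"), axis=-1
    )
    coords = np.moveaxis(grid + inner.vectors, -1, 0)
    sampled = np.stack(
        [
            ndimage.map_coordinates(outer.vectors[..., k], coords, order=1, mode="nearest")
            for k in range(inner.ndim)
        ],
        axis=-1,
    )
    return DisplacementField(inner.vectors + sampled, inner.spacing)


def sample_deformation_parts(
    cfg: SimulatorConfig, shape, spacing, rng: np.random.Generator
) -> Tuple[DisplacementField, str, DisplacementField, DisplacementField]:
    """Draw one gold-standard field; returns (field, label, affine, elastic).

    With probability ``large_fraction`` the large regime is used. The affine
    part is centred on the grid's physical centre; the elastic part is
    composed outside the affine part. The separate parts support analyses
    such as the affine-only recovery ceiling.
    """
    label = "large" if rng.random() < cfg.large_fraction else "small"
    regime = cfg.large if label == "large" else cfg.small
    shape = tuple(int(n) for n in shape)
    center = (np.array(shape) - 1) * np.asarray(spacing, dtype=float) / 2.0
    aff = sample_affine(regime.affine, rng, ndim=len(shape), center=center)
    f_aff = affine_to_field(aff, shape, spacing)
    f_ela = sample_elastic(regime.elastic, shape, spacing, rng)
    return compose_fields(f_ela, f_aff), label, f_aff, f_ela


def sample_deformation(
    cfg: SimulatorConfig, shape, spacing, rng: np.random.Generator
) -> Tuple[DisplacementField, str]:
    """Draw one gold-standard field; returns (field, regime label)."""
    field, label, _, _ = sample_deformation_parts(cfg, shape, spacing, rng)
    return field, label
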