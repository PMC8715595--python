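"""Synthetic skull-bearing brain-CT phantoms with territory labels and landmarks.

Clinical head-CT registration data are rarely shareable, so the rest of the
package is exercised on phantoms: an ellipsoidal head with a bone shell
(skull), uniform brain tissue, a pair of elongated CSF-filled ventricles, an
MCA-territory-like sector label, and deterministic point landmarks placed on
constructed anatomical features (ventricle horn tips plus an interior ring).
Intersubject anatomical variation is emulated by jittering the geometry
parameters before rasterization.

Geometry and noise use separate, explicitly threaded random streams so that
a subject with ``variation_scale = 0`` is bit-identical to the unjittered
phantom at the same seed.
"""
from __future__ import annotations

import math
from dataclasses import dataclass, field, replace
from typing import List, Tuple

import numpy as np

from .grids import LabelMask, LandmarkSet, Volume

__all__ = [
    "PhantomSpec",
    "Subject",
    "InvalidSpecError",
    "generate_phantom",
    "generate_subject",
    "generate_cohort",
    "desk_spec_2d",
    "desk_spec_3d",
    "paper_scale_spec",
]


class InvalidSpecError(ValueError):
    """Raised when the requested geometry cannot fit on the grid."""


@dataclass
class PhantomSpec:
    """Geometry and intensity palette for one phantom family.

    All physical quantities are millimetres; HU values are Hounsfield units.
    ``variation_scale`` in [0, 1] scales the intersubject geometry jitter
    used by :func:`generate_subject`.
    """

    grid_shape: Tuple[int, ...] = (64, 64, 16)
    spacing: Tuple[float, ...] = (1.0, 1.0, 2.0)
    head_radii: Tuple[float, ...] = (26.0, 22.0, 13.0)
    skull_thickness: float = 3.0
    skull_hu: float = 1000.0
    brain_hu: float = 35.0
    csf_hu: float = 8.0
    background_hu: float = -1000.0
    ventricle_offset: Tuple[float, ...] = (6.0, 2.0, 0.0)
    ventricle_radii: Tuple[float, ...] = (3.5, 9.0, 4.0)
    territory_half_angle_deg: float = 55.0
    territory_radial_band: Tuple[float, float] = (0.25, 0.92)
    noise_sd: float = 4.0
    n_landmarks: int = 8
    variation_scale: float = 0.3

    def __post_init__(self):
        self.grid_shape = tuple(int(n) for n in self.grid_shape)
        nd = len(self.grid_shape)
        if nd not in (2, 3):
            raise InvalidSpecError("grid_shape must be 2-D or 3-D")
        for name in ("spacing", "head_radii", "ventricle_offset", "ventricle_radii"):
            v = tuple(float(x) for x in getattr(self, name))
            if len(v) != nd:
                raise InvalidSpecError(f"{name} must have length {nd}")
            setattr(self, name, v)
        if any(r <= 0 for r in self.head_radii + self.ventricle_radii):
            raise InvalidSpecError("all radii must be > 0")
        if not (self.skull_hu > self.brain_hu > self.csf_hu):
            raise InvalidSpecError("CT contrast ordering requires skull_hu > brain_hu > csf_hu")
        if self.n_landmarks < 4:
            raise InvalidSpecError("n_landmarks must be >= 4")
        if not (0.0 <= self.variation_scale <= 1.0):
            raise InvalidSpecError("variation_scale must be in [0, 1]")
        if self.noise_sd < 0:
            raise InvalidSpecError("noise_sd must be >= 0")
        self.territory_radial_band = tuple(float(x) for x in self.territory_radial_band)
        self._check_fit(self._geometry())

    @property
    def ndim(self) -> int:
        return len(self.grid_shape)

    def extent_mm(self) -> np.ndarray:
        return (np.array(self.grid_shape) - 1) * np.array(self.spacing)

    def _geometry(self) -> dict:
        center = self.extent_mm() / 2.0
        off = np.array(self.ventricle_offset)
        return dict(
            center=center,
            head_radii=np.array(self.head_radii),
            skull_thickness=float(self.skull_thickness),
            vent_centers=np.stack([center + off * s for s in (+1, -1)]),
            vent_radii=np.stack([np.array(self.ventricle_radii)] * 2),
            territory_half_angle=float(self.territory_half_angle_deg),
            territory_band=tuple(self.territory_radial_band),
        )

    def _check_fit(self, geo: dict):
        center, radii = geo["center"], geo["head_radii"]
        if np.any(center - radii < -1e-9) or np.any(center + radii > self.extent_mm() + 1e-9):
            raise InvalidSpecError(
                f"head radii {tuple(radii)} mm do not fit the grid extent "
                f"{tuple(self.extent_mm())} mm"
            )
        inner = radii - geo["skull_thickness"]
        if np.any(inner <= 0):
            raise InvalidSpecError("skull thickness exceeds a head radius")
        for vc, vr in zip(geo["vent_centers"], geo["vent_radii"]):
            margin = np.linalg.norm((vc - center) / inner) + float(np.max(vr / inner))
            if margin > 0.95:
                raise InvalidSpecError("a ventricle does not fit inside the brain")


@dataclass
class Subject:
    """One generated phantom: image, labels and landmarks (tuple-unpackable)."""

    volume: Volume
    territory_mask: LabelMask
    brain_mask: LabelMask
    landmarks: LandmarkSet

    def __iter__(self):
        return iter((self.volume, self.territory_mask, self.brain_mask, self.landmarks))


# ---------------------------------------------------------------------------


def _mm_grid(spec: PhantomSpec) -> List[np.ndarray]:
    axes = [np.arange(n) * s for n, s in zip(spec.grid_shape, spec.spacing)]
    return np.meshgrid(*axes, indexing="ij")


def _ellipsoid(mm, center, radii) -> np.ndarray:
    q = sum(((g - c) / r) ** 2 for g, c, r in zip(mm, center, radii))
    return q <= 1.0


def _ring_points(n: int, ndim: int) -> np.ndarray:
    """Deterministic unit directions: golden-angle ring (2-D) / Fibonacci sphere."""
    if n == 0:
        return np.zeros((0, ndim))
    if ndim == 2:
        theta = (np.arange(n) + 0.5) * (math.pi * (3 - math.sqrt(5)))
        return np.stack([np.cos(theta), np.sin(theta)], axis=1)
    i = np.arange(n) + 0.5
    z = 1 - 2 * i / n
    r = np.sqrt(np.clip(1 - z**2, 0, 1))
    theta = i * math.pi * (3 - math.sqrt(5))
    return np.stack([r * np.cos(theta), r * np.sin(theta), z], axis=1)


def _rasterize(spec: PhantomSpec, geo: dict, rng_noise: np.random.Generator) -> Subject:
    mm = _mm_grid(spec)
    center, radii = geo["center"], geo["head_radii"]
    inner_radii = radii - geo["skull_thickness"]
    head = _ellipsoid(mm, center, radii)
    brain = _ellipsoid(mm, center, inner_radii)
    skull = head & ~brain
    vents = np.zeros_like(brain)
    for vc, vr in zip(geo["vent_centers"], geo["vent_radii"]):
        vents |= _ellipsoid(mm, vc, vr)
    vents &= brain

    values = np.full(spec.grid_shape, spec.background_hu, dtype=float)
    values[brain] = spec.brain_hu
    values[vents] = spec.csf_hu
    values[skull] = spec.skull_hu
    if spec.noise_sd > 0:
        # truncated at +-3 sd so tissue HU ranges stay disjoint
        noise = rng_noise.normal(0.0, spec.noise_sd, size=spec.grid_shape)
        values = values + np.clip(noise, -3 * spec.noise_sd, 3 * spec.noise_sd)
    else:
        rng_noise.normal(0.0, 1.0, size=1)  # keep the stream position fixed

    # territory: angular sector of the brain on the +axis0 side, ventricles cut out
    rel = np.stack([(g - c) for g, c in zip(mm, center)], axis=-1)
    rho = np.sqrt(((rel / inner_radii) ** 2).sum(axis=-1))
    norm = np.linalg.norm(rel, axis=-1)
    with np.errstate(invalid="ignore", divide="ignore"):
        cosang = np.where(norm > 0, rel[..., 0] / np.maximum(norm, 1e-12), 1.0)
    lo, hi = geo["territory_band"]
    territory = (
        brain
        & ~vents
        & (cosang >= math.cos(math.radians(geo["territory_half_angle"])))
        & (rho >= lo)
        & (rho <= hi)
    )

    # landmarks sit on constructed anatomical features: 4 ventricle horn
    # tips along the elongation axis, then skull-inner (brain boundary)
    # points at deterministic golden-angle directions
    pts, names = [], []
    elong = int(np.argmax(geo["vent_radii"][0]))
    for vi, (vc, vr) in enumerate(zip(geo["vent_centers"], geo["vent_radii"])):
        for s, tag in ((+1, "ant"), (-1, "post")):
            p = vc.copy()
            p[elong] += s * 0.9 * vr[elong]
            pts.append(p)
            names.append(f"vent{vi}_horn_{tag}")
    n_extra = spec.n_landmarks - len(pts)
    for j, d in enumerate(_ring_points(max(n_extra, 0), spec.ndim)):
        pts.append(center + d * inner_radii * 0.88)
        names.append(f"skull_inner{j}")
    pts = np.array(pts[: max(spec.n_landmarks, 4)])
    names = names[: max(spec.n_landmarks, 4)]

    # landmarks must lie strictly inside the brain mask
    vox = np.round(pts / np.array(spec.spacing)).astype(int)
    inside = brain[tuple(vox.T)]
    if not inside.all():
        raise InvalidSpecError("a landmark fell outside the brain mask; geometry too tight")

    vol = Volume(values, spec.spacing, intensity_domain="HU")
    return Subject(
        volume=vol,
        territory_mask=LabelMask(territory.astype(np.uint8), spec.spacing),
        brain_mask=LabelMask(brain.astype(np.uint8), spec.spacing),
        landmarks=LandmarkSet(names, pts),
    )


def _streams(seed: int):
    geo = np.random.default_rng([int(seed), 17])
    noise = np.random.default_rng([int(seed), 23])
    return geo, noise


def generate_phantom(spec: PhantomSpec, seed: int) -> Subject:
    """Rasterize the unjittered phantom geometry; deterministic in (spec, seed)."""
    _, rng_noise = _streams(seed)
    return _rasterize(spec, spec._geometry(), rng_noise)


def _jitter(spec: PhantomSpec, geo: dict, rng: np.random.Generator) -> dict:
    vs = spec.variation_scale
    geo = dict(geo)
    geo["center"] = geo["center"] + vs * rng.uniform(-2.0, 2.0, spec.ndim)
    geo["head_radii"] = geo["head_radii"] * (1 + vs * rng.uniform(-0.2, 0.2, spec.ndim))
    centers, radii = [], []
    for vc, vr in zip(geo["vent_centers"], geo["vent_radii"]):
        centers.append(vc + vs * rng.uniform(-2.0, 2.0, spec.ndim))
        radii.append(vr * (1 + vs * rng.uniform(-0.3, 0.3, spec.ndim)))
    geo["vent_centers"] = np.stack(centers)
    geo["vent_radii"] = np.stack(radii)
    geo["territory_half_angle"] = geo["territory_half_angle"] + vs * rng.uniform(-10, 10)
    return geo


def generate_subject(spec: PhantomSpec, seed: int) -> Subject:
    """Phantom with variation_scale-proportional geometry jitter.

    ``variation_scale = 0`` reproduces :func:`generate_phantom` exactly.
    """
    rng_geo, rng_noise = _streams(seed)
    geo = _jitter(spec, spec._geometry(), rng_geo)
    spec._check_fit(geo)
    return _rasterize(spec, geo, rng_noise)


def subject_seed(seed: int, index: int) -> int:
    """Deterministic per-subject seed derived from (cohort seed, index)."""
    ss = np.random.SeedSequence([int(seed), int(index)])
    return int(ss.generate_state(1)[0] % (2**31))


def generate_cohort(spec: PhantomSpec, n: int, seed: int) -> List[Subject]:
    """Generate ``n`` mutually distinct subjects with derived per-subject seeds."""
    if n < 1:
        raise ValueError("cohort size must be >= 1")
    return [generate_subject(spec, subject_seed(seed, i)) for i in range(n)]


# -- presets ----------------------------------------------------------------


def desk_spec_3d(**overrides) -> PhantomSpec:
    """Desk-scale 3-D phantom (64x64x16 at 1x1x2 mm)."""
    return replace(PhantomSpec(), **overrides) if overrides else PhantomSpec()


def desk_spec_2d(**overrides) -> PhantomSpec:
    """Desk-scale 2-D phantom (64x64 at 1x1 mm) for CPU-budget experiments."""
    base = PhantomSpec(
        grid_shape=(64, 64),
        spacing=(1.0, 1.0),
        head_radii=(27.0, 23.0),
        ventricle_offset=(6.0, 2.0),
        ventricle_radii=(3.5, 9.0),
    )
    return replace(base, **overrides) if overrides else base


def paper_scale_spec(**overrides) -> PhantomSpec:
    """Full-scale preset (512x512x64 at 0.36x0.36x2 mm); not used in tests."""
    base = PhantomSpec(
        grid_shape=(512, 512, 64),
        spacing=(0.36, 0.36, 2.0),
        head_radii=(78.0, 88.0, 55.0),
        skull_thickness=5.0,
        ventricle_offset=(14.0, 6.0, 0.0),
        ventricle_radii=(8.0, 24.0, 12.0),
    )
    return replace(base, **overrides) if overrides else base
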