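"""The hybrid registration loss and its three sub-losses.

total = alpha * L_F + beta * L_M0 + gamma * L_M1

* ``L_F`` — mean Euclidean deviation (mm) between the predicted and
  gold-standard displacement fields, averaged over all voxels. Computed in
  mm so anisotropic spacing weights the axes physically.
* ``L_M0`` / ``L_M1`` — negated mean of the squared local windowed
  normalized cross-correlation between a reference image and the image
  warped by the predicted field (supervised and self-supervised pair
  respectively). Windows are cubes of half-width ``radius`` centred at every
  voxel with border-clamped neighbourhoods; a small epsilon in the
  denominator makes constant windows contribute ~0 instead of dividing by
  zero.

Defaults: alpha = 1/13, beta = gamma = 0.4, balancing the three terms'
contributions to the gradient.

This module holds the plain-numpy implementations used for evaluation and
testing; :func:`ad_field_loss` / :func:`ad_local_sq_ncc_loss` are the
autodiff twins used inside the training loop and are tested to agree with
these to floating precision.
"""
from __future__ import annotations

from dataclasses import dataclass
from typing import Dict, Tuple, Union

import numpy as np
from scipy import ndimage

from . import autodiff as ad
from .grids import DisplacementField, Volume

__all__ = [
    "LossWeights",
    "SimilarityWindow",
    "field_loss",
    "local_sq_ncc_loss",
    "hybrid_loss",
    "ad_field_loss",
    "ad_local_sq_ncc_loss",
]

ArrayLike = Union[Volume, np.ndarray]


@dataclass(frozen=True)
class LossWeights:
    """Balancing hyperparameters of the hybrid loss."""

    alpha: float = 1.0 / 13.0
    beta: float = 0.4
    gamma: float = 0.4

    def __post_init__(self):
        for name in ("alpha", "beta", "gamma"):
            v = getattr(self, name)
            if not np.isfinite(v) or v < 0:
                raise ValueError(f"{name} must be finite and >= 0")


@dataclass(frozen=True)
class SimilarityWindow:
    """Window geometry for the local squared-NCC similarity."""

    radius: int = 4
    epsilon: float = 1e-5

    def __post_init__(self):
        if self.radius < 1:
            raise ValueError("radius must be >= 1")
        if self.epsilon <= 0:
            raise ValueError("epsilon must be > 0")


def _values(x: ArrayLike) -> np.ndarray:
    return np.asarray(x.values if isinstance(x, Volume) else x, dtype=float)


def field_loss(pred: DisplacementField, gold: DisplacementField) -> float:
    """Mean L2 deviation (mm) between two displacement fields."""
    if pred.spatial_shape != gold.spatial_shape:
        raise ValueError(
            f"field shape mismatch: {pred.spatial_shape} vs {gold.spatial_shape}"
        )
    if pred.spacing != gold.spacing:
        raise ValueError(f"field spacing mismatch: {pred.spacing} vs {gold.spacing}")
    diff_mm = (pred.vectors - gold.vectors) * np.asarray(pred.spacing)
    return float(np.sqrt((diff_mm**2).sum(axis=-1)).mean())


def _window_moments(a: np.ndarray, b: np.ndarray, radius: int):
    """Window sums of a, b, ab, a^2, b^2 with edge-clamped borders."""
    size = 2 * radius + 1
    n = float(size ** a.ndim)

    def wsum(x):
        return ndimage.uniform_filter(x, size=size, mode="nearest") * n

    sa, sb = wsum(a), wsum(b)
    cross = wsum(a * b) - sa * sb / n
    va = wsum(a * a) - sa * sa / n
    vb = wsum(b * b) - sb * sb / n
    return cross, va, vb


def local_sq_ncc_loss(ref: ArrayLike, pred: ArrayLike, w: SimilarityWindow = SimilarityWindow()) -> float:
    """Negated mean squared local NCC; in (-1, 0] for epsilon -> 0."""
    a, b = _values(ref), _values(pred)
    if a.shape != b.shape:
        raise ValueError(f"image shape mismatch: {a.shape} vs {b.shape}")
    cross, va, vb = _window_moments(a, b, w.radius)
    return float(-(cross**2 / (va * vb + w.epsilon)).mean())


def hybrid_loss(
    Fp0: DisplacementField,
    Fg0: DisplacementField,
    I0: ArrayLike,
    Ip0: ArrayLike,
    I1: ArrayLike,
    Ip1: ArrayLike,
    wts: LossWeights = LossWeights(),
    w: SimilarityWindow = SimilarityWindow(),
) -> Tuple[float, Dict[str, float]]:
    """Weighted sum of the three sub-losses; parts returned for logging."""
    parts = {
        "L_F": field_loss(Fp0, Fg0),
        "L_M0": local_sq_ncc_loss(I0, Ip0, w),
        "L_M1": local_sq_ncc_loss(I1, Ip1, w),
    }
    total = wts.alpha * parts["L_F"] + wts.beta * parts["L_M0"] + wts.gamma * parts["L_M1"]
    return float(total), parts


# -- autodiff twins (training path) -----------------------------------------


def ad_field_loss(pred: ad.Tensor, gold: DisplacementField) -> ad.Tensor:
    """Differentiable mean L2 field deviation (mm); pred shape (*S, d)."""
    sp = np.asarray(gold.spacing, dtype=pred.data.dtype)
    diff = (pred - ad.Tensor(gold.vectors.astype(pred.data.dtype))) * ad.Tensor(sp)
    # tiny floor keeps sqrt differentiable at exact zero deviation
    return (diff.square().sum(axis=-1) + 1e-12).sqrt().mean()


def ad_local_sq_ncc_loss(
    ref: np.ndarray, pred: ad.Tensor, w: SimilarityWindow = SimilarityWindow()
) -> ad.Tensor:
    """Differentiable twin of :func:`local_sq_ncc_loss` (gradient w.r.t. pred)."""
    r = w.radius
    n = float((2 * r + 1) ** ref.ndim)
    a = ad.Tensor(np.asarray(ref, dtype=pred.data.dtype))
    b = pred
    sa, sb = ad.boxsum(a, r), ad.boxsum(b, r)
    cross = ad.boxsum(a * b, r) - sa * sb * (1.0 / n)
    va = ad.boxsum(a.square(), r) - sa.square() * (1.0 / n)
    vb = ad.boxsum(b.square(), r) - sb.square() * (1.0 / n)
    return -((cross.square() / (va * vb + w.epsilon)).mean())
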