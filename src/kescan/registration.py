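"""Volumetric alignment of the below-edge scan onto the above-edge frame.

The two scans image the same object at two energies, so their intensities
are monotonically related and correlation-based similarity suffices.
Translation is estimated by spectral phase correlation with sub-voxel
upsampling; an optional coarse per-axis scale search handles radiation
induced shrinkage.  The convention throughout is that the 16.5 keV
(below-edge) volume moves onto the 17.2 keV (above-edge) frame, which
stays untouched.
"""

from __future__ import annotations

from dataclasses import dataclass

import numpy as np
import scipy.ndimage as ndi
from skimage.registration import phase_cross_correlation

__all__ = ["RigidScaleTransform", "EstimationError", "estimate_transform", "resample"]

_SCALE_BOUNDS = (0.8, 1.2)


class EstimationError(ValueError):
    """Raised when a transform cannot be estimated (e.g. constant input)."""


@dataclass(frozen=True)
class RigidScaleTransform:
    """Per-axis translation (voxels) plus per-axis scale about the origin.

    The forward content map is x ↦ scale·x + translation in (z, y, x)
    voxel coordinates.
    """

    translation: tuple[float, float, float] = (0.0, 0.0, 0.0)
    scale: tuple[float, float, float] = (1.0, 1.0, 1.0)

    def __post_init__(self) -> None:
        if len(self.translation) != 3 or len(self.scale) != 3:
            raise ValueError("translation and scale must be length-3")
        lo, hi = _SCALE_BOUNDS
        if any(not (lo < s < hi) for s in self.scale):
            raise ValueError(f"scale factors must lie in ({lo}, {hi})")
        object.__setattr__(self, "translation", tuple(float(t) for t in self.translation))
        object.__setattr__(self, "scale", tuple(float(s) for s in self.scale))

    @property
    def is_identity(self) -> bool:
        return all(t == 0.0 for t in self.translation) and all(
            s == 1.0 for s in self.scale
        )

    def inverse(self) -> "RigidScaleTransform":
        inv_scale = tuple(1.0 / s for s in self.scale)
        inv_trans = tuple(-t / s for t, s in zip(self.translation, self.scale))
        return RigidScaleTransform(inv_trans, inv_scale)

    def compose(self, other: "RigidScaleTransform") -> "RigidScaleTransform":
        """Transform equivalent to applying ``other`` first, then ``self``."""
        scale = tuple(s1 * s2 for s1, s2 in zip(self.scale, other.scale))
        trans = tuple(
            s1 * t2 + t1
            for s1, t2, t1 in zip(self.scale, other.translation, self.translation)
        )
        return RigidScaleTransform(trans, scale)

    def apply_to_points(self, points: np.ndarray) -> np.ndarray:
        pts = np.asarray(points, dtype=float)
        return pts * np.asarray(self.scale) + np.asarray(self.translation)


def resample(moving: np.ndarray, transform: RigidScaleTransform) -> np.ndarray:
    """Resample ``moving`` under the forward content map of ``transform``.

    Linear interpolation; voxels pulled from outside the field of view are
    zero-filled.  Output shape equals input shape.
    """
    moving = np.asarray(moving, dtype=np.float32)
    if transform.is_identity:
        return moving.copy()
    inv = transform.inverse()
    # output(x) = moving(inv.scale·x + inv.translation)
    out = ndi.affine_transform(
        moving,
        matrix=np.asarray(inv.scale),
        offset=np.asarray(inv.translation),
        order=1,
        mode="constant",
        cval=0.0,
        output=np.float32,
    )
    return out


def _ncc(a: np.ndarray, b: np.ndarray) -> float:
    a = a.ravel() - a.mean()
    b = b.ravel() - b.mean()
    denom = np.linalg.norm(a) * np.linalg.norm(b)
    if denom == 0:
        return 0.0
    return float(np.dot(a, b) / denom)


def estimate_transform(
    moving: np.ndarray,
    fixed: np.ndarray,
    upsample_factor: int = 10,
    estimate_scale: bool = False,
    scale_candidates: np.ndarray | None = None,
) -> RigidScaleTransform:
    """Estimate the transform aligning ``moving`` onto ``fixed``.

    Translation comes from phase correlation at sub-voxel precision.  With
    ``estimate_scale`` a coarse per-axis grid search over ``scale_candidates``
    (default 0.99…1.01) maximizes normalized cross-correlation, re-estimating
    translation for each candidate.
    """
    moving = np.asarray(moving, dtype=np.float32)
    fixed = np.asarray(fixed, dtype=np.float32)
    if moving.shape != fixed.shape:
        raise ValueError("moving and fixed must have the same shape")
    if np.ptp(moving) == 0 or np.ptp(fixed) == 0:
        raise EstimationError("constant volume: no structure to register")

    def translation_for(mov: np.ndarray) -> tuple[float, float, float]:
        shift, _, _ = phase_cross_correlation(
            fixed, mov, upsample_factor=upsample_factor, normalization=None
        )
        return tuple(float(s) for s in shift)

    if not estimate_scale:
        return RigidScaleTransform(translation=translation_for(moving))

    if scale_candidates is None:
        scale_candidates = np.array([0.99, 0.995, 1.0, 1.005, 1.01])
    best_scale = [1.0, 1.0, 1.0]
    # Per-axis sweeps, other axes held at current best.
    for axis in range(3):
        best_score = -np.inf
        best_s = 1.0
        for s in scale_candidates:
            trial_scale = list(best_scale)
            trial_scale[axis] = float(s)
            scaled = resample(moving, RigidScaleTransform(scale=tuple(trial_scale)))
            t = translation_for(scaled)
            aligned = resample(
                moving, RigidScaleTransform(translation=t, scale=tuple(trial_scale))
            )
            score = _ncc(aligned, fixed)
            if score > best_score:
                best_score = score
                best_s = float(s)
        best_scale[axis] = best_s
    scaled = resample(moving, RigidScaleTransform(scale=tuple(best_scale)))
    translation = translation_for(scaled)
    return RigidScaleTransform(translation=translation, scale=tuple(best_scale))
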