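"""Five-threshold morphological segmentation of K-edge material.

The protocol isolates voxels whose dual-energy subtraction signal is due
to the target element while rejecting two confounders: paired bright/dark
rims caused by inter-scan shrinkage (handled by a dilated negative-value
mask) and shifted high-Z mineral inclusions (handled by a high cut on the
above-edge volume intersected with the subtraction mask).

Stages, with their conventional letter names:

========  =============================================================
A         above-edge volume ≥ 3.8 cm⁻¹ (candidate K-edge material)
B         above-edge volume ≥ 12 cm⁻¹ (high-Z minerals)
C         subtraction volume ≥ 3 cm⁻¹
D         subtraction volume < 0, dilated once in 3D (shift artifacts)
E         below-edge volume in [3, 4] cm⁻¹ (optional extra exclusion)
f         (A ∧ C) − D
g         26-connectivity dilation of f
h         g ∧ C
i         h − (B ∧ C)            [final mask]
========  =============================================================

"×" in the protocol is voxelwise AND of binary masks, "−" is set
difference (x ∧ ¬y); thresholds are inclusive ("no less than").
"""

from __future__ import annotations

from dataclasses import dataclass, field

import numpy as np
import scipy.ndimage as ndi

from kescan.subtraction import SubtractionVolume

__all__ = [
    "SegmentationParams",
    "BinaryMask",
    "RegionInfo",
    "LabelResult",
    "STRUCT_26",
    "threshold_mask",
    "dilate26",
    "shift_artifact_mask",
    "segment_yttria",
    "label_regions",
    "dice",
]

#: Full 3×3×3 structuring element: all 26 face/edge/corner neighbours.
STRUCT_26 = np.ones((3, 3, 3), dtype=bool)


@dataclass(frozen=True)
class SegmentationParams:
    """Thresholds (cm⁻¹) and protocol options.

    ``h_rule`` selects how stage h is derived from g: ``"table2"`` keeps
    g ∧ C (the canonical reading); ``"text"`` removes C from g instead
    (g ∧ ¬C).  ``use_threshold_E`` adds (E ∧ C) to the final exclusion.
    """

    threshold_A: float = 3.8
    threshold_B: float = 12.0
    threshold_C: float = 3.0
    threshold_D_cutoff: float = 0.0
    threshold_E: tuple[float, float] = (3.0, 4.0)
    dilation_iterations: int = 1
    h_rule: str = "table2"
    use_threshold_E: bool = False

    def __post_init__(self) -> None:
        if self.threshold_A <= 0 or self.threshold_B <= 0 or self.threshold_C <= 0:
            raise ValueError("thresholds A, B, C must be positive")
        if self.threshold_B <= self.threshold_A:
            raise ValueError("threshold B must exceed threshold A")
        if self.threshold_E[0] > self.threshold_E[1]:
            raise ValueError("threshold E lower bound must not exceed upper bound")
        if self.dilation_iterations < 0:
            raise ValueError("dilation iterations must be >= 0")
        if self.h_rule not in ("table2", "text"):
            raise ValueError("h_rule must be 'table2' or 'text'")


@dataclass(frozen=True)
class BinaryMask:
    """A {0,1} voxel mask with a stage label (A…E, f…i)."""

    data: np.ndarray
    label: str = ""

    def __post_init__(self) -> None:
        object.__setattr__(self, "data", np.asarray(self.data, dtype=bool))

    @property
    def shape(self) -> tuple[int, ...]:
        return self.data.shape

    @property
    def voxel_count(self) -> int:
        return int(self.data.sum())

    def __and__(self, other: "BinaryMask") -> "BinaryMask":
        return BinaryMask(self.data & other.data)

    def __sub__(self, other: "BinaryMask") -> "BinaryMask":
        return BinaryMask(self.data & ~other.data)

    def __or__(self, other: "BinaryMask") -> "BinaryMask":
        return BinaryMask(self.data | other.data)


def _as_array(volume) -> np.ndarray:
    if isinstance(volume, SubtractionVolume):
        return volume.data
    if isinstance(volume, BinaryMask):
        return volume.data
    return np.asarray(volume)


def threshold_mask(
    volume,
    lower: float,
    upper: float | None = None,
    label: str = "",
) -> BinaryMask:
    """Voxels with ``lower ≤ value`` (and ``value ≤ upper`` when bounded).

    Both bounds are inclusive.
    """
    if upper is not None and lower > upper:
        raise ValueError("lower bound exceeds upper bound")
    data = _as_array(volume)
    mask = data >= lower
    if upper is not None:
        mask &= data <= upper
    return BinaryMask(mask, label=label)


def dilate26(mask: BinaryMask, iterations: int = 1) -> BinaryMask:
    """Morphological dilation with the full 26-neighbour structuring element."""
    if iterations < 0:
        raise ValueError("iterations must be >= 0")
    if iterations == 0:
        return BinaryMask(mask.data.copy(), label=mask.label)
    out = ndi.binary_dilation(mask.data, structure=STRUCT_26, iterations=iterations)
    return BinaryMask(out, label=mask.label)


def shift_artifact_mask(sub: SubtractionVolume, params: SegmentationParams | None = None) -> BinaryMask:
    """Stage D: dark (negative Δµ) voxels dilated once in 3D.

    Shrinkage or shift between the two scans produces paired dark/bright
    rims in the subtraction; dilating the dark half covers the adjacent
    spurious bright half.
    """
    params = params or SegmentationParams()
    negative = BinaryMask(_as_array(sub) < params.threshold_D_cutoff, label="D")
    return BinaryMask(dilate26(negative, 1).data, label="D")


def segment_yttria(
    above: np.ndarray,
    below: np.ndarray,
    sub: SubtractionVolume,
    params: SegmentationParams | None = None,
    full_output: bool = False,
):
    """Run the full threshold/dilation/mask-arithmetic chain.

    Returns the final mask (stage i), or ``(mask, stages)`` with every
    intermediate when ``full_output`` is set.
    """
    params = params or SegmentationParams()
    above = np.asarray(above)
    below = np.asarray(below)
    sub_data = _as_array(sub)
    if not (above.shape == below.shape == sub_data.shape):
        raise ValueError("above, below and subtraction volumes must share a shape")
    if not isinstance(sub, SubtractionVolume):
        sub = SubtractionVolume(data=sub_data)

    A = threshold_mask(above, params.threshold_A, label="A")
    B = threshold_mask(above, params.threshold_B, label="B")
    C = threshold_mask(sub_data, params.threshold_C, label="C")
    D = shift_artifact_mask(sub, params)
    E = threshold_mask(below, params.threshold_E[0], params.threshold_E[1], label="E")

    f = BinaryMask(((A & C) - D).data, label="f")
    g = BinaryMask(dilate26(f, params.dilation_iterations).data, label="g")
    if params.h_rule == "table2":
        h = BinaryMask((g & C).data, label="h")
    else:  # literal text reading: remove high subtraction values from g
        h = BinaryMask((g - C).data, label="h")
    exclusion = B & C
    if params.use_threshold_E:
        exclusion = exclusion | (E & C)
    i = BinaryMask((h - exclusion).data, label="i")

    if full_output:
        stages = {m.label: m for m in (A, B, C, D, E, f, g, h, i)}
        return i, stages
    return i


@dataclass(frozen=True)
class RegionInfo:
    region_id: int
    voxel_count: int
    bounding_box: tuple[tuple[int, int], ...]  # per-axis (start, stop)


@dataclass(frozen=True)
class LabelResult:
    labels: np.ndarray
    regions: tuple[RegionInfo, ...] = field(default_factory=tuple)

    @property
    def n_regions(self) -> int:
        return len(self.regions)


def label_regions(mask: BinaryMask) -> LabelResult:
    """26-connectivity connected-component labelling with per-region counts."""
    labels, n = ndi.label(mask.data, structure=STRUCT_26)
    regions = []
    if n:
        counts = np.bincount(labels.ravel())[1:]
        slices = ndi.find_objects(labels)
        for rid, (count, slc) in enumerate(zip(counts, slices), start=1):
            bbox = tuple((s.start, s.stop) for s in slc)
            regions.append(RegionInfo(region_id=rid, voxel_count=int(count), bounding_box=bbox))
    return LabelResult(labels=labels, regions=tuple(regions))


def dice(a: BinaryMask | np.ndarray, b: BinaryMask | np.ndarray) -> float:
    """Dice overlap 2|X∩Y| / (|X|+|Y|); defined as 1.0 for two empty masks."""
    a = _as_array(a).astype(bool)
    b = _as_array(b).astype(bool)
    denom = int(a.sum()) + int(b.sum())
    if denom == 0:
        return 1.0
    return 2.0 * int((a & b).sum()) / denom
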