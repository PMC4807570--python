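"""Voxelwise concentration mapping from the dual-energy subtraction signal.

Inside the segmented mask, concentration follows the simplified KES
relation C = 1000·Δµ / Δ(µ/ρ): Δµ in cm⁻¹, the K-edge mass-attenuation
difference in cm²/g, output in mg/cc.  The relation assumes all of Δµ in
a voxel is attributable to the target element, which is why the map is
defined as zero outside the mask by default.
"""

from __future__ import annotations

import logging
from dataclasses import dataclass

import numpy as np

from kescan.segmentation import BinaryMask, LabelResult
from kescan.subtraction import SubtractionVolume

__all__ = ["ConcentrationMap", "RegionStats", "concentration_map", "region_stats", "preview_stack"]

logger = logging.getLogger(__name__)

#: Display maximum (mg/cc) used for color-mapped previews.
DEFAULT_DISPLAY_MAX = 132.35


@dataclass(frozen=True)
class ConcentrationMap:
    """Per-voxel concentration in mg/cc; zero outside the source mask."""

    data: np.ndarray
    delta_mu_rho: float
    mask_label: str = ""

    @property
    def shape(self) -> tuple[int, ...]:
        return self.data.shape


@dataclass(frozen=True)
class RegionStats:
    """Summary of one labelled region (``region_id`` 0 = whole volume)."""

    region_id: int
    voxel_count: int
    volume_mm3: float
    min_mg_cc: float
    max_mg_cc: float
    mean_mg_cc: float


def concentration_map(
    sub: SubtractionVolume,
    mask: BinaryMask,
    delta_mu_rho: float,
) -> ConcentrationMap:
    """Convert Δµ to concentration inside ``mask``.

    Negative Δµ inside the mask (noise) is clamped to zero with a logged
    warning; the map is exactly zero outside the mask.
    """
    if delta_mu_rho <= 0:
        raise ValueError("delta_mu_rho must be positive")
    data = sub.data if isinstance(sub, SubtractionVolume) else np.asarray(sub)
    if data.shape != mask.shape:
        raise ValueError("subtraction volume and mask must share a shape")
    conc = np.zeros(data.shape, dtype=np.float32)
    inside = mask.data
    values = 1000.0 * data[inside] / delta_mu_rho
    n_neg = int((values < 0).sum())
    if n_neg:
        logger.warning(
            "clamped %d negative subtraction values inside the mask to 0", n_neg
        )
        values = np.maximum(values, 0.0)
    conc[inside] = values
    return ConcentrationMap(data=conc, delta_mu_rho=float(delta_mu_rho), mask_label=mask.label)


def region_stats(
    cmap: ConcentrationMap,
    regions: LabelResult,
    voxel_size_mm: float,
) -> list[RegionStats]:
    """Per-region voxel count, physical volume and concentration range.

    The first row (``region_id`` 0) summarizes all labelled voxels
    together; one row per connected component follows.  Empty label sets
    yield an empty list.
    """
    if voxel_size_mm <= 0:
        raise ValueError("voxel size must be positive")
    if not regions.regions:
        return []
    voxel_volume = voxel_size_mm**3
    labels = regions.labels
    out: list[RegionStats] = []
    all_values = cmap.data[labels > 0]
    out.append(
        RegionStats(
            region_id=0,
            voxel_count=int(all_values.size),
            volume_mm3=float(all_values.size * voxel_volume),
            min_mg_cc=float(all_values.min()),
            max_mg_cc=float(all_values.max()),
            mean_mg_cc=float(all_values.mean()),
        )
    )
    for region in regions.regions:
        values = cmap.data[labels == region.region_id]
        out.append(
            RegionStats(
                region_id=region.region_id,
                voxel_count=int(values.size),
                volume_mm3=float(values.size * voxel_volume),
                min_mg_cc=float(values.min()),
                max_mg_cc=float(values.max()),
                mean_mg_cc=float(values.mean()),
            )
        )
    return out


def preview_stack(
    cmap: ConcentrationMap,
    display_max: float = DEFAULT_DISPLAY_MAX,
    colormap: str = "inferno",
) -> np.ndarray:
    """8-bit RGB color-mapped preview of the concentration map.

    Values are scaled linearly onto [0, display_max]; higher values clip
    at the top of the colormap (mirrors the display convention of capping
    the color scale below the true maximum).
    """
    if display_max <= 0:
        raise ValueError("display_max must be positive")
    from matplotlib import colormaps

    cm = colormaps[colormap]
    scaled = np.clip(cmap.data / display_max, 0.0, 1.0)
    rgba = cm(scaled)
    return (rgba[..., :3] * 255).astype(np.uint8)
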