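"""TIFF stack, CSV, and YAML I/O.

Volumes are (z, y, x) float32 arrays stored either as a single multipage
TIFF or as a directory of per-slice TIFFs in natural-sort order; both
dialects read back to the identical volume.  Masks are written as 8-bit
TIFF (0/255 for viewer friendliness, any nonzero reads as True).
"""

from __future__ import annotations

import re
from pathlib import Path

import numpy as np
import pandas as pd
import tifffile
import yaml

from kescan.concentration import RegionStats
from kescan.subtraction import PixelHistogram

__all__ = [
    "StackFormatError",
    "read_stack",
    "write_stack",
    "write_mask_stack",
    "read_mask_stack",
    "load_yaml",
    "save_yaml",
    "write_histogram_csv",
    "write_region_stats_csv",
]


class StackFormatError(ValueError):
    """Stack on disk is malformed (mixed shapes, empty directory, ...)."""


def _natural_key(path: Path) -> list:
    return [
        int(tok) if tok.isdigit() else tok.lower()
        for tok in re.split(r"(\d+)", path.name)
    ]


def read_stack(path: str | Path) -> tuple[np.ndarray, dict]:
    """Read a volume from a multipage TIFF or a directory of slice TIFFs.

    Returns ``(volume, metadata)`` with the volume as float32 in (z, y, x)
    order, slices sorted naturally (z ascending).
    """
    path = Path(path)
    if path.is_dir():
        files = sorted(
            (p for p in path.iterdir() if p.suffix.lower() in (".tif", ".tiff")),
            key=_natural_key,
        )
        if not files:
            raise IOError(f"no TIFF slices found in {path}")
        slices = [tifffile.imread(f) for f in files]
        shapes = {s.shape for s in slices}
        if len(shapes) != 1:
            raise StackFormatError(f"mixed slice shapes in {path}: {shapes}")
        volume = np.stack(slices, axis=0)
        meta = {"path": str(path), "n_slices": len(files), "dialect": "directory"}
    else:
        if not path.exists():
            raise IOError(f"no such file: {path}")
        volume = tifffile.imread(path)
        if volume.ndim == 2:
            volume = volume[np.newaxis]
        if volume.ndim != 3:
            raise StackFormatError(f"expected a 2D/3D TIFF stack, got ndim={volume.ndim}")
        meta = {"path": str(path), "n_slices": volume.shape[0], "dialect": "multipage"}
    return np.ascontiguousarray(volume, dtype=np.float32), meta


def write_stack(volume: np.ndarray, path: str | Path, dtype: str = "float32") -> Path:
    """Write a (z, y, x) volume as a multipage TIFF; returns the path."""
    path = Path(path)
    path.parent.mkdir(parents=True, exist_ok=True)
    data = np.asarray(volume)
    if data.ndim == 2:
        data = data[np.newaxis]
    tifffile.imwrite(path, data.astype(dtype), photometric="minisblack")
    return path


def write_mask_stack(mask: np.ndarray, path: str | Path) -> Path:
    """Write a binary mask as an 8-bit TIFF stack (foreground = 255)."""
    data = (np.asarray(mask, dtype=bool).astype(np.uint8)) * 255
    return write_stack(data, path, dtype="uint8")


def read_mask_stack(path: str | Path) -> np.ndarray:
    volume, _ = read_stack(path)
    return volume > 0


def load_yaml(path: str | Path) -> dict:
    with open(path) as fh:
        return yaml.safe_load(fh) or {}


def save_yaml(obj: dict, path: str | Path) -> Path:
    path = Path(path)
    path.parent.mkdir(parents=True, exist_ok=True)
    with open(path, "w") as fh:
        yaml.safe_dump(obj, fh, sort_keys=True)
    return path


def write_histogram_csv(
    hist_above: PixelHistogram,
    hist_below: PixelHistogram,
    path: str | Path,
) -> Path:
    """Dual-energy histogram table: bin_center, count_above, count_below."""
    if not np.allclose(hist_above.bin_edges, hist_below.bin_edges):
        raise ValueError("histograms must share identical binning")
    path = Path(path)
    path.parent.mkdir(parents=True, exist_ok=True)
    pd.DataFrame(
        {
            "bin_center": hist_above.bin_centers,
            "count_above": hist_above.counts,
            "count_below": hist_below.counts,
        }
    ).to_csv(path, index=False)
    return path


def write_region_stats_csv(stats: list[RegionStats], path: str | Path) -> Path:
    path = Path(path)
    path.parent.mkdir(parents=True, exist_ok=True)
    pd.DataFrame([vars(s) for s in stats]).to_csv(path, index=False)
    return path
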