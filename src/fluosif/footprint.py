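"""Upscaling nadir SIF to the eddy-covariance (EC) flux footprint.

The tower-mounted fiber samples a fixed circle a few metres across, while the
EC flux footprint covers hectares and moves with the wind.  Given half-hourly
footprint weights w_i on a raster co-registered with a per-pixel NIRv-like
vegetation index (VI), nadir SIF is scaled by the ratio of the
footprint-weighted VI to the VI of the pixel containing the SIF target:

    VI_footprint = sum_i w_i VI_i
    ratio        = VI_footprint / VI_SIFpixel
    SIF_footprint = SIF_nadir * ratio

PAR and fluorescence yield are assumed uniform across the footprint, so the
ratio reduces to a pure VI ratio.  Grids are row-major with origin at the
domain's northwest corner; pixel indices are (row, col).
"""

from __future__ import annotations

import math
from dataclasses import dataclass
from pathlib import Path

import numpy as np

__all__ = [
    "WeightGrid",
    "VIGrid",
    "footprint_weighted_vi",
    "upscaling_ratio",
    "upscale_sif",
    "read_ascii_grid",
    "write_ascii_grid",
]


@dataclass
class WeightGrid:
    """Footprint weights on a raster; nonnegative, normalized to sum to 1."""

    weights: np.ndarray
    tower_pixel: tuple[int, int]
    pixel_size_m: float = 3.0
    #: sum of the raw weights before normalization (diagnostic)
    raw_sum: float = 1.0

    def __post_init__(self) -> None:
        w = np.asarray(self.weights, dtype=float)
        if w.ndim != 2:
            raise ValueError("weights must be a 2-D array")
        if np.any(w < 0):
            raise ValueError("footprint weights must be nonnegative")
        r, c = self.tower_pixel
        if not (0 <= r < w.shape[0] and 0 <= c < w.shape[1]):
            raise ValueError("tower pixel outside grid")
        total = float(w.sum())
        if total <= 0:
            raise ValueError("weights sum to zero")
        self.raw_sum = total
        self.weights = w / total


@dataclass
class VIGrid:
    """Per-pixel vegetation-index raster co-registered with a WeightGrid.

    ``sif_pixel`` is the (row, col) of the pixel containing the nadir SIF
    target area.  Non-finite or nonpositive entries are treated as gaps.
    """

    values: np.ndarray
    sif_pixel: tuple[int, int]
    pixel_size_m: float = 3.0

    def __post_init__(self) -> None:
        v = np.asarray(self.values, dtype=float)
        if v.ndim != 2:
            raise ValueError("VI grid must be a 2-D array")
        r, c = self.sif_pixel
        if not (0 <= r < v.shape[0] and 0 <= c < v.shape[1]):
            raise ValueError("SIF pixel outside grid")
        self.values = v

    @property
    def valid(self) -> np.ndarray:
        return np.isfinite(self.values) & (self.values > 0)


def footprint_weighted_vi(weights: WeightGrid, vi: VIGrid) -> float:
    """Footprint-weighted mean VI, sum_i w_i VI_i over valid pixels.

    When the VI raster has gaps, weights are renormalized over the valid
    pixels so the result stays a weighted mean.
    """
    if weights.weights.shape != vi.values.shape:
        raise ValueError("weight and VI grids must have the same shape")
    valid = vi.valid
    if not valid.any():
        raise ValueError("VI grid has no valid pixels")
    w = weights.weights[valid]
    wsum = w.sum()
    if wsum <= 0:
        raise ValueError("no footprint weight over valid VI pixels")
    return float(np.sum(w * vi.values[valid]) / wsum)


def upscaling_ratio(weights: WeightGrid, vi: VIGrid) -> float:
    """Ratio of footprint-weighted VI to the VI at the SIF tower pixel."""
    pix = vi.values[vi.sif_pixel]
    if not np.isfinite(pix) or pix <= 0:
        raise ValueError("VI at the SIF pixel is missing or nonpositive")
    return footprint_weighted_vi(weights, vi) / float(pix)


def upscale_sif(sif_nadir: float, ratio: float) -> float:
    """Footprint-matched SIF; NaN inputs propagate as NaN."""
    if sif_nadir is None or ratio is None:
        return math.nan
    return float(sif_nadir) * float(ratio)


# -- plain-text raster I/O (ncols/nrows header, nodata) ----------------------

def write_ascii_grid(path: str | Path, grid: np.ndarray, nodata: float = -9999.0) -> None:
    g = np.asarray(grid, dtype=float).copy()
    g[~np.isfinite(g)] = nodata
    with open(path, "w") as fh:
        fh.write(f"ncols {g.shape[1]}\n")
        fh.write(f"nrows {g.shape[0]}\n")
        fh.write(f"nodata_value {nodata}\n")
        np.savetxt(fh, g, fmt="%.10g")


def read_ascii_grid(path: str | Path) -> np.ndarray:
    with open(path) as fh:
        header: dict[str, float] = {}
        pos = fh.tell()
        for _ in range(6):
            pos = fh.tell()
            line = fh.readline()
            parts = line.split()
            if len(parts) == 2 and parts[0].lower() in {
                "ncols", "nrows", "nodata_value", "xllcorner", "yllcorner", "cellsize",
            }:
                header[parts[0].lower()] = float(parts[1])
            else:
                fh.seek(pos)
                break
        grid = np.loadtxt(fh)
    grid = np.atleast_2d(grid)
    if "nodata_value" in header:
        grid[grid == header["nodata_value"]] = np.nan
    if "ncols" in header and grid.shape[1] != int(header["ncols"]):
        raise ValueError("grid shape does not match header")
    return grid
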