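"""Vegetation indices from broadband hemispherical-directional reflectance.

Reflectance factor R = pi L / E from the 350-1100 nm channel; indices use
fixed band windows (NIR 770-780 nm because the detector is noisy beyond
800 nm; red 650-660; blue 460-470; red edge 720-730; green 545-565) and four
single wavelengths (531, 570, 708, 775 nm) read as +/-1 nm means.  The
five-minute reflectance spectra are averaged to the half hour first and the
indices computed from the mean spectrum, in that order.
"""

from __future__ import annotations

import math
from dataclasses import dataclass, fields

import numpy as np
import pandas as pd

from .spectra import Spectrum

__all__ = [
    "VIRecord",
    "reflectance",
    "band_mean",
    "compute_vis",
    "aggregate_reflectance_then_vi",
]

# band windows (nm)
NIR = (770.0, 780.0)
RED = (650.0, 660.0)
BLUE = (460.0, 470.0)
RED_EDGE = (720.0, 730.0)
GREEN = (545.0, 565.0)
HALF_WIDTH = 1.0  # +/- window for single-wavelength reads


@dataclass
class VIRecord:
    """One set of vegetation indices (all unitless).

    ``fpar_vi`` is the red-edge-NDVI estimate of fPAR
    (1.37 * RededgeNDVI - 0.17), reported unclipped; clipping to [0, 1]
    happens only where fPAR enters the SIF decomposition.  The relation was
    developed for corn and soybean and is not applicable to miscanthus.
    """

    ndvi: float = math.nan
    evi: float = math.nan
    nirv: float = math.nan
    ci_rededge: float = math.nan
    ci_green: float = math.nan
    pri: float = math.nan
    rededge_ndvi: float = math.nan
    fpar_vi: float = math.nan

    def as_dict(self) -> dict[str, float]:
        return {f.name: getattr(self, f.name) for f in fields(self)}


def reflectance(e: Spectrum, l: Spectrum) -> Spectrum:
    """Hemispherical-directional reflectance factor R = pi L / E.

    Pixels where E <= 0 (night, detector gaps) are flagged NaN.
    """
    if not e.same_grid(l):
        raise ValueError("E and L grids differ")
    with np.errstate(divide="ignore", invalid="ignore"):
        r = math.pi * l.values / e.values
    r[e.values <= 0] = np.nan
    return Spectrum(e.wavelengths, r, "reflectance (unitless)")


def band_mean(r: Spectrum, lo: float, hi: float) -> float:
    """Unweighted mean of reflectance samples with lo <= lambda <= hi."""
    mask = r.window(lo, hi)
    if not mask.any():
        raise ValueError(f"no samples in window {lo}-{hi} nm")
    vals = r.values[mask]
    vals = vals[np.isfinite(vals)]
    return float(vals.mean()) if vals.size else math.nan


def _point(r: Spectrum, lam: float) -> float:
    return band_mean(r, lam - HALF_WIDTH, lam + HALF_WIDTH)


def _ratio(num: float, den: float) -> float:
    return num / den if np.isfinite(den) and den != 0 else math.nan


def compute_vis(r: Spectrum) -> VIRecord:
    """All indices from one reflectance spectrum.

    NDVI = (R_nir - R_red) / (R_nir + R_red)
    NIRv = R_nir * NDVI
    EVI  = 2.5 (R_nir - R_red) / (R_nir + 6 R_red - 7.5 R_blue + 1)
    CI_rededge = R_nir / R_720-730 - 1
    CI_green   = R_nir / R_545-565 - 1
    PRI  = (R_531 - R_570) / (R_531 + R_570)
    RededgeNDVI = (R_775 - R_708) / (R_775 + R_708)
    fPAR_VI = 1.37 RededgeNDVI - 0.17
    """
    nir = band_mean(r, *NIR)
    red = band_mean(r, *RED)
    blue = band_mean(r, *BLUE)
    rededge = band_mean(r, *RED_EDGE)
    green = band_mean(r, *GREEN)
    r531, r570 = _point(r, 531.0), _point(r, 570.0)
    r708, r775 = _point(r, 708.0), _point(r, 775.0)

    ndvi = _ratio(nir - red, nir + red)
    re_ndvi = _ratio(r775 - r708, r775 + r708)
    return VIRecord(
        ndvi=ndvi,
        evi=_ratio(2.5 * (nir - red), nir + 6.0 * red - 7.5 * blue + 1.0),
        nirv=nir * ndvi,
        ci_rededge=_ratio(nir, rededge) - 1.0 if np.isfinite(rededge) else math.nan,
        ci_green=_ratio(nir, green) - 1.0 if np.isfinite(green) else math.nan,
        pri=_ratio(r531 - r570, r531 + r570),
        rededge_ndvi=re_ndvi,
        fpar_vi=1.37 * re_ndvi - 0.17,
    )


def aggregate_reflectance_then_vi(
    spectra: list[tuple[pd.Timestamp, Spectrum]]
) -> pd.DataFrame:
    """Half-hourly indices: average the reflectance spectra per bin first,
    then compute indices on each mean spectrum (VI of the mean, not the mean
    of VIs).  Returns a DataFrame indexed by bin start.
    """
    if not spectra:
        return pd.DataFrame()
    grid = spectra[0][1].wavelengths
    rows = []
    for ts, spec in spectra:
        if not np.array_equal(spec.wavelengths, grid):
            raise ValueError("all reflectance spectra must share one grid")
        rows.append((pd.Timestamp(ts).floor("30min"), spec.values))
    frame = pd.DataFrame(
        [v for _, v in rows], index=pd.DatetimeIndex([t for t, _ in rows])
    )
    out = {}
    for ts, chunk in frame.groupby(level=0):
        mean_spec = Spectrum(grid, chunk.mean(axis=0).to_numpy())
        out[ts] = compute_vis(mean_spec).as_dict()
    result = pd.DataFrame.from_dict(out, orient="index")
    result.index.name = "timestamp_start"
    return result
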