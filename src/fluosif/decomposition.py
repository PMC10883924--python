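"""Decomposing canopy SIF into structural, radiation and physiological parts.

Under the light-use-efficiency framework the far-red canopy signal factors as

    SIF = fPAR * PAR * Phi_F,canopy * f_esc

with fPAR the fraction of photosynthetically active radiation absorbed by the
canopy (measured by quantum sensors or estimated from red-edge NDVI), f_esc
the escape probability of emitted far-red photons (NIRv / fPAR), and
Phi_F,canopy the apparent fluorescence yield obtained by inverting the
identity.  Phi_F is kept in the instruments' mixed units
((mW m-2 nm-1 sr-1) / (umol m-2 s-1)); only its variation matters here.

The variance of peak-season SIF is attributed to the four factors with the
Lindeman-Merenda-Gold (LMG) relative-importance decomposition: each
regressor's contribution is its sequential increment to R^2 averaged over all
orderings of the regressors, which sums exactly to the full-model R^2.
"""

from __future__ import annotations

import math
from dataclasses import dataclass
from itertools import permutations

import numpy as np
import pandas as pd

__all__ = [
    "PARBundle",
    "DecompositionRecord",
    "LMGResult",
    "fpar_meas",
    "apar",
    "f_esc",
    "phi_f",
    "peak_season_mask",
    "daily_daytime_average",
    "regress_r2",
    "lmg_importance",
    "decompose_sif",
]

DAY_START_HOUR = 8   # local (CST) daytime window for daily averages
DAY_END_HOUR = 18


@dataclass(frozen=True)
class PARBundle:
    """Quantum-sensor PAR streams, umol m-2 s-1 (par_soil optional)."""

    par_in: float
    par_out: float
    par_trans: float
    par_soil: float = 0.0

    def __post_init__(self) -> None:
        for name in ("par_in", "par_out", "par_trans", "par_soil"):
            if getattr(self, name) < 0:
                raise ValueError(f"{name} must be nonnegative")
        if self.par_in < self.par_out:
            raise ValueError("par_in must be >= par_out")


@dataclass
class DecompositionRecord:
    fpar: float
    apar: float
    f_esc: float
    phi_f: float
    fpar_source: str = "fPAR_Meas"
    fpar_clipped: bool = False


@dataclass
class LMGResult:
    """Per-regressor share of the model R^2 (shares sum to total R^2)."""

    contributions: dict[str, float]
    total_r2: float
    fpar_source: str = ""


def fpar_meas(bundle: PARBundle, include_soil: bool = False,
              clip: bool = True) -> tuple[float, bool]:
    """Measured fPAR: (PAR_in - PAR_out - PAR_trans [+ PAR_soil]) / PAR_in.

    The soil term (upward PAR reflected under the canopy) is added back at
    sites where a downward-facing line quantum sensor measured it.  Returns
    (fpar, clipped_flag); NaN when PAR_in <= 0.
    """
    if bundle.par_in <= 0:
        return math.nan, False
    num = bundle.par_in - bundle.par_out - bundle.par_trans
    if include_soil:
        num += bundle.par_soil
    raw = num / bundle.par_in
    if clip:
        clipped = raw < 0.0 or raw > 1.0
        return min(max(raw, 0.0), 1.0), clipped
    return raw, False


def apar(fpar: float, par_in: float) -> float:
    """Absorbed PAR = fPAR * PAR_in, umol m-2 s-1."""
    return fpar * par_in


def f_esc(nirv: float, fpar: float) -> float:
    """Far-red photon escape probability, NIRv / fPAR; NaN when fPAR <= 0."""
    if not np.isfinite(fpar) or fpar <= 0:
        return math.nan
    return nirv / fpar


def phi_f(sif760: float, fpar: float, par: float, fesc: float) -> float:
    """Apparent canopy fluorescence yield SIF / (fPAR * PAR * f_esc).

    Units are instrument-relative: energy-flux SIF over photon-flux APAR.
    NaN when any factor is missing or the denominator is nonpositive.
    """
    denom = fpar * par * fesc
    if not np.isfinite(denom) or denom <= 0 or not np.isfinite(sif760):
        return math.nan
    return sif760 / denom


def peak_season_mask(ndvi_daily: pd.Series, fraction: float = 0.85) -> pd.Series:
    """Days where daily NDVI exceeds ``fraction`` of the site-year maximum."""
    finite = ndvi_daily.dropna()
    if finite.empty:
        raise ValueError("no finite NDVI values")
    threshold = fraction * finite.max()
    return ndvi_daily > threshold


def daily_daytime_average(halfhourly: pd.Series, min_fraction: float = 0.75) -> pd.Series:
    """Daily mean of the 08:00-18:00 local half hours.

    The window holds 20 half-hourly slots; a day's mean is emitted only when
    strictly more than ``min_fraction`` of them (i.e. >15 of 20) are present.
    """
    if not isinstance(halfhourly, pd.Series):
        raise TypeError("expected a pandas Series with a DatetimeIndex")
    idx = halfhourly.index
    day = halfhourly[(idx.hour >= DAY_START_HOUR) & (idx.hour < DAY_END_HOUR)].dropna()
    n_slots = (DAY_END_HOUR - DAY_START_HOUR) * 2
    out = {}
    for d, chunk in day.groupby(day.index.normalize()):
        out[d] = chunk.mean() if chunk.size > min_fraction * n_slots else math.nan
    return pd.Series(out, dtype=float)


def regress_r2(y, x) -> float:
    """R^2 of the simple linear regression of y on x (squared Pearson r)."""
    y = np.asarray(y, dtype=float)
    x = np.asarray(x, dtype=float)
    ok = np.isfinite(x) & np.isfinite(y)
    x, y = x[ok], y[ok]
    if x.size < 3:
        raise ValueError("need at least 3 paired finite values")
    sx, sy = x.std(), y.std()
    if sx == 0 or sy == 0:
        return math.nan
    r = np.corrcoef(x, y)[0, 1]
    return float(r * r)


def _subset_r2(y: np.ndarray, x: np.ndarray, cols: tuple[int, ...],
               cache: dict) -> float:
    """R^2 of the OLS of y on the given regressor columns (with intercept)."""
    if cols in cache:
        return cache[cols]
    if not cols:
        cache[cols] = 0.0
        return 0.0
    design = np.column_stack([np.ones(y.size), x[:, list(cols)]])
    coef, *_ = np.linalg.lstsq(design, y, rcond=None)
    resid = y - design @ coef
    sst = float(np.sum((y - y.mean()) ** 2))
    r2 = 1.0 - float(np.sum(resid**2)) / sst
    cache[cols] = r2
    return r2


def lmg_importance(y, x, names: list[str] | None = None) -> LMGResult:
    """LMG relative importance by exact enumeration of regressor orderings.

    For each regressor the sequential increment in R^2 when it is added to
    the model is averaged over all p! orderings (exact for p <= 6; more
    regressors are refused).  The contributions telescope to the full-model
    R^2 by construction.
    """
    y = np.asarray(y, dtype=float)
    x = np.asarray(x, dtype=float)
    if x.ndim != 2:
        raise ValueError("x must be 2-D (n, p)")
    n, p = x.shape
    if names is None:
        names = [f"x{i}" for i in range(p)]
    if len(names) != p:
        raise ValueError("names length mismatch")
    if p > 6:
        raise ValueError("exact LMG enumeration limited to 6 regressors")
    ok = np.isfinite(y) & np.all(np.isfinite(x), axis=1)
    y, x = y[ok], x[ok]
    n = y.size
    if n <= p + 1:
        raise ValueError("need n > p + 1 observations")
    if y.std() == 0:
        raise ValueError("response has zero variance")
    sv = np.linalg.svd(np.column_stack([np.ones(n), (x - x.mean(0)) / np.where(x.std(0) == 0, 1, x.std(0))]),
                       compute_uv=False)
    if sv[-1] < 1e-10 * sv[0]:
        raise ValueError("singular design")

    cache: dict[tuple[int, ...], float] = {}
    totals = np.zeros(p)
    orderings = list(permutations(range(p)))
    for order in orderings:
        seen: tuple[int, ...] = ()
        for j in order:
            before = _subset_r2(y, x, tuple(sorted(seen)), cache)
            seen = seen + (j,)
            after = _subset_r2(y, x, tuple(sorted(seen)), cache)
            totals[j] += after - before
    contrib = totals / len(orderings)
    total_r2 = _subset_r2(y, x, tuple(range(p)), cache)
    return LMGResult(dict(zip(names, contrib.tolist())), total_r2)


def decompose_sif(
    records: pd.DataFrame,
    species: str,
    standardize: bool = False,
    log_space: bool = False,
) -> LMGResult:
    """LMG attribution of peak-season SIF to {fPAR, PAR, Phi_F, f_esc}.

    ``records`` must carry columns ``sif760``, ``par`` and either measured or
    VI-based fPAR (``fpar_meas`` / ``fpar_vi``), plus ``nirv``.  The fPAR
    source follows the site conventions: the red-edge NDVI estimate is only
    valid for corn and soybean, never miscanthus; measured fPAR is preferred
    whenever present.  ``log_space`` regresses log SIF on log factors, which
    makes the multiplicative identity additive; default is the linear form.
    """
    needed = {"sif760", "par", "nirv"}
    missing = sorted(needed - set(records.columns))
    if missing:
        raise ValueError(f"missing factor columns: {missing}")
    species_l = species.lower()
    if "fpar_meas" in records.columns and records["fpar_meas"].notna().any():
        fpar = records["fpar_meas"]
        source = "fPAR_Meas"
    elif "fpar_vi" in records.columns:
        if species_l.startswith("mis"):
            raise ValueError("VI-based fPAR is not applicable to miscanthus")
        fpar = records["fpar_vi"]
        source = "fPAR_VI"
    else:
        raise ValueError("missing factor columns: ['fpar_meas' or 'fpar_vi']")

    fpar = fpar.clip(0.0, 1.0)
    fesc = records["nirv"] / fpar
    phi = records["sif760"] / (fpar * records["par"] * fesc)
    frame = pd.DataFrame(
        {
            "sif760": records["sif760"],
            "fPAR": fpar,
            "PAR": records["par"],
            "Phi_F": phi,
            "f_esc": fesc,
        }
    ).replace([np.inf, -np.inf], np.nan).dropna()
    y = frame["sif760"].to_numpy()
    x = frame[["fPAR", "PAR", "Phi_F", "f_esc"]].to_numpy()
    if log_space:
        if np.any(y <= 0) or np.any(x <= 0):
            raise ValueError("log-space decomposition requires positive factors")
        y, x = np.log(y), np.log(x)
    if standardize:
        x = (x - x.mean(0)) / x.std(0)
    result = lmg_importance(y, x, ["fPAR", "PAR", "Phi_F", "f_esc"])
    result.fpar_source = source
    return result
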