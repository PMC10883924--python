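"""The half-hourly deposited product: schema, I/O, pipeline and validation.

One CSV row is one half hour at one site-year, with 32 columns: site
metadata and timestamps (CST, fixed UTC-6), the five raw SIF760 retrievals
with standard errors, the calibration adjustment factor and footprint ratio,
PAR/fPAR/APAR (measured and VI-based), six vegetation indices, and the
instrument enclosure temperature.  -9999 marks missing values on disk; in
memory missing is NaN.
"""

from __future__ import annotations

import logging
import math
from importlib import resources
from pathlib import Path

import numpy as np
import pandas as pd

from . import calibration as cal
from . import decomposition as dec
from . import indices as vix
from . import retrieval as ret
from . import synthetic as syn
from .footprint import upscaling_ratio
from .spectra import Spectrum

__all__ = [
    "PRODUCT_COLUMNS",
    "MISSING",
    "read_product",
    "write_product",
    "derive_corrected_columns",
    "site_years",
    "site_year_counts",
    "validate",
    "run_pipeline",
]

log = logging.getLogger("fluosif")

MISSING = -9999.0

PRODUCT_COLUMNS = [
    "site", "year", "species", "latitude", "longitude",
    "timestamp_start", "timestamp_end", "doy",
    "SIF_sFLD_raw", "SIF_sFLD_raw_stderror",
    "SIF_3FLD_raw", "SIF_3FLD_raw_stderror",
    "SIF_iFLD_raw", "SIF_iFLD_raw_stderror",
    "SIF_SFM_nonlinear_raw", "SIF_SFM_nonlinear_raw_stderror",
    "SIF_SFM_linear_raw", "SIF_SFM_linear_raw_stderror",
    "f_cal_corr_QEPRO", "ratio_Ecfootprint_SIFpixel",
    "PAR", "FPAR_VI", "APAR_VI", "FPAR_measured", "APAR_measured",
    "NDVI", "EVI", "NIRv", "CI_red_edge", "CI_green", "PRI",
    "enclosure_temp",
]

#: product column per retrieval method id
SIF_COLUMNS = {
    "sFLD": "SIF_sFLD_raw",
    "3FLD": "SIF_3FLD_raw",
    "iFLD": "SIF_iFLD_raw",
    "SFM_nonlinear": "SIF_SFM_nonlinear_raw",
    "SFM_linear": "SIF_SFM_linear_raw",
}

VI_COLUMNS = ["NDVI", "EVI", "NIRv", "CI_red_edge", "CI_green", "PRI"]

_TS_FORMAT = "%Y-%m-%d %H:%M:%S"


# -- schema-locked I/O --------------------------------------------------------

def read_product(path: str | Path) -> pd.DataFrame:
    """Read the 32-column half-hourly product; -9999 becomes NaN."""
    head = pd.read_csv(path, nrows=0)
    got = list(head.columns)
    if got != PRODUCT_COLUMNS:
        missing = [c for c in PRODUCT_COLUMNS if c not in got]
        extra = [c for c in got if c not in PRODUCT_COLUMNS]
        raise ValueError(
            f"product schema mismatch: missing columns {missing}, "
            f"unknown columns {extra}"
        )
    df = pd.read_csv(path)
    df = df.replace(MISSING, np.nan)
    for col in ("timestamp_start", "timestamp_end"):
        parsed = pd.to_datetime(df[col], format=_TS_FORMAT, errors="coerce")
        bad = df.index[parsed.isna() & df[col].notna()]
        if len(bad):
            raise ValueError(
                f"malformed timestamp in column {col} at line {bad[0] + 2}"
            )
        df[col] = parsed
    return df


def write_product(df: pd.DataFrame, path: str | Path) -> None:
    """Write the product CSV with the locked header and -9999 sentinels."""
    out = df.copy()
    missing_cols = [c for c in PRODUCT_COLUMNS if c not in out.columns]
    if missing_cols:
        raise ValueError(f"cannot write product, missing columns {missing_cols}")
    out = out[PRODUCT_COLUMNS]
    for col in ("timestamp_start", "timestamp_end"):
        out[col] = pd.to_datetime(out[col]).dt.strftime(_TS_FORMAT)
    num = out.select_dtypes(include=[np.number]).columns
    out[num] = out[num].fillna(MISSING)
    out.to_csv(path, index=False, float_format="%.6g")


def derive_corrected_columns(df: pd.DataFrame) -> pd.DataFrame:
    """Add calibration-corrected and footprint-upscaled SIF columns.

    corrected = raw * f_cal_corr_QEPRO; upscaled = corrected * ratio.
    Missing factors propagate to the derived columns only.
    """
    out = df.copy()
    for method, col in SIF_COLUMNS.items():
        out[f"SIF_{method}_corrected"] = out[col] * out["f_cal_corr_QEPRO"]
        out[f"SIF_{method}_upscaled"] = (
            out[f"SIF_{method}_corrected"] * out["ratio_Ecfootprint_SIFpixel"]
        )
    return out


# -- site-year metadata -------------------------------------------------------

def site_years() -> pd.DataFrame:
    """The packaged site-year table: 15 site-years, crops and date windows."""
    with resources.files("fluosif").joinpath("data/site_years.csv").open() as fh:
        df = pd.read_csv(fh, parse_dates=[
            "season_start", "season_end", "spectra_start", "spectra_end",
        ])
    return df


def site_year_counts(meta: pd.DataFrame | None = None) -> dict[str, int]:
    meta = site_years() if meta is None else meta
    counts = meta["crop"].value_counts().to_dict()
    counts["total"] = int(len(meta))
    return counts


# -- technical validation -----------------------------------------------------

def _pairwise_r2(df: pd.DataFrame, cols: list[str]) -> pd.DataFrame:
    mat = pd.DataFrame(np.nan, index=cols, columns=cols)
    for i, a in enumerate(cols):
        for b in cols[i:]:
            try:
                r2 = dec.regress_r2(df[a], df[b])
            except ValueError:
                r2 = math.nan
            mat.loc[a, b] = mat.loc[b, a] = r2
    return mat


def validate(product: pd.DataFrame | str | Path) -> dict:
    """Technical-validation statistics of a half-hourly product.

    Returns a dict with: per-site-year cross-method pairwise R^2 matrices of
    the five raw SIF columns; per-species R^2 of calibration-corrected iFLD
    SIF against each VI and against VI*PAR at half-hourly and daily scales;
    APAR-SIF R^2; peak-season LMG contributions; and site-year counts per
    crop from the packaged metadata.  Statistics that cannot be computed from
    the rows at hand are reported as NaN/None, never raised.
    """
    df = read_product(product) if not isinstance(product, pd.DataFrame) else product.copy()
    df = derive_corrected_columns(df)
    sif_cols = list(SIF_COLUMNS.values())

    report: dict = {"site_year_counts": site_year_counts()}

    cross: dict[tuple, pd.DataFrame] = {}
    for key, chunk in df.groupby(["site", "year"]):
        cross[key] = _pairwise_r2(chunk, sif_cols)
    report["cross_method_r2"] = cross

    sif = "SIF_iFLD_corrected"
    vi_stats: dict[str, pd.DataFrame] = {}
    lmg: dict[str, dec.LMGResult | None] = {}
    apar_r2: dict[str, float] = {}
    for species, chunk in df.groupby("species"):
        chunk = chunk.set_index("timestamp_start")
        rows = {}
        for vi in VI_COLUMNS:
            entry = {}
            for label, x in (("vi", chunk[vi]), ("vi_par", chunk[vi] * chunk["PAR"])):
                try:
                    entry[f"halfhourly_{label}"] = dec.regress_r2(chunk[sif], x)
                except ValueError:
                    entry[f"halfhourly_{label}"] = math.nan
                try:
                    daily_y = dec.daily_daytime_average(chunk[sif])
                    daily_x = dec.daily_daytime_average(x)
                    entry[f"daily_{label}"] = dec.regress_r2(
                        daily_y, daily_x.reindex(daily_y.index)
                    )
                except ValueError:
                    entry[f"daily_{label}"] = math.nan
            rows[vi] = entry
        vi_stats[species] = pd.DataFrame.from_dict(rows, orient="index")

        apar = chunk["APAR_measured"].fillna(chunk["APAR_VI"])
        try:
            apar_r2[species] = dec.regress_r2(chunk[sif], apar)
        except ValueError:
            apar_r2[species] = math.nan

        try:
            daily_ndvi = dec.daily_daytime_average(chunk["NDVI"])
            peak_days = dec.peak_season_mask(daily_ndvi)
            peak_idx = chunk.index.normalize().isin(peak_days.index[peak_days])
            peak = chunk[peak_idx]
            records = pd.DataFrame(
                {
                    "sif760": peak[sif],
                    "par": peak["PAR"],
                    "nirv": peak["NIRv"],
                    "fpar_meas": peak["FPAR_measured"],
                    "fpar_vi": peak["FPAR_VI"],
                }
            )
            lmg[species] = dec.decompose_sif(records, species)
        except (ValueError, KeyError):
            lmg[species] = None
    report["sif_vi_r2"] = vi_stats
    report["apar_sif_r2"] = apar_r2
    report["lmg"] = lmg
    return report


# -- end-to-end synthetic pipeline -------------------------------------------

def run_pipeline(
    config: syn.SimConfig | None = None,
    n_days: int = 2,
    hours: tuple[float, float] = (8.0, 18.0),
    site: str = "US-UiC",
    species: str = "corn",
    qepro_gain_error: float = 1.0,
    footprint_heterogeneity: float = 0.05,
    phi_variability: float = 0.2,
    out_path: str | Path | None = None,
    outlier_bounds: tuple[float, float] = (0.0, 5.0),
) -> pd.DataFrame:
    """Simulate, retrieve, correct, upscale and aggregate a product table.

    The simulator provides truth-bearing paired spectra; retrieval runs at
    the native 5-minute cadence, the physical-range filter drops outliers,
    half-hourly bins need more than four of six slots, the degradation factor
    is recovered by cross-instrument regression (``qepro_gain_error``
    emulates a mis-calibrated SIF channel), and the footprint ratio comes
    from a synthetic weight/VI scene.  Truth columns are attached with a
    ``truth_`` prefix (dropped on write, which is schema-locked).
    """
    config = config or syn.SimConfig()
    series = syn.generate_series(
        config, n_days, phi_variability=phi_variability, hours=hours
    )
    log.info("simulated %d five-minute observations", len(series))

    if qepro_gain_error != 1.0:
        for obs, _ in series:
            obs.e_hr = obs.e_hr.with_values(obs.e_hr.values * qepro_gain_error)
            obs.l_hr = obs.l_hr.with_values(obs.l_hr.values * qepro_gain_error)

    rows = []
    refl_spectra = []
    for obs, truth in series:
        results = ret.retrieve_all(obs)
        row = {
            "timestamp": pd.Timestamp(obs.timestamp),
            "par_ref": truth.par_true,
            "par_spec": math.nan,
            "nir_q": math.nan,
            "nir_hr": math.nan,
            "par_in": obs.meta["par_in"],
            "par_out": obs.meta["par_out"],
            "par_trans": obs.meta["par_trans"],
            "par_soil": obs.meta["par_soil"],
            "enclosure_temp": obs.enclosure_temp,
            "truth_sif760": truth.sif760,
            "truth_fpar": truth.fpar_true,
        }
        for method, res in results.items():
            row[method] = res.sif760 if res.ok else math.nan
        if truth.par_true > 0:
            row["par_spec"] = cal.par_from_spectrum(obs.e_bb)
            # common NIR interval fully inside both channel grids
            row["nir_q"] = cal.nir_integral(obs.e_hr, 730.0, 779.9)
            row["nir_hr"] = cal.nir_integral(obs.e_bb, 730.0, 779.9)
            refl_spectra.append((row["timestamp"], vix.reflectance(obs.e_bb, obs.l_bb)))
        rows.append(row)
    five_min = pd.DataFrame(rows).set_index("timestamp")

    # physical-range outlier filter per method, then half-hourly aggregation
    lo, hi = outlier_bounds
    halfhour: dict[str, pd.DataFrame] = {}
    for method in ret.METHODS:
        vals = five_min[method]
        kept = vals.where((vals >= lo) & (vals <= hi))
        log.info(
            "%s: %d of %d retrievals inside [%g, %g]",
            method, int(kept.notna().sum()), int(vals.notna().sum()), lo, hi,
        )
        halfhour[method] = ret.aggregate_halfhour(kept)

    # degradation adjustment from cross-instrument regressions
    day = five_min[five_min["par_ref"] > 0]
    fcal = cal.compute_f_cal(
        day["par_spec"], day["par_ref"], day["nir_q"], day["nir_hr"]
    ).f_cal_corr
    log.info("f_cal_corr_QEPRO = %.4f", fcal)

    # footprint ratio from a synthetic scene (one daily VI grid)
    weights, vigrid = syn.generate_footprint_scene(
        64, 64, (32, 32), heterogeneity=footprint_heterogeneity, seed=config.seed
    )
    ratio = upscaling_ratio(weights, vigrid)

    vis = vix.aggregate_reflectance_then_vi(refl_spectra)

    par_hh = ret.aggregate_halfhour(five_min["par_in"])
    truth_hh = ret.aggregate_halfhour(five_min["truth_sif760"])
    fpar_rows = {}
    for ts, r in five_min.iterrows():
        if r["par_in"] > 0:
            bundle = dec.PARBundle(r["par_in"], r["par_out"], r["par_trans"], r["par_soil"])
            fpar_rows[ts] = dec.fpar_meas(bundle, include_soil=True)[0]
    fpar_hh = ret.aggregate_halfhour(pd.Series(fpar_rows, dtype=float))

    meta = site_years()
    match = meta[(meta["site"] == site) & (meta["crop"] == species)]
    lat = float(match["latitude"].iloc[0]) if len(match) else config.latitude
    lon = float(match["longitude"].iloc[0]) if len(match) else config.longitude

    index = halfhour["iFLD"].index
    product = pd.DataFrame(index=index)
    product["site"] = site
    product["year"] = index.year
    product["species"] = species
    product["latitude"] = lat
    product["longitude"] = lon
    product["timestamp_start"] = index.tz_localize(None)
    product["timestamp_end"] = (index + pd.Timedelta(minutes=30)).tz_localize(None)
    product["doy"] = index.dayofyear
    for method, col in SIF_COLUMNS.items():
        hh = halfhour[method].reindex(index)
        product[col] = hh["mean"].to_numpy()
        product[f"{col}_stderror"] = hh["stderror"].to_numpy()
    product["f_cal_corr_QEPRO"] = fcal
    product["ratio_Ecfootprint_SIFpixel"] = ratio
    product["PAR"] = par_hh.reindex(index)["mean"].to_numpy()
    vis_idx = vis.reindex(index.tz_localize(None) if vis.index.tz is None else index)
    product["NDVI"] = vis_idx["ndvi"].to_numpy()
    product["EVI"] = vis_idx["evi"].to_numpy()
    product["NIRv"] = vis_idx["nirv"].to_numpy()
    product["CI_red_edge"] = vis_idx["ci_rededge"].to_numpy()
    product["CI_green"] = vis_idx["ci_green"].to_numpy()
    product["PRI"] = vis_idx["pri"].to_numpy()
    product["FPAR_VI"] = vis_idx["fpar_vi"].to_numpy()
    product["APAR_VI"] = product["FPAR_VI"].clip(0, 1) * product["PAR"]
    product["FPAR_measured"] = fpar_hh.reindex(index)["mean"].to_numpy()
    product["APAR_measured"] = product["FPAR_measured"] * product["PAR"]
    product["enclosure_temp"] = 25.0
    product["truth_SIF760"] = truth_hh.reindex(index)["mean"].to_numpy()

    product = product.reset_index(drop=True)
    # the deposited product keeps daytime rows only
    hour = product["timestamp_start"].dt.hour
    kept = product[(hour >= 8) & (hour < 18)].reset_index(drop=True)
    log.info("product rows: %d half-hours (%d before daytime filter)", len(kept), len(product))
    if out_path is not None:
        write_product(kept, out_path)
    return kept
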