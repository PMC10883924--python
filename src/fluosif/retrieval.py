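"""Far-red SIF retrieval at the O2-A band (760 nm) from paired E/L spectra.

Five retrievals are implemented.  The Fraunhofer-line-depth (FLD) family
exploits the in-band drop of downwelling irradiance: writing the upwelling
radiance as L = R*E/pi + SIF at an in-band and an out-of-band wavelength,

    sFLD:  SIF = (E_out L_in - E_in L_out) / (E_out - E_in)

assumes R and SIF equal inside and outside the band; 3FLD replaces the single
out-of-band reference with a linear interpolation of the two shoulders; iFLD
keeps the sFLD form but corrects for non-flat R and SIF with factors

    alpha_R = R_app(out) / ~R_app(in),   alpha_F = E(out) / ~E(in)
    SIF = (alpha_R E_out L_in - E_in L_out) / (alpha_R E_out - alpha_F E_in)

where the tilde quantities interpolate the apparent reflectance
(R_app = pi L / E) and the irradiance continuum across the absorption feature
from the shoulders.  The spectral-fitting methods (SFM) instead least-squares
fit the whole window: SFM-linear assumes R and SIF both linear in wavelength;
SFM-nonlinear models SIF as a Gaussian and R as a cubic spline.

All spectra must be in calibrated radiometric units (E in mW m-2 nm-1, L in
mW m-2 nm-1 sr-1); SIF760 is returned in mW m-2 nm-1 sr-1.
"""

from __future__ import annotations

import math
from dataclasses import dataclass, field

import numpy as np
import pandas as pd
from scipy.interpolate import BSpline, LSQUnivariateSpline
from scipy.optimize import least_squares

from .spectra import PairedObservation, Spectrum

__all__ = [
    "BandSelection",
    "RetrievalResult",
    "METHODS",
    "find_band",
    "sfld",
    "threefld",
    "ifld",
    "sfm_linear",
    "sfm_nonlinear",
    "retrieve_all",
    "filter_sif",
    "aggregate_halfhour",
]

#: canonical method identifiers, in deposited-product column order
METHODS = ("sFLD", "3FLD", "iFLD", "SFM_nonlinear", "SFM_linear")

# default search windows (nm) for band selection
IN_WINDOW = (758.5, 761.5)
LEFT_WINDOW = (757.0, 759.5)
RIGHT_WINDOW = (768.0, 772.0)
FIT_WINDOW = (758.0, 772.0)


@dataclass(frozen=True)
class BandSelection:
    """Wavelengths anchoring the FLD retrievals and the SFM fit window."""

    lambda_in: float
    lambda_left: float
    lambda_right: float
    shoulder_left: tuple[float, float]
    shoulder_right: tuple[float, float]
    fit_window: tuple[float, float] = FIT_WINDOW
    #: half-width (nm) of the window mean used for 3FLD shoulder reads;
    #: 0 reads the single nearest pixel
    shoulder_half_width: float = 0.2
    #: half-width (nm) of the window means used for all four iFLD band reads
    ifld_half_width: float = 0.2

    def __post_init__(self) -> None:
        if not self.lambda_left < self.lambda_in < self.lambda_right:
            raise ValueError("require lambda_left < lambda_in < lambda_right")


@dataclass
class RetrievalResult:
    method: str
    sif760: float
    params: dict = field(default_factory=dict)
    residual_norm: float = math.nan
    band: BandSelection | None = None
    status: str = "ok"
    message: str = ""

    @property
    def ok(self) -> bool:
        return self.status == "ok"


def find_band(
    e: Spectrum,
    in_window: tuple[float, float] = IN_WINDOW,
    left_window: tuple[float, float] = LEFT_WINDOW,
    right_window: tuple[float, float] = RIGHT_WINDOW,
    fit_window: tuple[float, float] = FIT_WINDOW,
    min_depth: float = 0.01,
) -> BandSelection:
    """Locate the absorption feature on the irradiance spectrum.

    lambda_in is the irradiance minimum inside ``in_window``; the shoulders
    are the irradiance maxima of ``left_window`` and ``right_window``.  An
    error is raised when the relative dip depth against the
    shoulder-interpolated continuum is below ``min_depth``.
    """
    if not e.covers(745.0, 775.0):
        raise ValueError("spectrum must cover 745-775 nm")

    def _extremum(window, op):
        mask = e.window(*window)
        if not mask.any():
            raise ValueError(f"no samples in window {window}")
        idx = np.flatnonzero(mask)[op(e.values[mask])]
        return float(e.wavelengths[idx]), float(e.values[idx])

    lam_in, e_in = _extremum(in_window, np.argmin)
    lam_l, e_l = _extremum(left_window, np.argmax)
    lam_r, e_r = _extremum(right_window, np.argmax)
    cont = np.interp(lam_in, [lam_l, lam_r], [e_l, e_r])
    if cont <= 0 or 1.0 - e_in / cont < min_depth:
        raise ValueError("no absorption feature (dip depth below threshold)")
    return BandSelection(
        lambda_in=lam_in,
        lambda_left=lam_l,
        lambda_right=lam_r,
        shoulder_left=(max(float(e.wavelengths[0]), lam_l - 6.0), lam_l + 0.5),
        shoulder_right=(lam_r - 0.5, min(float(e.wavelengths[-1]), lam_r + 4.0)),
        fit_window=fit_window,
    )


def _at(s: Spectrum, lam: float) -> float:
    return s.value_at(lam)


def _window_read(s: Spectrum, lam: float, half_width: float) -> tuple[float, float]:
    """Mean value and mean wavelength over |lambda - lam| <= half_width.

    A zero half-width reads the single nearest pixel.  Window means trade a
    little spectral locality for a sqrt(n) reduction of pixel noise; they are
    linear and applied identically to E and L, so retrievals whose exactness
    rests on L = R E / pi + SIF holding per read are unaffected.
    """
    if half_width <= 0:
        return s.value_at(lam), float(s.wavelengths[s.index_of(lam)])
    mask = s.window(lam - half_width, lam + half_width)
    if not mask.any():
        return s.value_at(lam), float(s.wavelengths[s.index_of(lam)])
    return float(s.values[mask].mean()), float(s.wavelengths[mask].mean())


# -- FLD family --------------------------------------------------------------

def sfld(e: Spectrum, l: Spectrum, band: BandSelection) -> RetrievalResult:
    """Standard FLD with the right shoulder as the out-of-band reference."""
    e_in, e_out = _at(e, band.lambda_in), _at(e, band.lambda_right)
    l_in, l_out = _at(l, band.lambda_in), _at(l, band.lambda_right)
    if math.isclose(e_out, e_in, rel_tol=1e-12, abs_tol=1e-300):
        raise ValueError("no band contrast (E_out equals E_in)")
    sif = (e_out * l_in - e_in * l_out) / (e_out - e_in)
    return RetrievalResult("sFLD", sif, {"E_in": e_in, "E_out": e_out}, band=band)


def threefld(e: Spectrum, l: Spectrum, band: BandSelection) -> RetrievalResult:
    """3FLD: shoulder values linearly interpolated to the in-band wavelength.

    Shoulder reads are small window means (the continuum is smooth there, so
    the mean is the value at the window's mean wavelength for any linear
    R and SIF); the in-band read stays single-pixel because irradiance
    curvature inside the dip would bias a window mean.
    """
    hw = band.shoulder_half_width
    e_l, lam_l = _window_read(e, band.lambda_left, hw)
    e_r, lam_r = _window_read(e, band.lambda_right, hw)
    l_l, _ = _window_read(l, band.lambda_left, hw)
    l_r, _ = _window_read(l, band.lambda_right, hw)
    if math.isclose(lam_r, lam_l):
        raise ValueError("degenerate shoulders")
    w_left = (lam_r - band.lambda_in) / (lam_r - lam_l)
    w_right = 1.0 - w_left
    e_star = w_left * e_l + w_right * e_r
    l_star = w_left * l_l + w_right * l_r
    e_in, l_in = _at(e, band.lambda_in), _at(l, band.lambda_in)
    if math.isclose(e_star, e_in, rel_tol=1e-12, abs_tol=1e-300):
        raise ValueError("no band contrast")
    sif = (e_star * l_in - e_in * l_star) / (e_star - e_in)
    return RetrievalResult("3FLD", sif, {"w_left": w_left, "w_right": w_right}, band=band)


def _shoulder_interpolant(s: Spectrum, band: BandSelection):
    """Cubic spline fitted on the shoulder windows only, bridging the gap.

    Interior knots are placed inside each shoulder window; with sparse
    shoulders the spline degenerates to a single cubic, which is the intended
    smooth continuum model across the absorption feature.
    """
    mask = s.window(*band.shoulder_left) | s.window(*band.shoulder_right)
    x = s.wavelengths[mask]
    y = s.values[mask]
    if x.size == 0:
        raise ValueError("interpolation window empty")
    if x.size < 8:
        raise ValueError("too few shoulder samples for interpolation")
    for knots in (
        [band.shoulder_left[0] + 1.0, band.lambda_left - 1.0,
         band.lambda_right + 0.5, band.shoulder_right[1] - 0.5],
        [band.lambda_left - 1.0, band.lambda_right + 0.5],
        [],
    ):
        kn = [t for t in knots if x[0] < t < x[-1]]
        try:
            return LSQUnivariateSpline(x, y, kn, k=3)
        except ValueError:
            continue
    raise ValueError("shoulder spline fit failed")


def ifld(e: Spectrum, l: Spectrum, band: BandSelection) -> RetrievalResult:
    """Improved FLD with reflectance/fluorescence correction factors.

    Band values are window means (iFLD is the method that exploits the whole
    spectrum rather than discrete bands, and the correction factors absorb
    the resulting smooth biases).
    """
    hw = band.ifld_half_width
    e_in, _ = _window_read(e, band.lambda_in, hw)
    e_out, _ = _window_read(e, band.lambda_right, hw)
    l_in, _ = _window_read(l, band.lambda_in, hw)
    l_out, _ = _window_read(l, band.lambda_right, hw)
    r_app = l.with_values(math.pi * l.values / e.values)
    e_tilde = float(_shoulder_interpolant(e, band)(band.lambda_in))
    r_tilde = float(_shoulder_interpolant(r_app, band)(band.lambda_in))
    if e_tilde <= 0 or r_tilde <= 0:
        raise ValueError("continuum interpolation nonpositive")
    alpha_r = (math.pi * l_out / e_out) / r_tilde
    alpha_f = e_out / e_tilde
    denom = alpha_r * e_out - alpha_f * e_in
    if math.isclose(denom, 0.0, abs_tol=1e-300):
        raise ValueError("degenerate iFLD denominator")
    sif = (alpha_r * e_out * l_in - e_in * l_out) / denom
    return RetrievalResult(
        "iFLD", sif, {"alpha_R": alpha_r, "alpha_F": alpha_f}, band=band
    )


# -- spectral fitting methods -------------------------------------------------

def sfm_linear(e: Spectrum, l: Spectrum, band: BandSelection) -> RetrievalResult:
    """Joint linear fit L = (a*lambda + b) E/pi + (c*lambda + d) over the window.

    Solved in the centred variable x = lambda - 760 nm for conditioning, with
    regressors {x E/pi, E/pi, x, 1}; SIF760 is then the intercept of the SIF
    line directly.  Raises on a rank-deficient design (no absorption contrast
    makes E/pi collinear with the polynomial terms).
    """
    mask = e.window(*band.fit_window)
    if mask.sum() < 8:
        raise ValueError("need at least 8 samples in the fit window")
    x = e.wavelengths[mask] - 760.0
    ee = e.values[mask] / math.pi
    ll = l.values[mask]
    design = np.column_stack([x * ee, ee, x, np.ones_like(x)])
    scale = np.linalg.norm(design, axis=0)
    if np.any(scale == 0):
        raise ValueError("degenerate window")
    dn = design / scale
    svals = np.linalg.svd(dn, compute_uv=False)
    # with no absorption contrast the E terms are near-collinear with the
    # polynomial terms (exactly so for a flat continuum); the dip lifts the
    # normalized condition ratio by several orders of magnitude
    if svals[-1] < 1e-6 * svals[0]:
        raise ValueError("degenerate window (design rank-deficient)")
    coef, *_ = np.linalg.lstsq(dn, ll, rcond=None)
    coef = coef / scale
    a, r760, c, sif760 = coef
    resid = ll - design @ coef
    params = {"a": a, "b": r760 - 760.0 * a, "c": c, "d": sif760 - 760.0 * c}
    return RetrievalResult(
        "SFM_linear", float(sif760), params,
        residual_norm=float(np.linalg.norm(resid)), band=band,
    )


def _spline_basis(x: np.ndarray, knot_spacing: float = 2.0) -> np.ndarray:
    """Cubic B-spline design matrix with knots every ``knot_spacing`` nm."""
    k = 3
    lo, hi = x[0], x[-1]
    n_int = max(int((hi - lo) / knot_spacing) - 1, 0)
    interior = np.linspace(lo, hi, n_int + 2)[1:-1]
    t = np.r_[[lo] * (k + 1), interior, [hi] * (k + 1)]
    return BSpline.design_matrix(x, t, k).toarray()


def sfm_nonlinear(
    e: Spectrum,
    l: Spectrum,
    band: BandSelection,
    max_nfev: int = 200,
) -> RetrievalResult:
    """Gaussian-SIF + spline-reflectance fit by variable projection.

    SIF(lambda) = a' exp(-(lambda - c')^2 / (2 b'^2)) (the Gaussian's nominal
    centring wavelength cancels algebraically, so the collapsed form is
    fitted); R(lambda) is a cubic spline with knots every 2 nm.  For fixed
    (a', b', c') the spline coefficients solve a linear least-squares problem,
    so only the three Gaussian parameters are iterated.  Initial a' comes from
    the sFLD estimate; bounds a' in [0, 10], b' in [5, 60] nm, c' in
    [720, 770] nm.  Non-convergence returns a flagged result with SIF NaN.
    """
    mask = e.window(*band.fit_window)
    x = e.wavelengths[mask]
    if x.size < 10 or x[-1] - x[0] < 2.0:
        raise ValueError("fit window too narrow")
    ee = e.values[mask] / math.pi
    ll = l.values[mask]
    basis = _spline_basis(x) * ee[:, None]

    def _residual(p):
        a, b, c = p
        fluor = a * np.exp(-((x - c) ** 2) / (2.0 * b * b))
        rhs = ll - fluor
        coef, *_ = np.linalg.lstsq(basis, rhs, rcond=None)
        return rhs - basis @ coef

    try:
        a0 = sfld(e, l, band).sif760
    except ValueError:
        a0 = 1.0
    a0 = min(max(a0, 1e-6), 10.0)
    p0 = np.array([a0, 20.0, 745.0])
    sol = least_squares(
        _residual, p0,
        bounds=([0.0, 5.0, 720.0], [10.0, 60.0, 770.0]),
        max_nfev=max_nfev, method="trf",
    )
    a, b, c = sol.x
    sif760 = float(a * math.exp(-((760.0 - c) ** 2) / (2.0 * b * b)))
    coef, *_ = np.linalg.lstsq(basis, ll - a * np.exp(-((x - c) ** 2) / (2 * b * b)), rcond=None)
    result = RetrievalResult(
        "SFM_nonlinear", sif760,
        {"a_prime": float(a), "b_prime": float(b), "c_prime": float(c),
         "spline_coef": coef},
        residual_norm=float(np.linalg.norm(sol.fun)), band=band,
    )
    if not sol.success:
        result.status = "failed"
        result.message = sol.message
        result.sif760 = math.nan
    return result


# -- orchestration ------------------------------------------------------------

_RETRIEVERS = {
    "sFLD": sfld,
    "3FLD": threefld,
    "iFLD": ifld,
    "SFM_nonlinear": sfm_nonlinear,
    "SFM_linear": sfm_linear,
}


def retrieve_all(
    obs: PairedObservation, band: BandSelection | None = None
) -> dict[str, RetrievalResult]:
    """Run all five retrievals on one observation; failures stay per-method."""
    if obs.e_hr is None or obs.l_hr is None:
        raise ValueError("observation lacks high-resolution spectra")
    results: dict[str, RetrievalResult] = {}
    try:
        band = band or find_band(obs.e_hr)
    except ValueError as exc:
        return {
            m: RetrievalResult(m, math.nan, status="failed", message=str(exc))
            for m in METHODS
        }
    for method in METHODS:
        try:
            results[method] = _RETRIEVERS[method](obs.e_hr, obs.l_hr, band)
        except Exception as exc:  # noqa: BLE001 - isolation contract
            results[method] = RetrievalResult(
                method, math.nan, band=band, status="failed", message=str(exc)
            )
    return results


def filter_sif(values, lo: float = 0.0, hi: float = 5.0) -> np.ndarray:
    """Physical-plausibility filter: keep lo <= SIF <= hi (bounds included).

    NaNs and out-of-range values are dropped; the bounds reflect the crop
    canopy range of far-red SIF in mW m-2 nm-1 sr-1.
    """
    arr = np.asarray(values, dtype=float)
    return arr[(arr >= lo) & (arr <= hi)]


def aggregate_halfhour(series: pd.Series, min_count: int = 5) -> pd.DataFrame:
    """Half-hourly mean and standard error of a 5-minute series.

    Bins are [h:00, h:30) and [h:30, h+1:00).  A bin's mean and standard
    error (sd/sqrt(n), ddof=1) are emitted only when strictly more than four
    of its six 5-minute slots are present; otherwise both are NaN.  Returns a
    DataFrame indexed by bin start with columns mean, stderror, n.
    """
    if not isinstance(series, pd.Series):
        raise TypeError("expected a pandas Series with a DatetimeIndex")
    clean = series.dropna()
    grouped = clean.groupby(clean.index.floor("30min"))
    out = grouped.agg(["mean", "sem", "count"]).rename(
        columns={"sem": "stderror", "count": "n"}
    )
    sparse = out["n"] < min_count
    out.loc[sparse, ["mean", "stderror"]] = np.nan
    out.index.name = "timestamp_start"
    return out
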