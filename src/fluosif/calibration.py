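"""Radiometric calibration: dark correction, panel cross-calibration, and the
cross-instrument degradation adjustment factor f_cal-corr for the SIF channel.

The SIF spectrometer's irradiance path is calibrated against a lamp whose
output degrades over the years.  Because SIF is an absolute radiance (unlike
reflectance-ratio vegetation indices), that degradation biases SIF directly.
The adjustment factor is the product of two no-intercept regression slopes:

    f1 = slope of reference PAR (quantum sensor) on spectrometer-derived PAR
    f2 = slope of reference NIR irradiance on SIF-channel NIR irradiance
    f_cal_corr = f1 * f2,      corrected SIF = raw SIF * f_cal_corr

so when the instruments agree with their references the factor is exactly 1.
"""

from __future__ import annotations

import math
import warnings
from dataclasses import dataclass
from datetime import date

import numpy as np
from scipy.constants import Avogadro, c as _c, h as _h

from .spectra import DN_RATE_UNITS, Spectrum

__all__ = [
    "CalibrationCoefficients",
    "PanelObservation",
    "CalCorrFactor",
    "dark_correct",
    "match_dark",
    "cross_calibrate_radiance",
    "select_calibration",
    "par_from_spectrum",
    "nir_integral",
    "slope_through_origin",
    "compute_f_cal",
]


@dataclass
class CalibrationCoefficients:
    """Per-wavelength gain converting DN s-1 to physical units."""

    gains: Spectrum
    channel: str = "radiance"
    session_date: date | None = None

    def __post_init__(self) -> None:
        if np.any(self.gains.values <= 0):
            raise ValueError("calibration gains must be strictly positive")

    def apply(self, dn_rate: Spectrum, quantity: str) -> Spectrum:
        if not self.gains.same_grid(dn_rate):
            raise ValueError("DN-rate grid does not match coefficient grid")
        return Spectrum(dn_rate.wavelengths, dn_rate.values * self.gains.values, quantity)


@dataclass
class PanelObservation:
    """Simultaneous view of a Spectralon reference panel.

    ``e`` is the calibrated downwelling irradiance (cosine corrector path),
    ``l_dn_rate`` the raw DN-rate spectrum of the panel seen by the bare
    fiber, and ``rho`` the panel's known reflectance (0 < rho <= 1).
    """

    e: Spectrum
    l_dn_rate: Spectrum
    rho: Spectrum

    def __post_init__(self) -> None:
        if np.any((self.rho.values <= 0) | (self.rho.values > 1)):
            raise ValueError("panel reflectance must be in (0, 1]")


@dataclass(frozen=True)
class CalCorrFactor:
    f1: float
    f2: float

    @property
    def f_cal_corr(self) -> float:
        return self.f1 * self.f2

    def __post_init__(self) -> None:
        if self.f1 <= 0 or self.f2 <= 0:
            raise ValueError("correction factors must be positive")


# -- detector-level corrections ---------------------------------------------

def dark_correct(raw_dn: Spectrum, dark_dn: Spectrum, t_int: float,
                 t_int_dark: float | None = None) -> Spectrum:
    """(raw - dark) / t_int in DN s-1, negatives clipped to zero.

    The SIF channel records a dark frame at the observation's own integration
    time, so ``t_int_dark`` (when given) must equal ``t_int``.
    """
    if t_int <= 0:
        raise ValueError("integration time must be positive")
    if t_int_dark is not None and not math.isclose(t_int_dark, t_int, rel_tol=1e-9):
        raise ValueError("dark and observation integration times differ")
    if not raw_dn.same_grid(dark_dn):
        raise ValueError("raw and dark grids differ")
    rate = np.clip((raw_dn.values - dark_dn.values) / t_int, 0.0, None)
    return Spectrum(raw_dn.wavelengths, rate, DN_RATE_UNITS)


def match_dark(library: list[tuple[float, Spectrum]], t_obs: float) -> tuple[float, Spectrum]:
    """Nearest-integration-time dark frame; ties break toward the smaller time.

    ``library`` is a list of (t_int, dark spectrum); used for the broadband
    channel whose darks are collected at night over a grid of times.
    """
    if not library:
        raise ValueError("dark library is empty")
    best = min(library, key=lambda item: (abs(item[0] - t_obs), item[0]))
    return best


def cross_calibrate_radiance(
    panel: PanelObservation, irr_coeffs: CalibrationCoefficients | None = None
) -> CalibrationCoefficients:
    """Derive radiance-path gains from the calibrated irradiance path.

    A Lambertian panel of reflectance rho under irradiance E radiates
    L = rho*E/pi, so gain(lambda) = (rho*E/pi) / DNrate_L.  ``irr_coeffs`` is
    accepted for callers that still hold raw irradiance counts; ``panel.e``
    must already be in physical units.
    """
    e = panel.e
    if irr_coeffs is not None:
        # panel irradiance supplied as DN rate; convert first
        e = irr_coeffs.apply(e, "irradiance mW m-2 nm-1")
    if not e.same_grid(panel.l_dn_rate) or not e.same_grid(panel.rho):
        raise ValueError("panel spectra must share one grid")
    dn = panel.l_dn_rate.values
    bad = np.flatnonzero(dn <= 0)
    if bad.size:
        raise ValueError(
            f"zero/negative DN rate at pixel {bad[0]} "
            f"(lambda = {e.wavelengths[bad[0]]:.3f} nm)"
        )
    gains = panel.rho.values * e.values / math.pi / dn
    return CalibrationCoefficients(
        Spectrum(e.wavelengths, gains, "mW m-2 nm-1 sr-1 per DN s-1"), channel="radiance"
    )


def select_calibration(
    candidates: list[CalibrationCoefficients],
    panels: list[PanelObservation],
    retriever,
) -> CalibrationCoefficients:
    """Pick the coefficient set whose panel-view SIF is closest to zero.

    A Spectralon panel does not fluoresce, so the correct gains should make
    the retriever (iFLD by default in the pipeline) return ~0 on panel views.
    Candidates are scored by mean |SIF760| over all panels; ties break toward
    the earliest session date.  Panels where retrieval fails are skipped with
    a warning; if every panel fails for every candidate, an error is raised.
    """
    if not candidates:
        raise ValueError("no candidate coefficients")
    if not panels:
        raise ValueError("no panel observations")
    if len(candidates) == 1:
        return candidates[0]

    scores: list[tuple[float, date, int]] = []
    for idx, cand in enumerate(candidates):
        vals = []
        for panel in panels:
            try:
                l_cal = cand.apply(panel.l_dn_rate, "radiance mW m-2 nm-1 sr-1")
                vals.append(abs(retriever(panel.e, l_cal)))
            except Exception as exc:  # noqa: BLE001 - skip-and-warn contract
                warnings.warn(f"panel retrieval failed for candidate {idx}: {exc}", stacklevel=2)
        if vals:
            sess = cand.session_date or date.max
            scores.append((float(np.mean(vals)), sess, idx))
    if not scores:
        raise ValueError("retrieval failed on every panel for every candidate")
    scores.sort()
    return candidates[scores[0][2]]


# -- broadband integrals -----------------------------------------------------

def par_from_spectrum(e: Spectrum) -> float:
    """Photosynthetic photon flux, umol m-2 s-1, from irradiance in mW m-2 nm-1.

    Trapezoid integral over 400-700 nm of E(lambda) * lambda / (h c N_A),
    converting mW to W and nm to m.
    """
    if not e.covers(400.0, 700.0):
        raise ValueError("spectrum does not cover 400-700 nm")
    mask = e.window(400.0, 700.0)
    wl = e.wavelengths[mask]
    # photons per joule at wavelength lambda: lambda / (h c); per mole: / N_A
    w_per_nm = e.values[mask] * 1e-3  # mW -> W
    photon_mol = w_per_nm * (wl * 1e-9) / (_h * _c * Avogadro)  # mol m-2 s-1 nm-1
    return float(np.trapezoid(photon_mol, wl) * 1e6)  # -> umol


def nir_integral(e: Spectrum, lo: float = 730.0, hi: float = 780.0) -> float:
    """Integrated near-infrared irradiance over [lo, hi] nm, in W m-2."""
    if not e.covers(lo, hi):
        raise ValueError(f"spectrum does not cover {lo}-{hi} nm")
    mask = e.window(lo, hi)
    return float(np.trapezoid(e.values[mask], e.wavelengths[mask]) * 1e-3)


# -- degradation adjustment --------------------------------------------------

def slope_through_origin(x: np.ndarray, y: np.ndarray) -> float:
    """No-intercept least-squares slope sum(xy)/sum(x^2) over finite pairs."""
    x = np.asarray(x, dtype=float)
    y = np.asarray(y, dtype=float)
    if x.shape != y.shape:
        raise ValueError("series must be paired (same length)")
    ok = np.isfinite(x) & np.isfinite(y)
    x, y = x[ok], y[ok]
    if x.size < 2:
        raise ValueError("need at least two paired finite values")
    sxx = float(np.sum(x * x))
    if sxx <= 0:
        raise ValueError("regressor has zero sum of squares")
    return float(np.sum(x * y) / sxx)


def compute_f_cal(
    par_spec: np.ndarray,
    par_ref: np.ndarray,
    nir_sif_channel: np.ndarray,
    nir_ref_channel: np.ndarray,
) -> CalCorrFactor:
    """Degradation adjustment factor for the SIF channel.

    f1 regresses the reference quantum-sensor PAR on the broadband channel's
    spectrum-derived PAR; f2 regresses the broadband channel's 730-780 nm
    irradiance on the SIF channel's.  The factor multiplies raw SIF, so each
    reference is the regression response.
    """
    par_spec = np.asarray(par_spec, dtype=float)
    par_ref = np.asarray(par_ref, dtype=float)
    nir_sif = np.asarray(nir_sif_channel, dtype=float)
    nir_ref = np.asarray(nir_ref_channel, dtype=float)
    if par_spec.shape != par_ref.shape or nir_sif.shape != nir_ref.shape:
        raise ValueError("regression series are misaligned")
    f1 = slope_through_origin(par_spec, par_ref)
    f2 = slope_through_origin(nir_sif, nir_ref)
    return CalCorrFactor(f1=f1, f2=f2)
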