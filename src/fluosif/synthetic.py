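"""Forward-model generator for paired irradiance/radiance spectra with known truth.

Emulates a two-channel tower spectroscopy system: a high-resolution channel
(730-780 nm, FWHM 0.15 nm) used for far-red SIF retrieval in the O2-A
absorption band, and a broadband channel (350-1100 nm, FWHM 1.1 nm) used for
vegetation indices.  The forward model is deliberately minimal: a smooth solar
continuum multiplied by a single Gaussian transmittance dip near 760.4 nm
stands in for the O2-A band, canopy reflectance is smooth, fluorescence is an
additive far-red spectrum, and the instrument applies Gaussian line-spread
convolution, optional wavelength shift (radiance channel only, a surrogate for
enclosure-temperature drift) and multiplicative shot-like noise.

Every stochastic operation takes a seed (default 42) so downstream stages are
testable bit-for-bit.
"""

from __future__ import annotations

import math
from dataclasses import dataclass, field, replace
from datetime import date, datetime, timedelta

import numpy as np
from scipy.interpolate import CubicSpline, PchipInterpolator
from scipy.ndimage import gaussian_filter1d

from .footprint import VIGrid, WeightGrid
from .solar import CST, solar_zenith_deg
from .spectra import (
    IRRADIANCE_UNITS,
    RADIANCE_UNITS,
    PairedObservation,
    Spectrum,
)

__all__ = [
    "SimConfig",
    "SceneTruth",
    "make_irradiance",
    "make_reflectance",
    "make_sif",
    "compose_radiance",
    "instrument_model",
    "generate_series",
    "generate_footprint_scene",
]

_FWHM_TO_SIGMA = 1.0 / (2.0 * math.sqrt(2.0 * math.log(2.0)))  # 1/2.3548


@dataclass(frozen=True)
class SimConfig:
    """Instrument and scene constants for the forward model.

    Wavelengths in nm.  ``absorption_depth`` is the fractional transmittance
    loss at the dip centre (0 = no dip); ``noise_sd`` is the relative standard
    deviation of the multiplicative noise; ``radiance_shift`` displaces the
    radiance channel's wavelength registration only.
    """

    wavelength_range_hr: tuple[float, float] = (730.0, 780.0)
    step_hr: float = 0.015
    wavelength_range_bb: tuple[float, float] = (350.0, 1100.0)
    step_bb: float = 0.4
    fwhm_hr: float = 0.15
    fwhm_bb: float = 1.1
    absorption_center: float = 760.4
    # at 0.15 nm FWHM the convolved O2-A feature leaves ~10% of the continuum
    # at the band bottom, hence the deep default
    absorption_depth: float = 0.9
    absorption_width: float = 0.45
    noise_sd: float = 0.0
    radiance_shift: float = 0.0
    seed: int = 42
    #: solar continuum polynomial in x = lambda - 760 nm: c0 + c1 x + c2 x^2,
    #: in mW m-2 nm-1 at full sun
    continuum_coeffs: tuple[float, ...] = (1150.0, -1.0, -0.002)
    # site / season parameters for generate_series
    latitude: float = 40.0628
    longitude: float = -88.1984
    start: date = date(2019, 6, 1)
    season_length_days: float = 120.0
    day_of_season: float = 60.0
    #: SIF760 per unit APAR, (mW m-2 nm-1 sr-1) / (umol m-2 s-1)
    sif_yield: float = 0.0015
    sif_peak: float = 740.0
    sif_width: float = 20.0

    def __post_init__(self) -> None:
        if self.step_hr >= self.fwhm_hr / 2 or self.step_bb >= self.fwhm_bb / 2:
            raise ValueError("grid step must be below FWHM/2 for each channel")
        if not 0.0 <= self.absorption_depth < 1.0:
            raise ValueError("absorption depth must be in [0, 1)")
        if self.absorption_width <= 0:
            raise ValueError("absorption width must be positive")
        if self.noise_sd < 0:
            raise ValueError("noise_sd must be nonnegative")

    def grid_hr(self) -> np.ndarray:
        lo, hi = self.wavelength_range_hr
        return np.arange(lo, hi + self.step_hr / 2, self.step_hr)

    def grid_bb(self) -> np.ndarray:
        lo, hi = self.wavelength_range_bb
        return np.arange(lo, hi + self.step_bb / 2, self.step_bb)


@dataclass
class SceneTruth:
    """Ground truth attached to one simulated observation.

    Spectra are on the high-resolution instrument grid, before line-spread
    convolution and noise.
    """

    e: Spectrum
    r: Spectrum
    sif: Spectrum
    sif760: float
    par_true: float
    fpar_true: float
    phi_f: float = math.nan
    ndvi_true: float = math.nan

    def __post_init__(self) -> None:
        if np.any(self.sif.values < 0):
            raise ValueError("truth SIF must be nonnegative")
        if np.any((self.r.values < 0) | (self.r.values > 1)):
            raise ValueError("truth reflectance must lie in [0, 1]")


# -- elementary spectra ------------------------------------------------------

def _continuum(grid: np.ndarray, coeffs: tuple[float, ...]) -> np.ndarray:
    x = grid - 760.0
    return np.polynomial.polynomial.polyval(x, np.asarray(coeffs, dtype=float))


def make_irradiance(grid: np.ndarray, config: SimConfig, scale: float = 1.0) -> Spectrum:
    """Downwelling irradiance: smooth continuum times a Gaussian O2-A dip.

    E(lambda) = scale * C(lambda) * (1 - depth * exp(-(lambda-c)^2 / 2w^2)).
    Strictly positive whenever depth < 1 and the continuum is positive.
    """
    grid = np.asarray(grid, dtype=float)
    if grid.ndim != 1 or (grid.size >= 2 and not np.all(np.diff(grid) > 0)):
        raise ValueError("wavelength grid must be 1-D ascending")
    cont = _continuum(grid, config.continuum_coeffs)
    if np.any(cont <= 0):
        raise ValueError("continuum nonpositive on the requested grid")
    trans = 1.0 - config.absorption_depth * np.exp(
        -((grid - config.absorption_center) ** 2) / (2.0 * config.absorption_width**2)
    )
    return Spectrum(grid, scale * cont * trans, IRRADIANCE_UNITS)


def make_reflectance(grid: np.ndarray, kind: str = "constant", params: dict | None = None) -> Spectrum:
    """Smooth canopy reflectance on ``grid``; values constrained to [0, 1].

    kinds
    -----
    ``constant``      params: value
    ``linear``        params: a (nm^-1), b — R = a*lambda + b
    ``smooth-spline`` params: knots (nm), values — natural cubic spline
    ``vegetation``    params: greenness in [0, 1] — plausible crop/soil mix
                      with green bump, red absorption, red edge, NIR plateau
    """
    grid = np.asarray(grid, dtype=float)
    params = dict(params or {})
    if kind == "constant":
        r = np.full_like(grid, float(params.get("value", 0.4)))
    elif kind == "linear":
        a = float(params.get("a", 0.0))
        b = float(params.get("b", 0.4))
        r = a * grid + b
    elif kind == "smooth-spline":
        knots = np.asarray(params["knots"], dtype=float)
        vals = np.asarray(params["values"], dtype=float)
        r = CubicSpline(knots, vals, bc_type="natural")(grid)
    elif kind == "vegetation":
        g = float(params.get("greenness", 1.0))
        r = _vegetation_reflectance(grid, g)
    else:
        raise ValueError(f"unknown reflectance kind: {kind!r}")
    if np.any((r < 0) | (r > 1)):
        raise ValueError("reflectance parameters produce values outside [0, 1]")
    return Spectrum(grid, r, "reflectance (unitless)")


# control points for a fully green crop canopy and for bare soil
_VEG_KNOTS = np.array([350, 450, 500, 550, 600, 660, 690, 710, 730, 760, 800, 900, 1000, 1100], float)
_VEG_VALS = np.array([0.03, 0.035, 0.05, 0.10, 0.06, 0.04, 0.06, 0.20, 0.40, 0.46, 0.47, 0.46, 0.44, 0.42])
_SOIL_VALS = np.array([0.06, 0.08, 0.10, 0.12, 0.14, 0.16, 0.17, 0.175, 0.18, 0.19, 0.20, 0.22, 0.23, 0.24])


def _vegetation_reflectance(grid: np.ndarray, greenness: float) -> np.ndarray:
    if not 0.0 <= greenness <= 1.0:
        raise ValueError("greenness must be in [0, 1]")
    vals = greenness * _VEG_VALS + (1.0 - greenness) * _SOIL_VALS
    return PchipInterpolator(_VEG_KNOTS, vals, extrapolate=True)(grid)


def make_sif(
    grid: np.ndarray,
    kind: str = "gaussian",
    magnitude_760: float = 1.5,
    params: dict | None = None,
) -> Spectrum:
    """Additive far-red fluorescence spectrum with SIF(760) = magnitude_760.

    kinds: ``constant``; ``linear`` (params: slope c, intercept set so the
    760 nm value equals the magnitude); ``gaussian`` (params: peak nm, width
    nm; renormalized so the 760 nm value equals the magnitude).
    """
    grid = np.asarray(grid, dtype=float)
    if magnitude_760 < 0:
        raise ValueError("SIF magnitude must be nonnegative")
    params = dict(params or {})
    if kind == "constant":
        v = np.full_like(grid, magnitude_760)
    elif kind == "linear":
        c = float(params.get("slope", 0.0))
        d = magnitude_760 - c * 760.0
        v = c * grid + d
        if np.any(v < 0):
            raise ValueError("linear SIF goes negative on the grid")
    elif kind == "gaussian":
        peak = float(params.get("peak", 740.0))
        width = float(params.get("width", 20.0))
        shape = np.exp(-((grid - peak) ** 2) / (2.0 * width**2))
        at760 = math.exp(-((760.0 - peak) ** 2) / (2.0 * width**2))
        v = magnitude_760 * shape / at760
    else:
        raise ValueError(f"unknown SIF kind: {kind!r}")
    return Spectrum(grid, v, RADIANCE_UNITS)


def compose_radiance(e: Spectrum, r: Spectrum, sif: Spectrum) -> Spectrum:
    """Upwelling radiance L = R*E/pi + SIF on a common grid."""
    if not (e.same_grid(r) and e.same_grid(sif)):
        raise ValueError("E, R and SIF must share the same wavelength grid")
    return Spectrum(e.wavelengths, r.values * e.values / math.pi + sif.values, RADIANCE_UNITS)


def instrument_model(
    spectrum: Spectrum,
    fwhm: float,
    out_grid: np.ndarray,
    noise_sd: float = 0.0,
    shift: float = 0.0,
    seed: int | np.random.Generator | None = 42,
) -> Spectrum:
    """Sample a truth spectrum the way a grating spectrometer would.

    Gaussian line-spread convolution with sigma = FWHM/2.3548, wavelength
    registration shift (the instrument reports out_grid but actually samples
    out_grid + shift), then multiplicative Gaussian noise of relative sd
    ``noise_sd``.  Deterministic under a fixed seed.
    """
    out_grid = np.asarray(out_grid, dtype=float)
    wl = spectrum.wavelengths
    sampled = out_grid + shift
    margin = 3.0 * fwhm * _FWHM_TO_SIGMA
    if sampled[0] - margin < wl[0] - 1e-9 or sampled[-1] + margin > wl[-1] + 1e-9:
        raise ValueError("output grid (after shift and kernel margin) outside input support")
    if fwhm > 0:
        step = float(np.mean(np.diff(wl)))
        if not np.allclose(np.diff(wl), step, rtol=1e-6):
            raise ValueError("instrument_model requires a uniform input grid")
        sigma_samples = fwhm * _FWHM_TO_SIGMA / step
        blurred = gaussian_filter1d(spectrum.values, sigma_samples, mode="nearest")
    else:
        blurred = spectrum.values
    out = np.interp(sampled, wl, blurred)
    if noise_sd > 0:
        rng = seed if isinstance(seed, np.random.Generator) else np.random.default_rng(seed)
        out = out * (1.0 + rng.normal(0.0, noise_sd, out.shape))
    return Spectrum(out_grid, out, spectrum.quantity)


# -- seasonal / diurnal series ----------------------------------------------

def _greenness(day_of_season: float, season_length: float) -> float:
    """Logistic green-up, plateau, senescence; in [0, ~0.95]."""
    up = 1.0 / (1.0 + math.exp(-(day_of_season - 25.0) / 6.0))
    down = 1.0 / (1.0 + math.exp((day_of_season - (season_length - 20.0)) / 5.0))
    return 0.95 * up * down


def _par_from_irradiance(e: Spectrum) -> float:
    """Photon flux 400-700 nm in umol m-2 s-1 (local copy to avoid an import cycle)."""
    from .calibration import par_from_spectrum

    return par_from_spectrum(e)


def simulate_observation(
    config: SimConfig,
    when: datetime,
    greenness: float,
    rng: np.random.Generator,
    phi_scale: float = 1.0,
) -> tuple[PairedObservation, SceneTruth]:
    """One paired two-channel observation plus its ground truth."""
    zen = solar_zenith_deg(when, config.latitude, config.longitude)
    sun = max(math.cos(math.radians(zen)), 0.0)

    # truth grids finer than the instrument grids so convolution is honest
    hr_truth = np.arange(
        config.wavelength_range_hr[0] - 2.0,
        config.wavelength_range_hr[1] + 2.0 + 1e-9,
        config.step_hr / 3.0,
    )
    bb_truth = np.arange(
        config.wavelength_range_bb[0] - 5.0,
        config.wavelength_range_bb[1] + 5.0 + 1e-9,
        config.step_bb / 2.0,
    )

    e_hr_true = make_irradiance(hr_truth, config, scale=sun)
    e_bb_true = make_irradiance(bb_truth, config, scale=sun)
    r_bb_true = make_reflectance(bb_truth, "vegetation", {"greenness": greenness})
    r_hr_true = Spectrum(hr_truth, np.interp(hr_truth, bb_truth, r_bb_true.values))

    # radiation bookkeeping
    par_in = _par_from_irradiance(e_bb_true) if sun > 0 else 0.0
    albedo = 0.03 + 0.02 * greenness
    fpar_canopy = min(0.94 * greenness, 1.0 - albedo - 0.01)
    par_out = albedo * par_in
    par_trans = max(1.0 - fpar_canopy - albedo, 0.0) * par_in
    par_soil = 0.10 * par_trans
    fpar_true = (par_in - par_out - par_trans + par_soil) / par_in if par_in > 0 else 0.0

    phi = config.sif_yield * phi_scale
    sif760 = phi * fpar_true * par_in
    sif_hr_true = make_sif(
        hr_truth, "gaussian", sif760, {"peak": config.sif_peak, "width": config.sif_width}
    )
    l_hr_true = compose_radiance(e_hr_true, r_hr_true, sif_hr_true)
    # far-red SIF is negligible in the broadband channel's band windows
    l_bb_true = Spectrum(bb_truth, r_bb_true.values * e_bb_true.values / math.pi, RADIANCE_UNITS)

    grid_hr = config.grid_hr()
    grid_bb = config.grid_bb()
    obs = PairedObservation(
        timestamp=when,
        e_hr=instrument_model(e_hr_true, config.fwhm_hr, grid_hr, config.noise_sd, 0.0, rng),
        l_hr=instrument_model(
            l_hr_true, config.fwhm_hr, grid_hr, config.noise_sd, config.radiance_shift, rng
        ),
        e_bb=instrument_model(e_bb_true, config.fwhm_bb, grid_bb, config.noise_sd, 0.0, rng),
        l_bb=instrument_model(
            l_bb_true, config.fwhm_bb, grid_bb, config.noise_sd, config.radiance_shift, rng
        ),
        meta={
            "solar_zenith_deg": zen,
            "par_in": par_in,
            "par_out": par_out,
            "par_trans": par_trans,
            "par_soil": par_soil,
        },
    )
    on_grid = lambda s: Spectrum(grid_hr, np.interp(grid_hr, s.wavelengths, s.values), s.quantity)
    red = np.interp(655.0, bb_truth, r_bb_true.values)
    nir = np.interp(775.0, bb_truth, r_bb_true.values)
    truth = SceneTruth(
        e=on_grid(e_hr_true),
        r=on_grid(r_hr_true),
        sif=on_grid(sif_hr_true),
        sif760=sif760,
        par_true=par_in,
        fpar_true=fpar_true,
        phi_f=phi,
        ndvi_true=(nir - red) / (nir + red),
    )
    return obs, truth


def generate_series(
    config: SimConfig,
    n_days: int,
    samples_per_day: int = 288,
    phi_variability: float = 0.0,
    hours: tuple[float, float] | None = None,
) -> list[tuple[PairedObservation, SceneTruth]]:
    """Multi-day series of paired observations on the 5-minute acquisition grid.

    ``samples_per_day`` of the 288 daily 5-minute slots are taken with a
    uniform stride, so timestamps always fall on the 5-minute cadence.  The
    seasonal canopy trajectory (logistic green-up, plateau, senescence) is
    positioned by ``config.day_of_season``; the diurnal cycle scales the
    irradiance by cos(solar zenith).  ``phi_variability`` adds a smooth
    deterministic modulation of fluorescence yield (midday depression shape)
    so physiological variation can be switched on for decomposition tests.
    When ``hours`` = (start, end) is given, every 5-minute slot inside that
    local-time window is generated instead (full half-hourly bins for the
    aggregation stage) and ``samples_per_day`` is ignored.
    """
    if n_days < 1:
        raise ValueError("n_days must be >= 1")
    if not 1 <= samples_per_day <= 288:
        raise ValueError("samples_per_day must be in [1, 288]")
    rng = np.random.default_rng(config.seed)
    stride = max(288 // samples_per_day, 1)
    if hours is not None:
        slot_minutes = list(range(int(hours[0] * 60), int(hours[1] * 60), 5))
    else:
        slot_minutes = [(k * stride * 5) % 1440 for k in range(samples_per_day)]
    out: list[tuple[PairedObservation, SceneTruth]] = []
    for d in range(n_days):
        day = config.start + timedelta(days=d)
        g = _greenness(config.day_of_season + d, config.season_length_days)
        for minutes in slot_minutes:
            when = datetime(day.year, day.month, day.day, tzinfo=CST) + timedelta(minutes=minutes)
            hour = minutes / 60.0
            phi_scale = 1.0 - phi_variability * math.exp(-((hour - 13.0) ** 2) / (2 * 2.5**2))
            out.append(simulate_observation(config, when, g, rng, phi_scale))
    return out


# -- footprint scenes --------------------------------------------------------

def generate_footprint_scene(
    nx: int,
    ny: int,
    tower_pixel: tuple[int, int],
    heterogeneity: float = 0.1,
    seed: int = 42,
    base_vi: float = 0.35,
) -> tuple[WeightGrid, VIGrid]:
    """Toy footprint: Gaussian weight plume displaced downwind of the tower,
    plus a VI raster with controllable smooth spatial variance.

    ``heterogeneity`` is the relative standard deviation of the VI field
    (0 = perfectly uniform).  The SIF pixel coincides with the tower pixel.
    """
    r0, c0 = tower_pixel
    if not (0 <= r0 < ny and 0 <= c0 < nx):
        raise ValueError("tower pixel outside grid")
    if heterogeneity < 0:
        raise ValueError("heterogeneity must be nonnegative")
    rng = np.random.default_rng(seed)
    rows, cols = np.mgrid[0:ny, 0:nx]
    # plume centre displaced a few pixels from the tower
    dr, dc = rng.integers(-max(ny // 10, 1), max(ny // 10, 1) + 1, 2)
    sig = max(min(nx, ny) / 8.0, 1.0)
    w = np.exp(-(((rows - r0 - dr) ** 2) + ((cols - c0 - dc) ** 2)) / (2.0 * sig**2))
    weights = WeightGrid(w, tower_pixel)

    if heterogeneity == 0:
        vi = np.full((ny, nx), base_vi)
    else:
        from scipy.ndimage import gaussian_filter

        field_ = gaussian_filter(rng.standard_normal((ny, nx)), sigma=max(min(nx, ny) / 12.0, 1.0))
        sd = field_.std()
        if sd > 0:
            field_ /= sd
        vi = base_vi * np.clip(1.0 + heterogeneity * field_, 0.05, None)
    return weights, VIGrid(vi, tower_pixel)
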