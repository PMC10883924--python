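# Methods

This note documents the models implemented in `fluosif`, the defaults they
run with, the numerical choices that matter, and what the synthetic test bed
does and does not establish about real field data.

## Measurement model

Both channels observe downwelling irradiance *E* (cosine corrector,
mW m⁻² nm⁻¹) and upwelling canopy radiance *L* (nadir bare fiber, 25° FOV,
mW m⁻² nm⁻¹ sr⁻¹).  The target area of the nadir fiber is a circle of
diameter 2·h·tan(FOV/2): ≈2.2 m from 5 m above the surface, ≈1.1 m when a
2.5 m canopy stands under the fiber.  Radiance decomposes as
L = R·E/π + SIF with R the hemispherical–directional reflectance factor and
SIF the additive fluorescence radiance.  Timestamps are fixed-offset Central
Standard Time (UTC−6, never daylight saving); solar geometry uses the
standard NOAA low-accuracy ephemeris (good to ≲0.05°, ample for daytime
masks and cos(SZA) scaling).

## SIF₇₆₀ retrievals

All five operate on the high-resolution channel inside the O₂-A band and
report SIF at the absorption wavelength (λ_in ≈ 760.4 nm).

**Band selection.** λ_in is the irradiance minimum in 758.5–761.5 nm; the
shoulders are the irradiance maxima of 757–759.5 nm (left) and 768–772 nm
(right).  A dip shallower than 1% of the shoulder-interpolated continuum is
rejected ("no absorption feature").  All windows are configurable; the
right shoulder is the out-of-band reference (outside the telluric band).

**sFLD** is the literal two-band formula with single-pixel reads — it is the
baseline method and is algebraically exact when R and SIF are equal in and
out of the band.

**3FLD** interpolates the two shoulders linearly to λ_in.  Shoulder values
are window means over ±0.2 nm (the interpolation weights use the windows'
mean wavelengths); the in-band read stays single-pixel.  This choice is
deliberate: on the smooth continuum a window mean equals the value at the
window's mean wavelength for any linear R and SIF, so the method's exactness
regime (flat continuum + linear R + linear SIF) is preserved to machine
precision, while shoulder pixel noise is averaged down.  A window mean of
the curved dip bottom would *not* be exact, which is why the in-band read is
not averaged.

**iFLD** forms the apparent reflectance R_app = πL/E, fits cubic
least-squares splines to R_app and E over the shoulder regions only
(absorption region excluded; knots inside each shoulder, falling back to a
single cubic when the shoulders are sparse), and applies

α_R = R_app(λ_out)/R̃_app(λ_in), α_F = E(λ_out)/Ẽ(λ_in),
SIF = (α_R·E_out·L_in − E_in·L_out)/(α_R·E_out − α_F·E_in).

iFLD is the variant that exploits the whole spectrum rather than discrete
bands, so all four of its band reads are ±0.2 nm window means; its accuracy
contract is ≈2% on clean scenes, not machine exactness.  On the simulator it
recovers flat-R/constant-SIF truth to ~10⁻⁵ relative and has the lowest
noise floor of the line-depth family (median |error| ≈ 0.06 mW m⁻² nm⁻¹ sr⁻¹
at 1% pixel noise).

**SFM-linear** solves ordinary least squares for
L = (aλ+b)·E/π + (cλ+d) over the fit window (default 758–772 nm),
parameterized in x = λ−760 so the SIF intercept *is* SIF₇₆₀ and the design
is well scaled.  Without absorption contrast the E-columns are numerically
collinear with the polynomial columns; the solver rejects designs whose
column-normalized condition ratio falls below 10⁻⁶ ("degenerate window" —
the no-dip case).  Exact (≤10⁻⁶) whenever the truth lies in the model
family.  Caveat: because noisy E appears in the regressors, the method has a
classic errors-in-variables bias that scales with the *square* of the
relative noise and is amplified by the large R·E/π term; at 1% pixel noise
this drives estimates strongly negative and most retrievals fall outside the
physical filter.  At realistic detector SNR (noise ≲0.2%) the effect is
negligible.

**SFM-nonlinear** models SIF as a Gaussian a′·exp(−(λ−c′)²/2b′²) (the
published form subtracts a nominal centring wavelength from both λ and c′,
which cancels; the collapsed form is fitted) and R as a cubic B-spline with
knots every 2 nm.  The spline coefficients are linear given (a′,b′,c′), so
the fit uses variable projection: `scipy.optimize.least_squares` iterates
only the three Gaussian parameters (bounds a′∈[0,10], b′∈[5,60] nm,
c′∈[720,770] nm; a′ initialized from sFLD, b′=20 nm, c′=745 nm).
Non-convergence is returned as a flagged result with SIF missing, never an
exception.  Self-consistency on Gaussian-SIF truth is ~3·10⁻⁴ — not machine
precision, because a natural-spline truth reflectance is not exactly inside
the 2-nm-knot fitted family and the Gaussian/spline decomposition has a
shallow joint valley; the retrieval wavelength itself is pinned by the dip
and recovered well below 10⁻³.

**Wavelength-drift sensitivity.** The enclosure-temperature surrogate is a
radiance-only registration shift.  Under a 0.02 nm shift the implementation
shows SFM-linear ≫ FLD methods (≈5.8 vs ≈0.2 mW m⁻² nm⁻¹ sr⁻¹), but
SFM-nonlinear is *less* sensitive than the FLDs (≈0.03): the shift produces
an antisymmetric residual across the dip, which the broad Gaussian SIF term
cannot project onto (the 2-nm-knot spline cannot either), whereas the
linear-SIF tilt can, and the FLD in-band reads sit one half grid step off
the dip minimum where the second-order shift effect is ≈0.2.  The common
qualitative claim that *both* spectral-fitting variants are more
temperature-sensitive than line-depth methods does not hold under this
surrogate; reproducing it would require a drift model that also decalibrates
the fitted reflectance (e.g. a shift applied between the E and L paths of
the same fit in a correlated way).

**Filtering and aggregation.** Retrievals outside [0, 5] mW m⁻² nm⁻¹ sr⁻¹
are discarded (bounds inclusive; the filter runs on raw retrievals before
the calibration correction, with bounds configurable).  5-minute values are
averaged to half-hour bins [h:00,h:30), [h:30,h+1:00); a bin is reported
only when more than four of its six slots survive, with the standard error
sd/√n as the uncertainty.  In-memory missing is NaN; −9999 appears only on
disk.

## Calibration

Dark frames: the SIF channel records a dark at the observation's own
integration time (mismatches are an error); the broadband channel matches
the nearest library integration time, ties toward the smaller (deterministic
and conservative).  Negative dark-corrected counts clip to zero.

Radiance-path gains come from a Lambertian Spectralon panel:
gain = (ρ·E/π)/DNrate.  Among candidate calibration sessions the pipeline
keeps the one minimizing mean |SIF₇₆₀| retrieved (iFLD, the recommended
retriever) over all panel views — a fluorescence-free panel should retrieve
zero.  Ties break toward the earliest session.

The lamp-degradation factor multiplies raw SIF, so each regression is
oriented with the trusted reference as the response:
f1 = Σxy/Σx² of quantum-sensor PAR on spectrometer PAR,
f2 = the same for broadband-channel NIR (730–780 nm integral) on
SIF-channel NIR; f_cal_corr = f1·f2 and equals 1 exactly when the
instruments agree.  The module computes the factor per provided paired
series; windowing (per site-year vs per session) is the caller's choice.
PAR from spectra is the trapezoid photon integral of E·λ/(hcN_A) over
400–700 nm.

## Footprint upscaling

Weights and the per-pixel index raster are inputs (3 m pixels, row-major,
northwest origin); weights are renormalized to sum to one (the
pre-normalization sum is kept as a diagnostic) and renormalized again over
valid pixels when the index raster has gaps.  The ratio assumes PAR and
fluorescence yield uniform across the footprint, so it reduces to
Σwᵢ·VIᵢ / VI_SIFpixel, and the upscaled SIF tends to the nadir SIF as field
heterogeneity vanishes.  Daily index grids pair with half-hourly weights by
date.

## Vegetation indices and decomposition

Reflectance is πL/E per wavelength.  Band windows: NIR 770–780 nm (the
detector is noisy past 800 nm, so nothing beyond 800 nm is used), red
650–660, blue 460–470, red edge 720–730, green 545–565; the four
single-wavelength bands (531, 570, 708, 775 nm) are read as ±1 nm means
because single pixels of a 1.1 nm-FWHM instrument are noise-prone.
Five-minute reflectance is averaged per half hour *first* and the indices
computed from the mean spectrum — the two orders provably differ for ratio
indices.  fPAR_VI = 1.37·RededgeNDVI − 0.17 is reported unclipped in the VI
output (it was developed for corn and soybean and is not applied to
miscanthus); it is clipped to [0,1] only where fPAR enters the
decomposition denominators.

Measured fPAR is (PAR_in − PAR_out − PAR_trans [+ PAR_soil])/PAR_in, clipped
to [0,1] with a flag; APAR = fPAR·PAR_in; f_esc = NIRv/fPAR; and
Φ_F = SIF/(fPAR·PAR·f_esc), which makes SIF = fPAR·PAR·Φ_F·f_esc an identity
per record.  Φ_F keeps the instruments' mixed units (energy-flux SIF over
photon-flux APAR, sr⁻¹-scaled); only its variation is interpreted.

Peak season is the set of days whose daily daytime-average NDVI exceeds 85%
of the site-year maximum (daily averaging first, so the threshold is not
noise-driven).  Daily daytime averages use the 20 half-hours 08:00–18:00 CST
and require strictly more than 75% of them (≥16).  LMG relative importance
averages each regressor's sequential R² increment over all p! orderings
(exact enumeration, p ≤ 6, subset-R² cache); contributions telescope to the
full-model R² and are permutation- and affine-invariant.  The default
regression of SIF on {fPAR, PAR, Φ_F, f_esc} is linear in the raw factors; a
log-space option makes the multiplicative identity additive, and
standardized regressors are available by flag.

## The synthetic test bed

The simulator is the package's source of ground truth, not a radiative
transfer model.  It emulates: a smooth solar continuum (quadratic in λ,
≈1150 mW m⁻² nm⁻¹ at 760 nm at full sun) times a **single Gaussian
transmittance line** (centre 760.4 nm, depth 0.9, width 0.45 nm — at
0.15 nm FWHM the real convolved O₂-A band leaves roughly 10% of the
continuum at the bottom, and one resolvable dip suffices to exercise every
retrieval); smooth canopy reflectance (constant/linear/spline families plus
a plausible crop/soil mixture driven by a greenness parameter); additive
far-red SIF (constant, linear, or Gaussian peaking at 740 nm, width 20 nm,
pinned to its 760 nm value); Gaussian line-spread convolution; multiplicative
Gaussian noise applied per output pixel (a shot-noise proxy); and an optional
radiance-only wavelength shift as the enclosure-temperature surrogate.
Series follow the 5-minute acquisition cadence with cos(SZA) diurnal scaling,
a logistic green-up/plateau/senescence seasonal trajectory, consistent PAR
streams (PAR_in − PAR_out − PAR_trans + PAR_soil stays within [0, PAR_in]),
SIF truth proportional to absorbed PAR with yield 0.0015
(mW m⁻² nm⁻¹ sr⁻¹)/(µmol m⁻² s⁻¹) — peak canopy SIF ≈ 2.5–3, always inside
the 0–5 filter — and an optional midday yield depression for decomposition
scenarios.  Footprint scenes are Gaussian weight plumes over a smooth random
index field of controllable relative variance.  Every stochastic operation
is seeded (default 42).

What passing tests therefore show: the algebra, estimators, aggregation
rules and orchestration are correct on data whose generating process is
known.  What they do not show: performance under multi-line O₂-A structure,
BRDF and sun-glint effects, atmospheric variability, real detector
nonlinearity or stray light — none of which the generator models.

## Problem sizes and determinism

Default test and acceptance runs use desk-scale problems: 500 Monte-Carlo
draws for the noise study, two-to-three simulated days at 5-minute cadence
for pipeline statistics, 64×64 footprint scenes.  These sizes were chosen so
the entire suite replays in minutes on one core while every statistic is
estimated well away from its decision threshold.  All randomness flows from
explicit `numpy.random.Generator` seeds; pipeline reruns with the same seed
are byte-identical.

## Known limitations

- The O₂-A band is a single Gaussian line; retrieval accuracy figures do not
  transfer quantitatively to real spectra.
- SFM-linear's errors-in-variables bias at ≥1% regressor noise empties its
  half-hourly product; the method is retained because it is part of the
  protocol and behaves correctly at realistic SNR.
- The Φ_F units are instrument-relative; comparisons are meaningful within a
  site-year, not across instruments.
- `validate()` computes the full technical-validation statistics for any
  product file, but the deposited multi-year field product itself is an
  external download; the packaged metadata table (15 site-years: 8 corn,
  5 soybean, 2 miscanthus) is the only field data shipped.
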