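# Methods

## The boundary statistic

Where an oxygen minimum zone (OMZ) is present, the epipelagic community —
mostly crustacean and gelatinous zooplankton plus small pelagic fish —
occupies the oxygenated layer above the lower oxycline and thins out
abruptly below it. The package estimates the boundary per ping as the depth
`Z_VEEC` at which the cumulative echo energy, integrated downward from the
surface, first reaches a threshold fraction (default 0.98).

Cumulation is performed in the linear domain, sv = 10^(Sv/10): fractions of
a cumulated sum are only measure-like for a non-negative additive quantity,
which Sv in dB is not. The crossing depth is linearly interpolated inside
the crossing cell (a cell-precision flag returns the cell bottom instead).
Pings whose total weighted energy does not exceed a configurable floor are
marked invalid rather than assigned a depth.

Two channels feed the statistic: the "other" (non-fish) channel, by default
the 120 kHz no-fish Sv, and the fish channel, by default the 38 kHz fish Sv
(the swimbladder side of the frequency pair). Fish echoes are down-weighted
by 10⁻³ so that a handful of dense schools (~−50 dB against ~−85 dB
zooplankton at 38 kHz) cannot drag the community boundary. Both channel
assignments are configuration, not hard-coded: on school-free scenes the
120 kHz channel alone reproduces the combined estimate within one cell, and
the tests assert exactly that.

Why 0.98: lower thresholds sit visibly above the main limit of the
community; 0.99 turns erratic whenever a few strong scatterers lie below the
main boundary (the acceptance suite reproduces this as a ≥2× variance
inflation of the 0.99 series under sparse deep scatterers). `threshold_scan`
computes the 0.95–0.99 family plus per-ping cumulative-gradient (ΔSv)
profiles so the choice can be re-examined on any data set.

## Preprocessing

* **Noise model.** N(R) = 20·log₁₀(R) + 2αR + offset, with R the range below
  the transducer (m), α the absorption coefficient (dB m⁻¹, defaults
  0.0097 at 38 kHz and 0.0267 at 120 kHz for seawater) and `offset` the
  noise at 1 m (dB). α and offset are configuration inputs; a helper
  (`fit_noise_offset`, an extension beyond the core method) estimates the
  offset by least squares from the deepest 10 % of bins under a signal-free
  assumption.
* **Linear minus.** The noise field is subtracted in the linear domain;
  cells at or below the noise level have no remainder and become no-data —
  masking is the contract, not an error.
* **Resampling.** Echograms are averaged onto common elementary cells
  (default 1 ping × 0.75 m), arithmetic mean in the linear domain (standard
  echo-integration practice), no-data members excluded, output cell tops
  aligned to the surface, partial bottom cells dropped.
* **Depth convention.** Metres below the sea surface, positive downward.
  Echosounder sample ranges are below-transducer; the transducer depth
  (default 3.4 m) is added once at construction/load time, so every depth
  the package reports is already surface-referenced.
* **Diel classes.** Day is solar elevation > 0°, night < −12° (nautical
  dusk), twilight between; bounds are configurable and the solar position
  uses the standard low-precision NOAA/Meeus algorithm (~0.01°). Twilight
  pings are removed before the statistic because migrating mesopelagic
  organisms cross the boundary at dusk and dawn.

## Fish/other discrimination

A cell is fish iff (Sv38 + Sv120 > −135 dB) ∧ (Sv120 − Sv38 < +2 dB). The
sum is taken in the dB domain — deliberately: it is a contrast enhancement,
and a −135 dB criterion is only meaningful for a dB sum of two ~−65…−70 dB
channels. The +2 dB margin admits fish insonified more strongly by the
narrower 120 kHz beam. Both inequalities are strict; a cell exactly at the
threshold is not fish. Every valid cell is exactly one of {fish, other}.

## Oxycline features from DO profiles

Profiles (continuous CTD-O2 at ~0.03 mL L⁻¹ precision, or discrete Niskin
bottles at 0/10/25/50/75/100/150 m with ~0.1 mL L⁻¹) are linearly
interpolated. Features per profile:

* `z_iso` — shallowest downward crossing of the 0.8 mL L⁻¹ isoline
  (Z_0.8); undefined when the cast never reaches it.
* `z_max_grad` — depth of the most negative vertical DO gradient (1 m grid,
  centred differences, one-sided ends); the split between upper and lower
  oxycline.
* `z_bot_oxy` — base of the lower oxycline: the deeper of (A) the
  shallowest depth where DO < 0.5 mL L⁻¹ and (B) the deepest depth where
  the gradient is ≤ −0.02 mL L⁻¹ m⁻¹ (≡ −0.9 µmol kg⁻¹ m⁻¹ at density
  1.025 kg L⁻¹ and 22.392 mL mmol⁻¹). "Weaker than" is implemented as
  more-negative-than; the opposite reading would always select the profile
  bottom. Note that one published statement of this criterion prints
  −0.2 mL L⁻¹ m⁻¹ where the methods derivation gives −0.02; the derived
  value, consistent with the µmol kg⁻¹ m⁻¹ figure, is used here.

## Validation

Z_VEEC is displaced by internal waves at ~100 m horizontal scales, so
station comparisons average the closest 300 valid pings within 5 km of each
station (fewer ⇒ the station is excluded — a result, not an error). A
per-station `visible_track_depth_m` override represents the case where the
probe track is visible in the echogram and the crossing depth is read
exactly; detecting such tracks by image processing is out of scope.
Matched pairs feed ordinary least squares (slope, intercept, n, F of the
slope, two-sided p, R²) via statsmodels, one-way ANOVA for day/night and
inshore/offshore effects via scipy, and gridded difference maps with
box-plot summaries. Distances are great-circle on a 6371 km sphere —
adequate at the 5 km matching scale. p-values are reported at machine
precision and uncorrected (single planned comparisons). The
inshore/offshore zone is an input label on each station, not computed (no
objective rule exists for it).

## Habitat volume

Scattered Z_VEEC points are interpolated by triangulation-based linear
interpolation onto a regular lon/lat grid (kriging is deliberately out of
scope); cells outside the convex hull are invalid. The habitat volume over
a GeoJSON polygon mask is Σ z[km] × cell-area[km²], with spherical cell
areas (R²·Δλ·Δφ·cosφ) and boundary cells contributing their fractional
polygon-inside area. The sea surface is the upper bound; an optional
bathymetry grid clips z in shallow cells (off by default). A meridional
profile averages valid cells within 200 km of a supplied coastline
polyline, per grid-latitude band.

## Wavelet analysis

The Z_VEEC space series is resampled to uniform 100 m spacing (ping spacing
varies with vessel speed), demeaned (linear detrending by flag), and
convolved with Morlet atoms ψ₀(η) = π^(−1/4) e^(iω₀η) e^(−η²/2), ω₀ = 6,
normalized to unit energy per scale: W(s,x) = Σ d(x′)·√(dx/s)·ψ₀*((x′−x)/s).
Scales are dyadic with δj = 0.125 from s₀ = 2·dx; the equivalent Fourier
wavelength is s·4π/(ω₀+√(2+ω₀²)) ≈ 1.03 s. The convolution is evaluated in
the Fourier domain with zero padding past the widest atom's support, so it
equals direct convolution to rounding error (asserted against a brute-force
oracle).

Energy is displayed as the adjusted power |W|²/s, which gives
equal-amplitude oscillations equal peak power across scales. Note the
consequence: for white noise the *raw* power E|W|² is scale-flat (≈σ²), so
the adjusted spectrum of noise decays as 1/s — the tests assert the raw
flatness, which is the well-defined invariant. The cone of influence is
coi(x) = min(distance to either edge)/√2, the e-folding distance of an
edge-truncated atom; cells with s > coi(x) are untrustworthy. Pointwise
significance uses an AR(1) (red-noise) background with lag-1
autocorrelation estimated from the series: |W|² is χ²₂-distributed about
σ²·P(f), and a cell is significant at level q when |W|² exceeds
σ²·P(f)·χ²₂(q)/2. The AR(1) choice is this package's documented convention
(the classical framework's default), and a Monte-Carlo test checks the
false-positive rate is ~5 % at the 95 % level.

## The synthetic-scene generator

The generator emulates a cross-shore coastal transect (1 ping s⁻¹,
10 knots, 0.25 m native samples to 150 m, transducer at 3.4 m):

* **Oxycline field** Z*(x): linear trend + sinusoidal meso/submesoscale
  undulations + optional Gaussian filament ridge.
* **Zooplankton layer** above Z*, −85 dB at 38 kHz and −75 dB at 120 kHz,
  tapering to zero within 2 m below the base (the sharpness of the organism
  cutoff, a generator parameter). Per-cell mean-one lognormal speckle
  (5 dB) emulates echo variability; the same multiplicative field applies
  at both frequencies (scatterer density fluctuations are
  frequency-coherent), which keeps the dB difference clean.
* **Internal-wave displacement**: the rendered layer base is Z*(x) plus a
  smooth zero-mean displacement field (default σ = 4 m, 0.3 km
  correlation). This reproduces the ping-scale variability of the boundary
  (vertical excursions over ~100 m horizontal) and is the dominant noise
  term in Z_VEEC; per-cell speckle alone contributes only ~0.5 m. Station
  DO profiles are tied to the clean Z*, so the displacement acts as
  measurement noise in validation experiments.
* **Fish schools**: ellipses in ping × depth space, −50 dB at 38 kHz with
  Sv120 − Sv38 ∈ [−3, 0] dB.
* **Mesopelagic community**: optional. "merged" adds a (weaker, −90/−82 dB)
  community over the same vertical band at night, sharing the epipelagic
  patch structure — co-located communities are aggregated by the same
  physical processes — so the boundary is unchanged by construction,
  mirroring the observation that the boundary is diel-invariant. "deep"
  places the layer inside the OMZ (115–140 m) with independent patchiness;
  it demonstrates how a detectable deep community would bias the statistic.
* **Sparse deep scatterers**: on a configurable fraction of pings, a small
  blob at 120 m carrying ~1.5 % of the column energy (zooplankton-like
  frequency response). This is the regime that destabilises a 0.99
  threshold while leaving 0.98 stable.
* **Noise**: the deterministic field N(R) per frequency added in the linear
  domain, so the linear-minus correction can cancel it exactly and
  end-to-end denoising is testable.
* **DO profiles**: logistic family DO(z) = 0.05 + 5/(1+e^((z−z₅₀)/5))
  (mL L⁻¹), with z₅₀ chosen so the 0.8 mL L⁻¹ isoline lies exactly at
  Z*(x). The max-gradient depth is then ~8.7 m above Z_0.8 and the
  lower-oxycline base ~11 m below it, so Z_0.8 sits inside the lower
  oxycline as observed. Continuous stations sample every metre; Niskin
  stations sample the seven bottle levels and visibly degrade interpolated
  isoline depths.

Randomness is split into independent substreams (field phases, speckle,
fish, mesopelagic, displacement) seeded from one integer, so a day and a
night scene with the same seed are cell-for-cell comparable and every
output is bit-reproducible.

What the generator does *not* emulate: Rayleigh/Rice sample statistics and
beam geometry, transient/impulse noise, seabed echoes (scenes are
bottomless), attenuation events, 3-D school morphology, and any horizontal
structure in DO other than through Z*(x). Passing tests therefore show the
pipeline's correctness and its statistical behaviour under the stated scene
model — not robustness to every artefact of real echograms.

## Problem sizes and numerical choices

The test and acceptance experiments use a 25.7 km / ~5000-ping survey with
96 stations for validation (one station per ~270 m; adjacent matching
windows overlap, so station errors are correlated and regression
coefficients vary visibly across seeds — the tests' bands account for
this), a 60 km transect for wavelet scale recovery, 10 km scenes for the
diel and threshold experiments, and 100 replicates of n = 300 AR(1) series
for significance calibration. Monte-Carlo area integration uses 4×10⁵
points. Tolerances: one elementary cell (0.75 m) for depth recovery; 10⁻⁶
relative for the CWT against direct convolution; 1 % for volume against
Monte Carlo.

Degenerate inputs are defined, not accidental: all-no-data pings are
invalid; profiles that never cross an isoline yield undefined features;
stations with fewer than 300 in-range pings are excluded; an empty
mask-grid intersection is a zero volume with a warning; an all-twilight
survey is an empty (warned) echogram.

## Known limitations

* The 98 % statistic reads slightly above the layer base, proportionally to
  its depth, so regressions of Z_VEEC on Z_0.8 have slopes just below 1 and
  DO sampled at Z_VEEC averages slightly above 0.8 mL L⁻¹ on synthetic
  surveys. This mirrors the behaviour of the method, not a defect of the
  implementation.
* α/offset noise-parameter estimation from data is a simple least-squares
  helper, not a full noise-estimation procedure.
* No .raw-file parsing: echograms enter via the NetCDF/CSV dialects
  documented in `veec.echogram`.
* The habitat mask is an input polygon; classifying water masses to build
  it is out of scope, as are kriged interpolation and biomass estimation.
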