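# veec — acoustic estimation of the upper limit of oxygen minimum zones

Oxygen minimum zones (OMZs) are vast subsurface layers almost devoid of
dissolved oxygen (DO). Their upper boundary — the base of the lower
oxycline — caps the vertical habitat of most epipelagic organisms, and it is
rising as OMZs expand. Conventional monitoring relies on discrete
oceanographic casts and therefore resolves the boundary poorly in space.

`veec` implements an acoustic alternative: because zooplankton and small
pelagic fish crowd into the oxygenated surface layer, the lower limit of the
**v**ertical **e**xtension of the **e**pipelagic **c**ommunity, observed by
any bi-frequency (38/120 kHz) scientific echosounder, tracks the OMZ upper
boundary ping by ping — a ~5 m along-track resolution at survey speed,
versus tens of kilometres between casts.

## The statistic

For each ping, volume backscattering strength Sv (dB re 1 m⁻¹) is cumulated
downward from the surface in the linear domain (sv = 10^(Sv/10)):

    Z_VEEC = depth at which the weighted cumulative echo fraction
             first reaches 0.98

with the weighted column w(z) = sv_other(z) + 10⁻³ · sv_fish(z). Fish are
down-weighted because a single school can carry ~35 dB more echo than the
zooplankton that actually fills the habitat. Fish cells are identified
bi-frequency: a cell is fish when Sv38 + Sv120 > −135 dB (dB-domain contrast
sum) and Sv120 − Sv38 < +2 dB (swimbladder fish scatter at least as strongly
at 38 kHz; zooplankton much more strongly at 120 kHz).

Upstream of the statistic, echograms are noise-corrected by subtracting the
range-dependent field N(R) = 20 log₁₀(R) + 2αR + offset in the linear domain
("linear minus"), resampled to common elementary cells of 1 ping × 0.75 m,
and twilight pings are removed (migrating mesopelagic organisms cross the
boundary at dusk/dawn). Z_VEEC is validated against the depth of the
0.8 mL L⁻¹ DO isoline (Z_0.8) and the base of the lower oxycline from CTD-O2
or Niskin-bottle profiles, by averaging Z_VEEC over the closest 300 pings
within 5 km of each station and regressing. Gridded Z_VEEC fields integrate
into habitat volume over a GeoJSON mask, and a Morlet continuous wavelet
transform of the Z_VEEC space series quantifies mesoscale and submesoscale
structure.

Because no survey data ship with the package, a first-class synthetic-scene
generator renders bi-frequency surveys with known ground truth (oxycline
field, zooplankton layer, fish schools, mesopelagic migrators, noise, and DO
profiles whose 0.8 mL L⁻¹ isoline lies exactly at the layer base), so every
stage is testable end to end.

## Worked example

```python
import numpy as np
import veec
from veec.preprocess import preprocess_bifrequency, drop_twilight

spec = veec.SceneSpec(length_km=25.7, z_star_start_m=20.0, z_star_end_m=120.0,
                      n_schools=6, seed=1)
echograms, profiles, truth = veec.generate_scene(spec, n_stations=96)

prepped = drop_twilight(preprocess_bifrequency(echograms))
series = veec.zveec_series(prepped)            # one Z_VEEC per ping
print(round(np.nanstd(series.z_veec_m - truth.z_star_m), 2))

iso = {p.station_id: veec.z_isovalue(p, 0.8) for p in profiles}
matches = veec.match_survey(series, profiles, iso_depths=iso)
r = veec.ols_regression(matches["z_ref_m"], matches["z_veec_mean_m"])
print(round(r.slope, 3), round(r.intercept, 2), round(r.r2, 3))
```

prints

```
4.22
0.931 4.28 0.991
```

The first number is the per-ping spread of Z_VEEC about the true oxycline
depth (≈4 m, the internal-wave displacement the scene emulates). The second
line is the station-level regression of Z_VEEC on Z_0.8: slope near 1,
intercept of a few metres and R² ≈ 0.99 — the acoustic depth is an unbiased
proxy of the DO isoline depth. (The slope sits slightly below 1 because the
98 % threshold reads marginally above the layer base, proportionally to its
depth.)

A command line wraps the same stages:

```sh
veec --seed 1 --out run/ simulate --n-stations 24
veec --out run/ zveec run/sv38.nc run/sv120.nc --threshold 0.98 --fish-weight 1e-3
veec --out run/ oxycline run/do_profiles.csv
veec --seed 1 --out run/ run          # full pipeline + JSON report
```

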