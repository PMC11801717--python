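# vegeff — vegetation restoration effectiveness analysis

`vegeff` is a pipeline for evaluating how well a region's vegetation has
recovered under ecological engineering programmes, and for attributing the
spatial pattern of that recovery to climate, soil, geography, socioeconomic
and engineering drivers. It is aimed at landscape ecologists and remote
sensing analysts working with annual raster time series (NDVI/FVC, NPP) over
an administrative tessellation.

## What it computes

1. **Composite index.** FVC (from NDVI via the dimidiate pixel model) and
   NPP are min–max normalized and averaged into a vegetation
   quality–quantity index, `VQQI = (N_FVC + N_NPP)/2 × 100%`, combining
   vegetation structure and function with equal weights.
2. **Trend grading.** Each pixel's VQQI is regressed on year (OLS); the
   F-tested slope is classified into five grades — extremely significant
   improvement (p < 0.01), significant improvement, no significant change
   (p ≥ 0.05), significant degradation, extremely significant degradation —
   weighted ω = {+2, +1, 0, −1, −2}.
3. **County scores.** Grade area fractions A_k give each county's net change
   `N_t = Σ ω_k A_k ∈ [−2, 2]`; dividing by the baseline N0 (cross-county
   mean N over the first programme phase, 2000–2010) yields the
   effectiveness `E_t = N_t/N0`, classed degraded (E ≤ 0), not-significant
   (0 < E ≤ 1) or significant (E > 1). The regional VQQI series also gets an
   OLS trend and a Pettitt change-point year.
4. **Attribution.** Drivers (land-use transition intensities, afforestation
   normalized by county area, zonal climate/soil/terrain aggregates) are
   discretized by exact natural breaks and fed to the Geodetector:
   `q = 1 − Σ N_h σ_h²/(N σ²)` per factor with an F-based significance test,
   top-50%-and-significant main-factor selection, pairwise interaction
   typing, and risk detection of each factor's favorable range.

A synthetic-data module generates every input with known ground truth
(injected trends, change-point year, designed q values, exact land-use
transition bookkeeping), so the whole chain is testable offline. See
`docs/methods.md` for the model details and design choices.

## Worked example

The numbered scripts under `analysis/` run the bundled demonstration
scenario — 21 years (2000–2020) on a 180×180 km grid of 81 counties, 60% of
counties given strong positive greening trends, a step change entering 2011,
and 14 drivers with designed explanatory power:

```sh
$ python analysis/02_indices.py 1
mean VQQI 35.8%, trend +0.209%/yr (p = 9.3e-16)
change year 2010 (Pettitt p = 0.0011); injected step year was 2011

$ python analysis/03_trend_effectiveness.py 1
2000-2010: degraded 39.5% (32 counties), not-significant 0.0% (0 counties), significant 60.5% (49 counties)
2000-2015: degraded 39.5% (32 counties), not-significant 0.0% (0 counties), significant 60.5% (49 counties)
2000-2020: degraded 39.5% (32 counties), not-significant 0.0% (0 counties), significant 60.5% (49 counties)
baseline N0 = 0.321 (cross-county mean net change 2000-2010)

$ python analysis/04_attribution.py 1
factor ranking (designed q in the scenario spec):
  annual_precipitation                     q=0.750* (designed 0.75)
  gdp                                      q=0.601* (designed 0.61)
  accumulated_afforestation_intensity      q=0.570* (designed 0.57)
  ...
  soil_moisture_content                    q=0.028  (designed 0.03)
main factors: annual_precipitation, gdp, accumulated_afforestation_intensity, returning_farmland_to_grassland, population_density, annual_temperature, terrain_slope
strongest interaction: annual_precipitation x population_density q=1.000 (enhance-bivariate)
risk detector: annual_precipitation favors strata [6, 7] (value range 6.01-7.43)
```

Reading the output: the VQQI series rises at ~0.21%/yr; the Pettitt test
places the regime change within a year of the injected 2011 step (a step
embedded in a trend is localizable to ±1 year); the significant-restoration
area (60.5%) matches the designed 49/81 counties; and the factor detector
recovers each driver's designed q to within the generator tolerance, keeping
exactly the designed top half as main factors.

The same chain is available as a CLI (`vegeff simulate|indices|trend|
effectiveness|factors|detect|run|validate`), operating on plain-text rasters
(ESRI ASCII grid), CSV tables and YAML configs in a shared working
directory:

```sh
vegeff run --out demo_out --seed 1
```

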