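# Methods

`vegeff` evaluates vegetation restoration effectiveness over a gridded study
region and attributes its spatial pattern to environmental and management
drivers. This note records the model, the choices made where the design was
genuinely open, and what the synthetic test bed does and does not show.

## The composite index

Vegetation condition is summarized by a quality–quantity index combining a
structural attribute (fractional vegetation cover, FVC) and a functional one
(net primary productivity, NPP) with equal weights:

    VQQI = (N_FVC + N_NPP) / 2 × 100%      ∈ [0, 100]

where `N_·` denotes min–max normalization. FVC is derived from NDVI by the
dimidiate pixel model: each pixel is a linear mixture of a bare-soil and a
full-vegetation endmember,

    FVC = (NDVI − NDVI_soil) / (NDVI_veg − NDVI_soil), clipped to [0, 1],

with the endmembers taken as the 5th and 95th percentiles of each yearly
scene's valid pixels (configurable; the literature uses anything from 0.5/99.5
to 5/95 depending on scene contamination).

Two consequences of these conventions matter for interpretation:

* **Normalization scope.** `normalize_stack` fits one affine map over the
  whole space–time stack by default. Normalizing each year separately would
  delete interannual signal from the normalized variable, and with it the
  VQQI trend; a per-year mode exists behind a flag for users who want purely
  spatial contrast.
* **Scene-relative FVC.** Because the endmembers are re-estimated per year,
  FVC measures greenness *relative to the scene*. In a region where most
  pixels green up, a pixel improving slower than the scene average acquires a
  negative FVC trend. This is faithful to how the dimidiate model behaves on
  real imagery and is visible in the synthetic experiments: counties designed
  with mild absolute improvement below the scene average classify as
  relatively degraded.

## Per-pixel trend and grading

Each pixel's VQQI is regressed on calendar year (ordinary least squares,
closed form) over each evaluation period (defaults 2000–2010, 2000–2015,
2000–2020, inclusive). Significance is the regression F test with
(1, l−2) degrees of freedom — equivalent to the two-sided t test on the
slope. Pixels are graded:

| grade | condition | weight ω |
|---|---|---|
| 1 | slope > 0, p < 0.01 | +2 |
| 2 | slope > 0, 0.01 ≤ p < 0.05 | +1 |
| 3 | p ≥ 0.05 | 0 |
| 4 | slope < 0, 0.01 ≤ p < 0.05 | −1 |
| 5 | slope < 0, p < 0.01 | −2 |

Boundary p values fall into the less-significant class so that the rule is
total; a numerically zero slope is graded 3 regardless of p (under OLS+F a
zero slope forces F = 0, p = 1, so this branch is purely defensive). A
perfect nonconstant fit (zero residual variance) yields p = 0; a constant
series yields p = 1. Sums of squares are compared against a relative
tolerance of 1e−12 when deciding these degenerate branches.

## County scores

For each evaluation unit (county) and period, grade area fractions A_{k,t}
(cell counts over valid cells; equal-area grid assumed) give the net change

    N_t = Σ_k ω_k A_{k,t}     ∈ [−2, 2],

and the effectiveness score divides by a baseline shared across counties:

    N0 = mean over counties of N_{2000–2010},     E_t = N_t / N0.

E_t ≤ 0 is classed *degraded*, 0 < E_t ≤ 1 *not-significant* recovery, and
E_t > 1 *significant* recovery (the boundary E_t = 1 belongs to the middle
class). The baseline is deliberately a single scalar — per-county baselines
would force E equal to 1 for every county in the baseline period — and it is
an error, not a silent sign flip, when N0 is negative or within 1e−6 of zero,
because the class semantics assume N0 > 0. By construction the cross-county
mean of E in the baseline period is exactly 1.

## Change-point detection

The regional annual mean series is tested for a single abrupt shift with the
Pettitt rank test: U_t = Σ_{i≤t} Σ_{j>t} sign(x_j − x_i), K = max|U_t|,
p ≈ 2·exp(−6K²/(n³+n²)). The reported change year is the first year of the
new regime. Localization of a step embedded in a trend is inherently ±1 year:
for a purely monotone series |U_t| peaks (with a tie) at mid-series, so trend
plus step can pull the argmax one year off the step. Power analysis on
21-point series shows the ±1-year localization rate crosses 95% at a step of
about 2.5 interannual standard deviations; the bundled experiments use a 3σ
step.

## Driver preparation

Ecological-engineering drivers are pure area ratios per county, in percent:
conversion intensities (e.g. cropland→grassland between two land-use epochs),
maintenance intensities (class unchanged), and accumulated afforestation
(Σ yearly afforested area / county area, 2002 onward). The intensity
denominator is the whole county area by default — bounded and comparable
across counties; dividing by the prior-class area instead is available via
`denominator="prior"`. Continuous drivers are aggregated to counties by zonal
mean.

Discretization uses natural breaks implemented as the exact Fisher dynamic
program: the partition of the sorted values into L contiguous classes
minimizing total within-class squared deviation. The DP operates on blocks of
tied values (an exchange argument shows an optimum never needs to split
ties), is O(L·m²) in the number m of distinct values, and is verified against
exhaustive search. Default group counts follow the standard driver table:
climate/geography/socioeconomic 7, engineering 6, soil clay/moisture/organic
carbon 7/6/5.

## Geodetector

The factor detector measures how much a stratification explains the spatial
variance of county effectiveness:

    q = 1 − Σ_h N_h σ_h² / (N σ²),

with population variances, so q is exactly the between-strata share of the
total sum of squares: q ∈ [0, 1], invariant to affine transforms of the
response, and never decreased by refining the stratification.

**Significance.** Under the null of no stratified effect the monotone
transform F = (N−L)/(L−1)·q/(1−q) is the one-way ANOVA F statistic with a
central F(L−1, N−L) distribution, and that is the default p-value: its
type-I error is the nominal α (verified by Monte Carlo). The variant found in
widely circulated Geodetector implementations — a noncentral F whose
noncentrality is estimated from the sample stratum means — is provided as
`method="noncentral"` for comparability, but it is strongly conservative
(empirical size ≈ 0 at α = 0.05) and not location-invariant, so it is not
the default.

**Main factors** are those ranking in the top half by q that also pass
α = 0.05. **Interactions** compute q on the cross-classification (stratum =
ordered pair of single-factor strata) and type the comparison with the
standard five categories (weaken-nonlinear, weaken-single, enhance-bivariate,
enhance-nonlinear, independent at a 1e−9 equality tolerance). With dozens of
cross-cells over ~80 counties, interaction q values are inflated toward 1 by
small strata — a known small-sample property of the statistic, not a bug.
**Risk detection** reports per-stratum mean effectiveness with pairwise
Welch t tests (singleton strata excluded and flagged) and the favorable value
range: the argmax stratum merged with adjacent strata statistically
indistinguishable from it.

The analysis unit is the county (response = E_t, drivers aggregated to
counties); p-values are left undefined (NaN) when N ≤ L.

## The synthetic test bed

The generator produces every input with known ground truth, so each stage is
testable without external data:

* **Grids and counties.** Rectangular-block tessellations (any statistic is
  indifferent to county shape); polygons are accepted on input but not
  generated. The default scenario uses a 180×180 grid of 1 km² cells, 81
  counties in four sub-region bands, years 2000–2020.
* **Trends.** Pixel value = base + slope·(year−2000) + step·1[year ≥ break] +
  N(0, σ). Per-county mean slopes are specified; pixel slopes scatter around
  them (SD 0.0008/yr). Defaults: 60% of counties at +0.0035 NDVI/yr, the
  rest at −0.001; noise SD 0.015; step 0.015 entering 2011. NPP is an
  independent noisy affine image of the same latent structure. Noise is
  i.i.d. Gaussian — real imagery has spatial autocorrelation, so passing
  tests certify the estimators' calibration, not their behavior under
  spatially correlated error.
* **Factors.** A partition with designed explanatory power d is built by
  natural-breaks grouping of the effectiveness itself (the maximal-q
  partition — maximizing q is exactly minimizing within-class SSD), then
  degrading stratum purity by random swaps accepted only if they move the
  directly computed variance ratio toward d, stopping inside ±tol (default
  0.02, aimed at tol/2 so delivered ratios sit inside the band). Designs
  above the attainable maximum, or finer than swap granularity allows at
  small county counts, raise an infeasibility error. Factor values are drawn
  monotone in stratum with clear gaps, so discretizing the values recovers
  the strata.
* **Land use.** Two epoch rasters realize per-county transition fractions
  with deterministic largest-remainder cell counts; remaining cells carry an
  inert filler class. Realized fractions are recorded as bookkeeping and are
  exactly recoverable by cross-tabulation.
* **Determinism.** Every output draws from a substream derived from the
  scenario seed and the output's name (CRC-32), so identical configurations
  are bit-identical regardless of call order.

The default scenario's designed conditions mirror a two-decade restoration
programme: a ~0.2%/yr composite-index rise with a step after the first
programme phase, ~60% of county area under significant restoration, and a
14-factor driver table whose designed q ranking runs from precipitation
(0.75) down to soil moisture (0.03), grouped 7/7/7/6/5 by category.

## Problem sizes and numerical choices

Tests and the acceptance script run the default scenario (32 400 pixels ×
21 years, a sub-second pipeline) plus Monte Carlo batches sized for stable
estimates at small cost: 10⁴ null pixels for F-test calibration, 10³–10⁴
random instances for oracle and invariance checks, 20 seeds × 4 designs ×
500 units for q recovery, 200 replicates for change-point localization.
Tolerances: q against the oracle at 1e−12; noiseless slopes at 1e−10; the
interaction monotonicity slack and the independence tolerance at 1e−9; grade
fraction sums at 1e−9.

## File formats

Rasters travel as ESRI ASCII grids (plain-text, readable by any GIS), one
file per variable-year; tables as CSV; configurations as YAML; reports as
JSON; county tessellations additionally as GeoJSON rectangles. An
8-day→annual maximum-value-composite helper is provided for sub-annual NDVI
input.

## Known limitations

* No spatially autocorrelated noise, realistic climate surfaces, or sensor
  QA artifacts in the generator.
* The scene-relative FVC convention couples county classes to the regional
  trend distribution (see above); absolute-endmember variants would need
  fixed reference NDVI values.
* Interaction q on small cross-cells is optimistically biased; treat
  interaction magnitudes comparatively, not absolutely.
* The county-level analysis inherits the modifiable-areal-unit problem; a
  grid-sample unit mode would give different q magnitudes.
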