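# Methods

## Scope and design

`epeagree` implements a complete agreement analysis for extreme
precipitation event (EPE) exposure assessment: three exposure routes
(nearest station, fine interpolated grid, coarse assimilation-style
grid) feed binary EPE classifications whose pairwise agreement is
summarised with Cohen's kappa, overall and within sociodemographic and
station-proximity strata. Real archives (multi-decade station records,
4-km interpolated surfaces, hourly assimilation grids, census
demographics) are out of scope by design; a seed-reproducible synthetic
generator supplies inputs with the statistical structure the analysis
assumes, so every stage is testable end to end.

Geometry is planar, in km, on a square region. All distance and area
computations accept this convention natively; great-circle (haversine,
sphere radius 6371.0088 km) distance is available for lon/lat inputs.
Area centroids of tract polygons are the exposure-assessment points.

## Synthetic region generator

**Random fields.** All spatial structure comes from stationary Gaussian
fields with exponential covariance `exp(-d / range)`, synthesised by
circulant embedding on a doubled torus (FFT), cropped to kill
wrap-around correlation. Real and imaginary parts of each transform
supply two independent replicates. Negative embedding eigenvalues
(exponential covariance is not exactly embeddable) are clipped at zero;
the resulting covariance error is below 2% at the configurations used.

**Precipitation truth.** Daily wet/dry occurrence thresholds a
correlated standard-normal field at `Phi^{-1}(1 - wet_prob)`, giving an
exact marginal wet probability. Wet amounts apply a Gaussian-copula
quantile transform of a second correlated field to the
gamma(shape, scale) marginal, so wet-day amounts are exactly gamma
distributed *and* spatially coherent — extremes arrive as spatial
events, not salt-and-pepper noise. Dry cells are exactly 0 mm.

**Demographics and SVI.** Race composition is a softmax over smooth
Gaussian logit surfaces (white / Black / Native American / Asian /
other), with Hispanic ethnicity a separate logistic surface; percent
minority is the complement of the non-Hispanic-white share. The Native
American logit is dominated by a tract-level nugget (iid) term: high-NA
tracts occur as scattered pockets, which keeps their association with
station access attributable to the injected siting mechanism rather
than to shared smooth geography (see "Injected effects" below).
Poverty follows its own surface plus minority and Native American
terms (emulating the high poverty of reservation tracts). SVI is the
percentile rank of a composite `z(poverty) + z(minority) + z(NA)`
(NA weighted 1.0), so its marginal over tracts is exactly uniform and,
with 16 tracts, the percentiles are exactly {0.5/16, 1.5/16, ...}.
Urbanicity is assigned by population-density terciles
(rural / urban cluster / urban) — a seedable proxy for administrative
designations.

**Stations.** Station locations are drawn tract-first with probability
proportional to `exp(-siting_bias * SVI)`, then uniformly within the
tract; `siting_bias = 0` is provably uniform. Each station's record
carries outage blocks of geometric-distributed length (mean 10 days).
Half the network is "high quality" (outage rate one tenth of
`missing_rate`), the rest draws heavier rates, so the 99% completeness
screen genuinely splits the network. Observations are the truth field
at the station's cell plus truncated Gaussian gauge noise on wet days;
QC flags are Bernoulli(`qc_flag_rate`) on operating days.

**Derived products.** The interpolated product is inverse-distance
weighting (power 2) of each day's clean observations onto the fine
grid, with exact reproduction at station cells; a day with zero
operating stations raises an error (degenerate network). The
assimilation-style product block-averages truth to the coarse grid,
applies mean-preserving multiplicative lognormal noise
(`exp(sigma Z - sigma^2/2)`), and splits each daily value into 24
hourly layers by Dirichlet(0.3) simplex weights, conserving daily
totals to machine precision.

**Default study conditions.** 120 km square, 12x12 tracts, 730 days,
30 stations, siting_bias 8, wet_prob 0.35, spatial range 30 km (the
scale at which a single station's influence decays, matching the
radius-of-influence reading behind the 0–7/7–30/>30 km strata), gamma
shape 0.8 and scale 8 mm (typical mid-latitude daily amounts), gauge
noise 0.5 mm, missing rate 0.05, flag rate 0.005, fine cells 2 km,
coarse cells 12 km.

**What the generator does not emulate.** Orographic and storm-track
physics, seasonality, trend and inhomogeneity in station records, the
actual interpolation/assimilation algorithms of operational products,
population-weighted centroids, and real census geography. Passing
tests therefore demonstrate that the *measurement chain and statistics*
behave as specified under a controlled data-generating process — not
that any particular real-world agreement value is reproduced.

## Exposure conventions

- Wet day: value strictly greater than `wet_min_mm` (default 0.0);
  trace thresholds vary between networks, so the cut is a parameter.
- Quantile: linear interpolation between order statistics (the default
  of the major statistical environments); also a parameter.
- The completeness screen (fraction of clean, non-missing days
  >= 0.99, inclusive) is applied after QC-flag removal.
- Thresholds are static nearest-included-station assignments with ties
  broken by lexicographic station id; daily values come from the
  nearest station *operating that day*, so the assigning station can
  change daily.
- Distance strata: [0, 7) km, [7, 30] km, (30, inf) km on the mean of
  daily nearest-operating-station distances.
- Grid thresholds are restricted to wet days by default for
  comparability across sources; `threshold_population="all_days"`
  reproduces the literal all-days reading.
- Area-weighted averages renormalise over non-missing intersecting
  cells; a polygon whose intersecting cells are all missing yields a
  missing value with a warning.
- EPE indicators use strict inequality for both definitions; a value
  exactly at threshold is not an event. Missing unit-days propagate
  and are dropped pairwise from all contingency tables.

## Agreement statistics

Kappa is computed from the pooled 2x2 unit-day table of each
comparison (overall, per calendar year, or per stratum). Pooling is
the convention implied by the very narrow CIs that national pooled
comparisons produce; a per-unit kappa mode exists for sensitivity
analyses. The SE is the Fleiss–Cohen–Everitt (1969) asymptotic
variance (cross-checked in the test suite against an independent
implementation), the CI the +-1.96 SE normal interval, not clamped to
[-1, 1]. Kappa is undefined only when `p_e = 1` (both raters constant
on the same class); a single constant rater yields the conventional
kappa = 0. Landis–Koch band edges are right-closed with a 1e-12
tolerance so a kappa sitting on an edge up to float rounding stays in
the lower band. Negative kappas are reported as computed, never
clamped.

## Vulnerability analyses

Stratifications: majority flags at strictly > 50% of the relevant
share; low income strictly > 20% poverty (the inclusive >= 20% reading
is available via `poverty_op`); SVI bins right-closed at 0.25 / 0.50 /
0.75; urbanicity as generated. Topographic prominence is the max-minus-
min of the elevation raster block-aggregated (block mean) to a 500 m
target resolution over cells intersecting the tract. Matching uses the
referent group's mean ± one sample (n−1) SD, closed at the bounds, on
population density and prominence jointly. The distance regressions
are ordinary least squares of mean daily station distance (km) on
Native American share entered as a proportion (0–1), alone (Model 1)
and with prominence and/or density (Models 2–4), with classical normal-
theory CIs. One-way ANOVA uses the explicit between/within
decomposition; the degenerate zero-within-variance case reports an
infinite F with p = 0 and a flag rather than raising. Confusion counts
treat the designated reference source as a comparison baseline only —
the accompanying metadata states explicitly that no claim of ground
truth is made.

## Injected effects and the two studies

The generator injects one causal mechanism: vulnerability-biased
station siting. Two named studies (in `epeagree.studies`) check that
the analysis recovers it.

*Stratified-agreement study* (default region, 20 seeds): biased siting
leaves high-SVI tracts far from stations; nearest-station values
decorrelate from the interpolated surface with distance (beyond the
30 km correlation length the nearest gauge and the IDW blend draw on
effectively different weather), so mean kappa(station, interp) should
fall monotonically across SVI quartiles and be clearly lower in the
>30 km stratum than the 0–7 km stratum.

*Proximity-regression study* (240 km, 25x25 tracts, 300 stations,
siting_bias 4, 20 seeds per arm): the dense-network regime — most
units within a few km of a gauge, as in real national networks — where
a unit's station distance is dominated by whether its own tract hosts
a station. High Native American share raises the SVI composite,
suppresses hosting, and lengthens distances; Model 1 should find a
positive share coefficient with its 95% CI excluding zero in nearly
all seeds, and with the bias switched off the CI should cover zero at
its nominal rate. The nugget-dominated NA share is what makes the
null arm honest: a spatially smooth share would correlate with the
smooth distance surface by chance and invalidate classical OLS
intervals. Precipitation values play no role in station proximity, so
this study runs with a dry truth field. Station counts differ between
the studies deliberately: agreement degradation needs genuinely remote
tracts (sparse network), hosting-displacement regression needs spacing
below the tract-neighborhood scale (dense network).

## Numerical and degenerate-input choices

- Determinism: every stage draws from a substream of the single region
  seed via fixed spawn keys, so stages are individually reproducible
  and a rerun is byte-identical (the pipeline manifest digests all
  outputs).
- IDW at an exact station cell uses the station value (no division by
  zero); a day with no operating station raises rather than silently
  extrapolating.
- Dirichlet hourly weights guard against total underflow by falling
  back to uniform hours for the affected pixel-day.
- All-dry series raise a threshold-undefined error instead of
  returning a vacuous threshold.
- Empty strata or years yield flagged "undefined" kappa results, not
  exceptions, so result tables keep their shape.
- Rank-deficient regression designs raise a collinearity error naming
  the model's terms.

## Problem sizes

Default test and study sizes are chosen so the whole suite and the
acceptance script each run in a few minutes on one CPU: the demo
pipeline region is 16 tracts x 20 stations x 2 years; the stratified
study 144 tracts x 30 stations x 2 years x 20 seeds; the regression
study 625 tracts x 300 stations x 20 seeds per arm (dry field). These
are scaled-down analogues of a national analysis, which pools tens of
thousands of tracts over decades; kappa magnitudes depend on region
size, network density and correlation length, so only their qualitative
ordering — not their absolute values — is expected to transfer.

## Known limitations

Classical OLS and kappa CIs ignore residual spatial correlation, which
the synthetic fields genuinely carry; the regression study's null arm
is calibrated by construction of the NA share, not by robust inference.
Annual kappa assumes calendar-year blocks of a shared date index.
The per-unit kappa mode is often undefined for rare events at short
records (constant raters). The generator's two-tier station-quality
mixture is a stylisation; real completeness distributions are more
skewed. Only two EPE definitions are implemented; multi-day
accumulation or duration-based definitions are out of scope.
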