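# Methods

This note documents the models and procedures implemented in `amphiphen`,
the defaults that matter, and what the synthetic study does and does not
establish about real data.

## Migration detection

A sighting record is part of a migration when the individuals summed over
its spatio-temporal neighbourhood reach `min_individuals = 10`. The
neighbourhood of a record contains every conspecific record within
`radius_m` metres (great-circle/haversine on WGS84) **and** within
`window_days = 7` calendar days, including the record itself; a single
sighting of ≥ 10 individuals therefore always qualifies. Both cutoffs are
absolute differences, so membership is symmetric, and neighbourhood sums
only grow as records are added — flags are monotone in the data, the
radius, the window, and (inversely) the threshold. The suite verifies exact
agreement with an independent O(n²) pure-Python classifier on hundreds of
random tables.

“Within an area of 1 km²” is read as a moving disc of area 1 km² centred on
the examined record, hence `radius_m = √(10⁶/π) ≈ 564.19`. The criterion is
anchored on each examined observation, not on a fixed tessellation, which
makes the disc the natural reading; a fixed 1 km × 1 km grid mode
(`mode="grid"`) is provided for sensitivity analysis, and pre-projected
metric coordinates are supported via `metric="euclidean"`. The quantitative
threshold is applied as **≥ 10** summed individuals (the operational form of
the criterion); it is a parameter, not a constant.

Records are banded into climatic regions by site mean annual air
temperature (1971–2000 normal), half-open and left-closed: alpine < 5 °C,
cool [5, 7), moderate [7, 9), warm ≥ 9 °C. Alpine records are flagged and
excluded from onset analysis. MAT travels on each record; users with a
climate raster can join it upstream.

## Onset extraction

For each (species, region, year), the migration onset is the day-of-year of
the earliest flagged record, **suppressed** unless ≥ 4 flagged observations
support that region-year — a single early stray never defines a regional
start. The minimum counts flagged observations (not deduplicated events);
`count_events=True` switches to the stricter event-counting reading. Plant
onsets are the first report per (species, region, year) with no minimum.
DOY uses Jan 1 = 1 with real leap days (2008-02-27 → 58; 2007-03-01 → 60).

Pairing joins amphibian and plant onsets on (region, year), pooling regions
into one table per species pair. Region-level rows carry the MAT band
midpoint (cool 6, moderate 8, warm 10 °C) as a scalar covariate — a
region-year has no single site, and the midpoint is the simplest faithful
scalar encoding; a categorical encoding would cost a second degree of
freedom at these sample sizes.

## Statistics

* Pearson product-moment correlation, two-tailed via the t transform with
  n − 2 df. Against full permutation enumeration at n = 6–7 the t-based p
  agrees to ≈ 0.02 in the decision-relevant range; agreement degrades
  somewhat in the far right tail (p ≳ 0.7), which never affects decisions
  at α = 0.05.
* Mann–Kendall trend: S = Σ_{i<j} sign(x_j − x_i), variance with the
  standard tie-group correction, continuity-corrected normal z, and
  τ = S / (n(n−1)/2). For n ≤ 10 the exact permutation distribution of S is
  enumerated and reported (`p_exact`) alongside the normal approximation;
  the exact value is used by default for short series.
* Paired regional contrast: paired t on within-year differences. A
  zero-variance difference vector (an exactly constant shift) is reported
  with an `exact_difference` flag instead of an undefined t statistic.
* Shapiro–Wilk is a reported diagnostic only, never a gate.
* All pipeline reports evaluate at α = 0.05. No multiple-testing correction
  is applied, and that is stated in the reports rather than silently fixed.

## Robust MM-regression

The estimator chains a high-breakdown S-step and an efficient M-step:

1. **S-scale**: bisquare ρ with c = 1.547645 and target b = 0.5 (50%
   breakdown). Candidate coefficient vectors come from 200 random elemental
   p-subsets (seeded RNG, default seed 42 — fits are bit-reproducible);
   the best candidate is refined by alternating one-step IRLS and M-scale
   updates until the scale stops decreasing. The M-scale itself solves
   mean ρ(r/s) = b by fixed-point iteration.
2. **M-step**: IRLS with the redescending bisquare at c = 4.685061 (95%
   Gaussian efficiency), scale held fixed at the S-estimate.

Coefficient covariance uses the standard M-estimator sandwich with
empirical ψ moments, cov = s²·[Σψ(u)²/(n−p)] / [mean ψ′(u)]² · (XᵀX)⁻¹.
One test cross-checks coefficients, scale and the general magnitude of the
standard errors against an independent MM implementation (`MASS::rlm`,
method "MM") on contaminated data.

Degenerate inputs: rank-deficient designs raise an error naming the
collinear columns; an exactly-fitting model (scale → 0) returns unit
weights and zero covariance; a constant MAT covariate (single-region
table) is dropped with a logged warning because it is unidentifiable there.

Diagnostics are computed on the robustly weighted design: Cook's distance
with the 4/n screening threshold (rows are flagged for scrutiny, never
auto-dropped), VIF = 1/(1 − R²_j) with ∞ reported under perfect
collinearity, LOOCV RMSE by literal refitting (equal to the hat-matrix
PRESS shortcut in the OLS limit, which the suite asserts to 10⁻¹⁰), and a
null comparison against the intercept-only robust location fit, whose
adjusted R² is 0 by construction. A "robust R²" is computed from
weight-weighted sums of squares; it is a descriptive quantity, not a test.

Lag forecasts evaluate the linear predictor at a plant DOY (MAT defaulting
to its sample mean), with a 95% **confidence interval of the conditional
mean** (t quantile, n − p df). Mean-CIs, not prediction intervals, are the
default because the forecast target is the regional mean onset, and the
narrow published-style interval widths at n ≈ 23 are only consistent with
mean-CIs; `interval="prediction"` widens by the residual scale. Reported
integers round half away from zero; reals are retained internally.
Predictions > 15 days outside the fitted plant-DOY range carry an
extrapolation warning.

## Synthetic data generator

The generator emulates the *structure* of the Austrian 2000–2018
citizen-science record, with one latent temperature driver shared by plants
and amphibians:

* **Regions and sites.** Sites are placed ≥ 5 km apart (so 1 km²
  neighbourhoods never bridge sites) in three lon/lat boxes mimicking a
  cool-west / moderate / warm-east gradient; each site's MAT is drawn
  uniformly inside its region's band. Default 9 sites with mix
  (4/9, 4/9, 1/9) — the warm region is deliberately sparse, mirroring how
  few warm-region series the real record yields.
* **Onsets.** Per region-year anomaly a ~ N(0, 1.2 °C); every phenophase
  shifts by −3.5 d/°C × a (a typical spring-phenology temperature
  response) plus a regional offset (cool +9 d, moderate 0, warm −2 d; the
  +9 matches the observed cool-vs-moderate stagger). Plant bases run from
  snowdrop (day 38) to horse-chestnut/silver-birch leaf unfolding
  (days 100–103). Amphibian onsets are **anchored**: frog = goat-willow
  onset + 21 d, toad = +23 d, plus N(0, `onset_noise_sd_days`) — so the
  regression downstream has target slope 1 and intercept equal to the lag.
* **Observations.** Per site-year and species, a burst of 5–8 records
  within 7 days of the site onset (site effect N(0, 1 d)), first record on
  the onset day, counts ≥ 1 with total ≥ 10 by construction; plus
  Poisson(15) background singletons per region-year with 1–3 individuals
  scattered over January–May and the whole region box. Plant reports are
  per-site first events delayed by Exp(mean 2 d) — reports can be late,
  never early.

Identical seed and config give byte-identical CSVs.

**Known estimator bias, quantified.** "First report per region-year" is a
biased estimator on both sides: the earliest of several noisy site onsets
is slightly *early* (≈ −0.8 d with 3 sites), while the earliest delayed
plant report is *late* (≈ +0.6 d under the 2-day observer delay). The net
effect under default conditions is a fitted lag ≈ 1.2 d short of the true
21 d. The recovery test runs the full pipeline over 100 seeds (19 years ×
2 regions, onset noise 1 d) and requires the lag at the mean plant DOY
within 2 d of truth in ≥ 95% of seeds — it measures this bias instead of
hiding it.

**What the generator does not emulate:** daily weather or daylength,
per-project reporting-effort heterogeneity, roadkill mortality, spatial
autocorrelation beyond the site level, or absence data. Passing tests
therefore demonstrate that the pipeline's logic is correct and that its
estimators behave as analysed under a realistic noise model — not that the
ecological effect sizes in any real record match the defaults.

## Problem sizes

The test suite and the reproduction script use the generator's default
scale — 9 sites × 19 years (≈ 3,000 sighting records, ≈ 1,200 plant
reports) for single runs, and 6 sites × 19 years × 100 seeds for the
recovery study; oracle-agreement checks use 500 random tables of up to 200
records. These sizes give stable estimates (Monte-Carlo error well below
the tolerances tested) while keeping a full run in minutes on one core.

## Known limitations

* The MAT covariate enters as a region midpoint, so within-region MAT
  variation is not exploited; region-specific fits are available but not
  claimed equivalent to any published per-region model.
* The exponential observer-delay model has a single parameter; empirical
  delay distributions from real monitoring programs may be heavier-tailed.
* No correction is attempted for the first-report bias (both the published
  procedure and this implementation accept it); the synthetic study
  quantifies its magnitude under the default noise model.
* Mann–Kendall exact enumeration is limited to n ≤ 10 (10! orderings).
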