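# amphiphen

Predicting the onset of amphibian spring migration from plant phenology in
citizen-science records.

## The problem

Common toads (*Bufo bufo*) and common frogs (*Rana temporaria*) are
"explosive breeders": each spring, within a window of a few days, thousands
of animals move from hibernation sites to spawning waters. Where roads cross
these routes, conservation volunteers install temporary drift fences with
buckets — but only if they know *when* migration will start, which varies by
more than a month between years and regions. Both amphibian migration and
spring plant phenology (flowering, leaf unfolding) are driven largely by
temperature, so an easily observed plant phenophase can serve as a field
proxy for the harder-to-observe migration onset.

`amphiphen` implements that analysis as a tested pipeline over tabular
sighting records:

1. **Migration detection** — an amphibian sighting is classified as part of
   a migration when the individuals summed over its spatio-temporal
   neighbourhood (conspecific records within a disc of area 1 km², radius
   √(10⁶/π) ≈ 564.19 m, and within ±7 days) reach 10. Records are banded
   into climatic regions by site mean annual temperature (MAT): alpine
   (< 5 °C, excluded), cool [5, 7), moderate [7, 9), warm (≥ 9 °C).
2. **Onset extraction** — per species, region and year, the onset is the
   day-of-year (DOY, Jan 1 = 1) of the earliest flagged record, kept only
   when ≥ 4 flagged observations support that region-year; plant onsets are
   the plain first report per region-year.
3. **Statistics** — Shapiro–Wilk normality, paired t regional contrasts,
   Mann–Kendall trend (tie-corrected variance, continuity correction, exact
   permutation p for short series), two-tailed Pearson correlation.
4. **Robust modelling** — MM-regression (high-breakdown bisquare S-scale,
   then a 95%-efficiency bisquare M-step) of amphibian onset *y* on plant
   onset *x* and the region-midpoint MAT covariate:

       y = β₀ + β₁ x + β₂ MAT + ε

   with Cook's distance (4/n screening), VIF, leave-one-out
   cross-validated RMSE, and comparison against an intercept-only robust
   null model.
5. **Lag forecasts** — for a plant onset on day *d*, the predicted lag to
   migration is ŷ(d) − d with a 95% confidence interval of the conditional
   mean; because ŷ is affine, the lag shrinks linearly in *d* when β₁ < 1.

A synthetic-data generator produces citizen-science-like datasets with known
ground truth (true onsets, true plant→amphibian lags, shared regional
temperature anomalies), so the full pipeline is testable end to end without
any external data.

## Worked example

Run the numbered analysis scripts in order (seeded, deterministic):

```sh
python analysis/01_simulate.py
python analysis/02_detect_migrations.py
python analysis/03_extract_onsets.py
python analysis/04_trends_correlations.py
python analysis/05_models_lag_forecasts.py
```

The last step prints:

```
model comparison (LOOCV RMSE vs intercept-only null):
   response   predictor  n  slope  adj_r2  rmse_loocv  rmse_null  cooks_flags  max_vif
common_frog     apricot 57  0.944   0.936        1.73       5.92            2     2.77
common_frog goat_willow 57  0.840   0.917        1.98       5.92            2     2.29
common_toad goat_willow 57  0.863   0.946        1.50       5.91            0     2.29

forecast lags at goat-willow flowering DOY 60 (true lag 21 d):
   response       plant  plant_doy  lag_days  ci95_low  ci95_high  extrapolation
common_frog goat_willow         60      20.1      19.5       20.7          False
common_toad goat_willow         60      21.9      21.4       22.4          False
```

Reading: each plant-based model roughly triples forecast accuracy over the
null (LOOCV RMSE ≈ 1.5–2 d vs ≈ 5.9 d), and when goat willow flowers on day
60 the model forecasts common-frog migration 20.1 days later (95% CI
19.5–20.7). The generator's true lag is 21 d; the ≈ 1 d shortfall is the
net first-report bias (plant first reports can only be late; the earliest
of several noisy site onsets is slightly early) that the pipeline
quantifies rather than hides — see `docs/methods.md`.

The same stages are exposed as a CLI (`amphiphen simulate|detect|extract|
analyze|model|predict|run-all`); `amphiphen run-all --start-dates <csv>`
enters mid-pipeline from an existing onset table, e.g. a published
start-date dataset, bypassing detection.

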