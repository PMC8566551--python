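"""End-to-end orchestration: simulate -> detect -> extract -> analyze ->
model -> predict, as one reproducible run with a manifest.

Stages are skippable: a run can start from an externally supplied start-date
table (taxon, region, year, onset_doy) and only execute the statistics and
modelling stages — the entry point for reproducing results from a published
onset table when the raw sighting records are not available.
"""

from __future__ import annotations

import hashlib
import json
import logging
import time
from pathlib import Path

import numpy as np
import pandas as pd

from . import __version__
from .detection import annotate
from .io import AMPHIBIAN_SPECIES, PLANT_PHASES, read_start_dates, write_start_dates
from .robust import (compare_to_null, cooks_leverage, fit_model, model_table,
                     predict_onset, vif)
from .start_dates import amphibian_start_dates, pair_series, plant_start_dates
from .stats import correlation_report, paired_region_test, shapiro_wilk, trend_report
from .synthetic import SimulationConfig, simulate, write_dataset

logger = logging.getLogger("amphiphen")

#: the forecasting models the report always fits (response, predictors)
DEFAULT_MODELS = (
    ("common_frog", ("apricot",)),
    ("common_frog", ("goat_willow",)),
    ("common_toad", ("goat_willow",)),
)

LAG_LOOKUP_DOYS = tuple(range(50, 91, 5))


def _sha256(path: Path) -> str:
    return hashlib.sha256(path.read_bytes()).hexdigest()


def run_all(config: SimulationConfig | None = None, *, seed: int | None = None,
            outdir="results/run", start_dates_path=None,
            models=DEFAULT_MODELS) -> dict:
    """Execute the pipeline; returns the report dict (also written as JSON).

    Either simulate a dataset from ``config`` (``seed`` overrides the config
    seed) or enter mid-pipeline with ``start_dates_path``.
    """
    outdir = Path(outdir)
    outdir.mkdir(parents=True, exist_ok=True)
    timings: dict[str, float] = {}
    report: dict = {"versions": {"amphiphen": __version__,
                                 "numpy": np.__version__, "pandas": pd.__version__}}

    if start_dates_path is None:
        cfg = config or SimulationConfig()
        if seed is not None:
            cfg.seed = int(seed)
        t0 = time.perf_counter()
        sites, obs, phen, gt = simulate(cfg)
        write_dataset(outdir, obs, phen, gt, cfg)
        timings["simulate"] = time.perf_counter() - t0
        report["n_sites"] = len(sites)
        report["n_observations"] = len(obs)
        report["n_phenology_reports"] = len(phen)

        t0 = time.perf_counter()
        flagged = annotate(obs)
        flagged_out = flagged.copy()
        flagged_out["date"] = flagged_out["date"].dt.strftime("%Y-%m-%d")
        flagged_out.to_csv(outdir / "observations_flagged.csv", index=False)
        timings["detect"] = time.perf_counter() - t0
        report["n_migration_records"] = int(flagged["migration_flag"].sum())

        t0 = time.perf_counter()
        phen_r = phen.copy()
        from .detection import assign_region
        phen_r["region"] = assign_region(phen_r["mat_degc"].to_numpy())
        amph_sd = amphibian_start_dates(flagged)
        plant_sd = plant_start_dates(phen_r)
        start = pd.concat([amph_sd, plant_sd], ignore_index=True)
        write_start_dates(start, outdir / "start_dates.csv")
        timings["extract"] = time.perf_counter() - t0
    else:
        if config is not None:
            logger.warning("run_all: start_dates_path given; simulation config ignored")
        start = read_start_dates(start_dates_path)
        amph_sd = start[start["taxon"].isin(AMPHIBIAN_SPECIES)].reset_index(drop=True)
        plant_sd = start[start["taxon"].isin(PLANT_PHASES)].reset_index(drop=True)
        report["start_dates_input"] = str(start_dates_path)

    report["n_start_rows"] = {t: int((start["taxon"] == t).sum())
                              for t in start["taxon"].unique()}

    # --- analyze -----------------------------------------------------------
    t0 = time.perf_counter()
    trends = trend_report(start)
    paired_tables = {}
    for amph in AMPHIBIAN_SPECIES:
        for plant in PLANT_PHASES:
            tab = pair_series(amph_sd, plant_sd, amph, plant)
            if len(tab):
                paired_tables[(amph, plant)] = tab
    corr = correlation_report(paired_tables)
    normality = []
    for taxon, sub in start.groupby("taxon"):
        vals = sub["onset_doy"].to_numpy(dtype=float)
        if len(vals) >= 3 and np.ptp(vals) > 0:
            res = shapiro_wilk(vals)
            normality.append({"taxon": taxon, "W": res.statistic,
                              "p_value": res.p_value, "n": res.n})
    region_tests = []
    for taxon in AMPHIBIAN_SPECIES:
        a = amph_sd[(amph_sd["taxon"] == taxon) & (amph_sd["region"] == "cool")]
        b = amph_sd[(amph_sd["taxon"] == taxon) & (amph_sd["region"] == "moderate")]
        try:
            res = paired_region_test(a, b)
            region_tests.append({"taxon": taxon, "regions": "cool-vs-moderate",
                                 "mean_difference": res.extras["mean_difference"],
                                 "t": res.statistic, "p_value": res.p_value, "n": res.n})
        except ValueError:
            pass
    trends.to_csv(outdir / "trend_tests.csv", index=False)
    corr.to_csv(outdir / "correlations.csv", index=False)
    timings["analyze"] = time.perf_counter() - t0
    report["trend_tests"] = trends.to_dict(orient="records")
    report["correlations"] = corr.to_dict(orient="records")
    report["normality"] = normality
    report["region_comparisons"] = region_tests

    # --- model + predict ---------------------------------------------------
    t0 = time.perf_counter()
    model_reports = []
    lag_rows = []
    for response, predictors in models:
        tab = model_table(amph_sd, plant_sd, response, list(predictors), include_mat=True)
        n_min = len(predictors) + 1 + 1 + 3  # predictors + mat + intercept margin
        if len(tab) < n_min:
            logger.warning("model %s ~ %s skipped: only %d paired rows",
                           response, "+".join(predictors), len(tab))
            continue
        fit = fit_model(tab, list(predictors), include_mat=True, compute_loocv=True)
        cmp_null = compare_to_null(tab["amphibian_doy"].to_numpy(),
                                   tab[list(predictors) + ["mat_covariate"]])
        cooks = cooks_leverage(fit)
        vifs = vif(tab[list(predictors) + ["mat_covariate"]])
        entry = {
            "response": response,
            "predictors": list(predictors),
            "n": fit.n,
            "coefficients": fit.coefficients.round(6).to_dict(),
            "scale_days": fit.scale,
            "adj_r2": fit.adj_r2,
            "rmse_loocv": fit.rmse_loocv,
            "null": cmp_null["null"],
            "rmse_improvement_over_null": cmp_null["rmse_improvement"],
            "vif": vifs.round(4).to_dict(),
            "cooks_flagged_rows": int(cooks["flag"].sum()),
            "cooks_threshold": 4.0 / fit.n,
        }
        model_reports.append(entry)
        if len(predictors) == 1:
            for doy in LAG_LOOKUP_DOYS:
                pr = predict_onset(fit, doy)
                lag_rows.append({"response": response, "plant": predictors[0],
                                 "plant_doy": doy,
                                 "lag_days": round(pr.lag_days, 2),
                                 "ci95_low": round(pr.ci95_low, 2),
                                 "ci95_high": round(pr.ci95_high, 2),
                                 "extrapolation": pr.extrapolation_warning})
    lag_table = pd.DataFrame(lag_rows)
    lag_table.to_csv(outdir / "lag_lookup.csv", index=False)
    timings["model_predict"] = time.perf_counter() - t0
    report["models"] = model_reports
    report["lag_lookup"] = lag_rows

    # --- manifest ----------------------------------------------------------
    manifest = {
        "seed": getattr(config, "seed", seed) if start_dates_path is None else None,
        "config": (json.loads(json.dumps(
            {k: (list(v) if isinstance(v, tuple) else v)
             for k, v in vars(config or SimulationConfig()).items()
             if not isinstance(v, dict)})) if start_dates_path is None else None),
        "timings_s": {k: round(v, 4) for k, v in timings.items()},
        "digests": {p.name: _sha256(p) for p in sorted(outdir.glob("*.csv"))},
        "versions": report["versions"],
    }
    report["manifest"] = manifest
    (outdir / "report.json").write_text(json.dumps(report, indent=2, default=str))
    return report
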