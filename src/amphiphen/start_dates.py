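"""Reduce flagged sightings and phenology reports to onset tables.

The analysis's central object is the start-date series: for every taxon,
climatic region and year, the day-of-year of the earliest qualifying event.
For amphibians a region-year only yields an onset when at least four flagged
migration observations support it (a single early stray never defines the
regional start); plant phenophases take the plain first report per
region-year with no minimum.
"""

from __future__ import annotations

import logging

import pandas as pd

from .io import day_of_year

logger = logging.getLogger("amphiphen")

#: scalar MAT covariate for a region-level row: the band midpoint in degC
#: (warm is open above; its working midpoint uses the generator's 9-11 band)
REGION_MAT_MIDPOINT = {"cool": 6.0, "moderate": 8.0, "warm": 10.0}

ANALYSIS_REGIONS = ("cool", "moderate", "warm")


def _with_doy_year(records: pd.DataFrame) -> pd.DataFrame:
    out = records.copy()
    dates = pd.to_datetime(out["date"])
    out["year"] = dates.dt.year
    out["onset_doy"] = dates.dt.dayofyear
    return out


def amphibian_start_dates(flagged_records: pd.DataFrame, min_events: int = 4,
                          count_events: bool = False) -> pd.DataFrame:
    """Earliest flagged migration DOY per (species, region, year).

    Region-years with fewer than ``min_events`` flagged observations are
    suppressed (logged).  ``count_events=True`` counts distinct event ids
    instead of flagged observations, for the stricter reading of the
    event-minimum rule.
    """
    df = flagged_records
    if len(df) == 0:
        return pd.DataFrame(columns=["taxon", "region", "year", "onset_doy"])
    if "migration_flag" in df.columns:
        df = df[df["migration_flag"]]
    df = df[df["region"].isin(ANALYSIS_REGIONS)]
    if len(df) == 0:
        return pd.DataFrame(columns=["taxon", "region", "year", "onset_doy"])
    df = _with_doy_year(df)
    grp = df.groupby(["species", "region", "year"])
    if count_events and "event_id" in df.columns:
        support = grp["event_id"].nunique()
    else:
        support = grp.size()
    onset = grp["onset_doy"].min()
    keep = support >= min_events
    n_sup = int((~keep).sum())
    if n_sup:
        logger.info("amphibian_start_dates: %d region-years below the "
                    "%d-event minimum suppressed", n_sup, min_events)
    out = onset[keep].reset_index().rename(columns={"species": "taxon"})
    return out.sort_values(["taxon", "region", "year"]).reset_index(drop=True)


def plant_start_dates(phenology_records: pd.DataFrame) -> pd.DataFrame:
    """First report DOY per (plant species, region, year); no event minimum."""
    if len(phenology_records) == 0:
        return pd.DataFrame(columns=["taxon", "region", "year", "onset_doy"])
    df = phenology_records[phenology_records["region"].isin(ANALYSIS_REGIONS)]
    if len(df) == 0:
        return pd.DataFrame(columns=["taxon", "region", "year", "onset_doy"])
    df = _with_doy_year(df)
    onset = df.groupby(["species", "region", "year"])["onset_doy"].min()
    out = onset.reset_index().rename(columns={"species": "taxon"})
    return out.sort_values(["taxon", "region", "year"]).reset_index(drop=True)


def pair_series(amphibian: pd.DataFrame, plant: pd.DataFrame,
                amphibian_taxon: str, plant_taxon: str,
                regions=None) -> pd.DataFrame:
    """Inner-join amphibian and plant onsets on (region, year), pooled.

    Returns columns (region, year, amphibian_doy, plant_doy, mat_covariate);
    the MAT covariate is the region band midpoint.  An empty join returns an
    empty frame with the full schema rather than raising.
    """
    cols = ["region", "year", "amphibian_doy", "plant_doy", "mat_covariate"]
    a = amphibian[amphibian["taxon"] == amphibian_taxon]
    p = plant[plant["taxon"] == plant_taxon]
    if regions is not None:
        a = a[a["region"].isin(regions)]
        p = p[p["region"].isin(regions)]
    if len(a) == 0 or len(p) == 0:
        return pd.DataFrame(columns=cols)
    m = a.merge(p, on=["region", "year"], suffixes=("_a", "_p"))
    if len(m) == 0:
        logger.warning("pair_series(%s, %s): empty pairing", amphibian_taxon, plant_taxon)
        return pd.DataFrame(columns=cols)
    out = pd.DataFrame({
        "region": m["region"],
        "year": m["year"],
        "amphibian_doy": m["onset_doy_a"].astype(float),
        "plant_doy": m["onset_doy_p"].astype(float),
        "mat_covariate": m["region"].map(REGION_MAT_MIDPOINT),
    })
    return out.sort_values(["region", "year"]).reset_index(drop=True)
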