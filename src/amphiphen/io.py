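"""Reading, validating and writing the tabular formats the pipeline touches.

All tables are RFC-4180 CSV, UTF-8, header row, ISO-8601 dates and WGS84
decimal degrees.  Readers are *total*: every input row is either accepted or
rejected with a row-numbered diagnostic; malformed rows never abort a read
(missing mandatory columns do).
"""

from __future__ import annotations

import datetime as _dt
import logging
from pathlib import Path
from typing import Iterable, Sequence

import pandas as pd

logger = logging.getLogger("amphiphen")

AMPHIBIAN_SPECIES = ("common_toad", "common_frog")

#: valid (species -> phenophase) pairs; flowering for the early species,
#: leaf unfolding for the late trees.
PLANT_PHASES = {
    "snowdrop": "flowering",
    "common_hazel": "flowering",
    "goat_willow": "flowering",
    "apricot": "flowering",
    "european_larch": "leaf_unfolding",
    "horse_chestnut": "leaf_unfolding",
    "silver_birch": "leaf_unfolding",
}

REGIONS = ("alpine", "cool", "moderate", "warm")

OBSERVATION_COLUMNS = ("record_id", "species", "date", "lon", "lat", "individuals", "mat_degc")
PHENOLOGY_COLUMNS = ("record_id", "species", "phase", "date", "lon", "lat", "mat_degc")
START_DATE_COLUMNS = ("taxon", "region", "year", "onset_doy")

#: date dialects tried in order when parsing record dates
DEFAULT_DATE_FORMATS = ("%Y-%m-%d", "%d.%m.%Y")


class SchemaError(ValueError):
    """A file is structurally unusable (e.g. a mandatory column is absent)."""


def day_of_year(date) -> int:
    """Day-of-year index with January 1 = 1; leap days are real days.

    2008-02-27 is day 58 (2008 is a leap year but February precedes the leap
    day), 2007-03-01 is day 60.
    """
    ts = pd.Timestamp(date)
    return int(ts.dayofyear)


def date_from_doy(year: int, doy: int) -> _dt.date:
    """Inverse of :func:`day_of_year` for a given year."""
    return (_dt.date(int(year), 1, 1) + _dt.timedelta(days=int(doy) - 1))


def _parse_date(value, formats: Sequence[str]):
    if isinstance(value, (_dt.date, _dt.datetime, pd.Timestamp)):
        return pd.Timestamp(value).normalize()
    s = str(value).strip()
    for fmt in formats:
        try:
            return pd.Timestamp(_dt.datetime.strptime(s, fmt)).normalize()
        except ValueError:
            continue
    return None


def _normalise_header(df: pd.DataFrame, column_map: dict | None, required: Iterable[str]) -> pd.DataFrame:
    rename = {c: c.strip().lower() for c in df.columns}
    df = df.rename(columns=rename)
    if column_map:
        df = df.rename(columns={k.strip().lower(): v for k, v in column_map.items()})
    missing = [c for c in required if c not in df.columns]
    if missing:
        raise SchemaError(f"missing mandatory column(s): {', '.join(missing)}")
    return df


def _validate_rows(df, formats, years, check):
    """Run per-row validation; returns (accepted, rejected-with-reason)."""
    reasons = pd.Series("", index=df.index, dtype=object)
    dates = pd.to_datetime(df["date"].map(lambda v: _parse_date(v, formats)),
                           errors="coerce")
    reasons[dates.isna()] += "unparseable date; "
    if years is not None:
        lo, hi = years
        bad = dates.notna() & ~dates.dt.year.between(lo, hi)
        reasons[bad] += f"date outside study window {lo}-{hi}; "
    df = df.assign(date=dates)
    for idx, row in df.iterrows():
        msg = check(row)
        if msg:
            reasons[idx] += msg + "; "
    rejected = df[reasons != ""].assign(reason=reasons[reasons != ""].str.rstrip("; "))
    accepted = df[reasons == ""]
    for idx, reason in rejected["reason"].items():
        logger.warning("row %s rejected: %s", idx + 2, reason)  # +2: header + 1-based
    return accepted, rejected


def _num(v):
    try:
        return float(v)
    except (TypeError, ValueError):
        return None


def read_observations(path, *, date_formats=DEFAULT_DATE_FORMATS, column_map=None,
                      years=(2000, 2018), return_rejected=False):
    """Read amphibian sighting records, rejecting rows that violate invariants.

    Invariants: known species, individuals >= 1 integer, lat/lon in range,
    finite MAT, parseable date inside the study window (pass ``years=None``
    to lift the window).
    """
    raw = pd.read_csv(path, dtype=object)
    raw = _normalise_header(raw, column_map, OBSERVATION_COLUMNS)

    def check(row):
        probs = []
        if row["species"] not in AMPHIBIAN_SPECIES:
            probs.append(f"unknown species {row['species']!r}")
        ind = _num(row["individuals"])
        if ind is None or ind < 1 or ind != int(ind):
            probs.append(f"individuals must be integer >= 1, got {row['individuals']!r}")
        lon, lat = _num(row["lon"]), _num(row["lat"])
        if lon is None or not -180 <= lon <= 180:
            probs.append("lon out of range")
        if lat is None or not -90 <= lat <= 90:
            probs.append("lat out of range")
        if _num(row["mat_degc"]) is None:
            probs.append("non-numeric mat_degc")
        return "; ".join(probs)

    accepted, rejected = _validate_rows(raw, date_formats, years, check)
    accepted = accepted.astype({"lon": float, "lat": float, "mat_degc": float})
    accepted = accepted.assign(individuals=accepted["individuals"].astype(float).astype(int))
    logger.info("read_observations(%s): %d accepted, %d rejected", path, len(accepted), len(rejected))
    accepted = accepted.reset_index(drop=True)
    if return_rejected:
        return accepted, rejected.reset_index(drop=True)
    return accepted


def read_phenology(path, *, date_formats=DEFAULT_DATE_FORMATS, column_map=None,
                   years=(2000, 2018), return_rejected=False):
    """Read plant phenophase reports; the (species, phase) pair must be valid."""
    raw = pd.read_csv(path, dtype=object)
    raw = _normalise_header(raw, column_map, PHENOLOGY_COLUMNS)

    def check(row):
        probs = []
        expected = PLANT_PHASES.get(row["species"])
        if expected is None:
            probs.append(f"unknown plant species {row['species']!r}")
        elif row["phase"] != expected:
            probs.append(f"invalid phase {row['phase']!r} for {row['species']} (expected {expected})")
        lon, lat = _num(row["lon"]), _num(row["lat"])
        if lon is None or not -180 <= lon <= 180:
            probs.append("lon out of range")
        if lat is None or not -90 <= lat <= 90:
            probs.append("lat out of range")
        if _num(row["mat_degc"]) is None:
            probs.append("non-numeric mat_degc")
        return "; ".join(probs)

    accepted, rejected = _validate_rows(raw, date_formats, years, check)
    accepted = accepted.astype({"lon": float, "lat": float, "mat_degc": float})
    logger.info("read_phenology(%s): %d accepted, %d rejected", path, len(accepted), len(rejected))
    accepted = accepted.reset_index(drop=True)
    if return_rejected:
        return accepted, rejected.reset_index(drop=True)
    return accepted


def write_start_dates(rows: pd.DataFrame, path) -> None:
    """Write an onset table, sorted by (taxon, region, year); duplicate keys error."""
    df = pd.DataFrame(rows)[list(START_DATE_COLUMNS)].copy()
    dup = df.duplicated(subset=["taxon", "region", "year"], keep=False)
    if dup.any():
        key = df.loc[dup, ["taxon", "region", "year"]].iloc[0].tolist()
        raise ValueError(f"duplicate (taxon, region, year) key: {tuple(key)}")
    df = df.sort_values(["taxon", "region", "year"], kind="mergesort")
    df = df.astype({"year": int, "onset_doy": int})
    df.to_csv(path, index=False)


def read_start_dates(path) -> pd.DataFrame:
    """Read an onset table (also the entry point for an externally supplied
    per-taxon/region/year start-date table, bypassing the detection stages)."""
    df = pd.read_csv(path)
    df = _normalise_header(df, None, START_DATE_COLUMNS)
    df = df.astype({"year": int, "onset_doy": int})
    bad = ~df["onset_doy"].between(1, 366)
    if bad.any():
        raise ValueError(f"onset_doy out of [1, 366] in rows {list(df.index[bad])}")
    dup = df.duplicated(subset=["taxon", "region", "year"], keep=False)
    if dup.any():
        key = df.loc[dup, ["taxon", "region", "year"]].iloc[0].tolist()
        raise ValueError(f"duplicate (taxon, region, year) key: {tuple(key)}")
    return df.sort_values(["taxon", "region", "year"], kind="mergesort").reset_index(drop=True)


def write_events_geojson(records: pd.DataFrame, flags, path) -> None:
    """Optional GeoJSON export of classified records as Point features."""
    import json

    feats = []
    for (_, row), flag in zip(records.iterrows(), flags):
        props = {k: (v.isoformat() if isinstance(v, (pd.Timestamp, _dt.date)) else v)
                 for k, v in row.items() if k not in ("lon", "lat")}
        props["migration_flag"] = bool(flag)
        feats.append({
            "type": "Feature",
            "geometry": {"type": "Point", "coordinates": [row["lon"], row["lat"]]},
            "properties": props,
        })
    Path(path).write_text(json.dumps({"type": "FeatureCollection", "features": feats}))
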