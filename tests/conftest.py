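"""Shared fixtures and independent oracles.

The oracles here deliberately avoid the package's vectorised code paths:
pure-Python loops, stdlib math, and enumeration, so that agreement between
the two routes is a real check and not a tautology.
"""

from __future__ import annotations

import math

import numpy as np
import pandas as pd
import pytest

from amphiphen.synthetic import SimulationConfig, simulate

EARTH_RADIUS_M = 6_371_008.8


def haversine_oracle(lon1, lat1, lon2, lat2) -> float:
    """Scalar great-circle distance (m), written independently with math.*"""
    p1, p2 = math.radians(lat1), math.radians(lat2)
    dphi = p2 - p1
    dlmb = math.radians(lon2 - lon1)
    a = math.sin(dphi / 2) ** 2 + math.cos(p1) * math.cos(p2) * math.sin(dlmb / 2) ** 2
    return 2 * EARTH_RADIUS_M * math.asin(math.sqrt(a))


def brute_force_flags(records: pd.DataFrame, radius_m: float, window_days: int,
                      min_individuals: int) -> list[bool]:
    """O(n^2) reference classifier: per-record neighbourhood sum >= threshold."""
    rows = [(r["species"], r["date"], r["lon"], r["lat"], int(r["individuals"]))
            for _, r in records.iterrows()]
    flags = []
    for sp_i, d_i, lon_i, lat_i, _ in rows:
        total = 0
        for sp_j, d_j, lon_j, lat_j, ind_j in rows:
            if sp_j != sp_i:
                continue
            if abs((d_j - d_i).days) > window_days:
                continue
            if haversine_oracle(lon_i, lat_i, lon_j, lat_j) > radius_m:
                continue
            total += ind_j
        flags.append(total >= min_individuals)
    return flags


def random_sighting_table(rng: np.random.Generator, n: int) -> pd.DataFrame:
    """A random table dense enough that neighbourhoods genuinely interact."""
    lon0, lat0 = 14.0, 47.5
    return pd.DataFrame({
        "record_id": [f"r{i}" for i in range(n)],
        "species": rng.choice(["common_frog", "common_toad"], size=n),
        "date": pd.to_datetime("2010-03-01") + pd.to_timedelta(rng.integers(0, 30, n), "D"),
        "lon": lon0 + rng.uniform(-0.02, 0.02, n),
        "lat": lat0 + rng.uniform(-0.015, 0.015, n),
        "individuals": rng.integers(1, 13, n),
        "mat_degc": rng.uniform(5, 11, n),
    })


def make_records(specs, species="common_frog", lon0=14.0, lat0=47.5):
    """Tiny fixed tables from (d_east_m, d_north_m, day, individuals) tuples."""
    rows = []
    for i, (dx, dy, day, ind) in enumerate(specs):
        lat = lat0 + dy / 111_194.9
        lon = lon0 + dx / (111_194.9 * math.cos(math.radians(lat0)))
        rows.append({"record_id": f"r{i}", "species": species,
                     "date": pd.Timestamp("2010-03-01") + pd.Timedelta(days=day),
                     "lon": lon, "lat": lat, "individuals": ind, "mat_degc": 8.0})
    return pd.DataFrame(rows)


@pytest.fixture(scope="session")
def small_config() -> SimulationConfig:
    return SimulationConfig(sites_per_region=2, background_rate=5.0, seed=7)


@pytest.fixture(scope="session")
def small_dataset(small_config):
    return simulate(small_config)
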