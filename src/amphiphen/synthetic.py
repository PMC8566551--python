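"""Synthetic citizen-science data with known ground truth.

The generator emulates the structure of Austrian amphibian-sighting and
plant-phenology records from 2000-2018: sites scattered over three climatic
regions (cool / moderate / warm, banded by mean annual temperature), a shared
yearly temperature anomaly per region that shifts every spring phenophase,
amphibian migration *bursts* (clusters of sightings with many individuals
near the true regional onset) on top of scattered non-migration singleton
sightings, and plant first-event reports that can only be late, never early
(exponential observer delay).

Amphibian onsets are anchored to a reference plant phenophase: the true
regional amphibian onset equals the anchor plant's true onset plus a fixed
lag plus Gaussian noise, so the plant-amphibian regression downstream has a
known target slope (1) and intercept (the lag).
"""

from __future__ import annotations

import dataclasses
import logging
import math
from dataclasses import dataclass, field
from pathlib import Path

import numpy as np
import pandas as pd
import yaml

from .io import AMPHIBIAN_SPECIES, PLANT_PHASES, date_from_doy

logger = logging.getLogger("amphiphen")

#: lon/lat boxes the three usable regions are drawn in (an Austria-like
#: west-east gradient: cool uplands west/north, warm lowlands east)
REGION_BOXES = {
    "cool": (9.5, 12.8, 46.6, 48.9),
    "moderate": (13.0, 15.8, 46.6, 48.9),
    "warm": (16.0, 17.0, 47.4, 48.9),
}
REGION_MAT_RANGE = {"cool": (5.0, 7.0), "moderate": (7.0, 9.0), "warm": (9.0, 11.0)}

#: long-run first-event day-of-year in the moderate region (doy, climatology
#: of early-spring flowering herbs/shrubs through late leaf-unfolding trees)
DEFAULT_BASE_ONSET = {
    "snowdrop": 38.0,
    "common_hazel": 42.0,
    "goat_willow": 59.0,
    "apricot": 75.0,
    "european_larch": 97.0,
    "horse_chestnut": 100.0,
    "silver_birch": 103.0,
}

#: regional shifts: cool springs run ~9 days behind moderate, warm slightly ahead
DEFAULT_REGION_OFFSET = {"cool": 9.0, "moderate": 0.0, "warm": -2.0}

#: amphibian onset = anchor plant onset + lag (+ noise); goat willow flowers
#: ~3 weeks before frog migration, toads follow frogs by ~2 days
DEFAULT_ANCHOR = {"common_frog": "goat_willow", "common_toad": "goat_willow"}
DEFAULT_TRUE_LAG = {("goat_willow", "common_frog"): 21.0,
                    ("goat_willow", "common_toad"): 23.0}


class ConfigError(ValueError):
    """A simulation parameter is invalid; the message names the field."""


@dataclass
class SimulationConfig:
    """Study conditions for one synthetic dataset.

    ``region_mix`` weights the random region assignment of sites; the warm
    region is sparse by default, mirroring the few usable warm-region
    series in the real data.
    """

    years: tuple[int, int] = (2000, 2018)
    sites_per_region: int = 3
    n_sites: int | None = None  # overrides sites_per_region * active regions
    region_mix: dict = field(default_factory=lambda: {"cool": 4 / 9, "moderate": 4 / 9, "warm": 1 / 9})
    base_onset_doy: dict = field(default_factory=lambda: dict(DEFAULT_BASE_ONSET))
    region_offset_days: dict = field(default_factory=lambda: dict(DEFAULT_REGION_OFFSET))
    anchor_plant: dict = field(default_factory=lambda: dict(DEFAULT_ANCHOR))
    true_lag_days: dict = field(default_factory=lambda: dict(DEFAULT_TRUE_LAG))
    temp_sensitivity_days_per_degC: float = -3.5
    anomaly_sd_degC: float = 1.2
    onset_noise_sd_days: float = 1.0
    site_effect_sd_days: float = 1.0
    observer_delay_mean_days: float = 2.0
    burst_size_distribution: dict = field(default_factory=lambda: {
        "min_records": 5, "max_records": 8, "individuals_mean": 4.0})
    background_rate: float = 15.0
    background_max_individuals: int = 3
    seed: int = 0

    def validate(self) -> None:
        if self.years[1] < self.years[0]:
            raise ConfigError("years: end before start")
        if abs(sum(self.region_mix.values()) - 1.0) > 1e-9:
            raise ConfigError("region_mix: proportions must sum to 1")
        if any(w < 0 for w in self.region_mix.values()):
            raise ConfigError("region_mix: negative proportion")
        if self.temp_sensitivity_days_per_degC > 0:
            raise ConfigError("temp_sensitivity_days_per_degC: must be <= 0 "
                              "(warmer anomaly brings onsets forward)")
        if self.onset_noise_sd_days < 0:
            raise ConfigError("onset_noise_sd_days: must be >= 0")
        if self.observer_delay_mean_days < 0:
            raise ConfigError("observer_delay_mean_days: must be >= 0")
        if self.background_rate < 0:
            raise ConfigError("background_rate: must be >= 0")
        b = self.burst_size_distribution
        if b["min_records"] < 1 or b["max_records"] < b["min_records"]:
            raise ConfigError("burst_size_distribution: need max_records >= min_records >= 1")
        if b["individuals_mean"] < 1:
            raise ConfigError("burst_size_distribution: individuals_mean must be >= 1")
        for amph, plant in self.anchor_plant.items():
            if (plant, amph) not in self.true_lag_days:
                raise ConfigError(f"true_lag_days: missing lag for anchor pair ({plant}, {amph})")

    @classmethod
    def from_yaml(cls, path) -> "SimulationConfig":
        raw = yaml.safe_load(Path(path).read_text()) or {}
        if "years" in raw:
            raw["years"] = tuple(raw["years"])
        if "true_lag_days" in raw:  # YAML keys are "plant,amphibian" strings
            raw["true_lag_days"] = {tuple(k.split(",")): float(v)
                                    for k, v in raw["true_lag_days"].items()}
        cfg = cls(**raw)
        cfg.validate()
        return cfg

    def to_yaml(self, path) -> None:
        d = dataclasses.asdict(self)
        d["years"] = list(self.years)
        d["true_lag_days"] = {",".join(k): v for k, v in self.true_lag_days.items()}
        Path(path).write_text(yaml.safe_dump(d, sort_keys=True))


@dataclass
class GroundTruth:
    """What the generator knows and the pipeline must recover."""

    onsets: pd.DataFrame        # kind, taxon, region, year, true_onset_doy
    lags: dict                  # (plant, amphibian) -> true lag in days
    anomalies: pd.DataFrame     # region, year, anomaly_degc


def generate_sites(config: SimulationConfig, rng: np.random.Generator | None = None) -> pd.DataFrame:
    """Place observation sites in their regions, >= 5 km apart.

    Each site gets a MAT drawn uniformly inside its region's band, so the
    band lookup downstream recovers the region exactly; the 5 km separation
    guarantees the 1 km^2 neighbourhood criterion never bridges sites.
    """
    config.validate()
    rng = rng if rng is not None else np.random.default_rng(config.seed)
    active = [r for r, w in sorted(config.region_mix.items()) if w > 0]
    n = config.n_sites if config.n_sites is not None else config.sites_per_region * len(active)
    if n == 0:
        logger.warning("generate_sites: zero sites requested")
        return pd.DataFrame(columns=["site_id", "lon", "lat", "mat_degc", "region"])
    names = sorted(config.region_mix)
    probs = np.array([config.region_mix[r] for r in names])
    regions = rng.choice(names, size=n, p=probs)
    rows = []
    placed: dict[str, list] = {r: [] for r in names}
    for i, region in enumerate(regions):
        lo_lon, hi_lon, lo_lat, hi_lat = REGION_BOXES[region]
        for _ in range(10_000):
            lon = rng.uniform(lo_lon, hi_lon)
            lat = rng.uniform(lo_lat, hi_lat)
            ok = all(_approx_dist_m(lon, lat, plon, plat) >= 5000.0
                     for plon, plat in placed[region])
            if ok:
                break
        else:  # pragma: no cover - boxes are far larger than needed
            raise ConfigError("sites_per_region: cannot place sites >= 5 km apart")
        placed[region].append((lon, lat))
        mat = rng.uniform(*REGION_MAT_RANGE[region])
        rows.append((f"site{i:03d}", round(lon, 6), round(lat, 6), round(mat, 3), region))
    return pd.DataFrame(rows, columns=["site_id", "lon", "lat", "mat_degc", "region"])


def _approx_dist_m(lon1, lat1, lon2, lat2):
    latm = math.radians((lat1 + lat2) / 2)
    dx = math.radians(lon2 - lon1) * 6_371_008.8 * math.cos(latm)
    dy = math.radians(lat2 - lat1) * 6_371_008.8
    return math.hypot(dx, dy)


def generate_observations(config: SimulationConfig, sites: pd.DataFrame,
                          rng: np.random.Generator | None = None):
    """Simulate sightings and phenology reports for every site-year.

    Returns ``(observations, phenology, ground_truth)``.  Per site-year each
    amphibian species produces a burst of >= 4 records within 7 days of the
    site onset whose individuals sum to >= 10 (topped up if the draw falls
    short), plus Poisson-distributed background singletons (1-3 individuals,
    uniform over January-May) per region-year.  Plant reports are per-site
    first events delayed by an exponential observer delay.
    """
    config.validate()
    if len(sites) == 0:
        raise ConfigError("sites: must be nonempty")
    rng = rng if rng is not None else np.random.default_rng(config.seed + 1)
    years = list(range(config.years[0], config.years[1] + 1))
    regions = sorted(sites["region"].unique())

    anom_rows = []
    anomaly = {}
    for region in regions:
        for year in years:
            a = rng.normal(0.0, config.anomaly_sd_degC)
            anomaly[(region, year)] = a
            anom_rows.append((region, year, a))

    # true regional onsets
    onset_rows = []
    true_onset = {}
    sens = config.temp_sensitivity_days_per_degC
    for region in regions:
        off = config.region_offset_days[region]
        for year in years:
            shift = off + sens * anomaly[(region, year)]
            for plant, base in config.base_onset_doy.items():
                true_onset[(plant, region, year)] = base + shift
                onset_rows.append(("plant", plant, region, year, base + shift))
            for amph in AMPHIBIAN_SPECIES:
                anchor = config.anchor_plant[amph]
                lag = config.true_lag_days[(anchor, amph)]
                t = (true_onset[(anchor, region, year)] + lag
                     + rng.normal(0.0, config.onset_noise_sd_days))
                true_onset[(amph, region, year)] = t
                onset_rows.append(("amphibian", amph, region, year, t))

    burst = config.burst_size_distribution
    obs_rows, phen_rows = [], []
    rid = 0
    for _, site in sites.iterrows():
        region = site["region"]
        for year in years:
            for amph in AMPHIBIAN_SPECIES:
                site_onset = (true_onset[(amph, region, year)]
                              + rng.normal(0.0, config.site_effect_sd_days))
                n_rec = int(rng.integers(burst["min_records"], burst["max_records"] + 1))
                offsets = np.concatenate([[0], rng.integers(0, 8, size=n_rec - 1)])
                counts = 1 + rng.poisson(burst["individuals_mean"] - 1, size=n_rec)
                if counts.sum() < 10:  # migration criterion holds by construction
                    counts[0] += 10 - counts.sum()
                for off_d, cnt in zip(offsets, counts):
                    doy = max(1, round(site_onset) + int(off_d))
                    obs_rows.append((f"obs{rid:06d}", amph,
                                     date_from_doy(year, doy).isoformat(),
                                     round(site["lon"] + rng.normal(0, 0.002), 6),
                                     round(site["lat"] + rng.normal(0, 0.002), 6),
                                     int(cnt), site["mat_degc"],
                                     "burst", site["site_id"]))
                    rid += 1
            for plant in config.base_onset_doy:
                t = (true_onset[(plant, region, year)]
                     + rng.normal(0.0, config.site_effect_sd_days)
                     + rng.exponential(config.observer_delay_mean_days))
                doy = max(1, round(t))
                phen_rows.append((f"phen{rid:06d}", plant, PLANT_PHASES[plant],
                                  date_from_doy(year, doy).isoformat(),
                                  site["lon"], site["lat"], site["mat_degc"]))
                rid += 1

    # scattered non-migration singletons, small counts, anywhere in the region
    for region in regions:
        lo_lon, hi_lon, lo_lat, hi_lat = REGION_BOXES[region]
        mat_lo, mat_hi = REGION_MAT_RANGE[region]
        for year in years:
            n_bg = rng.poisson(config.background_rate)
            for _ in range(n_bg):
                amph = AMPHIBIAN_SPECIES[int(rng.integers(0, 2))]
                doy = int(rng.integers(1, 152))
                obs_rows.append((f"obs{rid:06d}", amph,
                                 date_from_doy(year, doy).isoformat(),
                                 round(rng.uniform(lo_lon, hi_lon), 6),
                                 round(rng.uniform(lo_lat, hi_lat), 6),
                                 int(rng.integers(1, config.background_max_individuals + 1)),
                                 round(rng.uniform(mat_lo, mat_hi), 3),
                                 "background", ""))
                rid += 1

    # source/site_id are generator provenance, kept for testability
    obs = pd.DataFrame(obs_rows, columns=["record_id", "species", "date", "lon",
                                          "lat", "individuals", "mat_degc",
                                          "source", "site_id"])
    phen = pd.DataFrame(phen_rows, columns=["record_id", "species", "phase", "date",
                                            "lon", "lat", "mat_degc"])
    obs["date"] = pd.to_datetime(obs["date"])
    phen["date"] = pd.to_datetime(phen["date"])
    gt = GroundTruth(
        onsets=pd.DataFrame(onset_rows, columns=["kind", "taxon", "region", "year",
                                                 "true_onset_doy"]),
        lags=dict(config.true_lag_days),
        anomalies=pd.DataFrame(anom_rows, columns=["region", "year", "anomaly_degc"]),
    )
    logger.info("generate_observations: %d sightings, %d phenology reports", len(obs), len(phen))
    return obs, phen, gt


def simulate(config: SimulationConfig):
    """Convenience wrapper: sites + observations from one seed."""
    rng = np.random.default_rng(config.seed)
    sites = generate_sites(config, rng)
    obs, phen, gt = generate_observations(config, sites, rng)
    return sites, obs, phen, gt


def write_dataset(outdir, obs: pd.DataFrame, phen: pd.DataFrame, gt: GroundTruth,
                  config: SimulationConfig | None = None) -> None:
    """Write observations.csv, phenology.csv, ground_truth*.csv (+ config.yaml)."""
    outdir = Path(outdir)
    outdir.mkdir(parents=True, exist_ok=True)
    for df, name in ((obs, "observations.csv"), (phen, "phenology.csv")):
        out = df.copy()
        out["date"] = pd.to_datetime(out["date"]).dt.strftime("%Y-%m-%d")
        out.to_csv(outdir / name, index=False, float_format="%.6f")
    onsets = gt.onsets.merge(gt.anomalies, on=["region", "year"])
    onsets.to_csv(outdir / "ground_truth.csv", index=False, float_format="%.6f")
    pd.DataFrame([{"plant": p, "amphibian": a, "true_lag_days": v}
                  for (p, a), v in gt.lags.items()]).to_csv(
        outdir / "ground_truth_lags.csv", index=False, float_format="%.6f")
    if config is not None:
        config.to_yaml(outdir / "config.yaml")
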