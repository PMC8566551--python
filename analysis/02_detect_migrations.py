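"""Classify sightings as migration events.

Applies the spatial (1 km² disc), temporal (±7 days) and quantitative
(summed individuals ≥ 10) criteria per species, and assigns each record to
a climatic region by its site MAT.  Isolated singletons stay unflagged.
"""

from pathlib import Path

from amphiphen.detection import annotate
from amphiphen.io import read_observations

ROOT = Path(__file__).resolve().parents[1] / "results"

if __name__ == "__main__":
    obs = read_observations(ROOT / "data" / "observations.csv")
    flagged = annotate(obs)
    out = flagged.copy()
    out["date"] = out["date"].dt.strftime("%Y-%m-%d")
    out.to_csv(ROOT / "observations_flagged.csv", index=False)
    n = len(flagged)
    k = int(flagged["migration_flag"].sum())
    print(f"{k}/{n} records classified as part of a migration ({k / n:.1%})")
    print(flagged.groupby(["species", "region"])["migration_flag"].sum().to_string())
    print(f"written to {ROOT / 'observations_flagged.csv'}")
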