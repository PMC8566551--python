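"""Reduce flagged records and plant reports to the onset table.

Amphibians: earliest flagged migration per species, region and year, kept
only where at least four flagged observations support that region-year.
Plants: plain first report per species, region and year.
"""

from pathlib import Path

import pandas as pd

from amphiphen.detection import assign_region
from amphiphen.io import read_phenology, write_start_dates
from amphiphen.start_dates import amphibian_start_dates, plant_start_dates

ROOT = Path(__file__).resolve().parents[1] / "results"

if __name__ == "__main__":
    flagged = pd.read_csv(ROOT / "observations_flagged.csv", parse_dates=["date"])
    phen = read_phenology(ROOT / "data" / "phenology.csv")
    phen["region"] = assign_region(phen["mat_degc"].to_numpy())
    amph = amphibian_start_dates(flagged)
    plant = plant_start_dates(phen)
    write_start_dates(pd.concat([amph, plant], ignore_index=True),
                      ROOT / "start_dates.csv")
    print(f"amphibian onset rows: {len(amph)}  plant onset rows: {len(plant)}")
    for taxon, sub in amph.groupby("taxon"):
        print(f"  {taxon}: mean onset DOY {sub['onset_doy'].mean():.1f} "
              f"({len(sub)} region-years)")
    print(f"written to {ROOT / 'start_dates.csv'}")
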