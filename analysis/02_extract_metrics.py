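#!/usr/bin/env python
"""Reduce the raw cohort to per-level and minute-level metrics.

Stable-period averaging (skipping the ~48 s transition of each 5-min step)
turns each channel into one value per subject per LBNP level: MAP, HR,
Pleth_A (trough-to-trough pulse area), mean belt impedance for the two EIT
belts, and |Z| per frequency for the three EIS sites; minute-level series
and 20 HRV features feed the classification stage.
"""

from pathlib import Path

import pandas as pd

from lbnpdet import extract_cohort, read_cohort, save_metrics

ROOT = Path(__file__).resolve().parents[1]


def main() -> None:
    recs, manifest = read_cohort(ROOT / "scratch" / "cohort.h5")
    missing = manifest.missing()
    if not missing.empty:
        print(f"note: {len(missing)} missing channels\n{missing}")
    cohort = extract_cohort(recs, transition_skip=48.0)
    save_metrics(cohort, ROOT / "scratch" / "metrics")

    table = cohort.level_table()
    res = ROOT / "results"
    res.mkdir(exist_ok=True)
    scalar = table[~table["metric"].str.startswith("EIS")]
    scalar.to_csv(res / "level_metrics.csv", index=False)

    print(f"extracted {len(cohort.subjects)} subjects -> scratch/metrics")
    wide = scalar.pivot_table(index="metric", columns="level", values="mean")
    print("\ncohort-mean metric values per LBNP level:")
    print(wide.groupby("metric").mean().round(2).to_string())


if __name__ == "__main__":
    main()
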