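#!/usr/bin/env python
"""Assemble the run's summary tables and machine-readable report.

Reads the per-stage result TSVs, rebuilds the stress-overview table
(per-organ mild/severe counts with union totals and chip percentages),
the interaction summary, and the trend summary, and writes a JSON run
report with the per-stage entity counts.
"""

import argparse
from pathlib import Path

import pandas as pd

from nwstress.report import (
    RunReport,
    interaction_table,
    stress_overview_table,
    trend_table,
)
from nwstress.trends import summarize_trends


def main():
    ap = argparse.ArgumentParser(description=__doc__)
    ap.add_argument("--results-dir", type=Path, default=Path("results"))
    ap.add_argument("--chip-total", type=int, default=None,
                    help="denominator for chip percentages (default: simulated size)")
    args = ap.parse_args()
    rd = args.results_dir

    de = {}
    for path in sorted((rd / "diffexpr").glob("de_*.tsv")):
        _de, organ, comp = path.stem.split("_")
        de[(organ, comp)] = pd.read_csv(path, sep="\t", index_col=0)
    inter = {
        p.stem.split("_")[1]: pd.read_csv(p, sep="\t", index_col=0)
        for p in sorted((rd / "interaction").glob("interaction_*.tsv"))
        if p.stem != "interaction_summary"
    }
    trends = {}
    for path in sorted((rd / "trends").glob("trends_*.tsv")):
        organ = path.stem.split("_")[1]
        trends[organ] = summarize_trends(pd.read_csv(path, sep="\t", index_col=0))

    n_sim = len(pd.read_csv(rd / "data" / "expression_raw.tsv", sep="\t",
                            usecols=[0]))
    chip_total = args.chip_total or n_sim
    water_de = {k: v for k, v in de.items() if k[1] in ("mild", "severe")}
    overview = stress_overview_table(water_de, chip_total=chip_total)
    itab = interaction_table(inter)
    ttab = trend_table(trends)

    rd.mkdir(parents=True, exist_ok=True)
    overview.to_csv(rd / "table_stress_overview.tsv", sep="\t")
    itab.to_csv(rd / "table_interaction.tsv", sep="\t")
    ttab.to_csv(rd / "table_trends.tsv", sep="\t")

    report = RunReport(parameters={"chip_total": chip_total})
    report.add_stage("simulated", n_sim)
    n_detected = len(pd.read_csv(rd / "data" / "expression_log2_baselined.tsv",
                                 sep="\t", usecols=[0]))
    report.add_stage("detected", n_detected)
    report.validate_monotone(["simulated", "detected"])
    report.to_json(rd / "run_report.json")

    print("stress overview (counts; total = union of mild and severe):")
    print(overview.to_string())
    print("\ninteraction summary (exclusive counts in parentheses):")
    print(itab.to_string())
    if len(ttab):
        print("\nnitrogen-dependent trend changes:")
        print(ttab.to_string())


if __name__ == "__main__":
    main()
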