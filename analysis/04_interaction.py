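#!/usr/bin/env python
"""Nitrogen x water interaction screening per organ.

Prescreens on the four pairwise fold changes of the 2x2 subdesign
(optimal/limiting N x optimal/severe W), runs the per-entity type-III
two-way ANOVA with BH correction, and classifies entities as nitrogen-,
water- or interaction-responsive, with the exclusively-interaction
subset in parentheses.
"""

import argparse
from pathlib import Path

from nwstress.data import ExpressionMatrix, SampleMetadata
from nwstress.interaction import interaction_analysis
from nwstress.report import interaction_table


def main():
    ap = argparse.ArgumentParser(description=__doc__)
    ap.add_argument("--fc", type=float, default=2.0)
    ap.add_argument("--alpha", type=float, default=0.05)
    ap.add_argument("--data-dir", type=Path, default=Path("results/data"))
    ap.add_argument("--out-dir", type=Path, default=Path("results/interaction"))
    args = ap.parse_args()

    logm = ExpressionMatrix.read_tsv(
        args.data_dir / "expression_log2_baselined.tsv", scale="log2-baselined"
    )
    metadata = SampleMetadata.read_tsv(args.data_dir / "sample_metadata.tsv")
    args.out_dir.mkdir(parents=True, exist_ok=True)

    results = {}
    for organ in sorted(metadata.table["organ"].unique()):
        res = interaction_analysis(logm, metadata, organ, fc_threshold=args.fc,
                                   alpha=args.alpha)
        res.to_csv(args.out_dir / f"interaction_{organ}.tsv", sep="\t")
        results[organ] = res
    table = interaction_table(results)
    table.to_csv(args.out_dir / "interaction_summary.tsv", sep="\t")
    print("entities explained by each effect (exclusive in parentheses):")
    print(table.to_string())


if __name__ == "__main__":
    main()
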