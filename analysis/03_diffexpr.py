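#!/usr/bin/env python
"""Single-factor differential-expression calls per organ.

For each organ: limiting vs optimal nitrogen at optimal water, and mild
/ severe water stress vs optimal water at optimal nitrogen — fold-change
filter first, then BH-corrected pooled t-tests. Prints per-comparison
counts and the cross-organ overlap of the water responses.
"""

import argparse
from pathlib import Path

from nwstress.data import ExpressionMatrix, SampleMetadata
from nwstress.diffexpr import COMPARISONS, de_call, significant_set, venn_partition


def main():
    ap = argparse.ArgumentParser(description=__doc__)
    ap.add_argument("--fc", type=float, default=2.0)
    ap.add_argument("--alpha", type=float, default=0.05)
    ap.add_argument("--data-dir", type=Path, default=Path("results/data"))
    ap.add_argument("--out-dir", type=Path, default=Path("results/diffexpr"))
    args = ap.parse_args()

    logm = ExpressionMatrix.read_tsv(
        args.data_dir / "expression_log2_baselined.tsv", scale="log2-baselined"
    )
    metadata = SampleMetadata.read_tsv(args.data_dir / "sample_metadata.tsv")
    args.out_dir.mkdir(parents=True, exist_ok=True)

    severe_sets = {}
    for organ in sorted(metadata.table["organ"].unique()):
        for comp in COMPARISONS:
            res = de_call(logm, metadata, organ, comp, fc_threshold=args.fc,
                          alpha=args.alpha)
            res.to_csv(args.out_dir / f"de_{organ}_{comp}.tsv", sep="\t")
            sig = significant_set(res)
            print(f"{organ:5s} {comp:8s}: {len(sig):5d} significant "
                  f"(family {int(res['in_family'].sum())})")
            if comp == "severe":
                severe_sets[organ] = sig
    if len(severe_sets) >= 2:
        print("severe-stress overlap between organs (exclusive regions):")
        for region, count in sorted(venn_partition(severe_sets).items(),
                                    key=lambda kv: sorted(kv[0])):
            print(f"  {'+'.join(sorted(region)):20s} {count}")


if __name__ == "__main__":
    main()
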