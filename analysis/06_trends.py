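#!/usr/bin/env python
"""Detect genes whose water-response trajectory changes with nitrogen.

Pairs each entity's optimal-N and limiting-N profiles (both must pass
their prescreens), runs the two-component mixture within each optimal-N
cluster group, and flags entities whose two observations receive
different components.
"""

import argparse
from pathlib import Path

import pandas as pd

from nwstress.trends import detect_trend_change, paired_profile_set, summarize_trends


def main():
    ap = argparse.ArgumentParser(description=__doc__)
    ap.add_argument("--organ", default="leaf")
    ap.add_argument("--fc-opt", type=float, default=3.0)
    ap.add_argument("--fc-lim", type=float, default=2.0)
    ap.add_argument("--global", dest="global_fit", action="store_true",
                    help="one two-component fit over all qualifying entities")
    ap.add_argument("--seed", type=int, default=1)
    ap.add_argument("--data-dir", type=Path, default=Path("results/data"))
    ap.add_argument("--cluster-dir", type=Path, default=Path("results/cluster"))
    ap.add_argument("--out-dir", type=Path, default=Path("results/trends"))
    args = ap.parse_args()

    p_opt = pd.read_csv(args.data_dir / f"profiles_{args.organ}_optimal.tsv",
                        sep="\t", index_col=0)
    p_lim = pd.read_csv(args.data_dir / f"profiles_{args.organ}_limiting.tsv",
                        sep="\t", index_col=0)
    qualifying, _ = paired_profile_set(p_opt, p_lim, fc_opt=args.fc_opt,
                                       fc_lim=args.fc_lim)
    print(f"{len(qualifying)} entities meet the fold-change criteria under both "
          "nitrogen regimes")

    groups = None
    if not args.global_fit:
        assign = pd.read_csv(
            args.cluster_dir / f"assignments_{args.organ}_optimal.tsv",
            sep="\t", index_col=0,
        )
        qualifying = [e for e in qualifying if e in assign.index]
        groups = assign.loc[qualifying, "map_group"]
    res = detect_trend_change(p_opt, p_lim, qualifying, groups, seed=args.seed,
                              per_cluster=not args.global_fit)
    args.out_dir.mkdir(parents=True, exist_ok=True)
    res.to_csv(args.out_dir / f"trends_{args.organ}.tsv", sep="\t")
    n_q, n_diff, pct = summarize_trends(res)
    print(f"{n_diff} of {n_q} entities ({pct}%) follow different trends under "
          "optimal and limiting nitrogen")


if __name__ == "__main__":
    main()
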