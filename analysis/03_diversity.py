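#!/usr/bin/env python
"""Rarefy and compute alpha and beta diversity.

Rarefies the decontaminated table to 2,000 reads per sample, tabulates
Shannon, inverse Simpson and Faith's PD by sample type, and writes the two
beta-diversity matrices the downstream analyses use: Jensen-Shannon
divergence on ASV relative abundances and generalized UniFrac (alpha = 0.5)
on the phylogeny, plus a PCoA embedding of the latter.
"""

import argparse
from pathlib import Path

import pandas as pd

from microstab import io as mio
from microstab.diversity import (alpha_diversity_table, generalized_unifrac,
                                 jsd_matrix, pcoa, rarefy)


def main():
    ap = argparse.ArgumentParser()
    ap.add_argument("--seed", type=int, default=1)
    ap.add_argument("--data", type=Path, default=Path("results/data"))
    ap.add_argument("--decontam", type=Path, default=Path("results/decontam"))
    ap.add_argument("--out", type=Path, default=Path("results/diversity"))
    args = ap.parse_args()
    args.out.mkdir(parents=True, exist_ok=True)

    table = mio.read_feature_table(args.decontam / "clean_table.tsv")
    metadata = mio.read_metadata(args.data / "metadata.tsv")
    tree = mio.read_tree(args.data / "tree.nwk")

    rt = rarefy(table, 2000, seed=args.seed)
    excluded = ", ".join(f"{s} ({n} reads)" for s, n in rt.excluded_samples)
    print(f"rarefied {len(rt.sample_ids)} samples at 2,000 reads; "
          f"excluded: {excluded or 'none'}")
    mio.write_feature_table(rt, args.out / "rarefied_table.tsv")

    alpha = alpha_diversity_table(rt, tree)
    alpha.to_csv(args.out / "alpha_diversity.tsv", sep="\t")
    summary = (alpha.join(metadata.frame["sample_type"])
               .groupby("sample_type").agg(["mean", "std", "count"]))
    summary.to_csv(args.out / "alpha_summary.tsv", sep="\t")
    print("alpha diversity by sample type (mean +/- SD):")
    for st, row in summary.iterrows():
        print(f"  {st:12s} Shannon {row[('shannon', 'mean')]:.2f} +/- "
              f"{row[('shannon', 'std')]:.2f}  invSimpson "
              f"{row[('inv_simpson', 'mean')]:.2f}  PD "
              f"{row[('faith_pd', 'mean')]:.2f}  (n={int(row[('shannon', 'count')])})")

    jsd_dm = jsd_matrix(rt)
    mio.write_distance_matrix(jsd_dm, args.out / "jsd.tsv")
    gu = generalized_unifrac(rt.drop_empty_features(), tree, alpha=0.5)
    mio.write_distance_matrix(gu, args.out / "gunifrac.tsv")
    res = pcoa(gu, n_axes=3)
    pd.DataFrame(res.coordinates, index=res.sample_ids,
                 columns=[f"PC{i+1}" for i in range(res.coordinates.shape[1])]
                 ).to_csv(args.out / "pcoa_gunifrac.tsv", sep="\t")
    print(f"PCoA of generalized UniFrac: first three axes explain "
          f"{100 * res.proportion_explained[:3].sum():.1f}% of variation")
    print(f"wrote diversity tables to {args.out}")


if __name__ == "__main__":
    main()
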