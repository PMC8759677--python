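#!/usr/bin/env python
"""Culture-vs-sequencing concordance and cross-habitat ASV overlap.

Each cultured urine sample is classed by whether every cultured genus also
appears in its sequencing profile (and whether all exceed 10% relative
abundance).  ASVs shared between habitats of the same volunteer are classed
confident or ambiguous by the 0.2% abundance rule; the cross-volunteer
sharing summary shows which ASVs form the common urogenital community.
"""

import argparse
from pathlib import Path

import pandas as pd

from microstab import io as mio
from microstab.concordance import (classify_concordance, classify_overlaps,
                                   sharing_summary)
from microstab.diversity import rarefy
from microstab.pipeline import summarize_counts


def main():
    ap = argparse.ArgumentParser()
    ap.add_argument("--data", type=Path, default=Path("results/data"))
    ap.add_argument("--diversity", type=Path, default=Path("results/diversity"))
    ap.add_argument("--out", type=Path, default=Path("results/concordance"))
    args = ap.parse_args()
    args.out.mkdir(parents=True, exist_ok=True)

    rt = mio.read_feature_table(args.diversity / "rarefied_table.tsv")
    metadata = mio.read_metadata(args.data / "metadata.tsv")
    culture = mio.read_culture(args.data / "culture.tsv")

    records, summary = classify_concordance(culture, rt)
    n = summary["n"]
    c = summary["counts"]
    n_all = c["ALL_CONFIRMED"] + c["ALL_CONFIRMED_HIGH"]
    print(f"culture vs sequencing over {n} CU samples:")
    print(f"  all cultured taxa sequenced:      {summarize_counts(n_all, n)}")
    print(f"    ... all above 10% abundance:    "
          f"{summarize_counts(c['ALL_CONFIRMED_HIGH'], n)}")
    print(f"  not all cultured taxa sequenced:  "
          f"{summarize_counts(c['PARTIAL'], n)}")
    print(f"  no bacterial growth:              "
          f"{summarize_counts(c['CULTURE_NEGATIVE'], n)}")
    pd.DataFrame([{
        "sample_id": r.sample_id,
        "cultured_genera": ";".join(r.cultured_genera),
        "class": r.concordance.value,
    } for r in records]).to_csv(args.out / "concordance.tsv", sep="\t",
                                index=False)

    cu_fecal = classify_overlaps(rt, metadata, ("CU", "fecal"))
    n_amb = sum(r.overlap.value == "AMBIGUOUS" for r in cu_fecal)
    feats = {r.feature_id for r in cu_fecal}
    print(f"CU/fecal overlap: {len(feats)} ASVs shared within volunteers; "
          f"{summarize_counts(n_amb, len(cu_fecal))} of overlap records "
          f"ambiguous (one side below 0.2%)")

    uro = []
    for pair in (("CU", "vswab"), ("CU", "pswab"), ("pswab", "vswab")):
        uro.extend(classify_overlaps(rt, metadata, pair))
    share = sharing_summary(uro, confident_only=True)
    share.to_csv(args.out / "urogenital_sharing.tsv", sep="\t", index=False)
    genus = rt.genus()
    print("most widely shared urogenital ASVs (confident overlaps):")
    for _, row in share.head(4).iterrows():
        print(f"  {row['feature_id']} ({genus.loc[row['feature_id']]}): "
              f"{row['n_volunteers']} volunteers, {row['n_samples']} samples")
    print(f"wrote concordance/overlap tables to {args.out}")


if __name__ == "__main__":
    main()
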