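#!/usr/bin/env python
"""Generate the synthetic longitudinal cohort all downstream analyses use.

Emulates the study design: 15 volunteers, four bimonthly visits with catheter
urine (CU), vaginal/periurethral swabs and a fecal sample, a visit-5 CU+MU
substudy in ten volunteers, three sterile-saline negative sampling controls,
and reagent contamination whose load scales inversely with sample biomass.
Writes the standard-format inputs under results/data/.
"""

import argparse
import json
from pathlib import Path

from microstab import io as mio
from microstab.simulate import generate_cohort, study_like_config


def main():
    ap = argparse.ArgumentParser()
    ap.add_argument("--seed", type=int, default=1)
    ap.add_argument("--out", type=Path, default=Path("results/data"))
    args = ap.parse_args()
    args.out.mkdir(parents=True, exist_ok=True)

    cohort = generate_cohort(study_like_config(seed=args.seed))
    mio.write_feature_table(cohort.table, args.out / "feature_table.tsv")
    mio.write_metadata(cohort.metadata, args.out / "metadata.tsv")
    mio.write_tree(cohort.tree, args.out / "tree.nwk")
    mio.write_culture(cohort.culture, args.out / "culture.tsv")
    gt = cohort.ground_truth
    with open(args.out / "ground_truth.json", "wt") as fh:
        json.dump({"contaminant_ids": gt.contaminant_ids,
                   "thetas": gt.thetas,
                   "contaminant_reads": gt.contaminant_reads}, fh, indent=2)

    types = cohort.metadata.frame["sample_type"].value_counts()
    print(f"cohort: {cohort.table.shape[0]} ASVs x {cohort.table.shape[1]} samples")
    print(types.to_string())
    print(f"planted contaminant ASVs: {gt.contaminant_ids}")
    print(f"wrote inputs to {args.out}")


if __name__ == "__main__":
    main()
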