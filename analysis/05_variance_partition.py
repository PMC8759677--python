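#!/usr/bin/env python
"""PERMANOVA variance partitioning of catheter-urine beta diversity.

Three models on the generalized UniFrac distances of CU visits 1-4 (999
permutations each): a univariate screen of every candidate covariate; a
sequential multivariate model containing volunteer ID after dropping terms
that are aliases of the ID (constant within every volunteer); and a
stratified model restricting permutations to within-volunteer shuffles so
that purely intraindividual covariate effects are isolated.  Also reports
the volunteer R2 for fecal samples and the sample-type effect across all
habitats.
"""

import argparse
from pathlib import Path

import pandas as pd

from microstab import io as mio
from microstab.variance import permanova, permanova_univariate, term_screen

CANDIDATES = ["diet", "fluid_intake", "contraceptive", "cycle_week",
              "time_since_intercourse"]


def main():
    ap = argparse.ArgumentParser()
    ap.add_argument("--seed", type=int, default=1)
    ap.add_argument("--data", type=Path, default=Path("results/data"))
    ap.add_argument("--diversity", type=Path, default=Path("results/diversity"))
    ap.add_argument("--out", type=Path, default=Path("results/permanova"))
    args = ap.parse_args()
    args.out.mkdir(parents=True, exist_ok=True)

    gu = mio.read_distance_matrix(args.diversity / "gunifrac.tsv")
    metadata = mio.read_metadata(args.data / "metadata.tsv")
    meta = metadata.frame

    def subset(sample_type, visits):
        ids = [s for s in gu.sample_ids
               if meta.loc[s, "sample_type"] == sample_type
               and meta.loc[s, "visit"] in visits]
        return gu.subset(ids)

    dm_cu = subset("CU", {"1", "2", "3", "4"})
    rows = []

    uni = permanova_univariate(dm_cu, metadata, CANDIDATES + ["volunteer_id"],
                               n_perm=999, seed=args.seed)
    print("univariate PERMANOVA (CU 1-4, generalized UniFrac):")
    for term, r in uni.items():
        print(f"  {term:24s} R2 = {r.r_squared:.2f}  p = {r.p_value:.3f}")
        rows.append({"model": "univariate", "term": term,
                     "r_squared": r.r_squared, "p": r.p_value})

    retained, excluded = term_screen(metadata, CANDIDATES)
    print(f"terms excluded from the ID model (constant within volunteer): "
          f"{', '.join(excluded) or 'none'}")
    multi = permanova(dm_cu, metadata, retained + ["volunteer_id"],
                      n_perm=999, seed=args.seed)
    print("multivariate (sequential, including volunteer ID):")
    for r in multi:
        p = "-" if r.p_value is None else f"{r.p_value:.3f}"
        print(f"  {r.term:24s} R2 = {r.r_squared:.2f}  p = {p}")
        rows.append({"model": "multivariate", "term": r.term,
                     "r_squared": r.r_squared, "p": r.p_value})

    strat = permanova(dm_cu, metadata, retained, n_perm=999, seed=args.seed,
                      strata="volunteer_id")
    print("stratified by volunteer (within-volunteer permutations):")
    for r in strat:
        p = "-" if r.p_value is None else f"{r.p_value:.3f}"
        print(f"  {r.term:24s} R2 = {r.r_squared:.2f}  p = {p}")
        rows.append({"model": "stratified", "term": r.term,
                     "r_squared": r.r_squared, "p": r.p_value})

    dm_fecal = subset("fecal", {"1", "2", "3", "4"})
    fec = permanova(dm_fecal, metadata, ["volunteer_id"], n_perm=999,
                    seed=args.seed)
    print(f"fecal 1-4 volunteer ID: R2 = {fec[0].r_squared:.2f} "
          f"p = {fec[0].p_value:.3f}")
    rows.append({"model": "fecal", "term": "volunteer_id",
                 "r_squared": fec[0].r_squared, "p": fec[0].p_value})

    all_ids = [s for s in gu.sample_ids
               if meta.loc[s, "sample_type"] != "neg_control"]
    allt = permanova(gu.subset(all_ids), metadata, ["sample_type"],
                     n_perm=999, seed=args.seed)
    print(f"all samples, sample type: R2 = {allt[0].r_squared:.2f} "
          f"p = {allt[0].p_value:.3f}")
    rows.append({"model": "all_samples", "term": "sample_type",
                 "r_squared": allt[0].r_squared, "p": allt[0].p_value})

    pd.DataFrame(rows).to_csv(args.out / "permanova.tsv", sep="\t", index=False)
    print(f"wrote PERMANOVA table to {args.out}")


if __name__ == "__main__":
    main()
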