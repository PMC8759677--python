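# microstab

Longitudinal stability analysis of low-biomass microbiota — a reusable
Python pipeline for 16S rRNA ASV studies that pair low-biomass urogenital
samples (catheter urine, midstream urine, vaginal/periurethral swabs) with
high-biomass fecal samples across repeated visits.

Studies of the urinary microbiota face three coupled problems: urine carries
so little bacterial biomass that reagent contamination can dominate the
sequencing signal; community composition drifts over months, so "the"
microbiota of a person is a distribution, not a point; and sequencing-based
profiles need anchoring against viable-organism evidence from expanded
urinary culture. `microstab` implements the corresponding analysis chain as
a tested library with a CLI:

1. **Decontamination** — an ASV is flagged as a contaminant when, across the
   sterile-saline negative sampling controls, its mean relative abundance
   exceeds 0.5%, it is present in *every* control, and it exceeds 5% in at
   least one (all three criteria, strict inequalities). Flagged ASVs are
   removed everywhere, and their summed abundance in real samples is
   correlated against post-extraction DNA concentration — a negative
   Pearson *r* (with Fisher-z CI) is the signature of reagent-borne
   contamination of low-biomass samples.
2. **Rarefaction and diversity** — single subsample without replacement to
   2,000 reads/sample; Shannon *H* = −Σ pᵢ ln pᵢ, inverse Simpson 1/Σ pᵢ²,
   Faith's PD; Jensen-Shannon divergence on ASV profiles
   (JSD(p,q) = ½KL(p‖m) + ½KL(q‖m), m = (p+q)/2, bounded by ln 2); the
   generalized UniFrac of Chen et al.,
   d(A,B) = Σ_b L_b (p_bA+p_bB)^α |p_bA−p_bB|/(p_bA+p_bB) ⁄
   Σ_b L_b (p_bA+p_bB)^α, with α = 0.5 by default; classical PCoA.
3. **Stability** — per sample, the median JSD to all other same-volunteer
   samples of the same type (visits 1–4); habitat comparison by two-sided
   Mann-Whitney U (exact enumeration for small samples).
4. **Variance partitioning** — sequential (Type I) PERMANOVA on the distance
   matrix: R² per term, pseudo-F, permutation p (999 permutations), with
   restricted within-volunteer permutations for stratified models and an
   automatic screen for covariates that are aliases of volunteer identity.
5. **Concordance and overlap** — cultured genera checked against sequencing
   profiles (all confirmed / all above 10% / partial / no growth), and ASVs
   shared between habitats of one volunteer classed confident vs ambiguous
   by the 0.2% relative-abundance rule.
6. **Synthetic cohorts** — a Dirichlet-multinomial generator reproducing the
   study design (15 volunteers × 4 visits × 4 habitats, a visit-5 CU+MU
   substudy, negative controls, biomass-dependent contamination, culture
   detections), with full ground truth for validating every stage.

## Worked example

The numbered scripts under `analysis/` run the full study on a synthetic
cohort and write tables under `results/`:

```bash
python analysis/01_simulate_cohort.py --seed 1
python analysis/02_decontaminate.py
python analysis/03_diversity.py --seed 1
python analysis/04_stability.py
python analysis/05_variance_partition.py --seed 1
python analysis/06_concordance_overlap.py
```

With seed 1 the decontamination step prints

```
flagged 5 ASVs belonging to 5 genera: Alkalibacterium, Bacteroides, Ralstonia, Serratia, Shewanella
ground truth check: 5/5 planted contaminants recovered, 0 false positives
contaminant abundance vs DNA concentration (CU, n=68): Pearson r = -0.661 [95% CI -0.777, -0.502]
CU mean reads before/after removal: 22726 -> 12313
```

— all five planted contaminants are flagged, no genuine ASV is lost, and the
flagged abundance anticorrelates with DNA concentration because the
contaminant fraction scales as c/(c + biomass). The stability step prints

```
CU    median intra-JSD 0.35 (range 0.01-0.58; IQR 0.28-0.48; n=56)
fecal median intra-JSD 0.16 (range 0.11-0.23; IQR 0.14-0.18; n=60)
Mann-Whitney two-sided p = 4.21e-10 -> urinary microbiota less stable than fecal
```

— urine drifts far more between visits than the gut. Variance partitioning
attributes about half of urinary beta diversity to volunteer identity
(`volunteer_id R2 = 0.49, p = 0.001`; fecal `R2 = 0.65`), excludes
volunteer-constant covariates (diet, fluid intake, contraceptive) from the
ID model, and the concordance step prints

```
all cultured taxa sequenced:      45 (68.2%)
  ... all above 10% abundance:    20 (30.3%)
not all cultured taxa sequenced:  12 (18.2%)
no bacterial growth:              9 (13.6%)
```

while every CU/fecal ASV overlap falls below the 0.2% confidence floor on at
least one side (ambiguous), and the most widely shared urogenital ASVs are
Lactobacillus ASVs present in all 15 volunteers.

The same pipeline is available as a CLI (`microstab simulate | decontam |
diversity | stability | permanova | run`), e.g.

```bash
microstab simulate --seed 1 --out-dir data/
microstab decontam --table data/feature_table.tsv --metadata data/metadata.tsv \
    --out-table clean.tsv --report calls.tsv
```

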