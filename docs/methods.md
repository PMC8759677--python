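# Methods

## Scope and data model

The package analyzes an ASV feature table (features × samples, raw integer
counts, genus-level taxonomy), per-sample metadata (volunteer, visit, sample
type from the closed set `CU, MU, vswab, pswab, fecal, neg_control`, DNA
concentration in ng/µl, lifestyle covariates), a rooted branch-length
phylogeny over the ASVs, and optionally a long-format culture table
(sample, genus, CFU/ml; an empty-genus marker row denotes a cultured sample
with no growth). Upstream read processing (denoising, chimera removal,
taxonomic classification) is out of scope: the pipeline consumes an
already-built, annotated table. Event visits such as `UTI1`/`UTI2` are
carried in metadata but excluded from the regular visit-1–4 analyses by the
default filters.

All files are plain TSV/Newick. BIOM input is not supported (no BIOM
library in the dependency set; the TSV dialect is the QIIME-style
features-in-rows layout with a `#OTU ID` first column and optional final
`taxonomy` column).

## Decontamination

Negative sampling controls are sterile saline processed through the full
collection chain, so ASVs abundant in them are procedural contaminants.
A feature is flagged when all of (defaults, AND-combined, each individually
switchable and re-combinable with OR):

* mean relative abundance across controls **> 0.005** (strict),
* prevalence across controls **≥ 1.0** (present in every control; presence
  means ≥ 1 read),
* maximum relative abundance in any single control **> 0.05** (strict).

Abundances for the criteria are computed within control samples from raw,
pre-rarefaction counts; zero-read controls are excluded with a warning.
AND-combination is the default because the conjunctive rule reproduces the
small removed set expected for reagent contaminants; flagging is monotone in
each threshold and the OR set always contains the AND set (both are tested
properties). Removal deletes flagged rows from all samples and conserves
every unflagged count exactly.

The contaminant–DNA-concentration statistic is the Pearson correlation
between per-sample summed relative abundance of flagged features and
`dna_conc` over non-control samples (optionally one sample type), with a
Fisher-z 95% CI; it requires ≥ 4 samples and non-constant vectors.

## Diversity

* **Rarefaction**: one multivariate-hypergeometric draw (uniform subsample
  without replacement) to exactly 2,000 reads per sample, deterministic
  given the seed; samples below depth are excluded and reported. A single
  rarefied table is used throughout (no rarefaction averaging).
* **Alpha**: Shannon in nats (base-2 by flag), inverse Simpson, Faith's PD.
  PD is root-inclusive by default (the minimal subtree connects the present
  leaves *and* the root), matching the common implementation lineage; a
  root-exclusive flag spans only the leaves' MRCA subtree. Alpha metrics are
  computed on the rarefied table.
* **JSD**: natural-log Jensen-Shannon divergence on renormalized rarefied
  profiles, clipped to [0, ln 2]; base-2 by flag.
* **Generalized UniFrac**: per-branch proportions are accumulated bottom-up;
  the Chen et al. weighted formula with exponent α (default 0.5; α = 1
  recovers weighted-normalized UniFrac, which is verified against an
  independent implementation in the tests). Branches with zero combined
  proportion are skipped; values lie in [0, 1].
* **PCoA**: classical MDS via eigendecomposition of the Gower-centered
  −½D² matrix. Negative eigenvalues (non-Euclidean distances) are retained
  in the eigenvalue report but clamped to zero for proportion-explained;
  coordinates are returned for positive eigenvalues only; no Cailliez
  correction.

## Stability statistic

For a group (one sample type, visits 1–4) the statistic of a sample is the
**median JSD between that sample and every other same-volunteer sample in
the group**; volunteers with fewer than two group samples are skipped with a
warning. Group comparisons report medians, IQRs, ranges, and a two-sided
Mann-Whitney p on the per-sample records by default; a per-volunteer-median
variant is provided because the unit of the original comparison is ambiguous
in such designs. The paired CU/MU analysis reports, per volunteer, the JSD
of the visit-5 pair against the set of pairwise visit-1–4 CU JSDs and
whether the pair exceeds that reference maximum.

## PERMANOVA

Sequential (Type I) sums of squares in caller-given term order: with
G = −½ J D² J and H_k the hat matrix of the design containing the intercept
and the first k term blocks, SS_k = tr(H_k G) − tr(H_{k−1} G); pseudo-F uses
the residual mean square. Significance permutes sample identities of the
distance matrix — freely, or within strata blocks when stratifying by
volunteer — recomputing all sequential F statistics per permutation;
p = (#{F* ≥ F} + 1)/(n_perm + 1), ties counted conservatively. When the
distinct permutation space (n! free, Π n_b! within strata) is no larger than
the request, it is enumerated exhaustively and p becomes the exact
permutation fraction; this path is verified against a brute-force oracle.
A term constant within every stratum is rejected as confounded. Categorical
terms are dummy-coded (first level dropped); samples missing any model term
are dropped listwise per model. The default 999 permutations give a p floor
of 0.001.

`term_screen` excludes, from models containing volunteer ID, covariates
whose within-volunteer modal-level frequency (minimized over volunteers)
meets a consistency threshold (default 1.0 — exactly constant within every
volunteer): such terms are aliases of identity and would absorb its
variance.

## Nonparametric tests

Rank tests are self-contained with exact small-sample paths so that
printed p-values are rationals over the enumeration space:

* Mann-Whitney U: exact enumeration of all C(n_a+n_b, n_a) assignments when
  n_a+n_b ≤ 12 and the pooled data are tie-free (two-sided = as-or-more
  extreme under min(U, n_a n_b − U)); otherwise the normal approximation
  with tie and continuity correction (p ≡ 1 at the null center).
* Wilcoxon signed-rank: zero differences dropped (Pratt by flag); exact
  sign-flip distribution by convolution over doubled midranks for ≤ 20
  nonzero pairs (six concordant pairs give 2/2⁶ ≈ 0.031), else the normal
  approximation. Exact paths are cross-checked against scipy's enumeration,
  and both tests' type-I error is calibrated under null simulations.
* Kruskal-Wallis (tie-corrected, χ² p) with Dunn's z post-tests,
  BH-adjusted.
* Pearson r with Fisher-z CI tanh(atanh r ± z/√(n−3)); |r| = 1 collapses
  the interval to the boundary.
* Benjamini-Hochberg step-up adjustment, monotone and capped at 1.

## Synthetic cohort generator

The generator provides ground truth for every stage and emulates the study
design: 15 volunteers (A–O), four bimonthly visits with CU, vaginal swab,
periurethral swab and fecal samples, a visit-5 CU+MU pair in 10 volunteers,
two missed CU visits, three negative sampling controls, five contaminant
ASVs.

Hierarchy per habitat: a volunteer base composition is drawn from a
Dirichlet over the habitat's genus pool expanded to ASV level (`spread` =
total concentration; smaller → more distinct volunteers), and each visit's
composition from Dirichlet(θ_habitat × base) (`theta` larger → more stable).
Visits are exchangeable by construction — the bimonthly spacing and the
median-JSD statistic treat them symmetrically, so no autoregressive
structure is modeled. Reads are multinomial at a lognormal depth.
Midstream urine is an admixture (1−λ)·CU + λ·(½ vswab + ½ pswab) at the
shared visit; a recent-intercourse covariate mixes vaginal flora into CU
(weight decaying with time since intercourse). A random bifurcating
phylogeny (congeneric ASVs coalesce first, exponential unit-mean branch
lengths) covers all features.

Contamination: each sample's expected contaminant read fraction is
c/(c + biomass) with biomass lognormal per habitat (urine ≈ 1, feces ≈ 2000
in arbitrary units) and reagent load c = 1, so urine loses roughly half its
reads to contaminants while feces are essentially clean; negative controls
(biomass 0) are contaminant-dominated apart from a 1% community cross-talk
floor. DNA concentration is proportional to biomass with lognormal noise
(σ = 0.8), producing the contaminant-vs-concentration anticorrelation
(r ≈ −0.6 on urine samples). Culture detections are Bernoulli with logistic
probability in log10 relative abundance (intercept 0.0, slope 0.4),
calibrated so the concordance-class distribution over cultured urine samples
(≈ 13% no growth, ≈ 70% fully confirmed, ≈ 30% fully confirmed above 10%,
≈ 15% partial) matches what expanded urinary culture typically yields.

Default calibration (chosen once, against the study conditions the pipeline
is meant to reproduce): CU `spread 6, theta 1.2`; vswab `3, 25`; pswab
`3, 18`; fecal `spread 40, theta 45` with 4 ASVs per genus. This yields a
median intraindividual CU JSD around 0.26–0.35 versus fecal 0.16–0.18,
Mann-Whitney separation with ≈ 90% power at the design size, volunteer R²
≈ 0.49 (CU) and ≈ 0.63 (fecal), and Lactobacillus-dominated urogenital
profiles with fecal alpha diversity well above urinary.

### What the generator does not capture

* Symmetric Dirichlet drift couples drift magnitude to profile sparsity: at
  the θ reproducing realistic urinary drift, per-visit urine profiles are
  spikier (lower Shannon) than real urine, and the fecal JSD median
  undershoots slightly when its IQR is kept realistically tight. Passing
  tests therefore demonstrate correct inference under the assumed
  hierarchical model, not distributional realism of every alpha statistic.
* With urine drift at its calibrated (high) level, within-volunteer
  covariate effects of realistic size are not detectable by stratified
  PERMANOVA, and the CU/MU pair divergence does not exceed each volunteer's
  own longitudinal maximum — the admixture mechanism is validated under a
  stable-urine configuration instead. Real urinary dynamics evidently drift
  within a constrained subspace while sampling technique adds novel taxa, a
  structure a single exchangeable Dirichlet level cannot express.
* No read-level error, chimeras or index hopping; cross-habitat "leak" is a
  uniform 0.1% admixture of the global mean community, which is what makes
  low-abundance cross-habitat overlaps (the ambiguous class) appear.

## Numerical and policy choices

* Strict inequalities at printed thresholds (0.5%, 5%, 10%; ambiguity rule
  "below 0.2%").
* Genus matching between culture and sequencing is case-insensitive with a
  small synonym map (e.g. cultured *Escherichia* ↔ sequencing taxon
  "Escherichia-Shigella"), extensible per call.
* "Detected by sequencing" means abundance > 0 in the rarefied table; a
  minimum-abundance floor is configurable.
* Rarefaction, cohort generation and permutation tests consume a single
  integer seed each; every pipeline stage is a pure function of inputs,
  config and seeds.
* Percentages in reports are rounded half-up to one decimal and always
  re-derivable from their printed numerator/denominator.

## Problem sizes

The test suite validates parameter recovery on 100 replicate cohorts at the
full design size (~260 samples, ~110 ASVs each) and calibrates type-I error
over 2,000 null replicates (PERMANOVA with 99 permutations at n = 12; rank
tests at n = 12–15); exhaustive-enumeration oracles run at n ≤ 7 samples
(≤ 5,040 permutations) and 8-leaf trees. These sizes keep the whole suite
under a minute of compute per criterion group while leaving the statistics
(binomial error on a 95% threshold at 100 replicates ≈ ±4%) meaningful.
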