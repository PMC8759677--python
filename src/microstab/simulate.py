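"""Synthetic longitudinal cohort generator with ground truth.

The generator emulates the statistical structure the downstream analyses
assume for a cohort of premenopausal volunteers sampled at four bimonthly
visits across several habitats (catheter urine CU, midstream urine MU,
vaginal and periurethral swabs, feces), plus sterile-saline negative
sampling controls:

* hierarchical Dirichlet-multinomial compositions — a volunteer-specific
  base community drawn from a habitat genus pool (Lactobacillus-dominated
  urogenital pools, a diverse fecal pool), per-visit drift around that base
  with habitat-specific concentration theta (higher = more stable, so
  theta_fecal > theta_urine makes urine the less stable habitat);
* reagent contamination — a fixed set of contaminant ASVs whose expected
  per-sample read fraction is c / (c + biomass), so low-biomass urine is
  heavily contaminated, high-biomass feces barely, and negative controls
  (biomass ~ 0) are dominated by them; post-extraction DNA concentration is
  proportional to biomass, producing the characteristic anticorrelation;
* midstream urine as an admixture (1-lambda) * CU + lambda * urethral flora
  (vaginal/periurethral mixture);
* a recent-intercourse covariate that mixes vaginal flora into CU samples,
  a detectable within-volunteer beta-diversity effect;
* expanded-culture detections as abundance-dependent Bernoulli draws
  (logistic in log10 relative abundance) with CFU/ml scaled by biomass;
* a random bifurcating phylogeny over all ASVs (congeneric ASVs cluster)
  with unit-mean exponential branch lengths.

Everything is deterministic given the config seed.
"""

from __future__ import annotations

from dataclasses import dataclass, field, replace

import numpy as np
import pandas as pd
import skbio

from .errors import MicrostabError
from .io import CultureTable, FeatureTable, SampleMetadata, read_tree

VOLUNTEER_LETTERS = "ABCDEFGHIJKLMNOPQRSTUVWXYZ"

#: genus pools (genus -> relative weight) per habitat; urogenital habitats
#: share one ASV inventory so the same Lactobacillus/Gardnerella ASVs recur
#: across CU, MU and swabs, while the fecal inventory is distinct
UROGENITAL_POOLS = {
    "CU": {
        "Lactobacillus": 50, "Gardnerella": 10, "Prevotella": 5,
        "Streptococcus": 4, "Staphylococcus": 3, "Corynebacterium": 3,
        "Finegoldia": 4, "Peptoniphilus": 3, "Anaerococcus": 3,
        "Fannyhessea": 2, "Veillonella": 2, "Escherichia-Shigella": 1,
        "Actinomyces": 1, "Bifidobacterium": 1,
    },
    "vswab": {
        "Lactobacillus": 85, "Gardnerella": 7, "Fannyhessea": 2,
        "Prevotella": 2, "Streptococcus": 2, "Bifidobacterium": 2,
    },
    "pswab": {
        "Lactobacillus": 62, "Gardnerella": 8, "Corynebacterium": 7,
        "Staphylococcus": 6, "Finegoldia": 5, "Anaerococcus": 4,
        "Peptoniphilus": 4, "Prevotella": 2, "Streptococcus": 2,
    },
}

FECAL_POOL = {
    "Bacteroides": 12, "Faecalibacterium": 10, "Blautia": 8, "Agathobacter": 6,
    "Roseburia": 6, "Bifidobacterium": 5, "Ruminococcus": 6, "Prevotella": 5,
    "Alistipes": 5, "Dorea": 4, "Coprococcus": 4, "Lachnospira": 4,
    "Parabacteroides": 4, "Subdoligranulum": 4, "Eubacterium": 4,
    "Oscillibacter": 3, "Collinsella": 3, "Akkermansia": 3,
    "Escherichia-Shigella": 2, "Streptococcus": 2,
}

CONTAMINANT_GENERA = ("Alkalibacterium", "Shewanella", "Serratia", "Bacteroides", "Ralstonia")

DIET_LEVELS = ("non-vegetarian", "non-vegetarian-lactose-free", "vegetarian")
DIET_PROBS = (11 / 15, 2 / 15, 2 / 15)
FLUID_LEVELS = ("<1.5", "1.5-3", ">3")
FLUID_PROBS = (2 / 15, 10 / 15, 3 / 15)
INTERCOURSE_LEVELS = ("<24h", "24-96h", ">96h-1wk", ">1wk")
INTERCOURSE_PROBS = (0.25, 0.30, 0.25, 0.20)
#: vaginal-admixture weight into CU per time-since-intercourse level
INTERCOURSE_MIX = {"<24h": 1.0, "24-96h": 0.5, ">96h-1wk": 0.25, ">1wk": 0.0}


@dataclass
class HabitatConfig:
    """Per-habitat generative parameters.

    ``pool``: genus -> weight; ``spread``: Dirichlet concentration of the
    volunteer base around the pool (lower = more distinct volunteers);
    ``theta``: within-volunteer concentration around the base (higher = more
    stable visits); ``depth_log`` / ``biomass_log``: (mu, sigma) of the
    lognormal sequencing depth and of the biomass (arbitrary units, urine
    << feces); ``asvs_per_genus``: ASV inventory granularity.
    """

    pool: dict
    spread: float
    theta: float
    depth_log: tuple[float, float]
    biomass_log: tuple[float, float]
    asvs_per_genus: int = 2


@dataclass
class CohortConfig:
    n_volunteers: int = 15
    visits: int = 4
    visit5_volunteers: int = 10  # subset providing a CU+MU pair at visit 5
    habitats: dict = field(default_factory=dict)  # habitat -> HabitatConfig
    urethral_admixture: float = 0.30  # lambda: MU = (1-l) CU + l urethral
    intercourse_effect: float = 0.15  # vaginal admixture into CU at <24h
    n_contaminant_asvs: int = 5
    reagent_load: float = 1.0  # c in contaminant fraction c/(c + biomass)
    n_neg_controls: int = 3
    neg_control_crosstalk: float = 0.01
    cross_habitat_leak: float = 0.001
    dna_conc_scale: float = 2.0  # ng/ul per biomass unit
    dna_conc_noise: float = 0.8  # lognormal sigma on dna_conc
    culture_logit_intercept: float = 0.0  # detection at log10(abund) = 0
    culture_logit_slope: float = 0.4
    dropouts: tuple = ()  # (volunteer_letter, visit, habitat) triples
    seed: int = 0

    def validate(self) -> None:
        if not self.habitats:
            raise MicrostabError("config defines no habitats")
        for name, hab in self.habitats.items():
            if not hab.pool:
                raise MicrostabError(f"habitat {name!r} has an empty genus pool")
            if hab.spread <= 0 or hab.theta <= 0:
                raise MicrostabError(f"habitat {name!r} needs positive spread/theta")
        if not 0.0 <= self.urethral_admixture <= 1.0:
            raise MicrostabError("urethral_admixture must lie in [0, 1]")
        if self.reagent_load < 0:
            raise MicrostabError("reagent_load must be >= 0")


@dataclass
class GroundTruth:
    contaminant_ids: list[str]
    volunteer_bases: dict  # (habitat, volunteer) -> composition over all ASVs
    thetas: dict  # habitat -> theta
    biomass: dict  # sample_id -> biomass
    contaminant_reads: dict  # sample_id -> reads assigned to contaminants
    true_compositions: dict  # sample_id -> community composition (no contam)


@dataclass
class Cohort:
    table: FeatureTable
    metadata: SampleMetadata
    tree: skbio.TreeNode
    culture: CultureTable
    ground_truth: GroundTruth
    config: CohortConfig


def study_like_config(seed: int = 0, **overrides) -> CohortConfig:
    """Default study-design configuration: 15 volunteers, 4 bimonthly visits
    of CU/vswab/pswab/fecal each, a 10-volunteer visit-5 CU+MU substudy, two
    missed CU visits, 5 contaminant ASVs, 3 negative sampling controls.

    Urogenital pools are Lactobacillus-heavy and the fecal pool diverse;
    theta_fecal > theta_CU makes urine the less stable habitat and fecal
    between-volunteer spread is tighter within volunteer, so the volunteer
    term explains more fecal than urinary beta diversity.
    """
    habitats = {
        "CU": HabitatConfig(UROGENITAL_POOLS["CU"], spread=6.0, theta=1.2,
                            depth_log=(np.log(20000), 0.6),
                            biomass_log=(0.0, 1.0)),
        "vswab": HabitatConfig(UROGENITAL_POOLS["vswab"], spread=3.0, theta=25.0,
                               depth_log=(np.log(30000), 0.5),
                               biomass_log=(np.log(50.0), 1.0)),
        "pswab": HabitatConfig(UROGENITAL_POOLS["pswab"], spread=3.0, theta=18.0,
                               depth_log=(np.log(25000), 0.5),
                               biomass_log=(np.log(10.0), 1.0)),
        "fecal": HabitatConfig(FECAL_POOL, spread=40.0, theta=45.0,
                               depth_log=(np.log(40000), 0.4),
                               biomass_log=(np.log(2000.0), 0.5),
                               asvs_per_genus=4),
    }
    cfg = CohortConfig(
        habitats=habitats,
        dropouts=(("F", "4", "CU"), ("O", "3", "CU")),
        seed=seed,
    )
    return replace(cfg, **overrides) if overrides else cfg


# ---------------------------------------------------------------------------
# generation
# ---------------------------------------------------------------------------

def generate_cohort(config: CohortConfig) -> Cohort:
    """Draw a complete cohort (feature table, metadata, tree, culture table)
    plus the ground truth needed to verify downstream inference."""
    config.validate()
    rng = np.random.default_rng(config.seed)

    inventory = _build_inventory(config, rng)
    asv_ids = inventory["asv_ids"]
    n_asv = len(asv_ids)
    contaminant_ids = inventory["contaminant_ids"]
    contam_idx = np.array([asv_ids.index(a) for a in contaminant_ids])

    volunteers = [VOLUNTEER_LETTERS[i] for i in range(config.n_volunteers)]
    vol_cov = _volunteer_covariates(volunteers, rng)

    # volunteer base compositions per habitat
    bases: dict[tuple[str, str], np.ndarray] = {}
    for hab, hcfg in config.habitats.items():
        alpha = inventory["pool_alpha"][hab] * hcfg.spread
        for v in volunteers:
            bases[(hab, v)] = _dirichlet(rng, alpha)

    contam_profile = rng.dirichlet(np.full(len(contaminant_ids), 15.0))
    global_mean = np.mean([b for b in bases.values()], axis=0)
    urogenital_mean = np.mean(
        [bases[(h, v)] for h in config.habitats if h != "fecal" for v in volunteers],
        axis=0,
    ) if any(h != "fecal" for h in config.habitats) else global_mean

    dropouts = {(v, str(t), h) for v, t, h in config.dropouts}
    counts: dict[str, np.ndarray] = {}
    meta_rows: list[dict] = []
    culture_rows: list[dict] = []
    culture_ids: list[str] = []
    gt_biomass, gt_contam_reads, gt_true_comp = {}, {}, {}

    def _emit_sample(sid, hab, vol, visit, composition, hcfg, cov):
        biomass = float(rng.lognormal(*hcfg.biomass_log))
        depth = max(200, int(round(rng.lognormal(*hcfg.depth_log))))
        frac = config.reagent_load / (config.reagent_load + biomass) \
            if config.reagent_load > 0 else 0.0
        n_cont = rng.binomial(depth, frac)
        comp = (1 - config.cross_habitat_leak) * composition \
            + config.cross_habitat_leak * global_mean
        reads = rng.multinomial(depth - n_cont, comp)
        if n_cont > 0:
            cvec = np.zeros(n_asv)
            cvec[contam_idx] = contam_profile
            reads = reads + rng.multinomial(n_cont, cvec)
        counts[sid] = reads
        dna = config.dna_conc_scale * biomass * float(
            rng.lognormal(0.0, config.dna_conc_noise)
        ) + 0.05
        meta_rows.append({
            "sample_id": sid, "volunteer_id": vol, "visit": visit,
            "sample_type": hab, "dna_conc": round(dna, 3), **cov,
        })
        gt_biomass[sid] = biomass
        gt_contam_reads[sid] = int(n_cont)
        gt_true_comp[sid] = composition
        return biomass

    visit_labels = [str(t + 1) for t in range(config.visits)]
    visit5_vols = volunteers[: config.visit5_volunteers]
    for v in volunteers:
        visits_v = list(visit_labels) + (["5"] if v in visit5_vols else [])
        for visit in visits_v:
            visit_cov = _visit_covariates(vol_cov[v], rng)
            # habitat visit compositions (urethral habitats first: CU admixes them)
            drawn: dict[str, np.ndarray] = {}
            for hab, hcfg in config.habitats.items():
                alpha = hcfg.theta * bases[(hab, v)] + 1e-6
                drawn[hab] = _dirichlet(rng, alpha)
            if "CU" in drawn and "vswab" in config.habitats:
                mix = config.intercourse_effect * INTERCOURSE_MIX.get(
                    visit_cov["time_since_intercourse"], 0.0)
                if mix > 0:
                    drawn["CU"] = (1 - mix) * drawn["CU"] + mix * drawn.get(
                        "vswab", bases[("vswab", v)])
            habitats_now = list(config.habitats) if visit != "5" else (
                ["CU"] if "CU" in config.habitats else [])
            for hab in habitats_now:
                if (v, visit, hab) in dropouts:
                    continue
                sid = f"{v}{visit}{hab}"
                biomass = _emit_sample(sid, hab, v, visit, drawn[hab],
                                       config.habitats[hab], visit_cov)
                if hab == "CU":
                    culture_ids.append(sid)
                    culture_rows.extend(
                        _culture_detections(sid, drawn[hab], inventory,
                                            biomass, config, rng))
            if visit == "5" and "CU" in drawn:
                lam = config.urethral_admixture
                urethral = 0.5 * drawn.get("vswab", drawn["CU"]) \
                    + 0.5 * drawn.get("pswab", drawn["CU"])
                mu_comp = (1 - lam) * drawn["CU"] + lam * urethral
                sid = f"{v}5MU"
                _emit_sample(sid, "MU", v, "5", mu_comp,
                             config.habitats["CU"], visit_cov)

    # negative sampling controls: contaminants plus a trace of carried-over
    # urogenital community (cross-talk)
    for k in range(config.n_neg_controls):
        sid = f"NC{k + 1}"
        depth = max(200, int(round(rng.lognormal(np.log(8000), 0.4))))
        if config.reagent_load > 0:
            prof = _dirichlet(rng, 200.0 * contam_profile + 1e-6)
            comp = np.zeros(n_asv)
            comp[contam_idx] = prof * (1 - config.neg_control_crosstalk)
            comp = comp + config.neg_control_crosstalk * urogenital_mean
        else:  # no reagent contamination: controls carry cross-talk only
            comp = urogenital_mean.copy()
        comp = comp / comp.sum()
        counts[sid] = rng.multinomial(depth, comp)
        meta_rows.append({
            "sample_id": sid, "volunteer_id": "control", "visit": "1",
            "sample_type": "neg_control", "dna_conc": np.nan,
            "diet": None, "fluid_intake": None, "contraceptive": None,
            "cycle_week": None, "time_since_intercourse": None,
        })
        gt_biomass[sid] = 0.0
        gt_contam_reads[sid] = int(counts[sid][contam_idx].sum())

    table = FeatureTable(
        pd.DataFrame(counts, index=asv_ids),
        pd.Series(inventory["taxonomy"], index=asv_ids),
    )
    metadata = SampleMetadata(pd.DataFrame(meta_rows))
    culture = CultureTable(
        pd.DataFrame(culture_rows, columns=["sample_id", "genus", "cfu_per_ml"]),
        sample_ids=culture_ids,
    )
    tree = _simulate_tree(inventory, rng)
    gt = GroundTruth(
        contaminant_ids=list(contaminant_ids),
        volunteer_bases={f"{h}:{v}": b for (h, v), b in bases.items()},
        thetas={h: c.theta for h, c in config.habitats.items()},
        biomass=gt_biomass,
        contaminant_reads=gt_contam_reads,
        true_compositions=gt_true_comp,
    )
    return Cohort(table, metadata, tree, culture, gt, config)


# ---------------------------------------------------------------------------
# internals
# ---------------------------------------------------------------------------

def _dirichlet(rng, alpha: np.ndarray) -> np.ndarray:
    """Dirichlet draw tolerant of (structurally) zero concentrations."""
    alpha = np.asarray(alpha, dtype=float)
    out = np.zeros_like(alpha)
    pos = alpha > 0
    if not pos.any():
        raise MicrostabError("all-zero Dirichlet concentration")
    draw = rng.gamma(alpha[pos], 1.0)
    total = draw.sum()
    if total <= 0:  # extreme small-alpha underflow
        draw = np.full(pos.sum(), 1.0)
        total = draw.sum()
    out[pos] = draw / total
    return out


def _build_inventory(config: CohortConfig, rng) -> dict:
    """ASV inventory: per-habitat genus pools expanded to ASV-level Dirichlet
    weights over a shared feature index, plus contaminant ASVs."""
    genus_sets: dict[str, int] = {}
    for hab, hcfg in config.habitats.items():
        k = hcfg.asvs_per_genus
        for genus in hcfg.pool:
            key = f"{hab if hab == 'fecal' else 'uro'}|{genus}"
            genus_sets[key] = max(genus_sets.get(key, 0), k)
    asv_ids, taxonomy, genus_of = [], [], []
    asv_index: dict[str, list[int]] = {}
    counter = 0
    for key, k in genus_sets.items():
        _, genus = key.split("|", 1)
        idxs = []
        for j in range(k):
            fid = f"asv{counter:04d}"
            counter += 1
            asv_ids.append(fid)
            taxonomy.append(f"d__Bacteria;g__{genus}")
            genus_of.append(genus)
            idxs.append(len(asv_ids) - 1)
        asv_index[key] = idxs
    contaminant_ids = []
    for i in range(config.n_contaminant_asvs):
        genus = CONTAMINANT_GENERA[i % len(CONTAMINANT_GENERA)]
        fid = f"contam{i:02d}"
        asv_ids.append(fid)
        taxonomy.append(f"d__Bacteria;g__{genus}")
        genus_of.append(genus)
        contaminant_ids.append(fid)

    n_asv = len(asv_ids)
    pool_alpha: dict[str, np.ndarray] = {}
    for hab, hcfg in config.habitats.items():
        alpha = np.zeros(n_asv)
        total = sum(hcfg.pool.values())
        for genus, w in hcfg.pool.items():
            key = f"{hab if hab == 'fecal' else 'uro'}|{genus}"
            idxs = asv_index[key]
            # habitat-specific split over the genus's shared ASV inventory:
            # the same ASVs recur across habitats, but e.g. a different
            # Lactobacillus ASV dominates the bladder than the vagina
            split = rng.dirichlet(np.full(len(idxs), 2.0))
            for i, j in zip(idxs, split):
                alpha[i] += (w / total) * j
        # normalize so habitat `spread` is the total Dirichlet concentration
        pool_alpha[hab] = alpha / alpha.sum()
    return {
        "asv_ids": asv_ids,
        "taxonomy": taxonomy,
        "genus_of": genus_of,
        "contaminant_ids": contaminant_ids,
        "pool_alpha": pool_alpha,
    }


def _volunteer_covariates(volunteers, rng) -> dict:
    out = {}
    for v in volunteers:
        out[v] = {
            "diet": rng.choice(DIET_LEVELS, p=DIET_PROBS),
            "fluid_intake": rng.choice(FLUID_LEVELS, p=FLUID_PROBS),
            "contraceptive": bool(rng.random() < 8 / 15),
        }
    return out


def _visit_covariates(vol_cov: dict, rng) -> dict:
    return {
        **vol_cov,
        "cycle_week": str(int(rng.integers(1, 5))),
        "time_since_intercourse": str(rng.choice(INTERCOURSE_LEVELS,
                                                 p=INTERCOURSE_PROBS)),
    }


def _culture_detections(sid, composition, inventory, biomass, config, rng):
    """Abundance-dependent Bernoulli culture detections at genus level."""
    genus_ab: dict[str, float] = {}
    for g, p in zip(inventory["genus_of"], composition):
        if p > 0:
            genus_ab[g] = genus_ab.get(g, 0.0) + float(p)
    rows = []
    for genus, p in sorted(genus_ab.items()):
        if p < 1e-6:
            continue
        logit = config.culture_logit_intercept \
            + config.culture_logit_slope * np.log10(p)
        if rng.random() < 1.0 / (1.0 + np.exp(-logit)):
            cfu = max(1.0, round(biomass * p * 1e4))
            rows.append({"sample_id": sid, "genus": genus, "cfu_per_ml": cfu})
    return rows


def _simulate_tree(inventory, rng) -> skbio.TreeNode:
    """Random bifurcating tree; same-genus ASVs coalesce first; exponential
    (unit-mean) branch lengths."""
    by_genus: dict[str, list[str]] = {}
    for fid, genus in zip(inventory["asv_ids"], inventory["genus_of"]):
        by_genus.setdefault(genus, []).append(fid)

    def _join(nodes) -> str:
        nodes = list(nodes)
        while len(nodes) > 1:
            i, j = rng.choice(len(nodes), size=2, replace=False)
            a, b = nodes[int(i)], nodes[int(j)]
            la, lb = rng.exponential(1.0), rng.exponential(1.0)
            merged = f"({a}:{la:.6f},{b}:{lb:.6f})"
            nodes = [n for k, n in enumerate(nodes) if k not in (int(i), int(j))]
            nodes.append(merged)
        return nodes[0]

    subtrees = [_join(fids) for fids in by_genus.values()]
    newick = _join(subtrees) + ";"
    return read_tree(newick, allow_missing_lengths=True)
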