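"""End-to-end orchestration: decontaminate -> rarefy -> diversity ->
stability -> variance partitioning -> concordance/overlap, with a
machine-readable report.

The pipeline is a pure function of (inputs, config, seeds); every stage
writes its table under the output directory and the report records seeds,
thresholds and versions for provenance.
"""

from __future__ import annotations

import decimal
import hashlib
import json
import logging
import warnings
from dataclasses import asdict, dataclass, field
from pathlib import Path

import numpy as np
import pandas as pd

from . import __version__
from .concordance import classify_concordance, classify_overlaps, sharing_summary
from .decontam import (call_contaminants, contaminant_dna_correlation,
                       flagged_ids, remove_contaminants)
from .diversity import (alpha_diversity_table, generalized_unifrac, jsd_matrix,
                        pcoa, rarefy)
from .errors import MicrostabError
from .io import (CultureTable, FeatureTable, SampleMetadata,
                 read_culture, read_feature_table, read_metadata, read_tree,
                 write_distance_matrix, align_table_metadata_tree)
from .stability import (compare_group_stability, intraindividual_stability,
                        paired_divergence, records_frame)
from .variance import permanova, permanova_univariate, term_screen

log = logging.getLogger("microstab.pipeline")


@dataclass
class PipelineConfig:
    # inputs: either paths ...
    table_path: str | None = None
    metadata_path: str | None = None
    tree_path: str | None = None
    culture_path: str | None = None
    # ... or in-memory objects
    table: FeatureTable | None = None
    metadata: SampleMetadata | None = None
    tree: object | None = None
    culture: CultureTable | None = None

    out_dir: str = "microstab_out"
    decontam_thresholds: dict = field(default_factory=dict)
    decontam_combine: str = "and"
    rarefaction_depth: int = 2000
    seed: int = 0
    gunifrac_alpha: float = 0.5
    visits: tuple = ("1", "2", "3", "4")
    stability_types: tuple = ("CU", "fecal")
    univariate_terms: tuple = ()
    multivariate_terms: tuple = ()
    strata_var: str = "volunteer_id"
    n_permutations: int = 999
    concordance_high_threshold: float = 0.10
    overlap_sites: tuple = ("CU", "fecal")
    overlap_ambiguity_threshold: float = 0.002

    def validate(self) -> None:
        if self.rarefaction_depth < 1:
            raise MicrostabError("rarefaction depth must be >= 1")
        for attr in ("table", "metadata"):
            if getattr(self, attr) is None and getattr(self, f"{attr}_path") is None:
                raise MicrostabError(f"pipeline config provides no {attr}")


def summarize_counts(numerator: int, denominator: int) -> str:
    """Format a count/total pair as ``"n (x.y%)"`` with half-up rounding to
    one decimal (so 9/15 -> "9 (60.0%)")."""
    if denominator == 0:
        raise MicrostabError("zero denominator")
    pct = decimal.Decimal(100 * numerator) / decimal.Decimal(denominator)
    pct = pct.quantize(decimal.Decimal("0.1"), rounding=decimal.ROUND_HALF_UP)
    return f"{numerator} ({pct}%)"


def run_pipeline(config: PipelineConfig) -> dict:
    """Execute the full analysis; returns the report dict (also written as
    ``report.json`` under ``config.out_dir``)."""
    config.validate()
    out = Path(config.out_dir)
    out.mkdir(parents=True, exist_ok=True)

    table = config.table or read_feature_table(config.table_path)
    metadata = config.metadata or read_metadata(config.metadata_path)
    tree = config.tree
    if tree is None and config.tree_path:
        tree = read_tree(config.tree_path)
    culture = config.culture
    if culture is None and config.culture_path:
        culture = read_culture(config.culture_path)

    table, metadata, tree, align_report = align_table_metadata_tree(
        table, metadata, tree)
    meta = metadata.frame
    report: dict = {
        "provenance": {
            "version": __version__,
            "seed": config.seed,
            "rarefaction_depth": config.rarefaction_depth,
            "gunifrac_alpha": config.gunifrac_alpha,
            "config_hash": hashlib.sha256(
                json.dumps({k: str(v) for k, v in asdict(config).items()
                            if not isinstance(v, (FeatureTable, SampleMetadata))},
                           sort_keys=True, default=str).encode()).hexdigest()[:16],
        },
        "alignment": align_report,
    }

    # --- decontamination ---------------------------------------------------
    has_controls = (meta["sample_type"] == "neg_control").any()
    if has_controls:
        log.info("decontam: thresholds=%s combine=%s",
                 config.decontam_thresholds or "default", config.decontam_combine)
        calls = call_contaminants(table, metadata,
                                  thresholds=config.decontam_thresholds or None,
                                  combine=config.decontam_combine)
        flagged = flagged_ids(calls)
        block = {"n_flagged": len(flagged), "flagged_features": flagged}
        if flagged:
            try:
                r, lo, hi, n = contaminant_dna_correlation(table, calls, metadata)
                block["dna_correlation"] = {"r": r, "ci": [lo, hi], "n": n}
            except MicrostabError as exc:
                block["dna_correlation"] = {"error": str(exc)}
            table, removal_report = remove_contaminants(table, calls)
            removal_report.to_csv(out / "decontam_reads.tsv", sep="\t")
        pd.DataFrame([c.__dict__ for c in calls]).to_csv(
            out / "contaminant_calls.tsv", sep="\t", index=False)
        report["decontam"] = block
    else:
        warnings.warn("no negative controls present: decontamination SKIPPED")
        report["decontam"] = {"skipped": "no negative controls"}

    # --- rarefaction ---------------------------------------------------------
    rt = rarefy(table, config.rarefaction_depth, seed=config.seed)
    report["rarefaction"] = {
        "depth": config.rarefaction_depth,
        "n_retained": len(rt.sample_ids),
        "excluded_samples": [list(x) for x in rt.excluded_samples],
    }

    # --- alpha diversity -----------------------------------------------------
    alpha = alpha_diversity_table(rt, tree)
    alpha.to_csv(out / "alpha_diversity.tsv", sep="\t")
    alpha_block = {}
    for st, grp in alpha.join(meta["sample_type"]).groupby("sample_type"):
        alpha_block[st] = {
            m: {"mean": float(grp[m].mean()), "sd": float(grp[m].std(ddof=1)),
                "n": int(len(grp))}
            for m in alpha.columns
        }
    report["alpha_diversity"] = alpha_block

    # --- beta diversity ------------------------------------------------------
    jsd_dm = jsd_matrix(rt)
    write_distance_matrix(jsd_dm, out / "jsd.tsv")
    gu_dm = None
    if tree is not None:
        gu_dm = generalized_unifrac(rt.drop_empty_features(), tree,
                                    alpha=config.gunifrac_alpha)
        write_distance_matrix(gu_dm, out / "gunifrac.tsv")
        ord_ = pcoa(gu_dm, n_axes=3)
        pd.DataFrame(ord_.coordinates, index=ord_.sample_ids,
                     columns=[f"PC{i+1}" for i in range(ord_.coordinates.shape[1])]
                     ).to_csv(out / "pcoa_gunifrac.tsv", sep="\t")

    # --- stability -----------------------------------------------------------
    type_a, type_b = config.stability_types
    try:
        rec_a = intraindividual_stability(jsd_dm, metadata, type_a, config.visits)
        rec_b = intraindividual_stability(jsd_dm, metadata, type_b, config.visits)
        comp = compare_group_stability(rec_a, rec_b)
        records_frame(rec_a + rec_b).to_csv(out / "stability_records.tsv",
                                            sep="\t", index=False)
        report["stability"] = {
            type_a: {"median": comp.median_a, "iqr": list(comp.iqr_a),
                     "range": list(comp.range_a), "n": len(rec_a)},
            type_b: {"median": comp.median_b, "iqr": list(comp.iqr_b),
                     "range": list(comp.range_b), "n": len(rec_b)},
            "mann_whitney_p": comp.test.p_value,
        }
    except MicrostabError as exc:
        report["stability"] = {"error": str(exc)}

    # paired CU/MU divergence when MU samples exist
    if (meta["sample_type"] == "MU").any():
        pairs = paired_divergence(jsd_dm, metadata)
        report["paired_divergence"] = {
            "n_pairs": len(pairs),
            "n_exceeding_reference": int(sum(p.exceeds_reference_max for p in pairs)),
        }

    # --- variance partitioning ------------------------------------------------
    beta_dm = gu_dm if gu_dm is not None else jsd_dm
    cu_ids = [s for s in beta_dm.sample_ids
              if meta.loc[s, "sample_type"] == type_a
              and meta.loc[s, "visit"] in set(map(str, config.visits))]
    perm_block = {}
    if len(cu_ids) >= 3:
        sub_dm = beta_dm.subset(cu_ids)
        if config.univariate_terms:
            uni = permanova_univariate(sub_dm, metadata,
                                       list(config.univariate_terms),
                                       n_perm=config.n_permutations,
                                       seed=config.seed)
            perm_block["univariate"] = {
                t: {"r_squared": r.r_squared, "p": r.p_value}
                for t, r in uni.items()
            }
        if config.multivariate_terms:
            retained, excluded = term_screen(metadata,
                                             list(config.multivariate_terms))
            if retained:
                res = permanova(sub_dm, metadata,
                                retained + ["volunteer_id"],
                                n_perm=config.n_permutations, seed=config.seed)
                perm_block["multivariate"] = {
                    r.term: {"r_squared": r.r_squared, "p": r.p_value}
                    for r in res
                }
                strat = permanova(sub_dm, metadata, retained,
                                  n_perm=config.n_permutations,
                                  seed=config.seed, strata=config.strata_var)
                perm_block["stratified"] = {
                    r.term: {"r_squared": r.r_squared, "p": r.p_value}
                    for r in strat
                }
            perm_block["terms_excluded_as_id_aliases"] = excluded
    report["permanova"] = perm_block

    # --- concordance & overlap -------------------------------------------------
    if culture is not None:
        records, summary = classify_concordance(
            culture, rt, high_threshold=config.concordance_high_threshold)
        pd.DataFrame([{
            "sample_id": r.sample_id,
            "cultured_genera": ";".join(r.cultured_genera),
            "class": r.concordance.value,
        } for r in records]).to_csv(out / "concordance.tsv", sep="\t", index=False)
        report["concordance"] = summary
    overlaps = classify_overlaps(rt, metadata, tuple(config.overlap_sites),
                                 config.overlap_ambiguity_threshold)
    share = sharing_summary(overlaps)
    share.to_csv(out / "overlap_sharing.tsv", sep="\t", index=False)
    report["overlap"] = {
        "site_pair": list(config.overlap_sites),
        "n_records": len(overlaps),
        "n_ambiguous": int(sum(r.overlap.value == "AMBIGUOUS" for r in overlaps)),
        "n_features": int(share.shape[0]),
    }

    with open(out / "report.json", "wt") as fh:
        json.dump(report, fh, indent=2, default=_jsonable)
    return report


def _jsonable(obj):
    if isinstance(obj, (np.integer,)):
        return int(obj)
    if isinstance(obj, (np.floating,)):
        return float(obj)
    if isinstance(obj, np.ndarray):
        return obj.tolist()
    return str(obj)
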