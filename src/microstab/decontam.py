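"""Negative-control based contaminant ASV removal for low-biomass samples.

Sterile-saline sampling controls run through the full collection and
processing pipeline pick up reagent/procedure contaminants.  An ASV is
flagged as a contaminant when, across the negative sampling controls, it
shows (all three by default, AND-combined):

* mean relative abundance > 0.5%,
* presence in every negative sampling control,
* relative abundance > 5% in at least one control.

Relative abundances for the criteria are computed within negative-control
samples from raw (pre-rarefaction) counts; "presence" means >= 1 read.
Flagged ASVs are removed from all samples, controls included.  The summed
relative abundance of flagged ASVs in real samples is expected to
anticorrelate with post-extraction DNA concentration (a biomass proxy) when
contamination is reagent-borne.
"""

from __future__ import annotations

import warnings
from dataclasses import dataclass

import numpy as np
import pandas as pd

from .errors import MicrostabError
from .io import FeatureTable, SampleMetadata
from .stats import pearson_fisher_ci

DEFAULT_THRESHOLDS = {"mean": 0.005, "prevalence": 1.0, "max_single": 0.05}


@dataclass
class ContaminantCall:
    feature_id: str
    mean_abund_neg: float
    prevalence_neg: float
    max_abund_neg: float
    flagged: bool


def call_contaminants(
    table: FeatureTable,
    metadata: SampleMetadata,
    thresholds: dict | None = None,
    combine: str = "and",
    criteria: tuple[str, ...] = ("mean", "prevalence", "max_single"),
) -> list[ContaminantCall]:
    """Score every feature seen in any negative sampling control.

    ``thresholds`` overrides any of ``mean`` (strict >), ``prevalence``
    (>=, fraction of controls containing the feature) and ``max_single``
    (strict >).  ``combine`` is ``"and"`` (default) or ``"or"`` over the
    criteria named in ``criteria``.  Controls with zero total reads are
    excluded with a warning; zero usable controls is an error.
    """
    thr = dict(DEFAULT_THRESHOLDS)
    if thresholds:
        unknown = set(thresholds) - set(DEFAULT_THRESHOLDS)
        if unknown:
            raise ValueError(f"unknown threshold(s): {sorted(unknown)}")
        thr.update(thresholds)
    if combine not in ("and", "or"):
        raise ValueError("combine must be 'and' or 'or'")
    unknown = set(criteria) - set(DEFAULT_THRESHOLDS)
    if unknown:
        raise ValueError(f"unknown criteria: {sorted(unknown)}")

    meta = metadata.frame
    neg_ids = [s for s in table.sample_ids
               if s in meta.index and meta.loc[s, "sample_type"] == "neg_control"]
    if not neg_ids:
        raise MicrostabError("no negative sampling controls in the table")
    neg = table.counts[neg_ids]
    totals = neg.sum(axis=0)
    empty = totals[totals == 0].index.tolist()
    if empty:
        warnings.warn(f"negative control(s) with zero reads excluded: {empty}")
        neg = neg.drop(columns=empty)
    if neg.shape[1] == 0:
        raise MicrostabError("all negative controls have zero reads")

    rel = neg / neg.sum(axis=0)
    present = (neg > 0)
    calls: list[ContaminantCall] = []
    for fid in table.feature_ids:
        if not present.loc[fid].any():
            continue
        mean_ab = float(rel.loc[fid].mean())
        prev = float(present.loc[fid].mean())
        max_ab = float(rel.loc[fid].max())
        checks = {
            "mean": mean_ab > thr["mean"],
            "prevalence": prev >= thr["prevalence"],
            "max_single": max_ab > thr["max_single"],
        }
        enabled = [checks[c] for c in criteria]
        flagged = all(enabled) if combine == "and" else any(enabled)
        calls.append(ContaminantCall(fid, mean_ab, prev, max_ab, flagged))
    return calls


def flagged_ids(calls: list[ContaminantCall]) -> list[str]:
    return [c.feature_id for c in calls if c.flagged]


def remove_contaminants(
    table: FeatureTable, calls: list[ContaminantCall]
) -> tuple[FeatureTable, pd.DataFrame]:
    """Drop flagged features from every sample (controls included).

    Returns the filtered table and a per-sample read-count report with
    ``reads_before``, ``reads_after`` and ``reads_removed`` columns.
    """
    known = set(table.feature_ids)
    for call in calls:
        if call.feature_id not in known:
            raise MicrostabError(f"call references unknown feature {call.feature_id!r}")
    drop = set(flagged_ids(calls))
    keep = [f for f in table.feature_ids if f not in drop]
    if not keep:
        raise MicrostabError("empty table after decontamination")
    before = table.sample_totals()
    filtered = table.filter_features(keep)
    after = filtered.sample_totals()
    report = pd.DataFrame({
        "reads_before": before,
        "reads_after": after,
        "reads_removed": before - after,
    }).rename_axis("sample_id")
    return filtered, report


def contaminant_dna_correlation(
    table: FeatureTable,
    calls: list[ContaminantCall],
    metadata: SampleMetadata,
    sample_types: tuple[str, ...] | None = None,
) -> tuple[float, float, float, int]:
    """Pearson r (with Fisher-z 95% CI) between the per-sample summed
    relative abundance of flagged contaminants and DNA concentration.

    Restricted to non-control samples with a recorded ``dna_conc``
    (optionally further restricted to ``sample_types``, e.g. ``("CU",)``).
    Returns ``(r, ci_low, ci_high, n)``.
    """
    drop = flagged_ids(calls)
    if not drop:
        raise MicrostabError("no flagged contaminants; correlation undefined")
    meta = metadata.frame
    if "dna_conc" not in meta.columns:
        raise MicrostabError("metadata has no dna_conc column")
    wanted = set(sample_types) if sample_types else set()
    ids = []
    for s in table.sample_ids:
        if s not in meta.index:
            continue
        row = meta.loc[s]
        if row["sample_type"] == "neg_control":
            continue
        if wanted and row["sample_type"] not in wanted:
            continue
        if pd.isna(row["dna_conc"]):
            continue
        ids.append(s)
    if len(ids) < 4:
        raise MicrostabError("need >= 4 non-control samples with dna_conc")
    rel = table.relative_abundance()[ids]
    contam_frac = rel.loc[drop].sum(axis=0).to_numpy()
    conc = meta.loc[ids, "dna_conc"].to_numpy(float)
    if np.ptp(contam_frac) == 0:
        raise MicrostabError("contaminant abundance is constant; correlation undefined")
    r, lo, hi = pearson_fisher_ci(contam_frac, conc)
    return r, lo, hi, len(ids)
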