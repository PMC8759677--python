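"""Culture-vs-sequencing concordance and cross-habitat ASV overlap.

Concordance: each cultured sample is classed by whether every cultured genus
also appears in its sequencing profile — ``ALL_CONFIRMED`` (every cultured
genus at relative abundance > 0), ``ALL_CONFIRMED_HIGH`` (additionally all
above a high-abundance threshold, 10% by default), ``PARTIAL`` (at least one
cultured genus absent), ``CULTURE_NEGATIVE`` (no growth).  Matching is
case-insensitive at genus level with a small synonym map (e.g. the 16S taxon
"Escherichia-Shigella" matches cultured "Escherichia").

Overlap: an ASV found in two habitats of the same volunteer is ``CONFIDENT``
when both relative abundances reach 0.2%, ``AMBIGUOUS`` when either is below
that — too close to the index-hopping/contamination floor to trust.
"""

from __future__ import annotations

import itertools
import warnings
from dataclasses import dataclass
from enum import Enum

import pandas as pd

from .io import CultureTable, FeatureTable, SampleMetadata

#: sequencing-taxon aliases for cultured genera (extensible via
#: ``extra_synonyms``); keys and values are lowercase genus names
GENUS_SYNONYMS = {
    "escherichia": ("escherichia-shigella", "escherichia/shigella"),
    "shigella": ("escherichia-shigella", "escherichia/shigella"),
    "clostridium": ("clostridium sensu stricto 1",),
}


class ConcordanceClass(str, Enum):
    ALL_CONFIRMED = "ALL_CONFIRMED"
    ALL_CONFIRMED_HIGH = "ALL_CONFIRMED_HIGH"
    PARTIAL = "PARTIAL"
    CULTURE_NEGATIVE = "CULTURE_NEGATIVE"


@dataclass
class ConcordanceRecord:
    sample_id: str
    cultured_genera: tuple[str, ...]
    genus_abundances: dict  # cultured genus -> sequencing relative abundance
    concordance: ConcordanceClass


def classify_concordance(
    culture: CultureTable,
    table: FeatureTable,
    high_threshold: float = 0.10,
    detection_floor: float = 0.0,
    extra_synonyms: dict | None = None,
) -> tuple[list[ConcordanceRecord], dict]:
    """Classify every cultured sample against its sequencing profile.

    ``detection_floor`` is the relative abundance a genus must strictly
    exceed to count as sequenced (0 = any read).  Returns the records plus a
    summary dict of class counts and fractions.  Cultured samples absent
    from the sequencing table are skipped with a warning.
    """
    synonyms = {k: tuple(v) for k, v in GENUS_SYNONYMS.items()}
    if extra_synonyms:
        for k, v in extra_synonyms.items():
            base = synonyms.get(k.lower(), ())
            synonyms[k.lower()] = base + tuple(x.lower() for x in v)

    genus_rel = table.collapse_genus()
    totals = table.counts.sum(axis=0).replace(0, 1)
    genus_rel = genus_rel / totals
    genus_rel.index = genus_rel.index.str.lower()
    available = set(table.sample_ids)

    records: list[ConcordanceRecord] = []
    skipped = []
    for sid in culture.sample_ids:
        if sid not in available:
            skipped.append(sid)
            continue
        detections = culture.detections(sid)
        genera = tuple(sorted(detections))
        if not genera:
            records.append(ConcordanceRecord(sid, (), {}, ConcordanceClass.CULTURE_NEGATIVE))
            continue
        abund = {}
        for gname in genera:
            keys = (gname.lower(),) + synonyms.get(gname.lower(), ())
            vals = [float(genus_rel.loc[k, sid]) for k in keys if k in genus_rel.index]
            abund[gname] = max(vals) if vals else 0.0
        if all(a > detection_floor for a in abund.values()):
            if all(a > high_threshold for a in abund.values()):
                cls = ConcordanceClass.ALL_CONFIRMED_HIGH
            else:
                cls = ConcordanceClass.ALL_CONFIRMED
        else:
            cls = ConcordanceClass.PARTIAL
        records.append(ConcordanceRecord(sid, genera, abund, cls))
    if skipped:
        warnings.warn(f"cultured sample(s) missing from sequencing table: {skipped}")
    summary = summarize_concordance(records)
    return records, summary


def summarize_concordance(records: list[ConcordanceRecord]) -> dict:
    n = len(records)
    counts = {c.value: 0 for c in ConcordanceClass}
    for r in records:
        counts[r.concordance.value] += 1
    # samples where every cultured genus was sequenced, at any abundance
    all_conf = counts["ALL_CONFIRMED"] + counts["ALL_CONFIRMED_HIGH"]
    return {
        "n": n,
        "counts": counts,
        "frac_all_confirmed": all_conf / n if n else float("nan"),
        "frac_all_confirmed_high": counts["ALL_CONFIRMED_HIGH"] / n if n else float("nan"),
        "frac_partial": counts["PARTIAL"] / n if n else float("nan"),
        "frac_culture_negative": counts["CULTURE_NEGATIVE"] / n if n else float("nan"),
    }


class OverlapClass(str, Enum):
    CONFIDENT = "CONFIDENT"
    AMBIGUOUS = "AMBIGUOUS"


@dataclass
class OverlapRecord:
    feature_id: str
    volunteer_id: str
    site_a: str  # sample ID at the first site
    site_b: str
    type_a: str
    type_b: str
    abund_a: float
    abund_b: float
    overlap: OverlapClass


def classify_overlaps(
    table: FeatureTable,
    metadata: SampleMetadata,
    site_pair: tuple[str, str],
    ambiguity_threshold: float = 0.002,
) -> list[OverlapRecord]:
    """Within-volunteer ASV overlap between two habitats.

    One record per (feature, volunteer, sample-at-site-A, sample-at-site-B)
    combination with nonzero relative abundance at both samples.
    ``AMBIGUOUS`` iff the smaller of the two abundances is below the
    threshold (0.2% by default).  Symmetric in the site pair.  Volunteers
    lacking samples at either site contribute nothing.
    """
    type_a, type_b = site_pair
    rel = table.relative_abundance()
    meta = metadata.frame
    have = set(table.sample_ids)
    out: list[OverlapRecord] = []
    for vol, grp in meta.groupby("volunteer_id"):
        ids_a = [s for s in grp.loc[grp["sample_type"] == type_a, "sample_id"] if s in have]
        ids_b = [s for s in grp.loc[grp["sample_type"] == type_b, "sample_id"] if s in have]
        if not ids_a or not ids_b:
            continue
        for sa, sb in itertools.product(ids_a, ids_b):
            cols = rel[[sa, sb]]
            both = cols[(cols[sa] > 0) & (cols[sb] > 0)]
            for fid, row in both.iterrows():
                a, b = float(row[sa]), float(row[sb])
                cls = (OverlapClass.AMBIGUOUS if min(a, b) < ambiguity_threshold
                       else OverlapClass.CONFIDENT)
                out.append(OverlapRecord(fid, vol, sa, sb, type_a, type_b, a, b, cls))
    return out


def sharing_summary(records: list[OverlapRecord],
                    confident_only: bool = False) -> pd.DataFrame:
    """Cross-volunteer sharing per feature: number of distinct volunteers
    and samples in which the feature overlaps, sorted by volunteer reach."""
    rows = [r for r in records
            if not confident_only or r.overlap is OverlapClass.CONFIDENT]
    if not rows:
        return pd.DataFrame(columns=["feature_id", "n_volunteers", "n_samples"])
    df = pd.DataFrame([r.__dict__ for r in rows])
    agg = df.groupby("feature_id").agg(
        n_volunteers=("volunteer_id", "nunique"),
        n_samples=("site_a", lambda s: len(set(s) | set(df.loc[s.index, "site_b"]))),
    )
    return (agg.sort_values(["n_volunteers", "n_samples"], ascending=False)
            .reset_index())
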