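"""Intraindividual community stability from a Jensen-Shannon distance matrix.

The stability statistic: for each sample in a group (same sample type,
regular visits, same volunteer), the median JSD between that sample and all
other samples from the same volunteer in the group.  Lower medians mean a
more stable community.  Group-level comparisons (e.g. catheter urine vs
fecal) use the Mann-Whitney U test on the per-sample records, with a
per-volunteer-median variant available.
"""

from __future__ import annotations

import warnings
from dataclasses import dataclass

import numpy as np
import pandas as pd

from .errors import MicrostabError
from .io import DistanceMatrix, SampleMetadata
from .stats import TestResult, mann_whitney


@dataclass
class StabilityRecord:
    sample_id: str
    volunteer_id: str
    group: str
    median_intra_jsd: float
    n_comparisons: int


@dataclass
class GroupComparison:
    median_a: float
    iqr_a: tuple[float, float]
    range_a: tuple[float, float]
    median_b: float
    iqr_b: tuple[float, float]
    range_b: tuple[float, float]
    test: TestResult


def intraindividual_stability(
    dm_jsd: DistanceMatrix,
    metadata: SampleMetadata,
    sample_type: str,
    visits=("1", "2", "3", "4"),
    group_label: str | None = None,
) -> list[StabilityRecord]:
    """Per-sample median JSD to the other same-volunteer samples in a group.

    The group is one sample type restricted to ``visits`` (event visits such
    as UTI1/UTI2 are excluded unless listed).  Volunteers contributing fewer
    than two group samples are skipped with a warning.
    """
    sel = metadata.select(sample_type=sample_type, visits=visits)
    ids = [s for s in sel.sample_ids if s in set(dm_jsd.sample_ids)]
    if not ids:
        raise MicrostabError(
            f"no samples for group {sample_type} visits {list(visits)}"
        )
    label = group_label or f"{sample_type}-visits-{'-'.join(map(str, visits))}"
    meta = sel.frame
    records: list[StabilityRecord] = []
    skipped = []
    for vol, grp in meta.loc[[s for s in ids]].groupby("volunteer_id"):
        samples = list(grp["sample_id"])
        if len(samples) < 2:
            skipped.append(vol)
            continue
        sub = dm_jsd.subset(samples)
        for i, s in enumerate(samples):
            others = np.delete(sub.data[i], i)
            records.append(StabilityRecord(
                s, vol, label, float(np.median(others)), len(others)
            ))
    if skipped:
        warnings.warn(
            f"volunteer(s) with <2 samples in group {label} skipped: {skipped}"
        )
    if not records:
        raise MicrostabError(f"no volunteer has >= 2 samples in group {label}")
    return records


def records_frame(records: list[StabilityRecord]) -> pd.DataFrame:
    return pd.DataFrame([r.__dict__ for r in records])


def per_volunteer_medians(records: list[StabilityRecord]) -> pd.Series:
    df = records_frame(records)
    return df.groupby("volunteer_id")["median_intra_jsd"].median()


def compare_group_stability(
    records_a: list[StabilityRecord],
    records_b: list[StabilityRecord],
    per_volunteer: bool = False,
) -> GroupComparison:
    """Compare two groups' stability values (medians, IQRs, ranges,
    two-sided Mann-Whitney p).

    ``per_volunteer=True`` collapses each group to one median per volunteer
    before testing; the default tests the per-sample records.
    """
    if per_volunteer:
        a = per_volunteer_medians(records_a).to_numpy()
        b = per_volunteer_medians(records_b).to_numpy()
    else:
        a = np.array([r.median_intra_jsd for r in records_a])
        b = np.array([r.median_intra_jsd for r in records_b])
    if a.size < 2 or b.size < 2:
        raise MicrostabError("need >= 2 stability values per group")
    if np.ptp(a) == 0 and np.ptp(b) == 0 and a[0] == b[0]:
        warnings.warn("all stability values identical; p computed with tie correction")
    test = mann_whitney(a, b)
    q = lambda v: (float(np.percentile(v, 25)), float(np.percentile(v, 75)))
    return GroupComparison(
        float(np.median(a)), q(a), (float(a.min()), float(a.max())),
        float(np.median(b)), q(b), (float(b.min()), float(b.max())),
        test,
    )


@dataclass
class PairedDivergence:
    volunteer_id: str
    pair: tuple[str, str]
    jsd_pair: float
    reference_jsds: list[float]
    exceeds_reference_max: bool


def paired_divergence(
    dm_jsd: DistanceMatrix,
    metadata: SampleMetadata,
    pair_types: tuple[str, str] = ("CU", "MU"),
    pair_visit: str = "5",
    reference_type: str = "CU",
    reference_visits=("1", "2", "3", "4"),
) -> list[PairedDivergence]:
    """Per volunteer: JSD between a same-visit sample pair (e.g. CU5 vs MU5)
    versus the pairwise JSDs among a longitudinal reference set (CU 1-4).

    Volunteers missing either pair member or with <2 reference samples are
    skipped with a warning.
    """
    meta = metadata.frame
    have = set(dm_jsd.sample_ids)
    out: list[PairedDivergence] = []
    skipped = []
    for vol, grp in meta.groupby("volunteer_id"):
        pair_ids = []
        for st in pair_types:
            match = grp[(grp["sample_type"] == st) & (grp["visit"] == str(pair_visit))]
            match = match[match["sample_id"].isin(have)]
            if len(match) != 1:
                pair_ids = []
                break
            pair_ids.append(match["sample_id"].iloc[0])
        refs = grp[(grp["sample_type"] == reference_type)
                   & grp["visit"].isin({str(v) for v in reference_visits})]
        ref_ids = [s for s in refs["sample_id"] if s in have]
        if not pair_ids or len(ref_ids) < 2:
            skipped.append(vol)
            continue
        jp = dm_jsd[pair_ids[0], pair_ids[1]]
        sub = dm_jsd.subset(ref_ids)
        iu = np.triu_indices(len(ref_ids), k=1)
        ref_vals = [float(v) for v in sub.data[iu]]
        out.append(PairedDivergence(
            vol, (pair_ids[0], pair_ids[1]), float(jp), ref_vals,
            jp > max(ref_vals),
        ))
    if skipped:
        warnings.warn(f"volunteer(s) without a usable pair skipped: {skipped}")
    return out
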