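"""Core data types and readers/writers for the standard plain-text formats.

The central object is the :class:`FeatureTable` (ASV x sample raw counts with
per-feature taxonomy).  Sample covariates live in :class:`SampleMetadata`,
pairwise dissimilarities in :class:`DistanceMatrix`, culture detections in
:class:`CultureTable`.  Phylogenies are plain ``skbio.TreeNode`` objects
(rooted, branch-length-bearing, leaves labelled by feature IDs).

All on-disk formats are tab-separated UTF-8 text:

* feature table: features in rows, first column ``#OTU ID`` or ``feature_id``,
  one column per sample, optional final ``taxonomy`` column;
* tree: Newick with branch lengths;
* metadata: one row per sample, required columns ``sample_id``,
  ``volunteer_id``, ``visit``, ``sample_type``;
* culture: long format ``sample_id, genus, cfu_per_ml``;
* distance matrix: square TSV with matching row/column headers.
"""

from __future__ import annotations

import io as _io
from dataclasses import dataclass, field

import numpy as np
import pandas as pd
import skbio

from .errors import ParseError, ValidationError

SAMPLE_TYPES = ("CU", "MU", "vswab", "pswab", "fecal", "neg_control")

#: Visits regarded as the regular longitudinal series; event-driven visits
#: (e.g. UTI1/UTI2) are carried in metadata but excluded by default filters.
REGULAR_VISITS = ("1", "2", "3", "4", "5")

FLUID_INTAKE_LEVELS = ("<1.5", "1.5-3", ">3")
INTERCOURSE_LEVELS = ("<24h", "24-96h", ">96h-1wk", ">1wk")

_OPTIONAL_METADATA_COLS = (
    "dna_conc",
    "diet",
    "fluid_intake",
    "contraceptive",
    "cycle_week",
    "time_since_intercourse",
)


# ---------------------------------------------------------------------------
# FeatureTable
# ---------------------------------------------------------------------------

@dataclass
class FeatureTable:
    """ASV x sample raw-count matrix with per-feature taxonomy.

    Parameters
    ----------
    counts
        Integer DataFrame, features in rows (index = feature IDs), samples in
        columns.
    taxonomy
        Per-feature lineage string indexed like ``counts``; semicolon-
        separated ranks with ``g__`` style prefixes are understood, a bare
        genus name is accepted, and ``"unclassified"`` marks absent
        annotation.
    """

    counts: pd.DataFrame
    taxonomy: pd.Series

    def __post_init__(self) -> None:
        self.validate()

    # -- invariants --------------------------------------------------------
    def validate(self) -> None:
        c = self.counts
        if c.index.has_duplicates:
            dups = c.index[c.index.duplicated()].unique().tolist()
            raise ValidationError(f"duplicate feature IDs: {dups}")
        if c.columns.has_duplicates:
            dups = c.columns[c.columns.duplicated()].unique().tolist()
            raise ValidationError(f"duplicate sample IDs: {dups}")
        arr = c.to_numpy()
        if not np.issubdtype(arr.dtype, np.number):
            raise ValidationError("counts must be numeric")
        if np.any(arr < 0):
            raise ValidationError("counts must be non-negative")
        if not np.allclose(arr, np.round(arr)):
            raise ValidationError("counts must be integral")
        self.counts = c.astype(np.int64)
        self.taxonomy = self.taxonomy.reindex(c.index).fillna("unclassified")

    # -- accessors ---------------------------------------------------------
    @property
    def feature_ids(self) -> list[str]:
        return list(self.counts.index)

    @property
    def sample_ids(self) -> list[str]:
        return list(self.counts.columns)

    @property
    def shape(self) -> tuple[int, int]:
        return self.counts.shape

    def sample_totals(self) -> pd.Series:
        return self.counts.sum(axis=0)

    def relative_abundance(self) -> pd.DataFrame:
        """Per-sample relative abundances; zero-total samples give zeros."""
        totals = self.counts.sum(axis=0)
        safe = totals.replace(0, 1)
        return self.counts / safe

    def genus(self) -> pd.Series:
        """Genus-level label per feature extracted from the lineage string."""
        return self.taxonomy.map(extract_genus)

    # -- transforms --------------------------------------------------------
    def filter_features(self, keep: list[str]) -> "FeatureTable":
        keep = [f for f in self.feature_ids if f in set(keep)]
        return FeatureTable(self.counts.loc[keep].copy(), self.taxonomy.loc[keep].copy())

    def filter_samples(self, keep: list[str]) -> "FeatureTable":
        keep = [s for s in self.sample_ids if s in set(keep)]
        return FeatureTable(self.counts[keep].copy(), self.taxonomy.copy())

    def drop_empty_features(self) -> "FeatureTable":
        nz = self.counts.sum(axis=1) > 0
        return FeatureTable(self.counts.loc[nz].copy(), self.taxonomy.loc[nz].copy())

    def collapse_genus(self) -> pd.DataFrame:
        """Genus x sample count matrix (features summed by genus label)."""
        return self.counts.groupby(self.genus()).sum()

    def __eq__(self, other: object) -> bool:
        if not isinstance(other, FeatureTable):
            return NotImplemented
        return (
            self.counts.equals(other.counts)
            and list(self.taxonomy) == list(other.taxonomy)
            and list(self.taxonomy.index) == list(other.taxonomy.index)
        )


def extract_genus(lineage: str) -> str:
    """Extract a genus label from a SILVA-style lineage string.

    ``"d__Bacteria;...;g__Lactobacillus;s__iners"`` -> ``"Lactobacillus"``.
    A bare single token without rank prefixes is taken as the genus itself.
    Returns ``"unclassified"`` when no genus-rank token is present.
    """
    if lineage is None:
        return "unclassified"
    lineage = str(lineage).strip()
    if not lineage or lineage.lower() == "unclassified":
        return "unclassified"
    tokens = [t.strip() for t in lineage.split(";") if t.strip()]
    genus = ""
    has_prefix = False
    for tok in tokens:
        if "__" in tok:
            has_prefix = True
            rank, _, name = tok.partition("__")
            if rank.strip().lower() == "g" and name.strip():
                genus = name.strip()
    if genus:
        return genus
    if not has_prefix and len(tokens) == 1:
        return tokens[0]
    return "unclassified"


def read_feature_table(path, format: str = "tsv") -> FeatureTable:
    """Read a feature table (QIIME-style TSV: features in rows).

    The first column must be named ``#OTU ID`` or ``feature_id``; an optional
    final ``taxonomy`` column carries lineages.
    """
    if format.lower() != "tsv":
        raise ValueError(f"unsupported feature-table format: {format!r} (TSV only)")
    with open(path, "rt", encoding="utf-8") as fh:
        header = fh.readline().rstrip("\n")
    cols = header.split("\t")
    if not cols or cols[0] not in ("#OTU ID", "feature_id"):
        raise ParseError(
            f"malformed feature-table header (expected '#OTU ID' or 'feature_id' "
            f"as first column): {header!r}"
        )
    df = pd.read_csv(path, sep="\t", dtype={cols[0]: str})
    df = df.set_index(cols[0])
    df.index.name = "feature_id"
    if "taxonomy" in df.columns:
        taxonomy = df["taxonomy"].astype(str)
        df = df.drop(columns=["taxonomy"])
    else:
        taxonomy = pd.Series("unclassified", index=df.index)
    for col in df.columns:
        vals = pd.to_numeric(df[col], errors="coerce")
        if vals.isna().any():
            bad = df[col][vals.isna()].index[0]
            raise ValidationError(f"non-numeric count for feature {bad!r}, sample {col!r}")
        df[col] = vals
    return FeatureTable(df, taxonomy)


def write_feature_table(table: FeatureTable, path) -> None:
    out = table.counts.copy()
    out.insert(len(out.columns), "taxonomy", table.taxonomy)
    out.index.name = "#OTU ID"
    out.to_csv(path, sep="\t")


# ---------------------------------------------------------------------------
# SampleMetadata
# ---------------------------------------------------------------------------

@dataclass
class SampleMetadata:
    """Per-sample covariates: volunteer, visit, sample type, DNA
    concentration and lifestyle variables.

    Required columns: ``sample_id`` (unique), ``volunteer_id``, ``visit``,
    ``sample_type`` (one of ``CU, MU, vswab, pswab, fecal, neg_control``).
    Optional columns (missing values allowed, dropped per-analysis):
    ``dna_conc`` (ng/ul), ``diet``, ``fluid_intake``, ``contraceptive``,
    ``cycle_week``, ``time_since_intercourse``.
    """

    frame: pd.DataFrame

    def __post_init__(self) -> None:
        self.validate()

    def validate(self) -> None:
        df = self.frame
        for col in ("sample_id", "volunteer_id", "visit", "sample_type"):
            if col not in df.columns:
                raise ValidationError(f"metadata missing required column {col!r}")
        if df["sample_id"].duplicated().any():
            dups = df.loc[df["sample_id"].duplicated(), "sample_id"].tolist()
            raise ValidationError(f"duplicate sample IDs in metadata: {dups}")
        bad = set(df["sample_type"]) - set(SAMPLE_TYPES)
        if bad:
            raise ValidationError(
                f"unknown sample_type level(s) {sorted(bad)}; allowed: {SAMPLE_TYPES}"
            )
        if "dna_conc" in df.columns:
            conc = pd.to_numeric(df["dna_conc"], errors="coerce")
            if (conc.dropna() < 0).any():
                raise ValidationError("dna_conc must be non-negative")
            df = df.assign(dna_conc=conc)
        df = df.assign(
            sample_id=df["sample_id"].astype(str),
            volunteer_id=df["volunteer_id"].astype(str),
            visit=df["visit"].astype(str),
        )
        self.frame = df.set_index(df["sample_id"].rename(None), drop=False)

    @property
    def sample_ids(self) -> list[str]:
        return list(self.frame["sample_id"])

    def subset(self, sample_ids) -> "SampleMetadata":
        keep = [s for s in self.frame.index if s in set(sample_ids)]
        return SampleMetadata(self.frame.loc[keep].reset_index(drop=True))

    def select(
        self,
        sample_type: str | None = None,
        visits=None,
        volunteers=None,
    ) -> "SampleMetadata":
        """Filter by sample type / visit labels / volunteers.

        ``visits`` accepts strings (``["1", "2"]``) or ints; event visits
        such as ``UTI1`` are excluded unless listed explicitly.
        """
        df = self.frame
        if sample_type is not None:
            df = df[df["sample_type"] == sample_type]
        if visits is not None:
            wanted = {str(v) for v in visits}
            df = df[df["visit"].isin(wanted)]
        if volunteers is not None:
            df = df[df["volunteer_id"].isin(set(volunteers))]
        return SampleMetadata(df.reset_index(drop=True))

    def __eq__(self, other: object) -> bool:
        if not isinstance(other, SampleMetadata):
            return NotImplemented
        return self.frame.reset_index(drop=True).equals(other.frame.reset_index(drop=True))


def read_metadata(path) -> SampleMetadata:
    df = pd.read_csv(path, sep="\t", dtype=str)
    if "dna_conc" in df.columns:
        df["dna_conc"] = pd.to_numeric(df["dna_conc"], errors="coerce")
    if "contraceptive" in df.columns:
        df["contraceptive"] = df["contraceptive"].map(
            {"True": True, "False": False, "true": True, "false": False, "1": True, "0": False}
        )
    return SampleMetadata(df)


def write_metadata(metadata: SampleMetadata, path) -> None:
    metadata.frame.to_csv(path, sep="\t", index=False)


# ---------------------------------------------------------------------------
# Phylogenetic tree
# ---------------------------------------------------------------------------

def read_tree(path_or_str, allow_missing_lengths: bool = False) -> skbio.TreeNode:
    """Read a rooted Newick tree with branch lengths.

    Missing branch lengths are rejected by default (``allow_missing_lengths``
    defaults them to 0 instead).  Duplicate leaf labels are rejected.
    """
    try:
        if isinstance(path_or_str, str) and path_or_str.lstrip().startswith("("):
            tree = skbio.TreeNode.read(_io.StringIO(path_or_str))
        else:
            tree = skbio.TreeNode.read(str(path_or_str))
    except Exception as exc:  # skbio raises its own parse errors
        raise ParseError(f"could not parse Newick tree: {exc}") from exc
    names = [t.name for t in tree.tips()]
    if len(names) != len(set(names)):
        raise ValidationError("duplicate leaf labels in tree")
    for node in tree.traverse(include_self=False):
        if node.length is None:
            if allow_missing_lengths:
                node.length = 0.0
            else:
                raise ValidationError(
                    f"branch without length at node {node.name!r}; "
                    "pass allow_missing_lengths=True to default to 0"
                )
        elif node.length < 0:
            raise ValidationError("negative branch length")
    return tree


def write_tree(tree: skbio.TreeNode, path) -> None:
    tree.write(str(path))


# ---------------------------------------------------------------------------
# Culture table
# ---------------------------------------------------------------------------

@dataclass
class CultureTable:
    """Expanded-culture detections: one row per (sample, genus) with CFU/ml.

    A sample present in ``sample_ids`` but with no rows is culture-negative
    (no growth).
    """

    frame: pd.DataFrame
    sample_ids: list[str] = field(default_factory=list)

    def __post_init__(self) -> None:
        df = self.frame
        for col in ("sample_id", "genus", "cfu_per_ml"):
            if col not in df.columns:
                raise ValidationError(f"culture table missing column {col!r}")
        df = df.assign(
            sample_id=df["sample_id"].astype(str),
            genus=df["genus"].fillna("").astype(str).str.strip(),
            cfu_per_ml=pd.to_numeric(df["cfu_per_ml"]).fillna(0),
        )
        # rows with an empty genus mark a cultured-but-no-growth sample
        markers = df[df["genus"] == ""]
        df = df[df["genus"] != ""]
        if (df["cfu_per_ml"] <= 0).any():
            raise ValidationError("cfu_per_ml must be positive")
        self.frame = df.reset_index(drop=True)
        self.sample_ids = list(self.sample_ids) + [
            s for s in markers["sample_id"] if s not in self.sample_ids]
        ids = list(self.sample_ids) if self.sample_ids else []
        for s in self.frame["sample_id"]:
            if s not in ids:
                ids.append(s)
        self.sample_ids = ids

    def detections(self, sample_id: str) -> dict[str, float]:
        rows = self.frame[self.frame["sample_id"] == sample_id]
        return dict(zip(rows["genus"], rows["cfu_per_ml"]))


def read_culture(path) -> CultureTable:
    df = pd.read_csv(path, sep="\t", dtype={"sample_id": str, "genus": str})
    return CultureTable(df)


def write_culture(culture: CultureTable, path) -> None:
    """Write detections plus empty-genus marker rows for no-growth samples,
    so the cultured-sample set survives a round trip."""
    out = culture.frame
    with_rows = set(out["sample_id"])
    markers = pd.DataFrame(
        [{"sample_id": s, "genus": "", "cfu_per_ml": 0}
         for s in culture.sample_ids if s not in with_rows])
    if len(markers):
        out = pd.concat([out, markers], ignore_index=True)
    out.to_csv(path, sep="\t", index=False)


# ---------------------------------------------------------------------------
# Distance matrix
# ---------------------------------------------------------------------------

@dataclass
class DistanceMatrix:
    """Symmetric non-negative dissimilarity matrix with zero diagonal."""

    sample_ids: list[str]
    data: np.ndarray
    metric_name: str = ""

    def __post_init__(self) -> None:
        self.data = np.asarray(self.data, dtype=float)
        n = len(self.sample_ids)
        if self.data.shape != (n, n):
            raise ValidationError(
                f"distance matrix shape {self.data.shape} does not match "
                f"{n} sample IDs"
            )
        if len(set(self.sample_ids)) != n:
            raise ValidationError("duplicate sample IDs in distance matrix")
        if not np.allclose(self.data, self.data.T, atol=1e-10):
            raise ValidationError("distance matrix is not symmetric")
        if np.any(np.diag(self.data) > 1e-10):
            raise ValidationError("distance matrix diagonal must be zero")
        if np.any(self.data < -1e-12):
            raise ValidationError("distances must be non-negative")
        self.data = np.maximum((self.data + self.data.T) / 2.0, 0.0)
        np.fill_diagonal(self.data, 0.0)

    def __getitem__(self, pair) -> float:
        i = self.sample_ids.index(pair[0])
        j = self.sample_ids.index(pair[1])
        return float(self.data[i, j])

    def subset(self, sample_ids) -> "DistanceMatrix":
        idx = [self.sample_ids.index(s) for s in sample_ids]
        return DistanceMatrix(list(sample_ids), self.data[np.ix_(idx, idx)], self.metric_name)

    def to_skbio(self) -> skbio.DistanceMatrix:
        return skbio.DistanceMatrix(self.data, ids=self.sample_ids)

    @classmethod
    def from_skbio(cls, dm: skbio.DistanceMatrix, metric_name: str = "") -> "DistanceMatrix":
        return cls(list(dm.ids), dm.data.copy(), metric_name)

    def to_frame(self) -> pd.DataFrame:
        return pd.DataFrame(self.data, index=self.sample_ids, columns=self.sample_ids)


def read_distance_matrix(path, metric_name: str = "") -> DistanceMatrix:
    df = pd.read_csv(path, sep="\t", index_col=0)
    if list(df.index) != list(df.columns):
        raise ParseError("distance-matrix row and column headers do not match")
    return DistanceMatrix([str(s) for s in df.index], df.to_numpy(float), metric_name)


def write_distance_matrix(dm: DistanceMatrix, path) -> None:
    dm.to_frame().to_csv(path, sep="\t")


# ---------------------------------------------------------------------------
# Alignment
# ---------------------------------------------------------------------------

def align_table_metadata_tree(
    table: FeatureTable,
    metadata: SampleMetadata,
    tree: skbio.TreeNode | None = None,
):
    """Restrict table/metadata (and optionally the table vs a tree) to their
    common samples/features, harmonizing order.

    Returns ``(table, metadata, tree, report)`` where ``report`` lists the
    dropped sample and feature IDs.  Raises :class:`ValidationError` on an
    empty sample intersection.  Idempotent on already-aligned inputs.
    """
    table_samples = table.sample_ids
    meta_samples = set(metadata.sample_ids)
    shared = [s for s in table_samples if s in meta_samples]
    if not shared:
        raise ValidationError("no samples shared between feature table and metadata")
    report = {
        "dropped_samples_table": [s for s in table_samples if s not in meta_samples],
        "dropped_samples_metadata": [s for s in metadata.sample_ids if s not in set(table_samples)],
        "dropped_features": [],
    }
    table = table.filter_samples(shared)
    metadata = metadata.subset(shared)
    if tree is not None:
        leaves = {t.name for t in tree.tips()}
        missing = [f for f in table.feature_ids if f not in leaves]
        if missing:
            report["dropped_features"] = missing
            table = table.filter_features([f for f in table.feature_ids if f in leaves])
            if table.shape[0] == 0:
                raise ValidationError("no features shared between table and tree")
    return table, metadata, tree, report
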