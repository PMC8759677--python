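"""Rarefaction, alpha diversity, beta diversity, and principal coordinates.

Alpha metrics are Shannon entropy (natural log by default), inverse Simpson
(1 / sum p_i^2) and Faith's phylogenetic diversity (root-inclusive by
default).  Beta metrics are the Jensen-Shannon divergence on relative ASV
abundances (bounded by ln 2 in nats) and the abundance-weighted generalized
UniFrac of Chen et al. with exponent ``alpha`` (alpha = 1 reduces to
weighted-normalized UniFrac).  Rarefaction is a single uniform subsample
without replacement to a fixed depth per sample.
"""

from __future__ import annotations

from dataclasses import dataclass, field

import numpy as np
import pandas as pd
import skbio

from .errors import MicrostabError, ValidationError
from .io import DistanceMatrix, FeatureTable

LN2 = float(np.log(2.0))


# ---------------------------------------------------------------------------
# Rarefaction
# ---------------------------------------------------------------------------

@dataclass(eq=False)
class RarefiedTable(FeatureTable):
    """A feature table whose retained samples all sum to ``rarefaction_depth``;
    samples with fewer reads are listed in ``excluded_samples`` as
    ``(sample_id, total_reads)`` pairs."""

    rarefaction_depth: int = 0
    excluded_samples: list = field(default_factory=list)

    def validate(self) -> None:
        super().validate()
        if self.rarefaction_depth > 0:
            sums = self.counts.sum(axis=0)
            if not (sums == self.rarefaction_depth).all():
                bad = sums[sums != self.rarefaction_depth].index.tolist()
                raise ValidationError(
                    f"rarefied column sums != depth for samples {bad}"
                )


def rarefy(table: FeatureTable, depth: int = 2000, seed: int | None = 0) -> RarefiedTable:
    """Subsample each sample to exactly ``depth`` reads without replacement.

    Samples with fewer than ``depth`` total reads are excluded (and
    reported).  The draw is multivariate hypergeometric, deterministic given
    ``seed``.  Features left with zero reads everywhere are dropped.
    """
    if depth <= 0:
        raise MicrostabError("rarefaction depth must be >= 1")
    rng = np.random.default_rng(seed)
    counts = table.counts
    kept_cols, excluded = {}, []
    for s in table.sample_ids:
        col = counts[s].to_numpy()
        total = int(col.sum())
        if total < depth:
            excluded.append((s, total))
            continue
        if total == depth:
            kept_cols[s] = col.copy()
        else:
            kept_cols[s] = rng.multivariate_hypergeometric(col, depth)
    if not kept_cols:
        raise MicrostabError(f"no sample reaches rarefaction depth {depth}")
    out = pd.DataFrame(kept_cols, index=counts.index)
    nz = out.sum(axis=1) > 0
    return RarefiedTable(
        out.loc[nz],
        table.taxonomy.loc[nz].copy(),
        rarefaction_depth=depth,
        excluded_samples=excluded,
    )


# ---------------------------------------------------------------------------
# Alpha diversity
# ---------------------------------------------------------------------------

def shannon(counts, base: float | None = None) -> float:
    """Shannon entropy -sum p ln p (nats by default; ``base=2`` for bits)."""
    p = _to_probs(counts)
    p = p[p > 0]
    h = float(-(p * np.log(p)).sum())
    if base is not None:
        h /= np.log(base)
    return h


def inverse_simpson(counts) -> float:
    """Inverse Simpson index 1 / sum p_i^2 (effective number of species)."""
    p = _to_probs(counts)
    return float(1.0 / np.sum(p ** 2))


def _to_probs(counts) -> np.ndarray:
    v = np.asarray(counts, dtype=float)
    if np.any(v < 0):
        raise MicrostabError("negative abundances")
    total = v.sum()
    if total <= 0:
        raise MicrostabError("diversity undefined for a zero-sum vector")
    return v / total


def faith_pd(counts, feature_ids, tree: skbio.TreeNode,
             include_root: bool = True) -> float:
    """Faith's phylogenetic diversity of one sample.

    Total branch length of the minimal subtree spanning the present features
    and (by default) the root.  ``include_root=False`` instead spans only the
    present leaves (their MRCA subtree), so a single-taxon sample scores 0.
    """
    v = np.asarray(counts, dtype=float)
    present = [f for f, c in zip(feature_ids, v) if c > 0]
    if not present:
        return 0.0
    lengths, member, leaf_index = _branch_structure(tree, list(feature_ids))
    pres = np.zeros(len(leaf_index), dtype=bool)
    for f in present:
        pres[leaf_index[f]] = True
    # number of present leaves below each branch
    below = member.astype(np.int64) @ pres.astype(np.int64)
    if include_root:
        return float(lengths[below > 0].sum())
    return float(lengths[(below > 0) & (below < pres.sum())].sum())


def alpha_diversity_table(table: FeatureTable, tree: skbio.TreeNode | None = None,
                          include_root: bool = True) -> pd.DataFrame:
    """Per-sample Shannon, inverse Simpson and (if a tree is given) Faith's PD."""
    records = {}
    fids = table.feature_ids
    if tree is not None:
        lengths, member, leaf_index = _branch_structure(tree, fids)
    for s in table.sample_ids:
        col = table.counts[s].to_numpy(float)
        rec = {"shannon": shannon(col), "inv_simpson": inverse_simpson(col)}
        if tree is not None:
            pres = col > 0
            below = member.astype(np.int64) @ pres.astype(np.int64)
            if include_root:
                rec["faith_pd"] = float(lengths[below > 0].sum())
            else:
                rec["faith_pd"] = float(
                    lengths[(below > 0) & (below < pres.sum())].sum()
                )
        records[s] = rec
    out = pd.DataFrame.from_dict(records, orient="index")
    out.index.name = "sample_id"
    return out


# ---------------------------------------------------------------------------
# Jensen-Shannon divergence
# ---------------------------------------------------------------------------

def jsd(p, q, base: float | None = None) -> float:
    """Jensen-Shannon divergence 0.5 KL(p||m) + 0.5 KL(q||m), m = (p+q)/2.

    Inputs are (re)normalized to probability vectors on a shared index.
    Natural log by default (range [0, ln 2]); ``base=2`` rescales to [0, 1].
    """
    p = _to_probs(p)
    q = _to_probs(q)
    if p.shape != q.shape:
        raise MicrostabError("p and q must share a feature index")
    m = 0.5 * (p + q)
    val = 0.5 * _kl(p, m) + 0.5 * _kl(q, m)
    if base is not None:
        val /= np.log(base)
    return float(min(max(val, 0.0), LN2 if base is None else LN2 / np.log(base)))


def _kl(p: np.ndarray, m: np.ndarray) -> float:
    mask = p > 0
    return float((p[mask] * np.log(p[mask] / m[mask])).sum())


def jsd_matrix(table: FeatureTable, base: float | None = None) -> DistanceMatrix:
    """All-pairs JSD over a table's samples (columns renormalized)."""
    rel = table.relative_abundance().to_numpy(float)
    totals = table.counts.sum(axis=0).to_numpy()
    if np.any(totals == 0):
        raise MicrostabError("zero-read sample in JSD computation")
    n = rel.shape[1]
    with np.errstate(divide="ignore", invalid="ignore"):
        plogp = np.where(rel > 0, rel * np.log(rel), 0.0).sum(axis=0)
    d = np.zeros((n, n))
    for i in range(n):
        pi = rel[:, i][:, None]
        qj = rel[:, i + 1:]
        m = 0.5 * (pi + qj)
        with np.errstate(divide="ignore", invalid="ignore"):
            mlogm = np.where(m > 0, m * np.log(m), 0.0).sum(axis=0)
        # JSD = H(m) - (H(p)+H(q))/2, with H in nats
        vals = -mlogm + 0.5 * (plogp[i] + plogp[i + 1:])
        d[i, i + 1:] = d[i + 1:, i] = np.clip(vals, 0.0, LN2)
    if base is not None:
        d /= np.log(base)
    return DistanceMatrix(table.sample_ids, d, metric_name="jsd")


# ---------------------------------------------------------------------------
# Generalized UniFrac
# ---------------------------------------------------------------------------

def _branch_structure(tree: skbio.TreeNode, feature_ids: list[str]):
    """Branch lengths and leaf membership for every edge of ``tree``.

    Returns ``(lengths, membership, leaf_index)`` where ``membership`` is a
    (branches x features) boolean matrix marking which features descend from
    each branch, in ``feature_ids`` order.
    """
    leaf_index = {f: i for i, f in enumerate(feature_ids)}
    tips = {t.name for t in tree.tips()}
    missing = [f for f in feature_ids if f not in tips]
    if missing:
        raise MicrostabError(f"features absent from tree: {missing[:5]}"
                             + ("..." if len(missing) > 5 else ""))
    lengths, rows = [], []
    nf = len(feature_ids)
    masks: dict[int, np.ndarray] = {}
    for node in tree.postorder(include_self=True):
        if node.is_tip():
            mask = np.zeros(nf, dtype=bool)
            if node.name in leaf_index:
                mask[leaf_index[node.name]] = True
        else:
            mask = np.zeros(nf, dtype=bool)
            for child in node.children:
                mask |= masks[id(child)]
        masks[id(node)] = mask
        if node.parent is not None:  # the root carries no edge
            lengths.append(float(node.length or 0.0))
            rows.append(mask)
    return np.asarray(lengths), np.asarray(rows), leaf_index


def generalized_unifrac(table: FeatureTable, tree: skbio.TreeNode,
                        alpha: float = 0.5) -> DistanceMatrix:
    """Generalized UniFrac distance matrix (Chen et al.).

    For samples A, B with per-branch descendant proportions p_bA, p_bB:

        d(A,B) = sum_b L_b (p_bA+p_bB)^alpha |p_bA-p_bB|/(p_bA+p_bB)
                 / sum_b L_b (p_bA+p_bB)^alpha

    over branches with p_bA + p_bB > 0.  ``alpha=1`` is weighted-normalized
    UniFrac; ``alpha=0.5`` is the canonical generalized setting.
    """
    totals = table.counts.sum(axis=0).to_numpy()
    if np.any(totals == 0):
        raise MicrostabError("zero-read sample in UniFrac computation")
    lengths, member, _ = _branch_structure(tree, table.feature_ids)
    rel = table.relative_abundance().to_numpy(float)
    bp = member.astype(float) @ rel  # branches x samples
    n = bp.shape[1]
    d = np.zeros((n, n))
    for i in range(n):
        pi = bp[:, i][:, None]
        qj = bp[:, i + 1:]
        s = pi + qj
        with np.errstate(divide="ignore", invalid="ignore"):
            w = np.where(s > 0, lengths[:, None] * s ** alpha, 0.0)
            ratio = np.where(s > 0, np.abs(pi - qj) / np.where(s > 0, s, 1.0), 0.0)
        num = (w * ratio).sum(axis=0)
        den = w.sum(axis=0)
        vals = np.where(den > 0, num / np.where(den > 0, den, 1.0), 0.0)
        d[i, i + 1:] = d[i + 1:, i] = vals
    return DistanceMatrix(table.sample_ids, d,
                          metric_name=f"generalized_unifrac(alpha={alpha})")


# ---------------------------------------------------------------------------
# PCoA
# ---------------------------------------------------------------------------

@dataclass
class PCoAResult:
    sample_ids: list[str]
    coordinates: np.ndarray  # samples x axes
    eigenvalues: np.ndarray  # descending, negatives retained
    proportion_explained: np.ndarray  # negatives clamped to 0 before normalizing


def pcoa(dm: DistanceMatrix, n_axes: int | None = None) -> PCoAResult:
    """Classical MDS: eigendecompose the Gower-centered -D^2/2 matrix.

    Negative eigenvalues (non-Euclidean input) are retained in
    ``eigenvalues`` but clamped to zero for ``proportion_explained``; axes
    are returned only for positive eigenvalues, ordered by decreasing
    eigenvalue.
    """
    d = dm.data
    g = _gower_center(d ** 2)
    evals, evecs = np.linalg.eigh(g)
    order = np.argsort(evals)[::-1]
    evals, evecs = evals[order], evecs[:, order]
    pos = evals > 1e-10 * max(1.0, abs(evals[0]) if evals.size else 1.0)
    coords = evecs[:, pos] * np.sqrt(evals[pos])
    clamped = np.clip(evals, 0.0, None)
    total = clamped.sum()
    prop = clamped / total if total > 0 else clamped
    if n_axes is not None:
        coords = coords[:, :n_axes]
    return PCoAResult(list(dm.sample_ids), coords, evals, prop)


def _gower_center(d2: np.ndarray) -> np.ndarray:
    n = d2.shape[0]
    j = np.eye(n) - np.ones((n, n)) / n
    return -0.5 * j @ d2 @ j
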