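"""Nonparametric tests and correlation intervals used across the pipeline.

Small-sample paths enumerate the exact permutation/sign-flip distribution, so
printed p-values are rationals over the enumeration-space size (e.g. six
concordant pairs in a signed-rank test give 2/64 ~ 0.031).  Larger samples
fall back to the usual normal approximations with tie and continuity
corrections (delegated to scipy).  Two-sidedness throughout is "as or more
extreme in either direction" on the null-symmetric statistic, which for the
exact paths coincides with doubling the smaller tail.
"""

from __future__ import annotations

import itertools
from dataclasses import dataclass

import numpy as np
from scipy import stats as sps

from .errors import MicrostabError

#: largest n_a + n_b for which the Mann-Whitney null is enumerated exactly
MW_EXACT_MAX_N = 12
#: largest number of nonzero pairs for which sign-flips are enumerated
WILCOXON_EXACT_MAX_N = 20


@dataclass
class TestResult:
    statistic: float
    p_value: float
    method: str  # "exact" | "normal-approximation"
    n_a: int | None = None
    n_b: int | None = None
    n_pairs: int | None = None
    tie_corrected: bool = False
    enumeration_size: int | None = None


# ---------------------------------------------------------------------------
# Mann-Whitney U
# ---------------------------------------------------------------------------

def mann_whitney(a, b, alternative: str = "two-sided") -> TestResult:
    """Mann-Whitney U test of two independent samples.

    Exact enumeration over all C(n_a+n_b, n_a) group assignments when
    ``n_a + n_b <= 12`` and the pooled data is tie-free; otherwise the normal
    approximation with tie and continuity correction.
    """
    a = np.asarray(a, dtype=float)
    b = np.asarray(b, dtype=float)
    if a.size == 0 or b.size == 0:
        raise MicrostabError("mann_whitney requires two non-empty samples")
    pooled = np.concatenate([a, b])
    has_ties = len(np.unique(pooled)) < pooled.size
    n_a, n_b = a.size, b.size

    ranks = sps.rankdata(pooled)
    u_a = float(ranks[:n_a].sum() - n_a * (n_a + 1) / 2.0)

    if alternative != "two-sided":
        raise ValueError("only two-sided alternative is supported")

    if n_a + n_b <= MW_EXACT_MAX_N and not has_ties:
        total = n_a * n_b
        obs_extreme = min(u_a, total - u_a)
        count = 0
        space = 0
        idx = range(n_a + n_b)
        for comb in itertools.combinations(idx, n_a):
            space += 1
            u = float(ranks[list(comb)].sum() - n_a * (n_a + 1) / 2.0)
            if min(u, total - u) <= obs_extreme + 1e-12:
                count += 1
        return TestResult(u_a, count / space, "exact", n_a=n_a, n_b=n_b,
                          enumeration_size=space)

    mean = n_a * n_b / 2.0
    n = n_a + n_b
    _, tie_counts = np.unique(pooled, return_counts=True)
    tie_term = np.sum(tie_counts ** 3 - tie_counts) / (n * (n - 1))
    var = n_a * n_b / 12.0 * (n + 1 - tie_term)
    if var <= 0:
        return TestResult(u_a, 1.0, "normal-approximation", n_a=n_a, n_b=n_b,
                          tie_corrected=True)
    if u_a == mean:
        p = 1.0
    else:
        z = (abs(u_a - mean) - 0.5) / np.sqrt(var)
        p = min(1.0, 2.0 * sps.norm.sf(max(z, 0.0)))
    return TestResult(u_a, p, "normal-approximation", n_a=n_a, n_b=n_b,
                      tie_corrected=has_ties)


# ---------------------------------------------------------------------------
# Wilcoxon signed-rank
# ---------------------------------------------------------------------------

def wilcoxon_signed_rank(a, b=None, alternative: str = "two-sided",
                         zero_method: str = "wilcox") -> TestResult:
    """Wilcoxon signed-rank test for paired samples (or differences).

    Zero differences are dropped (Wilcoxon's original treatment;
    ``zero_method="pratt"`` keeps them in the ranking).  For up to 20 nonzero
    pairs the full 2^n sign-flip distribution of W+ is computed by
    convolution over (doubled, integer) midranks; beyond that the normal
    approximation with continuity correction is used.
    """
    d = np.asarray(a, dtype=float)
    if b is not None:
        d = d - np.asarray(b, dtype=float)
    if alternative != "two-sided":
        raise ValueError("only two-sided alternative is supported")
    if zero_method not in ("wilcox", "pratt"):
        raise ValueError("zero_method must be 'wilcox' or 'pratt'")

    nonzero = d[d != 0]
    if nonzero.size == 0:
        raise MicrostabError("all paired differences are zero")

    if zero_method == "wilcox":
        ranked = nonzero
    else:
        ranked = d
    ranks = sps.rankdata(np.abs(ranked))
    signs = np.sign(ranked)
    w_plus = float(ranks[signs > 0].sum())
    if zero_method == "pratt":
        # zeros carry rank but no sign; center on the nonzero rank total
        t_total = float(ranks[signs != 0].sum())
        ranks = ranks[signs != 0]
        signs = signs[signs != 0]
    else:
        t_total = float(ranks.sum())
    n = signs.size

    if n <= WILCOXON_EXACT_MAX_N:
        # doubled ranks are integers even with midranks
        r2 = np.round(2 * ranks).astype(int)
        t2 = int(r2.sum())
        dist = np.zeros(t2 + 1, dtype=float)
        dist[0] = 1.0
        for r in r2:
            shifted = np.zeros_like(dist)
            shifted[r:] = dist[: t2 + 1 - r]
            dist = dist + shifted
        w2 = int(round(2 * w_plus))
        obs_extreme = min(w2, t2 - w2)
        vals = np.arange(t2 + 1)
        mask = np.minimum(vals, t2 - vals) <= obs_extreme
        p = float(dist[mask].sum() / 2.0 ** n)
        return TestResult(w_plus, min(p, 1.0), "exact", n_pairs=n,
                          enumeration_size=2 ** n)

    mean = t_total / 2.0
    var = float(np.sum(ranks ** 2)) / 4.0
    if var <= 0:
        return TestResult(w_plus, 1.0, "normal-approximation", n_pairs=n)
    if w_plus == mean:
        p = 1.0
    else:
        z = (abs(w_plus - mean) - 0.5) / np.sqrt(var)
        p = min(1.0, 2.0 * sps.norm.sf(max(z, 0.0)))
    ties = len(np.unique(np.abs(ranked))) < np.asarray(ranked).size
    return TestResult(w_plus, p, "normal-approximation", n_pairs=n,
                      tie_corrected=ties)


# ---------------------------------------------------------------------------
# Kruskal-Wallis + Dunn
# ---------------------------------------------------------------------------

def kruskal_dunn(groups: dict | list) -> tuple[TestResult, dict]:
    """Kruskal-Wallis H test with Dunn's post test (BH-adjusted).

    ``groups`` is a mapping name -> values (or a list of arrays).  Returns
    the omnibus result and a dict ``(name_i, name_j) -> TestResult`` whose
    p-values are Benjamini-Hochberg adjusted Dunn z-test p-values.
    """
    if not isinstance(groups, dict):
        groups = {str(i): g for i, g in enumerate(groups)}
    names = list(groups)
    if len(names) < 3:
        raise MicrostabError(
            "kruskal_dunn requires >= 3 groups; use mann_whitney for two"
        )
    arrays = [np.asarray(groups[g], dtype=float) for g in names]
    for g, arr in zip(names, arrays):
        if arr.size == 0:
            raise MicrostabError(f"empty group {g!r}")

    h, p = sps.kruskal(*arrays)
    kw = TestResult(float(h), float(p), "normal-approximation",
                    tie_corrected=True)

    pooled = np.concatenate(arrays)
    n = pooled.size
    ranks = sps.rankdata(pooled)
    _, tie_counts = np.unique(pooled, return_counts=True)
    tie_term = np.sum(tie_counts ** 3 - tie_counts) / (12.0 * (n - 1))
    offsets = np.cumsum([0] + [a.size for a in arrays])
    mean_ranks = {
        g: ranks[offsets[i]: offsets[i + 1]].mean() for i, g in enumerate(names)
    }
    pairs = list(itertools.combinations(names, 2))
    raw_p, stats_ = [], []
    for gi, gj in pairs:
        ni = arrays[names.index(gi)].size
        nj = arrays[names.index(gj)].size
        se = np.sqrt((n * (n + 1) / 12.0 - tie_term) * (1.0 / ni + 1.0 / nj))
        z = (mean_ranks[gi] - mean_ranks[gj]) / se if se > 0 else 0.0
        stats_.append(z)
        raw_p.append(min(1.0, 2.0 * sps.norm.sf(abs(z))))
    adj = benjamini_hochberg(raw_p)
    dunn = {
        pair: TestResult(float(z), float(pa), "normal-approximation",
                         tie_corrected=True)
        for pair, z, pa in zip(pairs, stats_, adj)
    }
    return kw, dunn


# ---------------------------------------------------------------------------
# Pearson correlation with Fisher-z CI
# ---------------------------------------------------------------------------

def pearson_fisher_ci(x, y, conf: float = 0.95) -> tuple[float, float, float]:
    """Sample Pearson r with a Fisher-z confidence interval.

    CI = tanh(atanh(r) +/- z_(1-(1-conf)/2) / sqrt(n-3)).  At |r| = 1 the
    interval degenerates to the boundary on that side.
    """
    x = np.asarray(x, dtype=float)
    y = np.asarray(y, dtype=float)
    if x.size != y.size or x.size < 4:
        raise MicrostabError("pearson_fisher_ci requires paired vectors with n >= 4")
    if np.ptp(x) == 0 or np.ptp(y) == 0:
        raise MicrostabError("correlation undefined for a constant vector")
    r = float(np.corrcoef(x, y)[0, 1])
    if abs(r) >= 1.0 - 1e-15:
        return r, r, r  # degenerate: interval collapses at the bound
    z = np.arctanh(r)
    half = sps.norm.ppf(1 - (1 - conf) / 2.0) / np.sqrt(x.size - 3)
    return r, float(np.tanh(z - half)), float(np.tanh(z + half))


# ---------------------------------------------------------------------------
# Benjamini-Hochberg
# ---------------------------------------------------------------------------

def benjamini_hochberg(pvals) -> np.ndarray:
    """Step-up Benjamini-Hochberg adjusted p-values (monotone, capped at 1)."""
    p = np.asarray(pvals, dtype=float)
    if p.size == 0:
        return p
    if np.any((p <= 0) | (p > 1)):
        raise MicrostabError("p-values must lie in (0, 1]")
    m = p.size
    order = np.argsort(p, kind="stable")
    adj = p[order] * m / np.arange(1, m + 1)
    adj = np.minimum.accumulate(adj[::-1])[::-1]
    out = np.empty(m)
    out[order] = np.minimum(adj, 1.0)
    return out
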