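"""PERMANOVA variance partitioning on a distance matrix.

Sequential (Type I) sums of squares in caller-given term order, computed
from the Gower-centered inner-product matrix G = -1/2 J D^2 J via projection
onto nested design blocks; significance by permuting sample labels, either
freely or restricted within strata blocks (e.g. within volunteer).  When the
distinct-permutation space is small, it is enumerated exhaustively instead
of sampled.
"""

from __future__ import annotations

import itertools
import math
import warnings
from dataclasses import dataclass

import numpy as np
import pandas as pd

from .errors import MicrostabError
from .io import DistanceMatrix, SampleMetadata


@dataclass
class PermanovaResult:
    term: str
    df: int
    sum_sq: float
    r_squared: float
    pseudo_f: float
    p_value: float | None
    n_permutations: int
    strata_var: str | None = None


def permanova(
    dm: DistanceMatrix,
    metadata: SampleMetadata | pd.DataFrame,
    terms: list[str],
    n_perm: int = 999,
    seed: int | None = 0,
    strata: str | None = None,
    exhaustive_limit: int = 10_000,
) -> list[PermanovaResult]:
    """Sequential PERMANOVA of ``terms`` (in order) on distance matrix ``dm``.

    Samples missing a value for any term (or the strata variable) are
    dropped listwise.  ``strata`` restricts permutations to within-block
    shuffles (blocks = levels of the strata variable); a term constant
    within every stratum is then confounded and rejected.  If the number of
    distinct permutations is at most ``min(n_perm, exhaustive_limit)`` the
    permutation distribution is enumerated exactly.  The final entry of the
    returned list is the residual row (no F / p).
    """
    meta = metadata.frame if isinstance(metadata, SampleMetadata) else metadata
    cols = list(terms) + ([strata] if strata else [])
    for t in cols:
        if t not in meta.columns:
            raise MicrostabError(f"term {t!r} not in metadata")
    ids = [s for s in dm.sample_ids
           if s in meta.index and not meta.loc[s, cols].isna().any()]
    if len(ids) < 3:
        raise MicrostabError("fewer than 3 usable samples after listwise dropping")
    sub = dm.subset(ids)
    meta = meta.loc[ids]

    strata_codes = None
    if strata is not None:
        strata_codes = pd.factorize(meta[strata])[0]
        for t in terms:
            vals = meta[t]
            if all(vals[strata_codes == g].nunique() == 1
                   for g in np.unique(strata_codes)):
                raise MicrostabError(
                    f"term {t!r} is constant within every {strata!r} stratum "
                    "(confounded with strata); drop it from the model"
                )

    g = _gower(sub.data)
    n = g.shape[0]
    designs, dfs = [], []
    x = np.ones((n, 1))
    for t in terms:
        block = _design_block(meta[t])
        if block.shape[1] == 0:
            raise MicrostabError(f"term {t!r} has fewer than 2 levels after dropping")
        x = np.hstack([x, block])
        designs.append(x.copy())
        dfs.append(block.shape[1])
    hats = [_hat(d) for d in designs]

    ss_total = float(np.trace(g))
    seq_ss = []
    prev = 0.0
    for h in hats:
        explained = float(np.sum(h * g))  # tr(H G), H symmetric idempotent
        seq_ss.append(explained - prev)
        prev = explained
    ss_resid = ss_total - prev
    df_resid = n - 1 - sum(dfs)
    if df_resid <= 0:
        f_obs = [math.inf if ss > 0 else 0.0 for ss in seq_ss]
    else:
        ms_resid = ss_resid / df_resid
        f_obs = [(ss / df) / ms_resid if ms_resid > 0 else math.inf
                 for ss, df in zip(seq_ss, dfs)]

    perms, exact = _permutations(n, n_perm, seed, strata_codes, exhaustive_limit)
    if df_resid <= 0:
        p_values = [None] * len(terms)
        n_used = 0
    else:
        counts = np.zeros(len(terms))
        n_used = 0
        for p in perms:
            gp = g[np.ix_(p, p)]
            prev = 0.0
            fs = []
            for h, df in zip(hats, dfs):
                explained = float(np.sum(h * gp))
                ss = explained - prev
                prev = explained
                fs.append(ss / df)
            ms_res = (ss_total - prev) / df_resid
            n_used += 1
            for k, fk in enumerate(fs):
                fperm = fk / ms_res if ms_res > 0 else math.inf
                if fperm >= f_obs[k] - 1e-12:
                    counts[k] += 1
        if exact:
            p_values = [c / n_used for c in counts]
        else:
            p_values = [(c + 1) / (n_used + 1) for c in counts]

    results = [
        PermanovaResult(t, df, ss, ss / ss_total if ss_total > 0 else 0.0,
                        f, p, n_used, strata)
        for t, df, ss, f, p in zip(terms, dfs, seq_ss, f_obs, p_values)
    ]
    results.append(PermanovaResult("residual", df_resid, ss_resid,
                                   ss_resid / ss_total if ss_total > 0 else 0.0,
                                   math.nan, None, n_used, strata))
    return results


def permanova_univariate(
    dm: DistanceMatrix,
    metadata: SampleMetadata | pd.DataFrame,
    terms: list[str],
    n_perm: int = 999,
    seed: int | None = 0,
    strata: str | None = None,
) -> dict[str, PermanovaResult]:
    """One single-term PERMANOVA per candidate term (Table-2 style
    univariate screen); returns term -> its result row."""
    out = {}
    for t in terms:
        res = permanova(dm, metadata, [t], n_perm=n_perm, seed=seed, strata=strata)
        out[t] = res[0]
    return out


def term_screen(
    metadata: SampleMetadata | pd.DataFrame,
    candidate_terms: list[str],
    id_var: str = "volunteer_id",
    id_consistency_threshold: float = 1.0,
) -> tuple[list[str], list[str]]:
    """Split candidate terms into (retained, excluded) for a model that
    already contains the volunteer-ID term.

    A term is excluded when its within-volunteer consistency (modal-level
    frequency among that volunteer's samples, minimized over volunteers) is
    at or above the threshold — such a term is (nearly) an alias of the ID.
    """
    meta = metadata.frame if isinstance(metadata, SampleMetadata) else metadata
    retained, excluded = [], []
    for t in candidate_terms:
        if t not in meta.columns:
            raise MicrostabError(f"term {t!r} not in metadata")
        consistencies = []
        for _, grp in meta.dropna(subset=[t]).groupby(id_var):
            if len(grp) == 0:
                continue
            modal = grp[t].value_counts().iloc[0]
            consistencies.append(modal / len(grp))
        if consistencies and min(consistencies) >= id_consistency_threshold:
            excluded.append(t)
        else:
            retained.append(t)
    return retained, excluded


# ---------------------------------------------------------------------------
# internals
# ---------------------------------------------------------------------------

def _gower(d: np.ndarray) -> np.ndarray:
    n = d.shape[0]
    j = np.eye(n) - np.ones((n, n)) / n
    return -0.5 * j @ (d ** 2) @ j


def _design_block(values: pd.Series) -> np.ndarray:
    """Dummy columns (drop-first) for a categorical term; numeric terms with
    many distinct values are treated as a single centered covariate."""
    if pd.api.types.is_numeric_dtype(values) and values.nunique() > 8:
        v = values.to_numpy(float)
        return (v - v.mean())[:, None]
    codes, uniques = pd.factorize(values, sort=True)
    k = len(uniques)
    if k < 2:
        return np.empty((len(values), 0))
    block = np.zeros((len(values), k - 1))
    for lvl in range(1, k):
        block[codes == lvl, lvl - 1] = 1.0
    return block


def _hat(x: np.ndarray) -> np.ndarray:
    q, r = np.linalg.qr(x)
    rank = np.sum(np.abs(np.diag(r)) > 1e-10 * max(1.0, np.abs(r[0, 0])))
    q = q[:, :int(rank)]
    return q @ q.T


def _permutations(n, n_perm, seed, strata_codes, exhaustive_limit):
    """Yield permutation index arrays; returns (iterable, exact_flag).

    The permutation space is all relabelings (free) or all products of
    within-block relabelings (strata).  If its size is <= min(n_perm,
    exhaustive_limit) it is enumerated exhaustively (identity included).
    """
    if strata_codes is None:
        space = math.factorial(n)
        if space <= min(n_perm, exhaustive_limit):
            return list(itertools.permutations(range(n))), True
        rng = np.random.default_rng(seed)
        return [rng.permutation(n) for _ in range(n_perm)], False

    blocks = [np.flatnonzero(strata_codes == g) for g in np.unique(strata_codes)]
    space = 1
    for b in blocks:
        space *= math.factorial(len(b))
        if space > exhaustive_limit:
            break
    if space <= min(n_perm, exhaustive_limit):
        warnings.warn(
            f"only {space} distinct within-strata permutations; "
            "using exhaustive enumeration"
        )
        per_block = [list(itertools.permutations(b)) for b in blocks]
        perms = []
        for combo in itertools.product(*per_block):
            p = np.empty(n, dtype=int)
            for b, order in zip(blocks, combo):
                p[b] = order
            perms.append(p)
        return perms, True
    rng = np.random.default_rng(seed)
    out = []
    for _ in range(n_perm):
        p = np.arange(n)
        for b in blocks:
            p[b] = b[rng.permutation(len(b))]
        out.append(p)
    return out, False
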