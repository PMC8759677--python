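import itertools

import numpy as np
import pandas as pd
import pytest
from scipy.spatial.distance import pdist, squareform

from microstab.errors import MicrostabError
from microstab.io import DistanceMatrix, SampleMetadata
from microstab.variance import permanova, permanova_univariate, term_screen


def _meta(ids, **columns):
    df = pd.DataFrame({"sample_id": ids})
    df["volunteer_id"] = columns.pop("volunteer_id", ["V"] * len(ids))
    df["visit"] = columns.pop("visit", ["1"] * len(ids))
    df["sample_type"] = columns.pop("sample_type", ["CU"] * len(ids))
    for k, v in columns.items():
        df[k] = v
    return SampleMetadata(df)


def _euclid_dm(points):
    ids = [f"s{i}" for i in range(len(points))]
    return DistanceMatrix(ids, squareform(pdist(np.asarray(points, float)))), ids


def brute_force_permanova(d, labels):
    """Independent one-way PERMANOVA by direct within-group sums of squared
    distances, enumerating every relabeling."""
    n = len(labels)

    def f_stat(lab):
        lab = np.asarray(lab)
        ss_tot = (d ** 2).sum() / (2 * n)
        ss_w = 0.0
        for g in set(lab):
            idx = np.flatnonzero(lab == g)
            sub = d[np.ix_(idx, idx)]
            ss_w += (sub ** 2).sum() / (2 * len(idx))
        a = len(set(lab))
        return ((ss_tot - ss_w) / (a - 1)) / (ss_w / (n - a)), \
            (ss_tot - ss_w) / ss_tot

    f_obs, r2 = f_stat(labels)
    count = total = 0
    for perm in itertools.permutations(range(n)):
        total += 1
        if f_stat([labels[i] for i in perm])[0] >= f_obs - 1e-12:
            count += 1
    return f_obs, r2, count / total


class TestPermanova:
    def test_saturated_model_explains_everything(self):
        dm, ids = _euclid_dm(np.random.default_rng(0).normal(size=(4, 2)))
        meta = _meta(ids, grp=["a", "b", "c", "d"])
        res = permanova(dm, meta, ["grp"], n_perm=9, seed=0)
        assert res[0].r_squared == pytest.approx(1.0)
        assert res[-1].sum_sq == pytest.approx(0.0, abs=1e-10)

    def test_exhaustive_p_matches_enumeration_oracle(self):
        rng = np.random.default_rng(1)
        for _ in range(4):
            pts = rng.normal(size=(6, 2))
            labels = ["x", "x", "x", "y", "y", "y"]
            dm, ids = _euclid_dm(pts)
            meta = _meta(ids, grp=labels)
            res = permanova(dm, meta, ["grp"], n_perm=10 ** 9, seed=0)
            f_ref, r2_ref, p_ref = brute_force_permanova(dm.data, labels)
            assert res[0].pseudo_f == pytest.approx(f_ref)
            assert res[0].r_squared == pytest.approx(r2_ref)
            assert res[0].p_value == pytest.approx(p_ref, abs=1e-12)

    def test_within_strata_enumeration_matches_oracle(self):
        # permutations restricted within two volunteer blocks of 3
        rng = np.random.default_rng(2)
        pts = rng.normal(size=(6, 2))
        dm, ids = _euclid_dm(pts)
        vols = ["A", "A", "A", "B", "B", "B"]
        grp = ["x", "y", "x", "y", "x", "y"]
        meta = _meta(ids, volunteer_id=vols, grp=grp)
        with pytest.warns(UserWarning, match="exhaustive"):
            res = permanova(dm, meta, ["grp"], n_perm=10 ** 6, seed=0,
                            strata="volunteer_id")
        # oracle: enumerate the 3! x 3! within-block index permutations and
        # recompute F each time from the permuted distance matrix
        from microstab.variance import _design_block, _gower, _hat
        g = _gower(dm.data)
        x = np.hstack([np.ones((6, 1)),
                       _design_block(pd.Series(grp))])
        h = _hat(x)
        ss_tot = np.trace(g)

        def f_of(gm):
            ss = np.sum(h * gm)
            return (ss / 1) / ((ss_tot - ss) / 4)

        f_obs = f_of(g)
        count = total = 0
        for pa in itertools.permutations([0, 1, 2]):
            for pb in itertools.permutations([3, 4, 5]):
                p = list(pa) + list(pb)
                total += 1
                if f_of(g[np.ix_(p, p)]) >= f_obs - 1e-12:
                    count += 1
        assert res[0].p_value == pytest.approx(count / total, abs=1e-12)
        assert res[0].n_permutations == total

    def test_term_confounded_with_strata_rejected(self):
        dm, ids = _euclid_dm(np.random.default_rng(3).normal(size=(6, 2)))
        meta = _meta(ids, volunteer_id=["A", "A", "A", "B", "B", "B"])
        with pytest.raises(MicrostabError, match="confounded"):
            permanova(dm, meta, ["volunteer_id"], strata="volunteer_id")

    def test_r_squared_invariant_to_relabeling(self):
        rng = np.random.default_rng(4)
        dm, ids = _euclid_dm(rng.normal(size=(8, 2)))
        grp = ["a", "a", "b", "b", "c", "c", "c", "a"]
        relabeled = {"a": "zebra", "b": "yak", "c": "x"}
        m1 = _meta(ids, grp=grp)
        m2 = _meta(ids, grp=[relabeled[g] for g in grp])
        r1 = permanova(dm, m1, ["grp"], n_perm=49, seed=7)
        r2 = permanova(dm, m2, ["grp"], n_perm=49, seed=7)
        assert r1[0].r_squared == pytest.approx(r2[0].r_squared)
        assert r1[0].p_value == r2[0].p_value

    def test_reproducible_given_seed(self):
        rng = np.random.default_rng(5)
        dm, ids = _euclid_dm(rng.normal(size=(12, 2)))
        meta = _meta(ids, grp=list("ababababcdcd"))
        a = permanova(dm, meta, ["grp"], n_perm=99, seed=42)
        b = permanova(dm, meta, ["grp"], n_perm=99, seed=42)
        assert a[0].p_value == b[0].p_value
        assert a[0].pseudo_f == b[0].pseudo_f

    def test_sequential_r_squared_sums_to_one(self):
        rng = np.random.default_rng(6)
        dm, ids = _euclid_dm(rng.normal(size=(12, 2)))
        meta = _meta(ids, g1=list("aabbaabbaabb"), g2=list("xxxyyyxxxyyy"))
        res = permanova(dm, meta, ["g1", "g2"], n_perm=9, seed=0)
        assert sum(r.r_squared for r in res) == pytest.approx(1.0)

    def test_missing_values_dropped_listwise(self):
        rng = np.random.default_rng(7)
        dm, ids = _euclid_dm(rng.normal(size=(6, 2)))
        grp = ["a", "a", "b", "b", None, "a"]
        meta = _meta(ids, grp=grp)
        res = permanova(dm, meta, ["grp"], n_perm=9, seed=0)
        # 5 usable samples -> residual df = 5 - 1 - 1 = 3
        assert res[-1].df == 3

    def test_univariate_wrapper_returns_per_term_rows(self):
        rng = np.random.default_rng(8)
        dm, ids = _euclid_dm(rng.normal(size=(8, 2)))
        meta = _meta(ids, g1=list("aabbccdd"), g2=list("xyxyxyxy"))
        out = permanova_univariate(dm, meta, ["g1", "g2"], n_perm=19, seed=0)
        assert set(out) == {"g1", "g2"}
        assert all(0 <= r.r_squared <= 1 for r in out.values())


class TestTermScreen:
    def _meta(self):
        rows = []
        for vol in "ABC":
            for visit in "1234":
                rows.append({
                    "sample_id": f"{vol}{visit}",
                    "volunteer_id": vol,
                    "visit": visit,
                    "sample_type": "CU",
                    "diet": {"A": "veg", "B": "nonveg", "C": "veg"}[vol],
                    "cycle_week": visit,  # varies within each volunteer
                    "mostly_const": "x" if visit != "4" else "y",
                })
        return SampleMetadata(pd.DataFrame(rows))

    def test_volunteer_constant_term_excluded(self):
        retained, excluded = term_screen(self._meta(), ["diet", "cycle_week"])
        assert excluded == ["diet"]
        assert retained == ["cycle_week"]

    def test_lower_threshold_excludes_mostly_constant_term(self):
        # constant in 3 of 4 visits for every volunteer -> consistency 0.75
        _, excluded = term_screen(self._meta(), ["mostly_const"],
                                  id_consistency_threshold=0.75)
        assert excluded == ["mostly_const"]
        retained, _ = term_screen(self._meta(), ["mostly_const"])
        assert retained == ["mostly_const"]
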