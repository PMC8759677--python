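import numpy as np
import pandas as pd
import pytest
from scipy.spatial.distance import jensenshannon, pdist, squareform

from microstab.diversity import (LN2, alpha_diversity_table, faith_pd,
                                 generalized_unifrac, inverse_simpson, jsd,
                                 jsd_matrix, pcoa, rarefy, shannon)
from microstab.errors import MicrostabError, ValidationError
from microstab.io import DistanceMatrix, FeatureTable, read_tree


def _table(counts: dict, index=None) -> FeatureTable:
    df = pd.DataFrame(counts)
    if index is not None:
        df.index = index
    return FeatureTable(df, pd.Series("unclassified", index=df.index))


class TestRarefy:
    def test_sample_at_depth_unchanged(self):
        t = _table({"s1": [1500, 500]})
        rt = rarefy(t, 2000, seed=1)
        assert rt.counts["s1"].tolist() == [1500, 500]

    def test_sample_below_depth_excluded(self):
        t = _table({"s1": [1999, 0], "s2": [2500, 100]})
        rt = rarefy(t, 2000, seed=1)
        assert rt.excluded_samples == [("s1", 1999)]
        assert rt.sample_ids == ["s2"]

    def test_column_sums_exactly_depth(self, cohort):
        rt = rarefy(cohort.table, 2000, seed=3)
        assert (rt.counts.sum(axis=0) == 2000).all()

    def test_reproducible_given_seed(self, cohort):
        a = rarefy(cohort.table, 2000, seed=42)
        b = rarefy(cohort.table, 2000, seed=42)
        assert a == b

    def test_hypergeometric_expectation(self):
        # E[rarefied count_i] = depth * count_i / total
        counts = np.array([10, 10, 20])
        t = _table({"s": counts})
        acc = np.zeros(3)
        n_rep = 500
        for seed in range(n_rep):
            acc += rarefy(t, 20, seed=seed).counts["s"].reindex(
                t.counts.index, fill_value=0).to_numpy()
        mean = acc / n_rep
        expected = 20 * counts / counts.sum()
        # hypergeometric sd per draw <= ~1.6; 4 sigma band on the mean
        se = 1.6 / np.sqrt(n_rep)
        assert np.all(np.abs(mean - expected) < 4 * se + 0.2)

    def test_nonpositive_depth_rejected(self):
        with pytest.raises(MicrostabError):
            rarefy(_table({"s": [10]}), 0)


class TestShannonSimpson:
    def test_single_feature_zero_entropy(self):
        assert shannon([0, 7, 0]) == 0.0
        assert inverse_simpson([0, 7, 0]) == pytest.approx(1.0)

    def test_uniform_maximum(self):
        assert shannon([3, 3, 3, 3]) == pytest.approx(np.log(4))
        assert inverse_simpson([3, 3, 3, 3]) == pytest.approx(4.0)

    def test_hand_values(self):
        assert shannon([1, 1, 2]) == pytest.approx(1.0397, abs=1e-4)
        assert inverse_simpson([2, 1, 1]) == pytest.approx(8 / 3)

    def test_invariant_to_permutation_and_scaling(self):
        v = np.array([5, 1, 9, 3])
        assert shannon(v) == pytest.approx(shannon(v[::-1]))
        assert shannon(v) == pytest.approx(shannon(10 * v))
        assert inverse_simpson(v) == pytest.approx(inverse_simpson(7 * v[::-1]))

    def test_zero_sum_rejected(self):
        with pytest.raises(MicrostabError):
            shannon([0, 0])


class TestFaithPD:
    def test_single_taxon_root_inclusive(self, simple_tree):
        assert faith_pd([1, 0, 0], ["A", "B", "C"], simple_tree) == 2.0

    def test_full_tree(self, simple_tree):
        assert faith_pd([1, 1, 1], ["A", "B", "C"], simple_tree) == 5.0

    def test_empty_sample_zero(self, simple_tree):
        assert faith_pd([0, 0, 0], ["A", "B", "C"], simple_tree) == 0.0

    def test_root_exclusive_variant(self, simple_tree):
        assert faith_pd([1, 0, 0], ["A", "B", "C"], simple_tree,
                        include_root=False) == 0.0
        assert faith_pd([1, 1, 0], ["A", "B", "C"], simple_tree,
                        include_root=False) == 2.0

    def test_monotone_in_added_taxa(self, simple_tree):
        pd_a = faith_pd([1, 0, 0], ["A", "B", "C"], simple_tree)
        pd_ab = faith_pd([1, 1, 0], ["A", "B", "C"], simple_tree)
        pd_abc = faith_pd([1, 1, 1], ["A", "B", "C"], simple_tree)
        assert pd_a <= pd_ab <= pd_abc

    def test_matches_skbio(self, cohort):
        from skbio.diversity.alpha import faith_pd as skbio_pd
        rng = np.random.default_rng(0)
        fids = cohort.table.feature_ids
        for _ in range(5):
            counts = rng.integers(0, 3, size=len(fids))
            mine = faith_pd(counts, fids, cohort.tree)
            ref = skbio_pd(counts, taxa=fids, tree=cohort.tree)
            assert mine == pytest.approx(ref)

    def test_missing_feature_rejected(self, simple_tree):
        with pytest.raises(MicrostabError, match="absent"):
            faith_pd([1], ["Z"], simple_tree)


class TestJSD:
    def test_identical_distributions_zero(self):
        assert jsd([0.2, 0.8], [0.2, 0.8]) == 0.0

    def test_disjoint_supports_maximal(self):
        assert jsd([1, 0], [0, 1]) == pytest.approx(LN2)

    def test_hand_value(self):
        assert jsd([1, 0], [0.5, 0.5]) == pytest.approx(0.2158, abs=1e-4)

    def test_symmetry_and_bounds(self):
        rng = np.random.default_rng(4)
        for _ in range(20):
            p = rng.dirichlet(np.ones(6))
            q = rng.dirichlet(np.ones(6))
            assert jsd(p, q) == pytest.approx(jsd(q, p))
            assert 0 <= jsd(p, q) <= LN2

    def test_matches_scipy(self):
        rng = np.random.default_rng(8)
        p, q = rng.dirichlet(np.ones(5)), rng.dirichlet(np.ones(5))
        assert jsd(p, q) == pytest.approx(jensenshannon(p, q, base=np.e) ** 2)

    def test_base_two_rescales_to_unit_range(self):
        assert jsd([1, 0], [0, 1], base=2) == pytest.approx(1.0)

    def test_matrix_consistent_with_pairwise(self):
        t = _table({"s1": [5, 5, 0], "s2": [1, 1, 8], "s3": [0, 0, 10]})
        dm = jsd_matrix(t)
        rel = t.relative_abundance()
        for i, a in enumerate(t.sample_ids):
            for j, b in enumerate(t.sample_ids):
                assert dm.data[i, j] == pytest.approx(
                    jsd(rel[a], rel[b]), abs=1e-12)


class TestGeneralizedUniFrac:
    def test_identical_samples_zero(self, simple_tree):
        t = _table({"s1": [5, 5, 5], "s2": [5, 5, 5]}, index=["A", "B", "C"])
        dm = generalized_unifrac(t, simple_tree)
        assert dm.data[0, 1] == pytest.approx(0.0)

    def test_star_tree_disjoint_taxa_maximal(self):
        tree = read_tree("(A:1,B:1,C:1,D:1);")
        t = _table({"s1": [5, 5, 0, 0], "s2": [0, 0, 5, 5]},
                   index=["A", "B", "C", "D"])
        for alpha in (0.0, 0.5, 1.0):
            dm = generalized_unifrac(t, tree, alpha=alpha)
            assert dm.data[0, 1] == pytest.approx(1.0)

    def test_alpha_one_equals_weighted_normalized_unifrac(self):
        from microstab.simulate import _simulate_tree
        from skbio.diversity import beta_diversity
        rng = np.random.default_rng(17)
        ids = [f"L{i}" for i in range(8)]
        inv = {"asv_ids": ids, "genus_of": [f"g{i % 3}" for i in range(8)]}
        for _ in range(5):
            tree = _simulate_tree(inv, rng)
            counts = rng.integers(0, 40, size=(8, 4)) + (
                rng.random((8, 4)) < 0.5)
            counts[0] += 1
            t = _table({f"s{j}": counts[:, j].astype(int) for j in range(4)},
                       index=ids)
            mine = generalized_unifrac(t, tree, alpha=1.0)
            ref = beta_diversity(
                "weighted_unifrac", t.counts.T.to_numpy(), ids=t.sample_ids,
                tree=tree, taxa=ids, normalized=True)
            np.testing.assert_allclose(mine.data, ref.data, atol=1e-10)

    def test_invariant_to_child_order_rotation(self):
        t = _table({"s1": [9, 1, 3], "s2": [1, 6, 2]}, index=["A", "B", "C"])
        d1 = generalized_unifrac(t, read_tree("((A:1,B:2):1,C:3);")).data
        d2 = generalized_unifrac(t, read_tree("(C:3,(B:2,A:1):1);")).data
        np.testing.assert_allclose(d1, d2, atol=1e-12)

    def test_distance_axioms_on_cohort(self, small_cohort):
        rt = rarefy(small_cohort.table, 2000, seed=0)
        sub = rt.filter_samples(rt.sample_ids[:20]).drop_empty_features()
        dm = generalized_unifrac(sub, small_cohort.tree, alpha=0.5)
        assert np.all(dm.data >= 0)
        assert np.allclose(dm.data, dm.data.T)
        assert np.allclose(np.diag(dm.data), 0)

    def test_zero_read_sample_rejected(self, simple_tree):
        t = _table({"s1": [1, 1, 1], "s2": [0, 0, 0]}, index=["A", "B", "C"])
        with pytest.raises(MicrostabError, match="zero"):
            generalized_unifrac(t, simple_tree)


class TestPCoA:
    def test_collinear_points_recovered(self):
        d = np.array([[0, 1, 2], [1, 0, 1], [2, 1, 0]], dtype=float)
        res = pcoa(DistanceMatrix(["a", "b", "c"], d))
        assert res.coordinates.shape[1] == 1
        rec = squareform(pdist(res.coordinates))
        np.testing.assert_allclose(rec, d, atol=1e-9)

    def test_zero_distances_give_zero_coordinates(self):
        d = np.zeros((3, 3))
        res = pcoa(DistanceMatrix(["a", "b", "c"], d))
        assert res.coordinates.shape[1] == 0

    def test_euclidean_cloud_self_consistency(self):
        rng = np.random.default_rng(12)
        pts = rng.normal(size=(10, 4))
        d = squareform(pdist(pts))
        res = pcoa(DistanceMatrix([f"s{i}" for i in range(10)], d))
        rec = squareform(pdist(res.coordinates))
        np.testing.assert_allclose(rec, d, atol=1e-8)
        assert np.all(np.diff(res.eigenvalues) <= 1e-9)
        assert res.proportion_explained.sum() <= 1 + 1e-9

    def test_matches_skbio_proportions(self):
        import warnings as _w
        from skbio.stats.ordination import pcoa as skbio_pcoa
        rng = np.random.default_rng(2)
        pts = rng.normal(size=(8, 3))
        d = squareform(pdist(pts))
        dm = DistanceMatrix([f"s{i}" for i in range(8)], d)
        mine = pcoa(dm)
        with _w.catch_warnings():
            _w.simplefilter("ignore")
            ref = skbio_pcoa(dm.to_skbio())
        np.testing.assert_allclose(
            mine.proportion_explained[:5],
            ref.proportion_explained.to_numpy()[:5], atol=1e-8)


def test_alpha_table_includes_pd_only_with_tree(tiny_table, simple_tree):
    no_tree = alpha_diversity_table(tiny_table)
    assert list(no_tree.columns) == ["shannon", "inv_simpson"]
    with_tree = alpha_diversity_table(tiny_table, simple_tree)
    assert "faith_pd" in with_tree.columns
    # spot check one sample against the scalar functions
    col = tiny_table.counts["s1"].to_numpy()
    assert with_tree.loc["s1", "shannon"] == pytest.approx(shannon(col))
    assert with_tree.loc["s1", "faith_pd"] == pytest.approx(
        faith_pd(col, tiny_table.feature_ids, simple_tree))
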