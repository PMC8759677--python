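import numpy as np
import pandas as pd
import pytest

from microstab.decontam import (call_contaminants, contaminant_dna_correlation,
                                flagged_ids, remove_contaminants)
from microstab.errors import MicrostabError
from microstab.io import FeatureTable, SampleMetadata


def _make(counts: dict, types: dict, dna: dict | None = None):
    df = pd.DataFrame(counts)
    table = FeatureTable(df, pd.Series("unclassified", index=df.index))
    rows = []
    for s in df.columns:
        rows.append({"sample_id": s, "volunteer_id": "X", "visit": "1",
                     "sample_type": types[s],
                     "dna_conc": (dna or {}).get(s, np.nan)})
    return table, SampleMetadata(pd.DataFrame(rows))


@pytest.fixture
def neg_control_table():
    # f_contam dominates all three controls; f_rare appears in 2/3
    counts = {
        "n1": [50, 40, 10],
        "n2": [60, 40, 0],
        "n3": [70, 30, 0],
        "r1": [5, 0, 95],
        "r2": [0, 2, 98],
    }
    df = pd.DataFrame(counts, index=["f_contam", "f_mid", "f_rare"])
    table = FeatureTable(df, pd.Series("unclassified", index=df.index))
    meta = SampleMetadata(pd.DataFrame({
        "sample_id": ["n1", "n2", "n3", "r1", "r2"],
        "volunteer_id": ["c"] * 3 + ["A", "B"],
        "visit": ["1"] * 5,
        "sample_type": ["neg_control"] * 3 + ["CU", "CU"],
    }))
    return table, meta


class TestCallContaminants:
    def test_clearly_contaminated_feature_flagged(self):
        table, meta = _make(
            {"n1": [10, 90], "n2": [20, 80], "n3": [30, 70], "r": [1, 99]},
            {"n1": "neg_control", "n2": "neg_control", "n3": "neg_control",
             "r": "CU"})
        calls = {c.feature_id: c for c in call_contaminants(table, meta)}
        c = calls[table.feature_ids[0]]
        assert c.flagged
        assert c.mean_abund_neg == pytest.approx(0.20)
        assert c.prevalence_neg == 1.0
        assert c.max_abund_neg == pytest.approx(0.30)

    def test_presence_in_all_controls_required_under_and(self, neg_control_table):
        table, meta = neg_control_table
        calls = {c.feature_id: c for c in call_contaminants(table, meta)}
        assert calls["f_contam"].flagged
        # present in only 1/3 controls at 10% -> fails the prevalence criterion
        assert calls["f_rare"].prevalence_neg == pytest.approx(1 / 3)
        assert not calls["f_rare"].flagged

    def test_or_combination_is_superset_of_and(self, neg_control_table):
        table, meta = neg_control_table
        and_ids = set(flagged_ids(call_contaminants(table, meta, combine="and")))
        or_ids = set(flagged_ids(call_contaminants(table, meta, combine="or")))
        assert and_ids <= or_ids
        assert "f_rare" in or_ids  # max 10% > 5% triggers OR

    def test_flagging_monotone_in_thresholds(self, neg_control_table):
        table, meta = neg_control_table
        base = set(flagged_ids(call_contaminants(table, meta)))
        looser = set(flagged_ids(call_contaminants(
            table, meta,
            thresholds={"mean": 0.0001, "prevalence": 0.3, "max_single": 0.01})))
        assert base <= looser

    def test_no_negative_controls_is_error(self):
        table, meta = _make({"r": [1, 2]}, {"r": "CU"})
        with pytest.raises(MicrostabError, match="negative"):
            call_contaminants(table, meta)

    def test_zero_read_control_excluded_with_warning(self):
        table, meta = _make(
            {"n1": [10, 90], "n2": [0, 0], "r": [1, 99]},
            {"n1": "neg_control", "n2": "neg_control", "r": "CU"})
        with pytest.warns(UserWarning, match="zero reads"):
            calls = call_contaminants(table, meta)
        # criteria computed from the single usable control
        assert all(c.prevalence_neg in (0.0, 1.0) for c in calls)


class TestRemoveContaminants:
    def test_nothing_flagged_is_identity(self, neg_control_table):
        table, meta = neg_control_table
        calls = call_contaminants(
            table, meta, thresholds={"mean": 0.99, "max_single": 0.99})
        out, report = remove_contaminants(table, calls)
        assert out == table
        assert (report["reads_removed"] == 0).all()

    def test_unflagged_counts_conserved_exactly(self, neg_control_table):
        table, meta = neg_control_table
        calls = call_contaminants(table, meta)
        out, report = remove_contaminants(table, calls)
        kept = [f for f in table.feature_ids if f not in flagged_ids(calls)]
        pd.testing.assert_frame_equal(out.counts, table.counts.loc[kept])
        expected_removed = table.counts.loc[flagged_ids(calls)].sum(axis=0)
        pd.testing.assert_series_equal(
            report["reads_removed"], expected_removed,
            check_names=False)

    def test_all_flagged_is_error(self):
        table, meta = _make({"n1": [100], "r": [100]},
                            {"n1": "neg_control", "r": "CU"})
        calls = call_contaminants(table, meta)
        assert flagged_ids(calls) == table.feature_ids
        with pytest.raises(MicrostabError, match="empty table"):
            remove_contaminants(table, calls)

    def test_unknown_feature_in_call_is_error(self, neg_control_table):
        table, meta = neg_control_table
        calls = call_contaminants(table, meta)
        calls[0].feature_id = "ghost"
        with pytest.raises(MicrostabError, match="unknown feature"):
            remove_contaminants(table, calls)


class TestDnaCorrelation:
    def test_inverse_biomass_contamination_gives_negative_r(self):
        # contaminant fraction proportional to 1/dna over 6 samples
        dna = {f"s{i}": float(i) for i in range(1, 7)}
        counts = {}
        for i in range(1, 7):
            contam = int(round(1000 / i))
            counts[f"s{i}"] = [contam, 1000 - contam + 200]
        counts["n1"] = [95, 5]
        types = {s: "CU" for s in dna}
        types["n1"] = "neg_control"
        table, meta = _make(counts, types, dna)
        calls = call_contaminants(table, meta)
        assert flagged_ids(calls) == [table.feature_ids[0]]
        r, lo, hi, n = contaminant_dna_correlation(table, calls, meta)
        assert r < 0
        assert lo < r < hi
        assert n == 6

    def test_constant_contaminant_abundance_is_error(self):
        dna = {f"s{i}": float(i) for i in range(1, 6)}
        counts = {f"s{i}": [50, 50] for i in range(1, 6)}
        counts["n1"] = [100, 0]
        types = {s: "CU" for s in dna}
        types["n1"] = "neg_control"
        table, meta = _make(counts, types, dna)
        calls = call_contaminants(table, meta)
        with pytest.raises(MicrostabError, match="constant"):
            contaminant_dna_correlation(table, calls, meta)

    def test_planted_contaminants_recovered_on_synthetic_cohort(self, cohort):
        calls = call_contaminants(cohort.table, cohort.metadata)
        assert sorted(flagged_ids(calls)) == sorted(
            cohort.ground_truth.contaminant_ids)
        out, report = remove_contaminants(cohort.table, calls)
        # per-sample totals drop by exactly the planted contaminant reads
        for sid, n_cont in cohort.ground_truth.contaminant_reads.items():
            assert report.loc[sid, "reads_removed"] == n_cont
        r, _, _, _ = contaminant_dna_correlation(
            cohort.table, calls, cohort.metadata, sample_types=("CU",))
        assert r < 0
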