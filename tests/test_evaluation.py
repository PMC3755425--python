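import numpy as np
import pytest
from hypothesis import given, settings
from hypothesis import strategies as st

from enrichdag.dagging import DaggingConfig
from enrichdag.datasets import LabeledDataset
from enrichdag.enrichment import FeatureMatrix
from enrichdag.evaluation import (
    REFERENCE_BENCHMARK,
    REFERENCE_N_NEG,
    REFERENCE_N_POS,
    ConfusionMatrix,
    IFSTable,
    MetricsRow,
    cross_validate,
    metrics_from_counts,
    reconstruct_counts,
    reference_benchmark_rows,
    run_ifs,
    summarize_metrics,
    term_category_report,
    union_optimal,
)
from enrichdag.io import AnnotationCatalog, OntologyDAG
from enrichdag.selection import RankedFeatures


class TestMetricsFromCounts:
    def test_benchmark_dataset1_counts(self):
        m = metrics_from_counts(ConfusionMatrix(TP=63, TN=511, FP=39, FN=47))
        assert m.Sn == pytest.approx(0.5727, abs=5e-5)
        assert m.Sp == pytest.approx(0.9291, abs=5e-5)
        assert m.Acc == pytest.approx(0.8697, abs=5e-5)
        assert m.MCC == pytest.approx(0.5174, abs=5e-5)

    def test_perfect_classifier(self):
        m = metrics_from_counts(ConfusionMatrix(10, 10, 0, 0))
        assert (m.Sn, m.Sp, m.Acc, m.MCC) == (1.0, 1.0, 1.0, 1.0)

    def test_chance_table(self):
        m = metrics_from_counts(ConfusionMatrix(5, 5, 5, 5))
        assert m.Acc == pytest.approx(0.5)
        assert m.MCC == pytest.approx(0.0, abs=1e-12)

    def test_zero_denominators_resolve_to_zero(self):
        m = metrics_from_counts(ConfusionMatrix(TP=0, TN=5, FP=0, FN=0))
        assert m.Sn == 0.0 and m.MCC == 0.0

    def test_negative_counts_rejected(self):
        with pytest.raises(ValueError):
            ConfusionMatrix(-1, 0, 0, 0)

    @settings(deadline=None, max_examples=200, derandomize=True)
    @given(st.tuples(*[st.integers(0, 500)] * 4))
    def test_mcc_bounds_on_random_tables(self, counts):
        tp, tn, fp, fn = counts
        if tp + tn + fp + fn == 0:
            return
        m = metrics_from_counts(ConfusionMatrix(tp, tn, fp, fn))
        assert -1.0 - 1e-12 <= m.MCC <= 1.0 + 1e-12
        assert 0.0 <= m.Acc <= 1.0

    def test_mcc_one_iff_no_errors_both_classes(self):
        assert metrics_from_counts(ConfusionMatrix(7, 3, 0, 0)).MCC == pytest.approx(1.0)
        assert metrics_from_counts(ConfusionMatrix(7, 3, 1, 0)).MCC < 1.0


class TestReconstructCounts:
    def test_dataset1(self):
        cm = reconstruct_counts(0.5727, 0.9291, 110, 550)
        assert (cm.TP, cm.TN, cm.FP, cm.FN) == (63, 511, 39, 47)

    def test_perfect(self):
        cm = reconstruct_counts(1.0, 1.0, 10, 10)
        assert (cm.TP, cm.TN, cm.FP, cm.FN) == (10, 10, 0, 0)

    def test_dataset7(self):
        cm = reconstruct_counts(0.5545, 0.9527, 110, 550)
        # FP = 550 - 524 = 26 missed negatives, FN = 110 - 61 = 49
        assert (cm.TP, cm.TN, cm.FP, cm.FN) == (61, 524, 26, 49)

    @pytest.mark.parametrize("row", REFERENCE_BENCHMARK, ids=lambda r: f"dataset{r[0]}")
    def test_benchmark_rows_internally_consistent(self, row):
        """Each published row's Acc and MCC follow from its Sn/Sp at 4 dp."""
        _, _, sn, sp, acc, mcc = row
        cm = reconstruct_counts(sn, sp, REFERENCE_N_POS, REFERENCE_N_NEG)
        m = metrics_from_counts(cm)
        assert m.Sn == pytest.approx(sn, abs=5e-5)
        assert m.Sp == pytest.approx(sp, abs=5e-5)
        assert m.Acc == pytest.approx(acc, abs=5e-5)
        assert m.MCC == pytest.approx(mcc, abs=5e-5)


class TestSummarize:
    def test_benchmark_summary_row(self):
        s = summarize_metrics(reference_benchmark_rows())
        assert s["Acc"][0] == pytest.approx(0.8755, abs=5e-5)
        assert s["Acc"][1] == pytest.approx(0.0113, abs=5e-5)
        assert s["Sn"][0] == pytest.approx(0.6127, abs=5e-5)

    def test_identical_rows_sd_zero(self):
        rows = [MetricsRow(0.5, 0.5, 0.5, 0.5)] * 3
        s = summarize_metrics(rows)
        assert all(v[1] == 0.0 for v in s.values())

    def test_single_row_rejected(self):
        with pytest.raises(ValueError):
            summarize_metrics([MetricsRow(1, 1, 1, 1)])


def _dataset_from_feature(f, y, extra=None):
    cols = [np.asarray(f, dtype=float)]
    if extra is not None:
        cols.extend(np.asarray(e, dtype=float) for e in extra)
    X = np.column_stack(cols)
    fm = FeatureMatrix(
        [f"g{i}" for i in range(len(y))],
        [f"t{j}" for j in range(X.shape[1])],
        np.abs(X),
        ["BP"] * X.shape[1],
    )
    return LabeledDataset(matrix=fm, labels=np.asarray(y), dataset_index=1)


class TestCrossValidate:
    def test_label_copy_feature_gives_mcc_one(self):
        y = np.array([1] * 20 + [0] * 40)
        ds = _dataset_from_feature(y * 5.0, y)
        m = cross_validate(ds, [0], DaggingConfig(k=3, seed=0), folds=5, seed=0)
        assert m.MCC == pytest.approx(1.0)

    def test_shuffled_labels_near_chance(self):
        rng = np.random.default_rng(0)
        mccs = []
        for s in range(20):
            y = np.array([1] * 30 + [0] * 90)
            f = rng.permutation(np.abs(rng.normal(size=120)))
            ds = _dataset_from_feature(f, y)
            m = cross_validate(ds, [0], DaggingConfig(k=3, seed=s), folds=5, seed=s)
            mccs.append(m.MCC)
        assert np.abs(np.mean(mccs)) < 0.15

    def test_deterministic(self):
        y = np.array([1] * 15 + [0] * 45)
        rng = np.random.default_rng(1)
        f = np.abs(rng.normal(size=60)) + y
        ds = _dataset_from_feature(f, y)
        a = cross_validate(ds, [0], DaggingConfig(k=3, seed=2), folds=5, seed=3)
        b = cross_validate(ds, [0], DaggingConfig(k=3, seed=2), folds=5, seed=3)
        assert a == b

    def test_minority_smaller_than_folds_rejected(self):
        y = np.array([1] * 3 + [0] * 30)
        ds = _dataset_from_feature(np.ones(33), y)
        with pytest.raises(ValueError, match="stratify"):
            cross_validate(ds, [0], folds=5, seed=0)


class TestRunIFS:
    def _ranked(self, n):
        return RankedFeatures(
            maxrel_order=list(range(n)), mrmr_order=list(range(n)), relevance=np.zeros(n)
        )

    def test_perfect_first_feature_optimal_d_one(self):
        rng = np.random.default_rng(5)
        y = np.array([1] * 20 + [0] * 40)
        noise = [np.abs(rng.normal(size=60)) for _ in range(3)]
        ds = _dataset_from_feature(y * 8.0, y, extra=noise)
        table = run_ifs(ds, self._ranked(4), DaggingConfig(k=3, seed=0), D_max=4, folds=5, seed=0)
        assert table.optimal_d == 1
        assert table.optimal_metrics.MCC == pytest.approx(1.0)

    def test_dmax_one_single_record(self):
        y = np.array([1] * 10 + [0] * 20)
        ds = _dataset_from_feature(y * 2.0, y)
        table = run_ifs(ds, self._ranked(1), DaggingConfig(k=2, seed=0), D_max=1, folds=5, seed=0)
        assert len(table.records) == 1 and table.optimal_d == 1

    def test_redundant_label_copies_stay_perfect(self):
        y = np.array([1] * 10 + [0] * 20)
        ds = _dataset_from_feature(y * 3.0, y, extra=[y * 3.0, y * 3.0])
        table = run_ifs(ds, self._ranked(3), DaggingConfig(k=2, seed=0), D_max=3, folds=5, seed=0)
        assert all(r.metrics.MCC == pytest.approx(1.0) for r in table.records)

    def test_csv_output(self, tmp_path):
        y = np.array([1] * 10 + [0] * 20)
        ds = _dataset_from_feature(y * 2.0, y)
        table = run_ifs(ds, self._ranked(1), DaggingConfig(k=2, seed=0), D_max=1, folds=5, seed=0)
        out = tmp_path / "ifs.csv"
        table.to_csv(out)
        assert out.read_text().splitlines()[0] == "d,Sn,Sp,Acc,MCC"


class TestUnionOptimal:
    def _cat(self):
        cat = AnnotationCatalog()
        cat.add("g", "GO:a", "BP")
        cat.add("g", "GO:b", "BP")
        cat.add("g", "GO:c", "MF")
        cat.add("g", "hsa1", "KEGG")
        return cat

    def test_simple_union(self):
        res = union_optimal([["GO:a", "GO:b"], ["GO:b", "GO:c"]], self._cat())
        assert res.union == ["GO:a", "GO:b", "GO:c"]
        assert res.namespace_counts == {"BP": 2, "MF": 1}

    def test_single_dataset_identity(self):
        res = union_optimal([["hsa1", "GO:a"]], self._cat())
        assert res.union == ["GO:a", "hsa1"]
        assert res.namespace_counts == {"BP": 1, "KEGG": 1}

    def test_empty_input_rejected(self):
        with pytest.raises(ValueError):
            union_optimal([], self._cat())


class TestTermCategoryReport:
    def _toy_dag(self):
        dag = OntologyDAG()
        dag.roots = {"root"}
        dag.parents = {
            "A": {"root"},
            "B": {"root"},
            "a1": {"A"},
            "a2": {"A"},
            "a3": {"A"},
            "b1": {"B"},
        }
        return dag

    def test_toy_counts_and_percentages(self):
        rows = term_category_report(["a1", "a2", "b1"], self._toy_dag())
        by_child = {r.child: r for r in rows}
        # category A = {A, a1, a2, a3} (4 members), 2 selected -> 50%
        assert by_child["A"].frequency == 2
        assert by_child["A"].category_size == 4
        assert by_child["A"].percentage == pytest.approx(50.0)
        # category B = {B, b1} (2 members), 1 selected -> 50%
        assert by_child["B"].frequency == 1
        assert by_child["B"].percentage == pytest.approx(50.0)

    def test_empty_selection_zero_frequencies(self):
        rows = term_category_report([], self._toy_dag())
        assert all(r.frequency == 0 for r in rows)

    def test_multiple_inheritance_counted_in_both(self):
        dag = self._toy_dag()
        dag.parents["ab"] = {"A", "B"}
        rows = term_category_report(["ab"], dag)
        by_child = {r.child: r for r in rows}
        assert by_child["A"].frequency == 1
        assert by_child["B"].frequency == 1

    def test_unknown_terms_flagged(self):
        rows = term_category_report(["nope"], self._toy_dag(), include_unknown=True)
        assert rows[-1].child == "(unknown)" and rows[-1].frequency == 1
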