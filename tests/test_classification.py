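"""Feature tables, stratified splits and the SVM evaluation harness."""

import numpy as np
import pytest

from mventropy import FeatureTable, ParameterError, evaluate, split


def make_table(n_per_class=50, n_features=3, gap=5.0, seed=0, classes=("a", "b")):
    rng = np.random.default_rng(seed)
    feats, labels, ids = [], [], []
    for c, name in enumerate(classes):
        feats.append(rng.normal(c * gap, 1.0, size=(n_per_class, n_features)))
        labels += [name] * n_per_class
        ids += [f"{name}{i}" for i in range(n_per_class)]
    return FeatureTable(ids=tuple(ids), labels=tuple(labels), features=np.vstack(feats))


class TestFeatureTable:
    def test_undefined_rows_excluded_and_counted(self):
        rows = np.array(
            [[1.0, 2.0], [np.nan, 1.0], [1.5, 2.5], [0.5, 0.5], [2.0, 1.0]]
        )
        table = FeatureTable.from_profiles(
            ["s0", "s1", "s4", "s2", "s3"], ["a", "a", "a", "b", "b"], rows
        )
        assert len(table) == 4
        assert table.n_excluded == 1
        assert "s1" not in table.ids

    def test_nan_features_rejected_in_direct_construction(self):
        with pytest.raises(ParameterError):
            FeatureTable(("a", "b"), ("x", "y"), np.array([[np.nan], [1.0]]))

    def test_minimum_class_requirements(self):
        with pytest.raises(ParameterError):
            FeatureTable(("a", "b"), ("x", "x"), np.zeros((2, 1)))
        with pytest.raises(ParameterError):
            FeatureTable(("a", "b", "c"), ("x", "x", "y"), np.zeros((3, 1)))


class TestSplit:
    def test_sizes_disjoint_exhaustive(self):
        table = make_table(50)
        splits = split(table, train_frac=0.75, n_repeats=5, seed=1)
        assert len(splits) == 5
        for train, test in splits:
            assert len(train) == 75 and len(test) == 25
            assert set(train).isdisjoint(test)
            assert set(train) | set(test) == set(range(100))

    def test_stratification_preserved(self):
        table = make_table(40)
        labels = np.asarray(table.labels)
        for train, test in split(table, 0.75, 3, seed=0):
            assert (labels[test] == "a").sum() == 10
            assert (labels[train] == "a").sum() == 30

    def test_determinism(self):
        table = make_table(20)
        a = split(table, 0.75, 4, seed=7)
        b = split(table, 0.75, 4, seed=7)
        for (ta, sa), (tb, sb) in zip(a, b):
            np.testing.assert_array_equal(ta, tb)
            np.testing.assert_array_equal(sa, sb)

    def test_empty_test_rejected(self):
        table = make_table(2)
        with pytest.raises(ParameterError):
            split(table, train_frac=0.99, n_repeats=1)
        with pytest.raises(ParameterError):
            split(table, train_frac=1.5, n_repeats=1)


class TestEvaluate:
    def test_separable_classes_reach_full_accuracy(self):
        report = evaluate(make_table(gap=10.0), n_repeats=5, seed=3)
        assert report.accuracies == (100.0,) * 5
        assert report.mean_accuracy == 100.0

    def test_mean_is_arithmetic_mean_and_bounded(self):
        report = evaluate(make_table(gap=0.5, seed=2), n_repeats=5, seed=2)
        assert report.mean_accuracy == pytest.approx(np.mean(report.accuracies))
        assert all(0.0 <= a <= 100.0 for a in report.accuracies)

    def test_row_order_invariance(self):
        table = make_table(gap=1.0, seed=4)
        rng = np.random.default_rng(0)
        perm = rng.permutation(len(table))
        shuffled = FeatureTable(
            ids=tuple(np.asarray(table.ids)[perm]),
            labels=tuple(np.asarray(table.labels)[perm]),
            features=table.features[perm],
        )
        a = evaluate(table, n_repeats=3, seed=9)
        b = evaluate(shuffled, n_repeats=3, seed=9)
        assert a.accuracies == b.accuracies

    def test_linear_kernel_option(self):
        report = evaluate(make_table(gap=10.0), kernel="linear", n_repeats=2, seed=0)
        assert report.mean_accuracy == 100.0
        assert "linear" in report.classifier
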