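import numpy as np
import pytest

from chemotrace.preprocessing import sg_filter
from chemotrace.synthetic_data import generate_dataset
from chemotrace.validation import (
    ConfusionMatrix,
    component_scan,
    confusion_matrix,
    confusion_metrics,
    loo_cv,
    roc_auc,
)

from conftest import small_signal_design
from oracles import pair_count_auc


@pytest.fixture(scope="module")
def processed_signal():
    return sg_filter(generate_dataset(small_signal_design(seed=4)))


class TestConfusionMetrics:
    def test_two_class_hand_computation(self):
        cm = ConfusionMatrix(["a", "b"], [[3, 1], [1, 5]])
        m = confusion_metrics(cm)
        assert m.per_class.loc["a", "precision"] == pytest.approx(0.75)
        assert m.per_class.loc["a", "sensitivity"] == pytest.approx(0.75)
        assert m.per_class.loc["a", "specificity"] == pytest.approx(5 / 6)
        assert m.accuracy == pytest.approx(0.8)

    def test_three_class_hand_computation(self):
        cm = ConfusionMatrix(["x", "y", "z"], [[5, 2, 0], [1, 6, 1], [0, 2, 7]])
        m = confusion_metrics(cm)
        expected = {
            "x": (5 / 6, 5 / 7, 16 / 17),
            "y": (6 / 10, 6 / 8, 12 / 16),
            "z": (7 / 8, 7 / 9, 14 / 15),
        }
        for label, (prec, sens, spec) in expected.items():
            assert m.per_class.loc[label, "precision"] == pytest.approx(prec)
            assert m.per_class.loc[label, "sensitivity"] == pytest.approx(sens)
            assert m.per_class.loc[label, "specificity"] == pytest.approx(spec)
        assert m.accuracy == pytest.approx(18 / 24)

    def test_diagonal_matrix_is_perfect(self):
        m = confusion_metrics(ConfusionMatrix(["a", "b", "c"], np.diag([4, 5, 6])))
        assert (m.per_class.to_numpy() == 1.0).all()
        assert m.accuracy == 1.0 and m.undefined == []

    def test_never_assigned_class_flags_undefined_precision(self):
        cm = ConfusionMatrix(["a", "b"], [[0, 4], [0, 6]])
        m = confusion_metrics(cm)
        assert np.isnan(m.per_class.loc["a", "precision"])
        assert ("a", "precision") in m.undefined

    def test_empty_matrix_rejected(self):
        with pytest.raises(ValueError):
            confusion_metrics(ConfusionMatrix(["a", "b"], np.zeros((2, 2))))


class TestROC:
    def test_perfect_separation(self):
        curve = roc_auc([3.0, 2.5, 1.0, 0.5], [True, True, False, False])
        assert curve.auc == 1.0

    def test_complete_ties(self):
        curve = roc_auc([1.0] * 6, [True, False] * 3)
        assert curve.auc == 0.5 and curve.p_value == 1.0

    def test_reversed_scores(self):
        curve = roc_auc([0.1, 0.2, 0.8, 0.9], [True, True, False, False])
        assert curve.auc == 0.0

    @pytest.mark.parametrize("seed", range(10))
    def test_pair_counting_oracle(self, seed):
        rng = np.random.default_rng(seed)
        n = int(rng.integers(5, 30))
        scores = rng.choice([0.0, 0.25, 0.5, 0.9, 1.3], size=n)  # forced ties
        positives = rng.random(n) < 0.5
        if positives.all() or not positives.any():
            positives[0] = ~positives[0]
        curve = roc_auc(scores, positives)
        assert curve.auc == pytest.approx(pair_count_auc(scores, positives), abs=1e-12)
        assert 0 < curve.p_value <= 1

    def test_curve_invariants(self):
        rng = np.random.default_rng(1)
        scores = rng.normal(0, 1, 40)
        positives = rng.random(40) < 0.4
        curve = roc_auc(scores, positives)
        assert (np.diff(curve.fpr) >= 0).all() and (np.diff(curve.tpr) >= 0).all()
        assert (curve.fpr[0], curve.tpr[0]) == (0.0, 0.0)
        assert (curve.fpr[-1], curve.tpr[-1]) == (1.0, 1.0)
        assert curve.auc == pytest.approx(np.trapezoid(curve.tpr, curve.fpr))

    def test_single_class_rejected(self):
        with pytest.raises(ValueError):
            roc_auc([1.0, 2.0], [True, True])


class TestLOOCV:
    def test_confusion_totals_conserved(self, processed_signal):
        report = loo_cv(processed_signal)
        assert report.confusion.total == processed_signal.n
        row_sums = report.confusion.counts.sum(axis=1)
        for label, expected in zip(
            report.confusion.class_labels, row_sums
        ):
            assert expected == (processed_signal.origins == label).sum()

    def test_high_snr_accuracy(self, processed_signal):
        report = loo_cv(processed_signal)
        assert report.accuracy >= 0.9
        assert all(curve.auc > 0.9 for curve in report.roc)
        assert 0 < report.r2 <= 1 and report.q2 <= 1

    def test_order_invariance(self, processed_signal):
        rng = np.random.default_rng(0)
        perm = rng.permutation(processed_signal.n)
        shuffled = processed_signal.subset(perm)
        a = loo_cv(processed_signal)
        b = loo_cv(shuffled)
        np.testing.assert_array_equal(a.confusion.counts, b.confusion.counts)
        assert a.q2 == pytest.approx(b.q2, rel=1e-9)
        assert a.r2 == pytest.approx(b.r2, rel=1e-9)

    def test_r2_monotone_in_components(self, processed_signal):
        r2s = [loo_cv(processed_signal, A=A).r2 for A in (1, 2, 3, 4)]
        assert all(b >= a - 1e-10 for a, b in zip(r2s, r2s[1:]))

    def test_singleton_class_fold_warns_but_completes(self):
        s = generate_dataset(small_signal_design(k=3, reps=5, p=100, seed=9))
        keep = np.ones(s.n, dtype=bool)
        lone_class = s.origins == "class_3"
        keep[np.flatnonzero(lone_class)[1:]] = False  # keep one class_3 sample
        reduced = sg_filter(s.subset(keep))
        report = loo_cv(reduced, A=1)
        assert report.fold_warnings  # the fold that drops class_3 is recorded
        assert report.confusion.total == reduced.n


class TestComponentScan:
    def test_rows_cover_1_to_k_minus_1(self, processed_signal):
        scan = component_scan(processed_signal)
        k = len(processed_signal.class_labels)
        assert scan.table["A"].tolist() == list(range(1, k))
        assert scan.a_default == k - 1
        assert {"accuracy", "r2", "q2", "mean_auc"} <= set(scan.table.columns)

    def test_single_row_scan(self, processed_signal):
        scan = component_scan(processed_signal, A_max=1)
        assert len(scan.table) == 1 and scan.a_best_q2 == 1
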