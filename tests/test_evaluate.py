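"""Metric formulas, median post-filter and k-fold cross-validation."""

import numpy as np
import pytest
from hypothesis import given, strategies as st

from cowfeed import (
    CNNClassifier,
    compute_metrics,
    confusion_from_predictions,
    evaluate_predictions,
    kfold_cross_validate,
    median_postfilter,
)


def brute_force_metrics(cm):
    """Independent per-class evaluation straight from the definitions."""
    cm = np.asarray(cm, dtype=float)
    out = {"precision": [], "recall": [], "f1": []}
    for i in range(3):
        tp = cm[i, i]
        fp = sum(cm[j, i] for j in range(3) if j != i)
        fn = sum(cm[i, j] for j in range(3) if j != i)
        p = tp / (tp + fp) if tp + fp > 0 else 0.0
        r = tp / (tp + fn) if tp + fn > 0 else 0.0
        f = 2 * p * r / (p + r) if p + r > 0 else 0.0
        out["precision"].append(p)
        out["recall"].append(r)
        out["f1"].append(f)
    out["micro_precision"] = (cm[0, 0] + cm[1, 1] + cm[2, 2]) / cm.sum()
    out["macro_f1"] = sum(out["f1"]) / 3.0
    return out


class TestComputeMetrics:
    def test_perfect_diagonal_scores_one(self):
        rep = compute_metrics(np.diag([5, 7, 9]))
        assert rep.macro_f1 == 1.0
        assert rep.micro_precision == 1.0
        np.testing.assert_array_equal(rep.precision, [1, 1, 1])
        np.testing.assert_array_equal(rep.recall, [1, 1, 1])

    def test_specific_matrix_matches_brute_force(self):
        cm = np.array([[8, 1, 1], [2, 6, 2], [0, 1, 9]])
        rep = compute_metrics(cm)
        ref = brute_force_metrics(cm)
        np.testing.assert_allclose(rep.precision, ref["precision"])
        np.testing.assert_allclose(rep.recall, ref["recall"])
        np.testing.assert_allclose(rep.f1, ref["f1"])
        assert rep.macro_f1 == pytest.approx(ref["macro_f1"])
        assert rep.micro_precision == pytest.approx(ref["micro_precision"])

    def test_agrees_with_brute_force_on_random_matrices(self):
        rng = np.random.default_rng(0)
        for _ in range(1000):
            cm = rng.integers(0, 50, size=(3, 3))
            if cm.sum() == 0:
                continue
            rep = compute_metrics(cm)
            ref = brute_force_metrics(cm)
            np.testing.assert_allclose(rep.f1, ref["f1"])
            assert rep.macro_f1 == pytest.approx(ref["macro_f1"])
            assert rep.micro_precision == pytest.approx(ref["micro_precision"])

    def test_micro_precision_is_trace_over_total(self):
        rng = np.random.default_rng(1)
        for _ in range(100):
            cm = rng.integers(0, 100, size=(3, 3)) + 1
            rep = compute_metrics(cm)
            assert rep.micro_precision == pytest.approx(np.trace(cm) / cm.sum())

    def test_agrees_with_sklearn(self):
        """Cross-check against an established implementation."""
        from sklearn.metrics import precision_recall_fscore_support

        rng = np.random.default_rng(2)
        y_true = rng.integers(0, 3, 500)
        y_pred = rng.integers(0, 3, 500)
        rep = evaluate_predictions(y_true, y_pred)
        p, r, f, _ = precision_recall_fscore_support(
            y_true, y_pred, labels=[0, 1, 2], zero_division=0
        )
        np.testing.assert_allclose(rep.precision, p)
        np.testing.assert_allclose(rep.recall, r)
        np.testing.assert_allclose(rep.f1, f)

    def test_zero_denominator_convention(self):
        # class 2 never predicted nor present -> all zeros, not NaN
        cm = np.array([[5, 1, 0], [1, 5, 0], [0, 0, 0]])
        rep = compute_metrics(cm)
        assert rep.precision[2] == rep.recall[2] == rep.f1[2] == 0.0

    def test_empty_matrix_errors(self):
        with pytest.raises(ValueError, match="empty"):
            compute_metrics(np.zeros((3, 3), dtype=int))

    @given(st.permutations([0, 1, 2]), st.integers(0, 2**31 - 1))
    def test_macro_f1_invariant_under_class_permutation(self, perm, seed):
        rng = np.random.default_rng(seed)
        y_true = rng.integers(0, 3, 200)
        y_pred = rng.integers(0, 3, 200)
        perm = np.asarray(perm)
        a = evaluate_predictions(y_true, y_pred).macro_f1
        b = evaluate_predictions(perm[y_true], perm[y_pred]).macro_f1
        assert a == pytest.approx(b)

    def test_confusion_orientation(self):
        cm = confusion_from_predictions([0, 0, 1], [0, 2, 1])
        assert cm[0, 2] == 1  # true feeding predicted as other
        assert cm.sum() == 3


class TestMedianPostfilter:
    def test_constant_sequence_unchanged(self):
        x = [1] * 10
        np.testing.assert_array_equal(median_postfilter(x), x)

    def test_isolated_spike_removed(self):
        x = [1, 1, 1, 2, 1, 1, 1]
        np.testing.assert_array_equal(median_postfilter(x), [1] * 7)

    def test_edges_truncated_symmetrically(self):
        # positions 1 and n-2 use a length-3 window; endpoints pass through
        x = [2, 0, 0, 0, 0, 0, 2]
        out = median_postfilter(x)
        assert out[0] == 2 and out[-1] == 2
        assert out[1] == 0 and out[-2] == 0

    def test_empty_sequence(self):
        assert len(median_postfilter([])) == 0

    def test_repeated_filtering_reaches_fixed_point(self):
        """Median filters converge to a root signal under iteration (a single
        pass need not be idempotent: ..1,1,0,0,1,1.. smooths in two passes)."""
        rng = np.random.default_rng(3)
        for _ in range(100):
            x = rng.integers(0, 3, rng.integers(1, 40))
            prev = median_postfilter(x)
            for _ in range(len(x)):
                cur = median_postfilter(prev)
                if np.array_equal(cur, prev):
                    break
                prev = cur
            np.testing.assert_array_equal(median_postfilter(prev), prev)

    def test_never_introduces_absent_class(self):
        rng = np.random.default_rng(4)
        for _ in range(50):
            x = rng.choice([0, 2], size=20)
            out = median_postfilter(x)
            assert set(np.unique(out)) <= set(np.unique(x))


class TestKFold:
    def make_estimator(self, seed):
        return CNNClassifier(conv_filters=(4, 4), epochs=2, random_state=seed)

    def test_folds_disjoint_and_exhaustive(self, target12_store):
        from sklearn.model_selection import StratifiedKFold

        store = target12_store
        skf = StratifiedKFold(n_splits=5, shuffle=True, random_state=0)
        seen = []
        for _, test_idx in skf.split(store.X[:, 0, 0], store.y):
            seen.append(test_idx)
        allidx = np.concatenate(seen)
        assert len(allidx) == len(store)
        assert len(np.unique(allidx)) == len(store)

    def test_training_partition_is_about_nine_tenths(self, target12_store):
        sizes = []

        class Probe(CNNClassifier):
            def fit(self, X, y=None):
                sizes.append(len(np.asarray(y)))
                return super().fit(X, y)

        sub = target12_store.subset(np.arange(0, len(target12_store), 6))
        kfold_cross_validate(
            sub,
            lambda s: Probe(conv_filters=(4, 4), epochs=1, random_state=s),
            k=10,
            seed=0,
            balance=False,
            rotate_every_window=False,
        )
        for n in sizes:
            assert abs(n - 0.9 * len(sub)) <= 3  # within one window per class

    def test_k_larger_than_class_count_errors(self, target12_store):
        tiny = target12_store.subset(np.arange(12))
        with pytest.raises(ValueError, match="exceeds"):
            kfold_cross_validate(tiny, self.make_estimator, k=50, seed=0)

    def test_report_aggregates_folds(self, target12_store, tmp_path):
        sub = target12_store.subset(np.arange(0, len(target12_store), 8))
        cv = kfold_cross_validate(sub, self.make_estimator, k=2, seed=0)
        assert len(cv.fold_reports) == 2
        assert 0.0 <= cv.mean_macro_f1 <= 1.0
        assert cv.confusion.sum() == len(sub)
        # one CSV row per fold per class, plus a JSON summary
        cv.to_csv(tmp_path / "folds.csv")
        cv.to_json(tmp_path / "summary.json")
        rows = (tmp_path / "folds.csv").read_text().strip().splitlines()
        assert len(rows) == 1 + 2 * 3
        import json

        assert "mean_macro_f1" in json.loads((tmp_path / "summary.json").read_text())
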