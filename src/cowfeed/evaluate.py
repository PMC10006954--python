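"""Accuracy evaluation: per-class precision/recall/F1, macro F1, micro
precision, confusion matrices, categorical median post-filtering and
stratified k-fold cross-validation.

With confusion-matrix entry (i, j) counting windows of true class i predicted
as class j, the per-class scores are

    Precision_i = TP_i / (TP_i + FP_i)      TP_i = cm[i, i]
    Recall_i    = TP_i / (TP_i + FN_i)      FP_i = column sum - TP_i
    F1_i        = 2 P_i R_i / (P_i + R_i)   FN_i = row sum - TP_i

the micro precision is trace/total (total correct over total classified) and
the macro F1 is the unweighted mean of the three F1_i.  A class with a zero
denominator scores 0 (not NaN) so fold aggregation stays total.
"""

from __future__ import annotations

from dataclasses import dataclass, field
from typing import Callable, Sequence

import numpy as np
from sklearn.metrics import confusion_matrix as _sk_confusion
from sklearn.model_selection import StratifiedKFold

from .augment import augment_training_set
from .ingest import CLASSES
from .preprocess import WindowStore


def confusion_from_predictions(y_true, y_pred) -> np.ndarray:
    """3x3 counts; entry (i, j) = true class i predicted as class j."""
    return _sk_confusion(y_true, y_pred, labels=[0, 1, 2]).astype(np.int64)


@dataclass
class MetricsReport:
    precision: np.ndarray  # per class
    recall: np.ndarray
    f1: np.ndarray
    micro_precision: float
    macro_f1: float
    confusion: np.ndarray
    n_windows: int

    def as_dict(self) -> dict:
        d = {
            "micro_precision": self.micro_precision,
            "macro_f1": self.macro_f1,
            "n_windows": self.n_windows,
        }
        for i, c in enumerate(CLASSES):
            d[f"precision_{c}"] = float(self.precision[i])
            d[f"recall_{c}"] = float(self.recall[i])
            d[f"f1_{c}"] = float(self.f1[i])
        return d


def _safe_div(num: float, den: float) -> float:
    return num / den if den > 0 else 0.0


def compute_metrics(cm: np.ndarray) -> MetricsReport:
    """Per-class and aggregate scores from a 3x3 confusion matrix."""
    cm = np.asarray(cm, dtype=np.int64)
    if cm.shape != (3, 3):
        raise ValueError("confusion matrix must be 3x3")
    total = int(cm.sum())
    if total == 0:
        raise ValueError("empty confusion matrix")
    tp = np.diag(cm).astype(float)
    fp = cm.sum(axis=0) - tp
    fn = cm.sum(axis=1) - tp
    precision = np.array([_safe_div(tp[i], tp[i] + fp[i]) for i in range(3)])
    recall = np.array([_safe_div(tp[i], tp[i] + fn[i]) for i in range(3)])
    f1 = np.array(
        [
            _safe_div(2 * precision[i] * recall[i], precision[i] + recall[i])
            for i in range(3)
        ]
    )
    return MetricsReport(
        precision=precision,
        recall=recall,
        f1=f1,
        micro_precision=float(tp.sum() / total),
        macro_f1=float(f1.mean()),
        confusion=cm,
        n_windows=total,
    )


def evaluate_predictions(y_true, y_pred) -> MetricsReport:
    return compute_metrics(confusion_from_predictions(y_true, y_pred))


def median_postfilter(labels: Sequence[int] | np.ndarray) -> np.ndarray:
    """Length-5 categorical median over a time-ordered class-code sequence.

    Classes are integer codes in fixed order (feeding=0, ruminating=1,
    other=2) — the median depends on the coding, so the order is part of the
    contract.  At the edges the window truncates symmetrically: positions 1
    and n-2 use a length-3 window; the first and last labels pass through.
    """
    x = np.asarray(labels, dtype=np.int64)
    n = len(x)
    if n == 0:
        return x.copy()
    out = x.copy()
    for i in range(1, n - 1):
        half = min(2, i, n - 1 - i)
        out[i] = int(np.median(x[i - half : i + half + 1]))
    return out


@dataclass
class CVResult:
    """Fold-aggregated metrics: mean and STD across folds plus the details."""

    fold_reports: list[MetricsReport]
    mean_macro_f1: float
    std_macro_f1: float
    mean_micro_precision: float
    std_micro_precision: float
    mean_f1_per_class: np.ndarray
    std_f1_per_class: np.ndarray
    confusion: np.ndarray  # pooled over folds

    def as_dict(self) -> dict:
        return {
            "mean_macro_f1": self.mean_macro_f1,
            "std_macro_f1": self.std_macro_f1,
            "mean_micro_precision": self.mean_micro_precision,
            "std_micro_precision": self.std_micro_precision,
            "mean_f1_per_class": {
                c: float(v) for c, v in zip(CLASSES, self.mean_f1_per_class)
            },
            "n_folds": len(self.fold_reports),
            "confusion": self.confusion.tolist(),
        }

    def to_json(self, path) -> None:
        import json

        with open(path, "w") as fh:
            json.dump(self.as_dict(), fh, indent=2)

    def to_csv(self, path) -> None:
        """One row per fold per class, plus the fold-level aggregates."""
        import csv

        with open(path, "w", newline="") as fh:
            w = csv.writer(fh)
            w.writerow(
                ["fold", "class", "precision", "recall", "f1",
                 "micro_precision", "macro_f1"]
            )
            for i, r in enumerate(self.fold_reports):
                for k, c in enumerate(CLASSES):
                    w.writerow(
                        [i, c, r.precision[k], r.recall[k], r.f1[k],
                         r.micro_precision, r.macro_f1]
                    )

    @classmethod
    def from_folds(cls, reports: list[MetricsReport]) -> "CVResult":
        macro = np.array([r.macro_f1 for r in reports])
        micro = np.array([r.micro_precision for r in reports])
        per_class = np.stack([r.f1 for r in reports])
        return cls(
            fold_reports=reports,
            mean_macro_f1=float(macro.mean()),
            std_macro_f1=float(macro.std(ddof=1)) if len(reports) > 1 else 0.0,
            mean_micro_precision=float(micro.mean()),
            std_micro_precision=float(micro.std(ddof=1)) if len(reports) > 1 else 0.0,
            mean_f1_per_class=per_class.mean(axis=0),
            std_f1_per_class=per_class.std(axis=0, ddof=1)
            if len(reports) > 1
            else np.zeros(3),
            confusion=sum(r.confusion for r in reports),
        )


def kfold_cross_validate(
    store: WindowStore,
    make_estimator: Callable[[int], "object"],
    k: int = 10,
    seed: int = 0,
    balance: bool = True,
    rotate_every_window: bool = True,
    train_subsampler: Callable[[WindowStore, np.random.Generator], WindowStore]
    | None = None,
) -> CVResult:
    """Stratified window-level k-fold evaluation.

    Per fold: the k-1 training folds (optionally subsampled by
    ``train_subsampler``) pass through rotation augmentation and per-file
    balancing, a fresh estimator from ``make_estimator(fold_seed)`` is
    fitted, and the untouched held-out fold is scored.  Validation windows
    are never augmented, so no overlapping-window leakage crosses the split.
    """
    counts = store.class_counts()
    if np.any(counts < k):
        raise ValueError(
            f"k={k} exceeds the smallest class count {counts.min()}"
        )
    skf = StratifiedKFold(n_splits=k, shuffle=True, random_state=seed)
    reports = []
    for fold, (train_idx, test_idx) in enumerate(skf.split(store.X[:, 0, 0], store.y)):
        fold_seed = int(
            np.random.SeedSequence([seed & 0x7FFFFFFF, fold]).generate_state(1)[0]
            & 0x7FFFFFFF
        )
        rng = np.random.default_rng(fold_seed)
        train_part = store.subset(train_idx)
        if train_subsampler is not None:
            train_part = train_subsampler(train_part, rng)
        train_part = augment_training_set(
            train_part, rng, rotate_every_window=rotate_every_window, balance=balance
        )
        est = make_estimator(fold_seed)
        est.fit(train_part.X, train_part.y)
        y_pred = est.predict(store.X[test_idx])
        reports.append(evaluate_predictions(store.y[test_idx], y_pred))
    return CVResult.from_folds(reports)
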