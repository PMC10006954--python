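"""The three study analyses as reproducible experiment drivers.

1. **Learning curves** — how macro F1 grows with training-set size, for
   random-weight initialization versus transfer learning from a source-profile
   model.  Sizes follow the per-file regime (n windows per class per cow-day
   file, so 56 files give 168, 336, ... windows) and then a fraction regime
   (10%, 20%, ... of the full window store).
2. **Window-size grid search** — full cross-validated evaluation over the
   window grid [5, 10, 30, 60, 90, 120, 180, 300] s per model and regime; the
   best size is the argmax of mean macro F1, with ties broken toward the
   smallest window (large windows mix behaviors at deployment time).
3. **Cross-dataset generalization** — a model trained on one sensor profile
   scored, without retraining, on the window store of the other.

Every driver is deterministic given its seeds: each (size, regime, fold)
combination gets a sub-seed derived from the top-level seed, so results do
not depend on execution order.
"""

from __future__ import annotations

import csv
from dataclasses import dataclass, field
from pathlib import Path
from typing import Callable, Mapping, Sequence

import numpy as np

from .evaluate import CVResult, MetricsReport, evaluate_predictions, kfold_cross_validate
from .ingest import CLASSES
from .preprocess import WINDOW_GRID_S, WindowStore


@dataclass(frozen=True)
class SizeSchedule:
    """Training-set sizes: per-file counts first, then store fractions.

    With ``n_files`` files, per-file count n yields ``3 * n_files * n``
    windows; the fraction regime yields ``round(frac * total)`` windows.
    The canonical 56-file / 48,540-window store gives
    168, 336, ..., 1680, 4854, 9708, ..., 48540.
    """

    per_file_counts: tuple[int, ...] = tuple(range(1, 11))
    fractions: tuple[float, ...] = tuple((i + 1) / 10 for i in range(10))

    def sizes(self, n_files: int, total_windows: int) -> list[int]:
        per_file = [3 * n_files * n for n in self.per_file_counts]
        frac = [int(round(f * total_windows)) for f in self.fractions]
        out = sorted(set(per_file) | set(frac))
        if not out:
            raise ValueError("empty schedule")
        return out

    def entries(self) -> list[tuple[str, float]]:
        """(regime, value) pairs in increasing-size order within regimes."""
        if not self.per_file_counts and not self.fractions:
            raise ValueError("empty schedule")
        return [("per_file", n) for n in self.per_file_counts] + [
            ("fraction", f) for f in self.fractions
        ]


def printed_size_sequence(n_files: int = 56, total_windows: int = 48540) -> list[int]:
    """The full-protocol size sequence for a given store."""
    return SizeSchedule().sizes(n_files, total_windows)


def subsample_per_file(
    store: WindowStore, n_per_class_per_file: int, rng: np.random.Generator
) -> WindowStore:
    """Draw n windows per class per cow-day file (without replacement when
    possible, with replacement when a file holds fewer than n)."""
    if n_per_class_per_file < 1:
        raise ValueError("n_per_class_per_file must be >= 1")
    y = store.y
    fids = np.asarray(store.file_ids)
    picked: list[np.ndarray] = []
    for f in store.files():
        for k in range(3):
            pool = np.flatnonzero((fids == f) & (y == k))
            if len(pool) == 0:
                pool = np.flatnonzero(y == k)  # resampling fallback
            replace = len(pool) < n_per_class_per_file
            picked.append(rng.choice(pool, size=n_per_class_per_file, replace=replace))
    return store.subset(np.concatenate(picked))


def subsample_fraction(
    store: WindowStore, fraction: float, rng: np.random.Generator
) -> WindowStore:
    """Stratified random fraction of the full window set."""
    if not 0.0 < fraction <= 1.0:
        raise ValueError("fraction must be in (0, 1]")
    if fraction == 1.0:
        return store
    picked = []
    for k in range(3):
        pool = np.flatnonzero(store.y == k)
        take = max(1, int(round(fraction * len(pool))))
        picked.append(rng.choice(pool, size=take, replace=False))
    return store.subset(np.concatenate(picked))


@dataclass
class ExperimentPoint:
    axis_value: float
    regime: str
    model: str
    mean_macro_f1: float
    std_macro_f1: float
    mean_f1_per_class: np.ndarray
    n_folds: int


@dataclass
class ExperimentResult:
    axis_name: str
    points: list[ExperimentPoint] = field(default_factory=list)

    def get(self, axis_value: float, regime: str, model: str | None = None):
        for p in self.points:
            if (
                p.axis_value == axis_value
                and p.regime == regime
                and (model is None or p.model == model)
            ):
                return p
        raise KeyError((axis_value, regime, model))

    def curve(self, regime: str, model: str | None = None) -> list[ExperimentPoint]:
        pts = [
            p
            for p in self.points
            if p.regime == regime and (model is None or p.model == model)
        ]
        return sorted(pts, key=lambda p: p.axis_value)

    def to_csv(self, path: str | Path) -> None:
        with open(path, "w", newline="") as fh:
            w = csv.writer(fh)
            w.writerow(
                [self.axis_name, "regime", "model", "mean_macro_f1", "std_macro_f1"]
                + [f"mean_f1_{c}" for c in CLASSES]
                + ["n_folds"]
            )
            for p in self.points:
                w.writerow(
                    [p.axis_value, p.regime, p.model, p.mean_macro_f1, p.std_macro_f1]
                    + [float(v) for v in p.mean_f1_per_class]
                    + [p.n_folds]
                )


def _sub_seed(*parts: int) -> int:
    return int(
        np.random.SeedSequence([p & 0x7FFFFFFF for p in parts]).generate_state(1)[0]
        & 0x7FFFFFFF
    )


def learning_curve(
    store: WindowStore,
    schedule: Sequence[tuple[str, float]],
    make_estimator: Callable[[int], "object"],
    regimes: Sequence[str] = ("random", "transfer"),
    pretrained=None,
    seeds: Sequence[int] = (0,),
    k: int = 10,
    model_name: str = "cnn2",
) -> ExperimentResult:
    """Macro F1 versus training-set size, per initialization regime.

    ``schedule`` holds (kind, value) entries, kind in {"per_file",
    "fraction"}.  Folds are split on the full store; only the training
    partition is subsampled to the scheduled size, so every point is scored
    against the same held-out windows.  With several ``seeds`` the fold
    results of all seeds pool into the reported mean and STD.

    ``pretrained`` may be a single source model or a sequence aligned with
    ``seeds``; the latter averages the transfer regime over independently
    pretrained source models, so the curve reflects the protocol rather
    than one pretraining draw.
    """
    if "transfer" in regimes and pretrained is None:
        raise ValueError("transfer regime requires a pretrained source model")
    if not schedule:
        raise ValueError("schedule is empty")
    if isinstance(pretrained, (list, tuple)):
        if len(pretrained) != len(seeds):
            raise ValueError("need one pretrained model per seed")
        pretrained_for = dict(zip(seeds, pretrained))
    else:
        pretrained_for = {s: pretrained for s in seeds}
    result = ExperimentResult(axis_name="n_training_windows")
    n_files = len(store.files())
    for kind, value in schedule:
        if kind == "per_file":
            size = 3 * n_files * int(value)
            sub = lambda s, rng, v=int(value): subsample_per_file(s, v, rng)
        elif kind == "fraction":
            size = int(round(value * len(store)))
            sub = lambda s, rng, v=float(value): subsample_fraction(s, v, rng)
        else:
            raise ValueError(f"unknown schedule kind {kind!r}")
        for regime in regimes:
            reports = []
            for seed in seeds:
                base = pretrained_for[seed] if regime == "transfer" else None

                def factory(fold_seed, base=base):
                    est = make_estimator(fold_seed)
                    if base is not None:
                        est.set_params(base_model=base)
                    return est

                cv = kfold_cross_validate(
                    store,
                    factory,
                    k=k,
                    seed=_sub_seed(seed, size, 0 if regime == "random" else 1),
                    train_subsampler=sub,
                )
                reports.extend(cv.fold_reports)
            agg = CVResult.from_folds(reports)
            result.points.append(
                ExperimentPoint(
                    axis_value=size,
                    regime=regime,
                    model=model_name,
                    mean_macro_f1=agg.mean_macro_f1,
                    std_macro_f1=agg.std_macro_f1,
                    mean_f1_per_class=agg.mean_f1_per_class,
                    n_folds=len(reports),
                )
            )
    return result


def window_size_search(
    stores: Mapping[float, WindowStore],
    make_estimator: Callable[[str, int, int], "object"],
    models: Sequence[str] = ("cnn2",),
    regimes: Sequence[str] = ("random",),
    pretrained: Mapping[tuple[str, float], "object"] | None = None,
    seed: int = 0,
    k: int = 10,
    grid: Sequence[float] = WINDOW_GRID_S,
) -> tuple[ExperimentResult, dict[str, float]]:
    """Cross-validated macro F1 per (window size, model, regime).

    ``stores`` maps window size (s) to its window store; sizes absent from
    ``stores`` raise.  ``make_estimator(model, window_len, seed)`` builds a
    fresh estimator.  Returns the result plus, per "model/regime", the best
    window size (highest mean macro F1; smallest window on ties).
    """
    result = ExperimentResult(axis_name="window_s")
    for ws in grid:
        if ws not in stores:
            raise KeyError(f"no window store for window size {ws} s")
        store = stores[ws]
        for model in models:
            for regime in regimes:
                base = None
                if regime == "transfer":
                    if pretrained is None or (model, ws) not in pretrained:
                        raise ValueError(
                            f"transfer regime requires a pretrained model for {model}@{ws}s"
                        )
                    base = pretrained[(model, ws)]

                def factory(fold_seed, model=model, store=store, base=base):
                    est = make_estimator(model, store.window_len, fold_seed)
                    if base is not None:
                        est.set_params(base_model=base)
                    return est

                cv = kfold_cross_validate(
                    store,
                    factory,
                    k=k,
                    seed=_sub_seed(
                        seed,
                        int(ws * 10),
                        sum(ord(c) for c in model),  # stable across processes
                        len(regime),
                    ),
                )
                result.points.append(
                    ExperimentPoint(
                        axis_value=ws,
                        regime=regime,
                        model=model,
                        mean_macro_f1=cv.mean_macro_f1,
                        std_macro_f1=cv.std_macro_f1,
                        mean_f1_per_class=cv.mean_f1_per_class,
                        n_folds=len(cv.fold_reports),
                    )
                )
    best: dict[str, float] = {}
    for model in models:
        for regime in regimes:
            pts = [
                p for p in result.points if p.model == model and p.regime == regime
            ]
            # ties break toward the smallest window
            top = max(pts, key=lambda p: (p.mean_macro_f1, -p.axis_value))
            best[f"{model}/{regime}"] = top.axis_value
    return result, best


def cross_dataset_eval(model, store: WindowStore) -> MetricsReport:
    """Score a fitted model on another profile's windows — no retraining."""
    y_pred = model.predict(store.X)
    return evaluate_predictions(store.y, y_pred)
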