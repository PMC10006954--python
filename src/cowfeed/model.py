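"""The CNN2 and CNN4 window classifiers, with a transfer-learning protocol.

Two 1-D convolutional architectures are compared throughout:

* **CNN2** — a human-activity-recognition template: two convolutions with
  kernel size 3, dropout, max pooling, flatten, softmax over the three
  behavior classes.
* **CNN4** — a deeper cow-activity network: two kernel-52 convolutions
  followed by two kernel-1 (pointwise) convolutions, dropout, global max
  pooling, softmax.

Transfer learning freezes every convolutional layer *before the last one*
(the first for CNN2, the first three for CNN4) and retrains the last
convolution and all subsequent layers on the target data.

`CNNClassifier` follows the scikit-learn estimator contract (``fit`` /
``predict`` / ``predict_proba`` / ``get_params``), so it composes with
sklearn model selection; ``build_model`` / ``train`` / ``transfer_train`` /
``predict`` are thin functional wrappers.
"""

from __future__ import annotations

import hashlib
import json
from dataclasses import dataclass, field
from pathlib import Path

import numpy as np
from sklearn.base import BaseEstimator, ClassifierMixin, clone

from . import _nn
from .preprocess import WindowStore

N_CLASSES = 3

_ARCH_DEFAULTS = {
    "cnn2": {"kernel_sizes": (3, 3), "conv_filters": (64, 64)},
    "cnn4": {"kernel_sizes": (52, 52, 1, 1), "conv_filters": (16, 16, 32, 32)},
}


@dataclass(frozen=True)
class ModelSpec:
    """Architecture description; invariants enforced at construction."""

    architecture: str
    window_len: int
    n_classes: int = N_CLASSES
    conv_filters: tuple[int, ...] = ()
    kernel_sizes: tuple[int, ...] = ()
    dropout_rate: float = 0.5

    def __post_init__(self) -> None:
        if self.architecture not in _ARCH_DEFAULTS:
            raise ValueError(f"unknown architecture {self.architecture!r}")
        defaults = _ARCH_DEFAULTS[self.architecture]
        if not self.kernel_sizes:
            object.__setattr__(self, "kernel_sizes", defaults["kernel_sizes"])
        if not self.conv_filters:
            object.__setattr__(self, "conv_filters", defaults["conv_filters"])
        if len(self.conv_filters) != len(self.kernel_sizes):
            raise ValueError("conv_filters and kernel_sizes lengths differ")
        if self.architecture == "cnn2":
            if len(self.kernel_sizes) != 2 or any(k != 3 for k in self.kernel_sizes):
                raise ValueError("CNN2 has exactly 2 conv layers with kernel size 3")
        else:
            if len(self.kernel_sizes) != 4 or any(
                k not in (52, 1) for k in self.kernel_sizes
            ):
                raise ValueError("CNN4 has exactly 4 conv layers with kernels in {52, 1}")
        if self.n_classes != N_CLASSES:
            raise ValueError("three behavior classes are fixed")
        receptive = sum(k - 1 for k in self.kernel_sizes) + 1
        if self.window_len < max(max(self.kernel_sizes), 2):
            raise ValueError(
                f"window_len {self.window_len} smaller than the receptive field "
                f"(kernels {self.kernel_sizes}, receptive {receptive})"
            )

    @property
    def n_conv_layers(self) -> int:
        return len(self.kernel_sizes)


@dataclass
class TrainConfig:
    """Training budget: a fixed 30-epoch run with Adam at lr 0.001."""

    epochs: int = 30
    learning_rate: float = 0.001
    batch_size: int = 32
    seed: int = 0
    transfer: bool = False
    pretrained_source: "CNNClassifier | str | Path | None" = None

    def __post_init__(self) -> None:
        if self.epochs < 1:
            raise ValueError("epochs must be >= 1")
        if self.learning_rate <= 0:
            raise ValueError("learning_rate must be positive")


def _build_network(spec: ModelSpec, rng: np.random.Generator) -> _nn.Network:
    layers: list[_nn.Layer] = []
    in_ch = 3
    for k, f in zip(spec.kernel_sizes, spec.conv_filters):
        layers.append(_nn.Conv1D(in_ch, f, k, rng))
        layers.append(_nn.ReLU())
        in_ch = f
    layers.append(_nn.Dropout(spec.dropout_rate))
    if spec.architecture == "cnn2":
        layers.append(_nn.MaxPool1D(2))
        layers.append(_nn.Flatten())
        layers.append(_nn.Dense((spec.window_len // 2) * in_ch, N_CLASSES, rng))
    else:
        layers.append(_nn.GlobalMaxPool())
        layers.append(_nn.Dense(in_ch, N_CLASSES, rng))
    return _nn.Network(layers)


class CNNClassifier(ClassifierMixin, BaseEstimator):
    """1-D CNN behavior classifier over fixed-length triaxial windows.

    Parameters
    ----------
    architecture : {"cnn2", "cnn4"}
    conv_filters, kernel_sizes : optional per-layer overrides; ``None`` uses
        the architecture defaults (CNN2: 64 filters, kernels 3; CNN4:
        16/16/32/32 filters, kernels 52/52/1/1).
    dropout_rate : dropout before pooling (default 0.5).
    epochs, learning_rate, batch_size : the training budget (defaults
        30 / 0.001 / 32, Adam).
    random_state : seed for weight init, shuffling and dropout; fixed seed
        plus single-threaded numpy gives bit-reproducible training.
    base_model : a fitted ``CNNClassifier`` to transfer from.  All weights
        are copied and every convolution before the last is frozen; only the
        last convolution and subsequent layers are retrained.

    ``X`` may be (n, L, 3) or flattened (n, 3L) with row-major (L, 3) layout.
    Ties in ``predict`` resolve to the lowest class index.
    """

    def __init__(
        self,
        architecture: str = "cnn2",
        conv_filters: tuple[int, ...] | None = None,
        kernel_sizes: tuple[int, ...] | None = None,
        dropout_rate: float = 0.5,
        epochs: int = 30,
        learning_rate: float = 0.001,
        batch_size: int = 32,
        random_state: int | None = None,
        base_model: "CNNClassifier | None" = None,
    ):
        self.architecture = architecture
        self.conv_filters = conv_filters
        self.kernel_sizes = kernel_sizes
        self.dropout_rate = dropout_rate
        self.epochs = epochs
        self.learning_rate = learning_rate
        self.batch_size = batch_size
        self.random_state = random_state
        self.base_model = base_model

    # -- helpers -----------------------------------------------------------
    def _coerce_X(self, X) -> np.ndarray:
        if isinstance(X, WindowStore):
            X = X.X
        X = np.asarray(X, dtype=np.float32)
        if X.ndim == 2:
            if X.shape[1] % 3:
                raise ValueError("flattened windows must have 3*L features")
            X = X.reshape(X.shape[0], -1, 3)
        if X.ndim != 3 or X.shape[2] != 3:
            raise ValueError(f"X must be (n, L, 3); got {X.shape}")
        return X

    def _make_spec(self, window_len: int) -> ModelSpec:
        return ModelSpec(
            architecture=self.architecture,
            window_len=window_len,
            conv_filters=tuple(self.conv_filters) if self.conv_filters else (),
            kernel_sizes=tuple(self.kernel_sizes) if self.kernel_sizes else (),
            dropout_rate=self.dropout_rate,
        )

    # -- estimator API -----------------------------------------------------
    def fit(self, X, y=None):
        if isinstance(X, WindowStore) and y is None:
            y = X.y
        Xa = self._coerce_X(X)
        ya = np.asarray(y, dtype=np.int64)
        if len(Xa) == 0:
            raise ValueError("empty training set")
        if len(Xa) != len(ya):
            raise ValueError("X and y length mismatch")
        present = set(np.unique(ya))
        if not present <= {0, 1, 2}:
            raise ValueError(f"labels must be class codes 0/1/2, got {present}")
        if present != {0, 1, 2}:
            raise ValueError(
                f"class absent from training set: {sorted({0, 1, 2} - present)}"
            )

        spec = self._make_spec(Xa.shape[1])
        rng = np.random.default_rng(self.random_state)
        net = _build_network(spec, rng)
        if self.base_model is not None:
            src = self.base_model
            if not hasattr(src, "net_"):
                raise ValueError("base_model must be a fitted CNNClassifier")
            if src.spec_.architecture != spec.architecture:
                raise ValueError("architecture mismatch between base model and target")
            if src.spec_.window_len != spec.window_len or tuple(
                src.spec_.conv_filters
            ) != tuple(spec.conv_filters):
                raise ValueError("base model spec does not match target windows")
            net.load_state(src.net_.state())
            self._freeze_lower(net, spec)

        self.history_ = net.fit(
            Xa, ya, self.epochs, self.learning_rate, self.batch_size, rng
        )
        self.net_ = net
        self.spec_ = spec
        self.classes_ = np.array([0, 1, 2])
        self.n_features_in_ = Xa.shape[1] * 3
        self.layer_trainable_ = [
            layer.trainable for layer in net.layers if layer.params()
        ]
        return self

    @staticmethod
    def _freeze_lower(net: _nn.Network, spec: ModelSpec) -> None:
        """Freeze every conv layer before the last conv; head stays trainable."""
        convs = [l for l in net.layers if isinstance(l, _nn.Conv1D)]
        for conv in convs[:-1]:
            conv.trainable = False

    def predict_proba(self, X) -> np.ndarray:
        self._check_fitted()
        Xa = self._coerce_X(X)
        if Xa.shape[1] != self.spec_.window_len:
            raise ValueError(
                f"window length {Xa.shape[1]} != fitted {self.spec_.window_len}"
            )
        return self.net_.predict_proba(Xa)

    def predict(self, X) -> np.ndarray:
        # argmax takes the lowest class index on exact ties
        return np.argmax(self.predict_proba(X), axis=1)

    def _check_fitted(self):
        if not hasattr(self, "net_"):
            raise ValueError("classifier is not fitted")

    # -- persistence & introspection --------------------------------------
    def conv_weight_checksums(self) -> list[str]:
        """SHA-256 of each convolution's weight bytes, in layer order."""
        self._check_fitted()
        return [
            hashlib.sha256(l.W.tobytes() + l.b.tobytes()).hexdigest()
            for l in self.net_.layers
            if isinstance(l, _nn.Conv1D)
        ]

    def save(self, path: str | Path) -> None:
        self._check_fitted()
        meta = {
            "architecture": self.spec_.architecture,
            "window_len": self.spec_.window_len,
            "conv_filters": list(self.spec_.conv_filters),
            "kernel_sizes": list(self.spec_.kernel_sizes),
            "dropout_rate": self.spec_.dropout_rate,
            "history": self.history_,
        }
        arrays = {f"p{i}": p for i, p in enumerate(self.net_.state())}
        np.savez(path, meta=json.dumps(meta), **arrays)

    @classmethod
    def load(cls, path: str | Path) -> "CNNClassifier":
        with np.load(path, allow_pickle=False) as z:
            meta = json.loads(str(z["meta"]))
            state = [z[f"p{i}"] for i in range(len(z.files) - 1)]
        clf = cls(
            architecture=meta["architecture"],
            conv_filters=tuple(meta["conv_filters"]),
            kernel_sizes=tuple(meta["kernel_sizes"]),
            dropout_rate=meta["dropout_rate"],
        )
        spec = clf._make_spec(meta["window_len"])
        net = _build_network(spec, np.random.default_rng(0))
        net.load_state(state)
        clf.net_ = net
        clf.spec_ = spec
        clf.history_ = list(meta["history"])
        clf.classes_ = np.array([0, 1, 2])
        clf.n_features_in_ = spec.window_len * 3
        clf.layer_trainable_ = [l.trainable for l in net.layers if l.params()]
        return clf


# -- functional wrappers ----------------------------------------------------

def build_model(spec: ModelSpec) -> CNNClassifier:
    """An untrained classifier configured from a spec."""
    return CNNClassifier(
        architecture=spec.architecture,
        conv_filters=spec.conv_filters,
        kernel_sizes=spec.kernel_sizes,
        dropout_rate=spec.dropout_rate,
    )


def _xy(windows, y=None):
    if isinstance(windows, WindowStore):
        return windows.X, windows.y
    return windows, y


def train(model: CNNClassifier, windows, cfg: TrainConfig, y=None) -> CNNClassifier:
    """Fit a fresh clone of ``model`` on the windows under ``cfg``."""
    X, y = _xy(windows, y)
    clf = clone(model)
    clf.set_params(
        epochs=cfg.epochs,
        learning_rate=cfg.learning_rate,
        batch_size=cfg.batch_size,
        random_state=cfg.seed,
    )
    if cfg.transfer:
        base = cfg.pretrained_source
        if base is None:
            raise ValueError("transfer requested but no pretrained_source given")
        if isinstance(base, (str, Path)):
            base = CNNClassifier.load(base)
        clf.set_params(base_model=base)
    return clf.fit(X, y)


def transfer_train(
    pretrained: CNNClassifier, windows, cfg: TrainConfig, y=None
) -> CNNClassifier:
    """Retrain the last convolution and subsequent layers on target windows."""
    X, y = _xy(windows, y)
    clf = CNNClassifier(
        architecture=pretrained.spec_.architecture,
        conv_filters=pretrained.spec_.conv_filters,
        kernel_sizes=pretrained.spec_.kernel_sizes,
        dropout_rate=pretrained.spec_.dropout_rate,
        epochs=cfg.epochs,
        learning_rate=cfg.learning_rate,
        batch_size=cfg.batch_size,
        random_state=cfg.seed,
        base_model=pretrained,
    )
    return clf.fit(X, y)


def predict(model: CNNClassifier, windows):
    """(labels, probability vectors) for a window set."""
    X, _ = _xy(windows)
    proba = model.predict_proba(X)
    return np.argmax(proba, axis=1), proba
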