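"""A compact 1-D convolutional network engine on numpy.

Implements exactly the pieces the classifiers need — "same"-padded 1-D
convolutions, ReLU, inverted dropout, max / global-max pooling, a dense
softmax head, categorical cross-entropy and Adam — with explicit
backpropagation.  Layers carry a ``trainable`` flag so transfer learning can
freeze the lower convolutional stack; frozen parameters are bit-identical
after training.  All randomness (init, shuffling, dropout) flows through
seeded generators, so single-threaded training is exactly reproducible.

Shapes are channels-last: (batch, length, channels).
"""

from __future__ import annotations

import numpy as np

DTYPE = np.float32


class Layer:
    trainable: bool = True

    def params(self) -> list[np.ndarray]:
        return []

    def grads(self) -> list[np.ndarray]:
        return []

    def forward(self, x: np.ndarray, training: bool, rng: np.random.Generator):
        raise NotImplementedError

    def backward(self, dout: np.ndarray) -> np.ndarray:
        raise NotImplementedError


class Conv1D(Layer):
    """Same-padded 1-D convolution; output length equals input length.

    Even kernels pad one sample less on the left, matching the usual
    deep-learning convention.
    """

    def __init__(self, in_ch: int, filters: int, kernel: int, rng: np.random.Generator):
        self.in_ch, self.filters, self.kernel = in_ch, filters, kernel
        scale = np.sqrt(2.0 / (kernel * in_ch))  # He init
        self.W = (rng.standard_normal((kernel * in_ch, filters)) * scale).astype(DTYPE)
        self.b = np.zeros(filters, dtype=DTYPE)
        self.dW = np.zeros_like(self.W)
        self.db = np.zeros_like(self.b)
        self.pad_left = (kernel - 1) // 2
        self.pad_right = kernel - 1 - self.pad_left

    def params(self):
        return [self.W, self.b]

    def grads(self):
        return [self.dW, self.db]

    def forward(self, x, training, rng):
        n, L, C = x.shape
        if L < self.kernel:
            raise ValueError(
                f"input length {L} shorter than kernel {self.kernel}"
            )
        xp = np.pad(x, ((0, 0), (self.pad_left, self.pad_right), (0, 0)))
        # (n, L, K, C) sliding view, flattened to (n, L, K*C) for one matmul
        patches = np.lib.stride_tricks.sliding_window_view(xp, self.kernel, axis=1)
        patches = np.ascontiguousarray(patches.transpose(0, 1, 3, 2)).reshape(
            n, L, self.kernel * C
        )
        self._patches = patches
        self._in_len = L
        return patches @ self.W + self.b

    def backward(self, dout):
        n, L, F = dout.shape
        K, C = self.kernel, self.in_ch
        flat = self._patches.reshape(-1, K * C)
        self.dW[...] = flat.T @ dout.reshape(-1, F)
        self.db[...] = dout.sum(axis=(0, 1))
        dpatch = (dout @ self.W.T).reshape(n, L, K, C)
        dxp = np.zeros((n, L + K - 1, C), dtype=DTYPE)
        for k in range(K):
            dxp[:, k : k + L] += dpatch[:, :, k, :]
        self._patches = None
        return dxp[:, self.pad_left : self.pad_left + self._in_len]


class ReLU(Layer):
    def forward(self, x, training, rng):
        self._mask = x > 0
        return x * self._mask

    def backward(self, dout):
        return dout * self._mask


class Dropout(Layer):
    def __init__(self, rate: float):
        if not 0.0 <= rate < 1.0:
            raise ValueError("dropout rate must be in [0, 1)")
        self.rate = rate

    def forward(self, x, training, rng):
        if not training or self.rate == 0.0:
            self._mask = None
            return x
        keep = 1.0 - self.rate
        self._mask = (rng.random(x.shape) < keep).astype(DTYPE) / keep
        return x * self._mask

    def backward(self, dout):
        return dout if self._mask is None else dout * self._mask


class MaxPool1D(Layer):
    def __init__(self, pool: int = 2):
        self.pool = pool

    def forward(self, x, training, rng):
        n, L, C = x.shape
        Lp = L // self.pool
        if Lp == 0:
            raise ValueError(f"input length {L} shorter than pool {self.pool}")
        self._in_shape = x.shape
        xr = x[:, : Lp * self.pool].reshape(n, Lp, self.pool, C)
        self._idx = xr.argmax(axis=2)
        return np.take_along_axis(xr, self._idx[:, :, None, :], axis=2)[:, :, 0, :]

    def backward(self, dout):
        n, L, C = self._in_shape
        Lp = L // self.pool
        dxr = np.zeros((n, Lp, self.pool, C), dtype=DTYPE)
        np.put_along_axis(dxr, self._idx[:, :, None, :], dout[:, :, None, :], axis=2)
        dx = np.zeros((n, L, C), dtype=DTYPE)
        dx[:, : Lp * self.pool] = dxr.reshape(n, Lp * self.pool, C)
        return dx


class GlobalMaxPool(Layer):
    def forward(self, x, training, rng):
        self._in_shape = x.shape
        self._idx = x.argmax(axis=1)  # (n, C)
        return np.take_along_axis(x, self._idx[:, None, :], axis=1)[:, 0, :]

    def backward(self, dout):
        dx = np.zeros(self._in_shape, dtype=DTYPE)
        np.put_along_axis(dx, self._idx[:, None, :], dout[:, None, :], axis=1)
        return dx


class Flatten(Layer):
    def forward(self, x, training, rng):
        self._in_shape = x.shape
        return x.reshape(x.shape[0], -1)

    def backward(self, dout):
        return dout.reshape(self._in_shape)


class Dense(Layer):
    def __init__(self, n_in: int, n_out: int, rng: np.random.Generator):
        scale = np.sqrt(2.0 / n_in)
        self.W = (rng.standard_normal((n_in, n_out)) * scale).astype(DTYPE)
        self.b = np.zeros(n_out, dtype=DTYPE)
        self.dW = np.zeros_like(self.W)
        self.db = np.zeros_like(self.b)

    def params(self):
        return [self.W, self.b]

    def grads(self):
        return [self.dW, self.db]

    def forward(self, x, training, rng):
        self._x = x
        return x @ self.W + self.b

    def backward(self, dout):
        self.dW[...] = self._x.T @ dout
        self.db[...] = dout.sum(axis=0)
        dx = dout @ self.W.T
        self._x = None
        return dx


def softmax(logits: np.ndarray) -> np.ndarray:
    z = logits - logits.max(axis=1, keepdims=True)
    e = np.exp(z)
    return e / e.sum(axis=1, keepdims=True)


class Network:
    """A plain layer stack with softmax cross-entropy training via Adam."""

    def __init__(self, layers: list[Layer]):
        self.layers = layers
        self._adam_m: list[np.ndarray] | None = None
        self._adam_v: list[np.ndarray] | None = None
        self._adam_t = 0

    def forward(
        self, x: np.ndarray, training: bool = False, rng: np.random.Generator | None = None
    ) -> np.ndarray:
        out = np.asarray(x, dtype=DTYPE)
        for layer in self.layers:
            out = layer.forward(out, training, rng)
        return out

    def predict_proba(self, x: np.ndarray, batch_size: int = 256) -> np.ndarray:
        outs = []
        for i in range(0, len(x), batch_size):
            outs.append(softmax(self.forward(x[i : i + batch_size], training=False)))
        return np.concatenate(outs) if outs else np.zeros((0, 3))

    def _init_adam(self):
        self._adam_m = [np.zeros_like(p) for layer in self.layers for p in layer.params()]
        self._adam_v = [np.zeros_like(p) for layer in self.layers for p in layer.params()]
        self._adam_t = 0

    def _adam_step(self, lr: float, beta1=0.9, beta2=0.999, eps=1e-7):
        if self._adam_m is None:
            self._init_adam()
        self._adam_t += 1
        t = self._adam_t
        i = 0
        for layer in self.layers:
            for p, g in zip(layer.params(), layer.grads()):
                if layer.trainable:
                    m = self._adam_m[i]
                    v = self._adam_v[i]
                    m[...] = beta1 * m + (1 - beta1) * g
                    v[...] = beta2 * v + (1 - beta2) * g * g
                    mhat = m / (1 - beta1**t)
                    vhat = v / (1 - beta2**t)
                    p -= lr * mhat / (np.sqrt(vhat) + eps)
                i += 1

    def train_step(
        self, x: np.ndarray, y: np.ndarray, lr: float, rng: np.random.Generator
    ) -> float:
        logits = self.forward(x, training=True, rng=rng)
        p = softmax(logits)
        n = len(y)
        loss = -float(np.mean(np.log(np.maximum(p[np.arange(n), y], 1e-12))))
        dlogits = p.copy()
        dlogits[np.arange(n), y] -= 1.0
        dlogits /= n
        dout = dlogits.astype(DTYPE)
        for layer in reversed(self.layers):
            dout = layer.backward(dout)
        self._adam_step(lr)
        return loss

    def fit(
        self,
        x: np.ndarray,
        y: np.ndarray,
        epochs: int,
        lr: float,
        batch_size: int,
        rng: np.random.Generator,
    ) -> list[float]:
        x = np.asarray(x, dtype=DTYPE)
        y = np.asarray(y, dtype=np.int64)
        n = len(y)
        history = []
        for _ in range(epochs):
            order = rng.permutation(n)
            losses, weights = [], []
            for i in range(0, n, batch_size):
                idx = order[i : i + batch_size]
                losses.append(self.train_step(x[idx], y[idx], lr, rng))
                weights.append(len(idx))
            history.append(float(np.average(losses, weights=weights)))
        return history

    def state(self) -> list[np.ndarray]:
        return [p.copy() for layer in self.layers for p in layer.params()]

    def load_state(self, state: list[np.ndarray]) -> None:
        i = 0
        for layer in self.layers:
            for p in layer.params():
                p[...] = state[i]
                i += 1
        if i != len(state):
            raise ValueError("state does not match network parameters")
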