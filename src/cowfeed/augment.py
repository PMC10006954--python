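"""Rotational augmentation about the neck axis and per-file class balancing.

Collar tags can rest at any angle around the cow's neck, so a training set is
made orientation-invariant by rotating the Y/Z acceleration components by a
random angle alpha ~ Uniform[0, 2*pi)::

    aX' = aX
    aY' = cos(a) aY - sin(a) aZ
    aZ' = sin(a) aY + cos(a) aZ

Balancing equalizes class counts within each cow-day file by adding rotated
copies of minority-class windows; it never removes windows.
"""

from __future__ import annotations

import numpy as np

from .preprocess import WindowStore


def rotation_matrix(alpha: float) -> np.ndarray:
    """3x3 rotation about the X (neck) axis."""
    c, s = np.cos(alpha), np.sin(alpha)
    return np.array([[1.0, 0.0, 0.0], [0.0, c, -s], [0.0, s, c]])


def rotate_values(values: np.ndarray, alpha: float | np.ndarray) -> np.ndarray:
    """Rotate (..., 3) acceleration about X; supports per-window angles.

    ``alpha`` is a scalar for a single window or an array broadcastable over
    the leading axes (one angle per window for a (n, L, 3) batch).
    """
    alpha = np.asarray(alpha, dtype=np.float64)
    if alpha.ndim == 1:
        alpha = alpha[:, None]
    c, s = np.cos(alpha), np.sin(alpha)
    out = np.empty_like(values, dtype=values.dtype)
    out[..., 0] = values[..., 0]
    out[..., 1] = c * values[..., 1] - s * values[..., 2]
    out[..., 2] = s * values[..., 1] + c * values[..., 2]
    return out


def rotate_windows(store: WindowStore, alphas: np.ndarray) -> WindowStore:
    """Rotate every window by its own angle; labels and lengths unchanged.

    Provenance: ``rotation`` accumulates the applied angle and ``augmented``
    is set, so tests can verify rotation coverage of a training path.
    """
    alphas = np.asarray(alphas, dtype=np.float64)
    if alphas.shape != (len(store),):
        raise ValueError("need exactly one angle per window")
    out = store.subset(np.arange(len(store)))
    out.X = rotate_values(store.X.astype(np.float64), alphas).astype(np.float32)
    out.rotation = store.rotation + alphas
    out.augmented = np.ones(len(store), dtype=bool)
    return out


def random_angles(n: int, rng: np.random.Generator) -> np.ndarray:
    return rng.uniform(0.0, 2.0 * np.pi, size=n)


def rotate_all(store: WindowStore, rng: np.random.Generator) -> WindowStore:
    """Fresh random rotation of every window (the default training path)."""
    return rotate_windows(store, random_angles(len(store), rng))


def balance_classes(
    store: WindowStore,
    rng: np.random.Generator,
    allow_cross_file_resample: bool = True,
) -> WindowStore:
    """Equalize class counts within each cow-day file by adding rotated copies.

    For every file, each minority class is topped up to the file's majority
    count by sampling that file's windows of the class with replacement and
    rotating each copy by a fresh random angle.  A file with zero windows of
    some class draws the copies from the class pool across all files when
    ``allow_cross_file_resample`` is set, and is an error otherwise.
    """
    if len(store) == 0:
        return store
    parts = [store]
    y = store.y
    fids = np.asarray(store.file_ids)
    missing_entirely: list[str] = []
    plan: list[tuple[str, int, int]] = []  # (file, class, deficit)
    for f in store.files():
        in_file = fids == f
        counts = np.bincount(y[in_file], minlength=3)
        top = counts.max()
        for k in range(3):
            if counts[k] < top:
                if counts[k] == 0 and not allow_cross_file_resample:
                    missing_entirely.append(f"{f} (class {k})")
                    continue
                plan.append((f, k, int(top - counts[k])))
    if missing_entirely:
        raise ValueError(
            "files lacking a class with cross-file resampling disabled: "
            + ", ".join(missing_entirely)
        )
    for f, k, deficit in plan:
        pool = np.flatnonzero((fids == f) & (y == k))
        if len(pool) == 0:
            pool = np.flatnonzero(y == k)
            if len(pool) == 0:
                raise ValueError(f"class {k} absent from the entire training set")
        picked = rng.choice(pool, size=deficit, replace=True)
        copies = store.subset(picked)
        copies.file_ids = np.array([f] * deficit, dtype=object)
        parts.append(rotate_windows(copies, random_angles(deficit, rng)))
    out = WindowStore.concat(parts)
    return out


def augment_training_set(
    store: WindowStore,
    rng: np.random.Generator,
    rotate_every_window: bool = True,
    balance: bool = True,
) -> WindowStore:
    """The training-path augmentation: rotation then per-file balancing.

    Applied to training partitions only — validation windows are never
    augmented or balanced.
    """
    out = rotate_all(store, rng) if rotate_every_window else store
    if balance:
        out = balance_classes(out, rng)
    return out
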