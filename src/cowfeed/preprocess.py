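"""Filtering, normalization, imputation, rate conversion and windowing.

The fixed processing order for target-profile (25 Hz) recordings is::

    impute zeros -> high-pass filter -> amplitude normalize -> segment

Source-profile (10 Hz) recordings are first brought onto the 25 Hz grid by
zero insertion (each source sample lands on its nearest target tick; all
other ticks are zero/missing), then follow the same chain.  Keeping the
zero-gapped structure end to end is deliberate: the classifiers consume the
same gap structure at training and deployment time.
"""

from __future__ import annotations

from dataclasses import dataclass, field
from functools import lru_cache
from pathlib import Path
from typing import Iterable, Sequence

import numpy as np
from scipy.signal import fftconvolve

from .ingest import UNLABELED, TagRecording

#: The window-size grid searched downstream, in seconds.
WINDOW_GRID_S: tuple[int, ...] = (5, 10, 30, 60, 90, 120, 180, 300)

#: Classification grid rate: all windows are cut at 25 Hz.
TARGET_RATE_HZ = 25.0

FILTER_NUMTAPS = 512  # order 511
FILTER_CUTOFF_HZ = 0.1


@lru_cache(maxsize=8)
def design_highpass(
    numtaps: int = FILTER_NUMTAPS,
    cutoff_hz: float = FILTER_CUTOFF_HZ,
    fs: float = TARGET_RATE_HZ,
) -> np.ndarray:
    """Hamming-window FIR high-pass (linear phase, even length).

    Even-length symmetric FIRs cannot be designed by spectral inversion of a
    lowpass around an integer center, so the ideal high-pass response is
    sampled directly with the fractional group delay (numtaps-1)/2 and
    Hamming-windowed; a constant correction then nulls the DC gain exactly.
    The response necessarily has a zero at Nyquist (type II); with a 0.1 Hz
    cutoff that is irrelevant to the band of interest.
    """
    m = np.arange(numtaps) - (numtaps - 1) / 2.0
    fc = cutoff_hz / fs  # cycles per sample
    ideal = np.sinc(m) - 2.0 * fc * np.sinc(2.0 * fc * m)
    h = ideal * np.hamming(numtaps)
    h -= h.sum() / numtaps  # exact DC null
    return h


def highpass_filter(rec: TagRecording) -> TagRecording:
    """Remove the gravity (DC) component from each axis.

    Linear-phase convolution with group-delay compensation: the input is
    zero-padded and the output realigned so sample k of the output
    corresponds to sample k of the input; length is unchanged.
    """
    h = design_highpass()
    n = rec.n_samples
    if n < len(h):
        raise ValueError(
            f"recording of {n} samples shorter than filter length {len(h)}"
        )
    delay = len(h) // 2  # group delay 255.5 rounded to 256 slots
    out = rec.copy()
    full = fftconvolve(rec.values, h[:, None], mode="full", axes=0)
    out.values = full[delay : delay + n]
    return out


def normalize_amplitude(values: np.ndarray) -> np.ndarray:
    """Scale so the global maximum absolute value over all axes is 1.

    All-zero input is returned unchanged.  Works on any array shape; the
    pipeline applies it per cow-day recording, before segmentation.
    """
    peak = np.max(np.abs(values)) if values.size else 0.0
    if peak == 0.0 or not np.isfinite(peak):
        return values.copy()
    return values / peak


def normalize_recording(rec: TagRecording) -> TagRecording:
    out = rec.copy()
    out.values = normalize_amplitude(rec.values)
    return out


def impute_missing(rec: TagRecording) -> TagRecording:
    """Replace masked slots by zeros on all axes; the mask is retained."""
    out = rec.copy()
    out.values[out.missing_mask] = 0.0
    return out


def resample_to_rate(rec: TagRecording, target_rate: float) -> TagRecording:
    """Zero-insertion upsampling onto the target-rate grid.

    Each source sample is placed at its nearest target tick; every
    unoccupied target tick is zero and flagged missing.  Duration is
    preserved.  Downsampling is refused.
    """
    if target_rate < rec.sampling_rate:
        raise ValueError("downsampling not supported")
    if target_rate == rec.sampling_rate:
        return rec.copy()
    ratio = target_rate / rec.sampling_rate
    n_src = rec.n_samples
    n_tgt = int(round(n_src * ratio))
    idx = np.floor(np.arange(n_src) * ratio + 0.5).astype(np.int64)
    idx = np.minimum(idx, n_tgt - 1)
    values = np.zeros((n_tgt, 3), dtype=np.float64)
    mask = np.ones(n_tgt, dtype=bool)
    src_present = ~rec.missing_mask
    values[idx[src_present]] = rec.values[src_present]
    mask[idx[src_present]] = False
    values[mask] = np.nan
    return TagRecording(
        cow_id=rec.cow_id,
        day=rec.day,
        sampling_rate=target_rate,
        values=values,
        missing_mask=mask,
    )


@dataclass
class WindowStore:
    """A set of fixed-length labeled classification windows.

    ``X`` has shape (n, L, 3) — the window is the unit of training and
    evaluation ("training sample").  ``file_ids`` keeps the cow-day
    provenance used for balancing and subsampling; ``augmented`` and
    ``rotation`` record augmentation provenance.
    """

    X: np.ndarray
    y: np.ndarray
    file_ids: np.ndarray
    start_s: np.ndarray
    augmented: np.ndarray
    rotation: np.ndarray
    window_s: float
    sampling_rate: float = TARGET_RATE_HZ

    def __post_init__(self) -> None:
        self.X = np.asarray(self.X, dtype=np.float32)
        self.y = np.asarray(self.y, dtype=np.int8)
        n = len(self.y)
        if self.X.shape[0] != n or self.X.ndim != 3 or self.X.shape[2] != 3:
            raise ValueError(f"X must be (n, L, 3); got {self.X.shape} for n={n}")

    def __len__(self) -> int:
        return len(self.y)

    @property
    def window_len(self) -> int:
        return self.X.shape[1]

    @classmethod
    def empty(cls, window_len: int, window_s: float, rate: float = TARGET_RATE_HZ):
        return cls(
            X=np.zeros((0, window_len, 3), dtype=np.float32),
            y=np.zeros(0, dtype=np.int8),
            file_ids=np.zeros(0, dtype=object),
            start_s=np.zeros(0),
            augmented=np.zeros(0, dtype=bool),
            rotation=np.zeros(0),
            window_s=window_s,
            sampling_rate=rate,
        )

    def subset(self, idx: np.ndarray | Sequence[int]) -> "WindowStore":
        idx = np.asarray(idx)
        return WindowStore(
            X=self.X[idx],
            y=self.y[idx],
            file_ids=self.file_ids[idx],
            start_s=self.start_s[idx],
            augmented=self.augmented[idx],
            rotation=self.rotation[idx],
            window_s=self.window_s,
            sampling_rate=self.sampling_rate,
        )

    @classmethod
    def concat(cls, stores: Iterable["WindowStore"]) -> "WindowStore":
        stores = [s for s in stores if len(s)]
        if not stores:
            raise ValueError("nothing to concatenate")
        first = stores[0]
        return cls(
            X=np.concatenate([s.X for s in stores]),
            y=np.concatenate([s.y for s in stores]),
            file_ids=np.concatenate([s.file_ids for s in stores]),
            start_s=np.concatenate([s.start_s for s in stores]),
            augmented=np.concatenate([s.augmented for s in stores]),
            rotation=np.concatenate([s.rotation for s in stores]),
            window_s=first.window_s,
            sampling_rate=first.sampling_rate,
        )

    def class_counts(self) -> np.ndarray:
        return np.bincount(self.y, minlength=3)

    def files(self) -> list[str]:
        seen: dict[str, None] = {}
        for f in self.file_ids:
            seen.setdefault(str(f), None)
        return list(seen)

    def save(self, path: str | Path) -> None:
        np.savez_compressed(
            path,
            X=self.X,
            y=self.y,
            file_ids=np.asarray(self.file_ids, dtype=str),
            start_s=self.start_s,
            augmented=self.augmented,
            rotation=self.rotation,
            window_s=self.window_s,
            sampling_rate=self.sampling_rate,
        )

    @classmethod
    def load(cls, path: str | Path) -> "WindowStore":
        with np.load(path, allow_pickle=False) as z:
            return cls(
                X=z["X"],
                y=z["y"],
                file_ids=z["file_ids"].astype(object),
                start_s=z["start_s"],
                augmented=z["augmented"],
                rotation=z["rotation"],
                window_s=float(z["window_s"]),
                sampling_rate=float(z["sampling_rate"]),
            )


def segment_windows(
    rec: TagRecording,
    slot_labels: np.ndarray,
    window_s: float,
    overlap: float = 0.0,
) -> WindowStore:
    """Cut the recording into pure fixed-length windows.

    Windows start every ``window_s * (1 - overlap)`` seconds.  A window is
    emitted only when every slot carries the same single class label (no
    unlabeled slots, no class changes); the window inherits that class.
    A recording shorter than one window yields an empty store.
    """
    rate = rec.sampling_rate
    L = int(round(window_s * rate))
    step = int(round(L * (1.0 - overlap)))
    if step <= 0:
        raise ValueError("overlap must leave a positive step")
    n = rec.n_samples
    starts = range(0, n - L + 1, step)

    xs, ys, ss = [], [], []
    for s0 in starts:
        lab = slot_labels[s0 : s0 + L]
        first = lab[0]
        if first == UNLABELED or np.any(lab != first):
            continue
        xs.append(rec.values[s0 : s0 + L])
        ys.append(first)
        ss.append(s0 / rate)
    if not xs:
        return WindowStore.empty(L, window_s, rate)
    k = len(xs)
    return WindowStore(
        X=np.stack(xs),
        y=np.array(ys, dtype=np.int8),
        file_ids=np.array([rec.file_id] * k, dtype=object),
        start_s=np.array(ss),
        augmented=np.zeros(k, dtype=bool),
        rotation=np.zeros(k),
        window_s=window_s,
        sampling_rate=rate,
    )


def preprocess_recording(
    rec: TagRecording, apply_filter: bool = True
) -> TagRecording:
    """The fixed chain up to (not including) segmentation.

    10 Hz source recordings are first zero-inserted onto the 25 Hz grid.
    """
    if rec.sampling_rate != TARGET_RATE_HZ:
        rec = resample_to_rate(rec, TARGET_RATE_HZ)
    rec = impute_missing(rec)
    if apply_filter:
        rec = highpass_filter(rec)
    return normalize_recording(rec)


def windows_from_recording(
    rec: TagRecording,
    bouts,
    window_s: float,
    overlap: float = 0.0,
    apply_filter: bool = True,
) -> WindowStore:
    """Full per-recording pipeline: preprocess, align labels, segment.

    Labels are aligned on the original grid and, for source-profile data,
    re-derived on the 25 Hz grid after resampling (bout times are in
    seconds, so alignment is rate-independent).
    """
    from .ingest import align_labels

    processed = preprocess_recording(rec, apply_filter=apply_filter)
    labels = align_labels(processed, bouts)
    return segment_windows(processed, labels, window_s, overlap)
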