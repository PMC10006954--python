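"""Reading raw collar-tag acceleration streams and behavior bout labels.

Raw data arrives as CSV rows ``time_s, ax_g, ay_g, az_g`` sampled on a nominal
fixed-rate grid (25 Hz for the collar tags, 10 Hz for the lossless open-dataset
profile).  Because messages are broadcast in five-sample packets and roughly
half are lost in a dense barn, received rows cover only part of the grid;
ingest reconstructs the full uniform grid and flags the absent ticks in a
missing mask.  Behavior labels are half-open bout intervals
``[start_s, end_s)`` carrying one of three mutually exclusive classes:
feeding, ruminating, other.
"""

from __future__ import annotations

import logging
from dataclasses import dataclass, field
from pathlib import Path
from typing import Sequence

import numpy as np
import pandas as pd

logger = logging.getLogger(__name__)

#: Fixed class order; integer codes matter downstream (the categorical median
#: post-filter operates on these codes).
CLASSES: tuple[str, str, str] = ("feeding", "ruminating", "other")
CLASS_TO_CODE: dict[str, int] = {c: i for i, c in enumerate(CLASSES)}
N_CLASSES = 3

UNLABELED = -1

RAW_COLUMNS = ("time_s", "ax_g", "ay_g", "az_g")
LABEL_COLUMNS = ("start_s", "end_s", "behavior_class")

#: Rows whose timestamp is further than this fraction of a grid tick from the
#: nearest tick are rejected (logged, not fatal).
SNAP_TOLERANCE_TICKS = 0.4


@dataclass
class TagRecording:
    """One cow-day of triaxial acceleration on a uniform time grid.

    ``values`` has shape (n, 3) in units of g; ``missing_mask`` is True where
    the grid slot was never received (or was dropped in a simulated packet
    loss).  Masked values are undefined and must not be consumed before
    imputation.
    """

    cow_id: str
    day: int
    sampling_rate: float
    values: np.ndarray
    missing_mask: np.ndarray

    def __post_init__(self) -> None:
        self.values = np.asarray(self.values, dtype=np.float64)
        self.missing_mask = np.asarray(self.missing_mask, dtype=bool)
        if self.values.ndim != 2 or self.values.shape[1] != 3:
            raise ValueError(f"values must be (n, 3), got {self.values.shape}")
        if self.missing_mask.shape != (self.values.shape[0],):
            raise ValueError("missing_mask length must equal number of grid slots")
        if self.sampling_rate <= 0:
            raise ValueError("sampling_rate must be positive")

    @property
    def n_samples(self) -> int:
        return self.values.shape[0]

    @property
    def duration_s(self) -> float:
        return self.n_samples / self.sampling_rate

    @property
    def times(self) -> np.ndarray:
        return np.arange(self.n_samples) / self.sampling_rate

    def copy(self) -> "TagRecording":
        return TagRecording(
            cow_id=self.cow_id,
            day=self.day,
            sampling_rate=self.sampling_rate,
            values=self.values.copy(),
            missing_mask=self.missing_mask.copy(),
        )

    @property
    def file_id(self) -> str:
        """Cow-day key: the unit of file storage, balancing and subsampling."""
        return f"{self.cow_id}_d{self.day}"


@dataclass(frozen=True)
class BoutLabel:
    """A labeled behavior interval [start_s, end_s), one class per bout."""

    start_s: float
    end_s: float
    behavior_class: str

    def __post_init__(self) -> None:
        if not self.start_s < self.end_s:
            raise ValueError(f"bout start {self.start_s} must precede end {self.end_s}")
        if self.behavior_class not in CLASS_TO_CODE:
            raise ValueError(
                f"unknown class {self.behavior_class!r}; expected one of {CLASSES}"
            )

    @property
    def code(self) -> int:
        return CLASS_TO_CODE[self.behavior_class]

    @property
    def duration_s(self) -> float:
        return self.end_s - self.start_s


def write_recording_csv(rec: TagRecording, path: str | Path) -> None:
    """Write a recording as received data would look: missing rows omitted."""
    present = ~rec.missing_mask
    df = pd.DataFrame(
        {
            "time_s": rec.times[present],
            "ax_g": rec.values[present, 0],
            "ay_g": rec.values[present, 1],
            "az_g": rec.values[present, 2],
        }
    )
    df.to_csv(path, index=False, float_format="%.6f")


def write_labels_csv(bouts: Sequence[BoutLabel], path: str | Path) -> None:
    df = pd.DataFrame(
        {
            "start_s": [b.start_s for b in bouts],
            "end_s": [b.end_s for b in bouts],
            "behavior_class": [b.behavior_class for b in bouts],
        }
    )
    df.to_csv(path, index=False)


def read_labels_csv(path: str | Path) -> list[BoutLabel]:
    df = pd.read_csv(path)
    missing = set(LABEL_COLUMNS) - set(df.columns)
    if missing:
        raise ValueError(f"label file {path} lacks columns {sorted(missing)}")
    return [
        BoutLabel(float(r.start_s), float(r.end_s), str(r.behavior_class))
        for r in df.itertuples()
    ]


def read_raw_csv(
    path: str | Path,
    expected_rate: float,
    duration_s: float | None = None,
    cow_id: str = "",
    day: int = 0,
) -> TagRecording:
    """Read a raw tag CSV and reconstruct the fixed-rate grid.

    Timestamps are snapped to the nearest tick of the ``expected_rate`` grid;
    ticks with no row are flagged missing.  Duplicate ticks keep the first
    occurrence.  Rows off-grid by more than ``SNAP_TOLERANCE_TICKS`` are
    dropped with a logged count.  If ``duration_s`` is given the grid covers
    exactly that span, otherwise it ends at the last received tick.
    """
    df = pd.read_csv(path)
    unknown = set(df.columns) - set(RAW_COLUMNS)
    if unknown:
        raise ValueError(f"unknown columns in {path}: {sorted(unknown)}")
    missing_cols = set(RAW_COLUMNS) - set(df.columns)
    if missing_cols:
        raise ValueError(f"{path} lacks columns {sorted(missing_cols)}")

    t = df["time_s"].to_numpy(dtype=np.float64)
    tick = 1.0 / expected_rate
    if len(t) > 1 and np.any(np.diff(t) < -SNAP_TOLERANCE_TICKS * tick):
        raise ValueError(f"non-monotone timestamps in {path}")

    ticks_float = t * expected_rate
    idx = np.floor(ticks_float + 0.5).astype(np.int64)
    off_grid = np.abs(ticks_float - idx) > SNAP_TOLERANCE_TICKS
    if off_grid.any():
        logger.warning("%s: rejected %d off-grid rows", path, int(off_grid.sum()))
    keep = ~off_grid
    idx = idx[keep]
    vals = df[["ax_g", "ay_g", "az_g"]].to_numpy(dtype=np.float64)[keep]

    # duplicates: keep the first occurrence
    _, first = np.unique(idx, return_index=True)
    first = np.sort(first)
    idx, vals = idx[first], vals[first]

    if duration_s is not None:
        n = int(round(duration_s * expected_rate))
        inside = idx < n
        idx, vals = idx[inside], vals[inside]
    else:
        n = int(idx[-1]) + 1 if len(idx) else 0

    values = np.zeros((n, 3), dtype=np.float64)
    mask = np.ones(n, dtype=bool)
    values[idx] = vals
    mask[idx] = False
    values[mask] = np.nan
    return TagRecording(
        cow_id=cow_id or Path(path).stem,
        day=day,
        sampling_rate=expected_rate,
        values=values,
        missing_mask=mask,
    )


def align_labels(rec: TagRecording, bouts: Sequence[BoutLabel]) -> np.ndarray:
    """Per-grid-slot class codes; ``UNLABELED`` (-1) outside every bout.

    Bouts are half-open [start, end): a slot at time t belongs to the bout iff
    start <= t < end.  Overlapping bouts are an error.
    """
    ordered = sorted(bouts, key=lambda b: b.start_s)
    for a, b in zip(ordered, ordered[1:]):
        if b.start_s < a.end_s - 1e-9:
            raise ValueError(
                f"overlapping bouts: [{a.start_s}, {a.end_s}) and [{b.start_s}, {b.end_s})"
            )
    codes = np.full(rec.n_samples, UNLABELED, dtype=np.int8)
    rate = rec.sampling_rate
    for b in ordered:
        lo = int(np.ceil(b.start_s * rate - 1e-9))
        hi = int(np.ceil(b.end_s * rate - 1e-9))
        lo = max(lo, 0)
        hi = min(hi, rec.n_samples)
        codes[lo:hi] = b.code
    return codes
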