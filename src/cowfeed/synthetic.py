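"""Synthetic collar-accelerometer recordings with the structure the pipeline assumes.

The generator emulates two sensor profiles:

* **target** — the collar-tag profile: 25 Hz sampling, data broadcast in
  5-sample packets of which roughly half are lost, producing missing runs in
  multiples of five samples;
* **source** — a lossless 10 Hz profile emulating a public halter-labeled
  dataset used for pre-training.

Each cow-day recording alternates bouts of the three behavior classes.  Bout
durations are log-normal (configurable per-class means, 10 s minimum) and the
class sequence is drawn with deficit-weighted probabilities so realized
per-class time fractions concentrate on the configured proportions.

The per-class signal surrogate is: a gravity vector rotated about the neck
(X) axis by a slowly drifting collar angle, plus a class-specific carrier
oscillation (feeding: 1.5-3 Hz high amplitude; rumination: regular ~1.2 Hz
low amplitude; other: near-static), plus Gaussian noise.  The surrogates are
stipulated, not fitted to real cows: they give class-separable spectra below
the 5 Hz Nyquist of the source profile, which is what the downstream stages
need to be exercised meaningfully.
"""

from __future__ import annotations

from dataclasses import dataclass, field
from pathlib import Path
from typing import Sequence

import numpy as np
import yaml

from .ingest import (
    CLASSES,
    BoutLabel,
    TagRecording,
    write_labels_csv,
    write_recording_csv,
)

MIN_BOUT_S = 10.0
#: log-normal shape parameter for bout durations; with the default class mean
#: durations this puts the fraction of bouts shorter than 300 s in the few-
#: percent range typical of barn ethograms.
BOUT_SIGMA = 0.6


@dataclass(frozen=True)
class ClassSignalModel:
    """Surrogate signal parameters for one behavior class.

    ``burst_freq_hz`` > 0 gates the carrier with an on/off envelope at that
    rate (feeding is bursty bite/chew activity with pauses; rumination is a
    steady chewing rhythm), which gives the classes an envelope-scale
    signature that is robust to the sensor's sampling structure.
    """

    carrier_freq_hz: tuple[float, float]  # (lo, hi); drawn per bout
    amplitude_g: float
    amplitude_jitter: float  # relative std of per-bout amplitude
    noise_std_g: float
    gravity_g: float = 1.0
    burst_freq_hz: float = 0.0
    burst_duty: float = 0.6
    impulse_rate: float = 0.0  # probability per sample of a jerk impulse
    impulse_std_g: float = 0.0

    def __post_init__(self) -> None:
        if self.noise_std_g < 0 or self.amplitude_jitter < 0:
            raise ValueError("stds must be non-negative")
        if not 0.0 < self.burst_duty <= 1.0:
            raise ValueError("burst_duty must be in (0, 1]")
        if not 0.0 <= self.impulse_rate <= 1.0:
            raise ValueError("impulse_rate must be in [0, 1]")


#: Feeding is bursty bite/tear activity: a gated 1.5-3 Hz carrier plus sparse
#: high-amplitude jerk impulses (head tugs at the feed rail).  Rumination is
#: a steady low-amplitude chewing rhythm near 1.2 Hz.  "Other" is near-static
#: gravity plus sensor noise.
DEFAULT_SIGNAL_MODELS: dict[str, ClassSignalModel] = {
    "feeding": ClassSignalModel(
        (1.5, 3.0), 0.50, 0.30, 0.08,
        burst_freq_hz=0.4, impulse_rate=0.08, impulse_std_g=0.5,
    ),
    "ruminating": ClassSignalModel((1.15, 1.25), 0.18, 0.10, 0.04),
    "other": ClassSignalModel((0.0, 0.0), 0.0, 0.0, 0.03),
}


@dataclass
class SyntheticConfig:
    """Study conditions for a generated dataset.

    Defaults follow the collar-tag study profile: 21 cows recorded 1-3 days
    each, 25 Hz sampling, 5-sample packets with 52.6% message loss, and class
    time proportions 19.7/36.9/43.3% (feeding/ruminating/other).
    """

    n_cows: int = 21
    days_per_cow: int | Sequence[int] = (3,) * 14 + (2,) * 7  # 56 cow-day files
    duration_s: float = 86400.0
    sampling_rate: float = 25.0
    class_proportions: tuple[float, float, float] = (0.197, 0.369, 0.433)
    mean_bout_durations: tuple[float, float, float] = (1100.0, 1140.0, 800.0)
    packet_size: int = 5
    message_loss_prob: float = 0.526
    collar_rotation_drift: float = 0.5  # radians/hour (random-walk scale)
    rng_seed: int = 0
    signal_models: dict[str, ClassSignalModel] = field(
        default_factory=lambda: dict(DEFAULT_SIGNAL_MODELS)
    )

    def __post_init__(self) -> None:
        props = np.asarray(self.class_proportions, dtype=float)
        # rounded published percentages (e.g. 19.7/36.9/43.3) sum to 0.999;
        # accept within 1% of unity and renormalize exactly
        if props.shape != (3,) or abs(props.sum() - 1.0) > 1e-2:
            raise ValueError("class_proportions must be a 3-vector summing to 1")
        if np.any(props < 0):
            raise ValueError("class_proportions must be non-negative")
        self.class_proportions = tuple(props / props.sum())
        if self.packet_size < 1:
            raise ValueError("packet_size must be >= 1")
        if not 0.0 <= self.message_loss_prob <= 1.0:
            raise ValueError("message_loss_prob must be in [0, 1]")
        if self.n_cows < 0:
            raise ValueError("n_cows must be non-negative")
        nyq = self.sampling_rate / 2.0
        for name, m in self.signal_models.items():
            if max(m.carrier_freq_hz) >= nyq:
                raise ValueError(f"{name}: carrier frequency must be below Nyquist {nyq}")

    def days_for_cow(self, cow: int) -> int:
        if isinstance(self.days_per_cow, int):
            return self.days_per_cow
        return int(self.days_per_cow[cow % len(self.days_per_cow)])

    @property
    def n_files(self) -> int:
        return sum(self.days_for_cow(c) for c in range(self.n_cows))


def target_profile_config(**overrides) -> SyntheticConfig:
    """Collar-tag profile: 25 Hz, 5-sample packets, ~52.6% loss."""
    return SyntheticConfig(**overrides)


def source_profile_config(**overrides) -> SyntheticConfig:
    """Lossless 10 Hz profile emulating the public pre-training dataset."""
    defaults = dict(
        sampling_rate=10.0,
        message_loss_prob=0.0,
        class_proportions=(0.176, 0.384, 0.440),
        n_cows=18,
        days_per_cow=2,
    )
    defaults.update(overrides)
    return SyntheticConfig(**defaults)


def _file_rng(cfg: SyntheticConfig, cow: int, day: int) -> np.random.Generator:
    """Deterministic per-file generator derived from (seed, cow, day)."""
    return np.random.default_rng(
        np.random.SeedSequence([int(cfg.rng_seed) & 0x7FFFFFFF, int(cow), int(day)])
    )


def _split_budget(
    budget_s: float, mean_s: float, rng: np.random.Generator
) -> list[float]:
    """Split a class's total time budget into log-normal bout durations.

    Durations are drawn until they cover the budget, then rescaled to sum to
    it exactly; the rescaling factor is close to 1, so the log-normal shape
    (and hence the fraction of short bouts) is preserved.
    """
    if budget_s <= 0:
        return []
    if budget_s <= MIN_BOUT_S:
        return [budget_s]
    mu = np.log(mean_s) - 0.5 * BOUT_SIGMA**2
    durs: list[float] = []
    total = 0.0
    while total < budget_s:
        d = max(float(np.exp(rng.normal(mu, BOUT_SIGMA))), MIN_BOUT_S)
        durs.append(d)
        total += d
    durs = [d * budget_s / total for d in durs]
    # rescaling can push the smallest bout under the minimum; fold such
    # slivers into the remaining bouts
    while len(durs) > 1 and min(durs) < MIN_BOUT_S:
        small = min(durs)
        durs.remove(small)
        durs = [d * budget_s / (budget_s - small) for d in durs]
    return durs


def _interleave(counts: list[int], rng: np.random.Generator) -> list[int]:
    """A random class sequence with given per-class counts and, whenever
    feasible, no two equal classes adjacent (greedy with random tie-breaks)."""
    remaining = list(counts)
    order: list[int] = []
    prev = -1
    for _ in range(sum(counts)):
        left = sum(remaining)
        avail = [k for k in range(3) if remaining[k] > 0 and k != prev]
        if not avail:
            avail = [k for k in range(3) if remaining[k] > 0]

        # keep the tail feasible: after placing k, no class may hold more
        # than half of the remaining slots (else adjacency is forced later)
        def ok(k: int) -> bool:
            rem = remaining.copy()
            rem[k] -= 1
            return 2 * max(rem) <= left  # left - 1 slots remain, +1 head room

        pool = [k for k in avail if ok(k)] or avail
        weights = np.array([remaining[k] for k in pool], dtype=float)
        k = int(rng.choice(pool, p=weights / weights.sum()))
        order.append(k)
        remaining[k] -= 1
        prev = k
    return order


def _draw_bouts(
    cfg: SyntheticConfig, duration_s: float, rng: np.random.Generator
) -> list[BoutLabel]:
    """Tile [0, duration) with alternating bouts matching the class proportions.

    Each class receives exactly its proportional share of the recording,
    split into log-normal bouts; the bouts are then interleaved avoiding
    same-class adjacency.  Realized time fractions therefore match the
    configured proportions exactly (up to grid quantization downstream).
    """
    props = np.asarray(cfg.class_proportions, dtype=float)
    means = np.asarray(cfg.mean_bout_durations, dtype=float)
    per_class = [
        _split_budget(props[k] * duration_s, means[k], rng) for k in range(3)
    ]
    order = _interleave([len(d) for d in per_class], rng)
    for durs in per_class:
        rng.shuffle(durs)
    iters = [iter(d) for d in per_class]
    bouts: list[BoutLabel] = []
    t = 0.0
    for k in order:
        dur = next(iters[k])
        end = t + dur
        # the greedy interleave can rarely still emit equal neighbours;
        # merge them — two adjacent equal-class bouts are one bout
        if bouts and bouts[-1].behavior_class == CLASSES[k]:
            bouts[-1] = BoutLabel(bouts[-1].start_s, end, CLASSES[k])
        else:
            bouts.append(BoutLabel(t, end, CLASSES[k]))
        t = end
    if bouts:
        # absorb floating-point residue so the tiling is exact
        last = bouts[-1]
        bouts[-1] = BoutLabel(last.start_s, duration_s, last.behavior_class)
    return bouts


def _collar_angle(
    n: int, rate: float, drift_per_hour: float, rng: np.random.Generator
) -> np.ndarray:
    """Bounded random walk of the collar angle about the neck axis.

    Scaled so the angle's std over one hour equals ``drift_per_hour``;
    reflected at +/- pi to stay bounded.
    """
    step = drift_per_hour / np.sqrt(3600.0 * rate)
    theta = np.cumsum(rng.normal(0.0, step, size=n)) + rng.uniform(0, 2 * np.pi)
    # reflect into [-pi, pi)
    theta = np.mod(theta + np.pi, 2 * np.pi) - np.pi
    return theta


def generate_recording(
    cfg: SyntheticConfig,
    cow_id: int | str,
    day: int,
    duration_s: float | None = None,
) -> tuple[TagRecording, list[BoutLabel]]:
    """One cow-day recording on a complete grid (no packet loss applied).

    Returns the recording plus the bout list, which tiles the duration
    exactly with no gaps or overlaps.
    """
    duration = float(duration_s if duration_s is not None else cfg.duration_s)
    if duration < MIN_BOUT_S:
        raise ValueError(f"duration {duration} s shorter than one minimal bout")
    cow_num = int(cow_id) if not isinstance(cow_id, str) else int("".join(
        ch for ch in cow_id if ch.isdigit()) or 0)
    rng = _file_rng(cfg, cow_num, day)

    rate = cfg.sampling_rate
    n = int(round(duration * rate))
    bouts = _draw_bouts(cfg, duration, rng)
    theta = _collar_angle(n, rate, cfg.collar_rotation_drift, rng)
    t = np.arange(n) / rate

    values = np.empty((n, 3), dtype=np.float64)
    for b in bouts:
        m = cfg.signal_models[b.behavior_class]
        lo = int(np.ceil(b.start_s * rate - 1e-9))
        hi = min(int(np.ceil(b.end_s * rate - 1e-9)), n)
        seg = slice(lo, hi)
        f = rng.uniform(*m.carrier_freq_hz) if m.carrier_freq_hz[1] > 0 else 0.0
        amp = m.amplitude_g * max(0.0, 1.0 + m.amplitude_jitter * rng.normal())
        phase = rng.uniform(0, 2 * np.pi)
        s = amp * np.sin(2 * np.pi * f * t[seg] + phase) if f > 0 else np.zeros(hi - lo)
        if m.burst_freq_hz > 0 and f > 0:
            # on/off bite-burst envelope with the configured duty cycle
            bf = m.burst_freq_hz * rng.uniform(0.8, 1.25)
            gate = np.sin(2 * np.pi * bf * t[seg] + rng.uniform(0, 2 * np.pi))
            s = s * (gate > np.cos(np.pi * m.burst_duty))
        if m.impulse_rate > 0:
            # sparse jerk impulses along a fixed body-frame direction
            imp = (rng.random(hi - lo) < m.impulse_rate) * rng.normal(
                0.0, m.impulse_std_g, hi - lo
            )
            s = s + imp
        # motion axis fixed in the neck frame; gravity along neck-frame Z
        mx, my, mz = 0.4 * s, 0.9 * s, 0.2 * s
        gz = m.gravity_g
        th = theta[seg]
        values[seg, 0] = mx
        values[seg, 1] = np.cos(th) * my + np.sin(th) * (mz + gz)
        values[seg, 2] = -np.sin(th) * my + np.cos(th) * (mz + gz)
    values += rng.normal(
        0.0,
        np.repeat(
            [cfg.signal_models[b.behavior_class].noise_std_g for b in bouts],
            [min(int(np.ceil(b.end_s * rate - 1e-9)), n) - int(np.ceil(b.start_s * rate - 1e-9)) for b in bouts],
        )[:, None],
        size=(n, 3),
    )

    rec = TagRecording(
        cow_id=f"cow{cow_num:03d}",
        day=day,
        sampling_rate=rate,
        values=values,
        missing_mask=np.zeros(n, dtype=bool),
    )
    return rec, bouts


def apply_packet_loss(
    rec: TagRecording, packet_size: int, loss_prob: float, seed: int
) -> TagRecording:
    """Drop whole packets of consecutive samples independently with ``loss_prob``.

    The grid length is unchanged; dropped slots are flagged missing and their
    values invalidated.  Missing runs therefore always come in multiples of
    ``packet_size`` (up to the final, possibly shorter packet).
    """
    if packet_size <= 0:
        raise ValueError("packet_size must be positive")
    if not 0.0 <= loss_prob <= 1.0:
        raise ValueError("loss_prob must be in [0, 1]")
    if rec.missing_mask.any():
        raise ValueError("packet loss expects a complete-grid recording")
    out = rec.copy()
    n = rec.n_samples
    n_packets = (n + packet_size - 1) // packet_size
    rng = np.random.default_rng(seed)
    dropped = rng.random(n_packets) < loss_prob
    mask = np.repeat(dropped, packet_size)[:n]
    out.missing_mask = mask
    out.values[mask] = np.nan
    return out


def generate_file_set(
    cfg: SyntheticConfig, duration_s: float | None = None
) -> list[tuple[TagRecording, list[BoutLabel]]]:
    """All cow-day recordings for ``cfg``, packet loss applied, in memory."""
    out = []
    for cow in range(cfg.n_cows):
        for day in range(cfg.days_for_cow(cow)):
            rec, bouts = generate_recording(cfg, cow, day, duration_s=duration_s)
            if cfg.message_loss_prob > 0:
                loss_seed = int(
                    np.random.SeedSequence(
                        [cfg.rng_seed & 0x7FFFFFFF, cow, day, 1]
                    ).generate_state(1)[0]
                    & 0x7FFFFFFF
                )
                rec = apply_packet_loss(
                    rec, cfg.packet_size, cfg.message_loss_prob, loss_seed
                )
            out.append((rec, bouts))
    return out


def generate_dataset(
    cfg: SyntheticConfig,
    out_dir: str | Path,
    duration_s: float | None = None,
) -> dict:
    """Write one CSV pair per cow-day file plus a manifest; return the manifest.

    Data CSV holds only received rows (``time_s, ax_g, ay_g, az_g``); labels
    live beside it as ``*_labels.csv``.  Existing files are an error.
    """
    out_dir = Path(out_dir)
    out_dir.mkdir(parents=True, exist_ok=True)
    manifest: dict = {
        "rng_seed": cfg.rng_seed,
        "sampling_rate": cfg.sampling_rate,
        "packet_size": cfg.packet_size,
        "message_loss_prob": cfg.message_loss_prob,
        "files": [],
    }
    for rec, bouts in generate_file_set(cfg, duration_s=duration_s):
        data_path = out_dir / f"{rec.file_id}.csv"
        label_path = out_dir / f"{rec.file_id}_labels.csv"
        if data_path.exists() or label_path.exists():
            raise FileExistsError(f"refusing to overwrite {data_path}")
        write_recording_csv(rec, data_path)
        write_labels_csv(bouts, label_path)
        total = sum(b.duration_s for b in bouts)
        fracs = [
            sum(b.duration_s for b in bouts if b.behavior_class == c) / total
            for c in CLASSES
        ]
        manifest["files"].append(
            {
                "data": data_path.name,
                "labels": label_path.name,
                "cow_id": rec.cow_id,
                "day": rec.day,
                "duration_s": rec.duration_s,
                "missing_fraction": float(rec.missing_mask.mean()),
                "class_fractions": [float(f) for f in fracs],
            }
        )
    with open(out_dir / "manifest.yaml", "w") as fh:
        yaml.safe_dump(manifest, fh, sort_keys=False)
    return manifest
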