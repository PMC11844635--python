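"""Core data model and I/O for extracellular recordings.

Time base is seconds (float64) with the session starting at 0. All intervals
are half-open ``[start, stop)`` so that disjoint epochs partition time without
double counting. Spike trains carry strictly increasing times; the LFP is a
channels x time int16 matrix with a microvolt scale factor and per-channel
depths, read from the de facto flat-binary convention (little-endian int16,
sample-interleaved across channels) plus a JSON sidecar.
"""

from __future__ import annotations

import json
from dataclasses import dataclass, field
from pathlib import Path
from typing import Iterable, Sequence

import numpy as np
import pandas as pd

EPOCH_LABELS = ("stim_chr2", "stim_arch", "run", "rest")


class LoadError(ValueError):
    """Raised when an on-disk artifact cannot be parsed into a core type."""


@dataclass
class SpikeTrain:
    """Sorted spike times (seconds) of a single unit.

    Times must be strictly increasing: duplicate timestamps within one unit
    are physically meaningless and are rejected.
    """

    unit_id: str
    times: np.ndarray

    def __post_init__(self) -> None:
        self.times = np.asarray(self.times, dtype=float)
        if self.times.ndim != 1:
            raise ValueError("spike times must be 1-D")
        if self.times.size and np.any(np.diff(self.times) <= 0):
            raise ValueError(f"unit {self.unit_id}: spike times must be strictly increasing")
        if self.times.size and self.times[0] < 0:
            raise ValueError(f"unit {self.unit_id}: negative spike time")

    @property
    def n_spikes(self) -> int:
        return int(self.times.size)

    def restrict(self, epochs: "EpochTable") -> "SpikeTrain":
        """Keep spikes falling inside any epoch (half-open intervals)."""
        mask = epochs.contains(self.times)
        return SpikeTrain(self.unit_id, self.times[mask])


@dataclass
class UnitInfo:
    """Per-unit metadata: putative type, opto-tag status, waveform, position."""

    unit_id: str
    putative_type: str = "unknown"  # {PYR, INT, unknown}
    tag_status: str = "untagged"  # {tagged-activated, tagged-suppressed, untagged}
    peak_channel: int | None = None
    waveform: np.ndarray | None = None  # mean extracellular waveform, uV
    waveform_fs: float | None = None  # waveform sampling rate, Hz
    depth_um: float | None = None  # relative to pyramidal-layer center

    def __post_init__(self) -> None:
        if self.waveform is not None:
            self.waveform = np.asarray(self.waveform, dtype=float)
            if self.waveform.size == 0:
                raise ValueError("waveform must have at least one sample")


@dataclass
class LfpRecording:
    """Multichannel LFP: channels x time int matrix + sampling metadata."""

    samples: np.ndarray  # (n_channels, n_samples) integer ADC units
    fs: float
    channel_depths: np.ndarray  # um per channel, along the probe
    scale_uv: float = 1.0  # uV per ADC unit

    def __post_init__(self) -> None:
        self.samples = np.atleast_2d(np.asarray(self.samples))
        self.channel_depths = np.asarray(self.channel_depths, dtype=float)
        if self.fs <= 0:
            raise ValueError("fs must be positive")
        if self.channel_depths.size != self.samples.shape[0]:
            raise ValueError("channel_depths length must equal channel count")

    @property
    def n_channels(self) -> int:
        return self.samples.shape[0]

    @property
    def n_samples(self) -> int:
        return self.samples.shape[1]

    @property
    def duration_s(self) -> float:
        return self.n_samples / self.fs

    def channel_uv(self, ch: int) -> np.ndarray:
        """One channel converted to microvolts (float64)."""
        return self.samples[ch].astype(float) * self.scale_uv


# ---------------------------------------------------------------------------
# interval algebra on (n, 2) float arrays of half-open [start, stop) intervals
# ---------------------------------------------------------------------------


def _as_intervals(start: Sequence[float], stop: Sequence[float]) -> np.ndarray:
    iv = np.column_stack([np.asarray(start, float), np.asarray(stop, float)])
    return iv.reshape(-1, 2)


def interval_intersect(a: np.ndarray, b: np.ndarray) -> np.ndarray:
    """Pairwise-sweep intersection of two sorted, disjoint interval sets."""
    out = []
    i = j = 0
    while i < len(a) and j < len(b):
        lo = max(a[i, 0], b[j, 0])
        hi = min(a[i, 1], b[j, 1])
        if lo < hi:
            out.append((lo, hi))
        if a[i, 1] <= b[j, 1]:
            i += 1
        else:
            j += 1
    return np.array(out, float).reshape(-1, 2)


def interval_complement(iv: np.ndarray, t0: float, t1: float) -> np.ndarray:
    """Complement of sorted disjoint intervals within [t0, t1)."""
    if t0 >= t1:
        raise ValueError("need t0 < t1")
    out = []
    cur = t0
    for lo, hi in iv:
        lo, hi = max(lo, t0), min(hi, t1)
        if hi <= cur:
            continue
        if lo > cur:
            out.append((cur, min(lo, t1)))
        cur = max(cur, hi)
        if cur >= t1:
            break
    if cur < t1:
        out.append((cur, t1))
    return np.array(out, float).reshape(-1, 2)


def interval_union(iv: np.ndarray) -> np.ndarray:
    """Merge overlapping/abutting intervals; result sorted and disjoint."""
    if len(iv) == 0:
        return np.empty((0, 2))
    iv = iv[np.argsort(iv[:, 0])]
    out = [list(iv[0])]
    for lo, hi in iv[1:]:
        if lo <= out[-1][1]:
            out[-1][1] = max(out[-1][1], hi)
        else:
            out.append([lo, hi])
    return np.array(out, float)


@dataclass
class EpochTable:
    """Labelled half-open intervals (behavioral state or stimulation pulses)."""

    start_s: np.ndarray
    stop_s: np.ndarray
    label: np.ndarray = None  # type: ignore[assignment]

    def __post_init__(self) -> None:
        self.start_s = np.asarray(self.start_s, dtype=float)
        self.stop_s = np.asarray(self.stop_s, dtype=float)
        if self.label is None:
            self.label = np.array([""] * self.start_s.size, dtype=object)
        else:
            self.label = np.asarray(self.label, dtype=object)
        if not (self.start_s.size == self.stop_s.size == self.label.size):
            raise ValueError("epoch columns must have equal length")
        if np.any(self.stop_s <= self.start_s):
            raise ValueError("epochs require start < stop")
        if np.any(np.diff(self.start_s) < 0):
            raise ValueError("epochs must be sorted by start")

    def __len__(self) -> int:
        return int(self.start_s.size)

    @property
    def intervals(self) -> np.ndarray:
        return _as_intervals(self.start_s, self.stop_s)

    @property
    def durations(self) -> np.ndarray:
        return self.stop_s - self.start_s

    @property
    def total_duration(self) -> float:
        return float(np.sum(self.durations))

    def select(self, label: str) -> "EpochTable":
        m = self.label == label
        return EpochTable(self.start_s[m], self.stop_s[m], self.label[m])

    def contains(self, times: np.ndarray) -> np.ndarray:
        """Boolean mask: which times fall in some epoch ([start, stop))."""
        times = np.asarray(times, float)
        if len(self) == 0:
            return np.zeros(times.shape, bool)
        idx = np.searchsorted(self.start_s, times, side="right") - 1
        ok = idx >= 0
        ok[ok] &= times[ok] < self.stop_s[idx[ok]]
        return ok

    def complement(self, t0: float, t1: float, label: str = "") -> "EpochTable":
        iv = interval_complement(interval_union(self.intervals), t0, t1)
        return EpochTable(iv[:, 0], iv[:, 1], np.array([label] * len(iv), object))

    def intersect(self, other: "EpochTable", label: str = "") -> "EpochTable":
        iv = interval_intersect(
            interval_union(self.intervals), interval_union(other.intervals)
        )
        return EpochTable(iv[:, 0], iv[:, 1], np.array([label] * len(iv), object))

    def to_frame(self) -> pd.DataFrame:
        return pd.DataFrame(
            {"start_s": self.start_s, "stop_s": self.stop_s, "label": self.label}
        )

    @classmethod
    def from_frame(cls, df: pd.DataFrame) -> "EpochTable":
        return cls(
            df["start_s"].to_numpy(float),
            df["stop_s"].to_numpy(float),
            df["label"].to_numpy(object) if "label" in df else None,
        )


@dataclass
class EventTable:
    """Detected (or planted) ripple events with peak time and properties."""

    start_s: np.ndarray
    peak_s: np.ndarray
    stop_s: np.ndarray
    peak_amplitude: np.ndarray = None  # type: ignore[assignment]  # z-units
    frequency_hz: np.ndarray = None  # type: ignore[assignment]

    def __post_init__(self) -> None:
        self.start_s = np.asarray(self.start_s, float)
        self.peak_s = np.asarray(self.peak_s, float)
        self.stop_s = np.asarray(self.stop_s, float)
        n = self.start_s.size
        if self.peak_amplitude is None:
            self.peak_amplitude = np.full(n, np.nan)
        if self.frequency_hz is None:
            self.frequency_hz = np.full(n, np.nan)
        self.peak_amplitude = np.asarray(self.peak_amplitude, float)
        self.frequency_hz = np.asarray(self.frequency_hz, float)
        for arr in (self.peak_s, self.stop_s, self.peak_amplitude, self.frequency_hz):
            if arr.size != n:
                raise ValueError("event columns must have equal length")
        if np.any(self.start_s > self.peak_s) or np.any(self.peak_s > self.stop_s):
            raise ValueError("events require start <= peak <= stop")
        if np.any(np.diff(self.start_s) < 0):
            raise ValueError("events must be sorted by start")

    def __len__(self) -> int:
        return int(self.start_s.size)

    @property
    def duration_s(self) -> np.ndarray:
        return self.stop_s - self.start_s

    @property
    def intervals(self) -> np.ndarray:
        return _as_intervals(self.start_s, self.stop_s)

    def as_epochs(self, label: str = "") -> EpochTable:
        return EpochTable(
            self.start_s, self.stop_s, np.array([label] * len(self), object)
        )

    def take(self, idx: np.ndarray) -> "EventTable":
        return EventTable(
            self.start_s[idx],
            self.peak_s[idx],
            self.stop_s[idx],
            self.peak_amplitude[idx],
            self.frequency_hz[idx],
        )

    def to_frame(self) -> pd.DataFrame:
        return pd.DataFrame(
            {
                "start_s": self.start_s,
                "peak_s": self.peak_s,
                "stop_s": self.stop_s,
                "peak_amplitude": self.peak_amplitude,
                "frequency_hz": self.frequency_hz,
                "duration_s": self.duration_s,
            }
        )

    @classmethod
    def from_frame(cls, df: pd.DataFrame) -> "EventTable":
        return cls(
            df["start_s"].to_numpy(float),
            df["peak_s"].to_numpy(float),
            df["stop_s"].to_numpy(float),
            df["peak_amplitude"].to_numpy(float) if "peak_amplitude" in df else None,
            df["frequency_hz"].to_numpy(float) if "frequency_hz" in df else None,
        )


# ---------------------------------------------------------------------------
# I/O
# ---------------------------------------------------------------------------


def read_spikes(path: str | Path) -> list[SpikeTrain]:
    """Read spike trains from a CSV/TSV with columns ``unit_id,time_s``."""
    path = Path(path)
    sep = "\t" if path.suffix.lower() in (".tsv", ".tab") else ","
    try:
        df = pd.read_csv(
            path, sep=sep, dtype={"unit_id": str}, float_precision="round_trip"
        )
    except pd.errors.EmptyDataError:
        return []
    if df.empty:
        return []
    if not {"unit_id", "time_s"} <= set(df.columns):
        raise LoadError(f"{path}: expected columns unit_id,time_s")
    times = pd.to_numeric(df["time_s"], errors="coerce")
    bad = np.flatnonzero(times.isna() | (times < 0))
    if bad.size:
        raise LoadError(f"{path}: malformed or negative time at data row {bad[0]}")
    trains = []
    for uid, grp in df.assign(time_s=times).groupby("unit_id", sort=True):
        t = np.sort(grp["time_s"].to_numpy(float))
        t = t[np.concatenate([[True], np.diff(t) > 0])]  # drop exact duplicates
        trains.append(SpikeTrain(str(uid), t))
    return trains


def write_spikes(trains: Iterable[SpikeTrain], path: str | Path) -> None:
    rows = [
        pd.DataFrame({"unit_id": tr.unit_id, "time_s": tr.times}) for tr in trains
    ]
    df = (
        pd.concat(rows, ignore_index=True)
        if rows
        else pd.DataFrame(columns=["unit_id", "time_s"])
    )
    df.to_csv(path, index=False)  # default float repr is shortest round-trip


def read_lfp(bin_path: str | Path, meta_path: str | Path) -> LfpRecording:
    """Read flat little-endian int16 interleaved LFP + JSON sidecar metadata."""
    bin_path, meta_path = Path(bin_path), Path(meta_path)
    if not meta_path.exists():
        raise LoadError(f"missing LFP sidecar metadata: {meta_path}")
    meta = json.loads(meta_path.read_text())
    n_ch = int(meta["n_channels"])
    raw = np.fromfile(bin_path, dtype="<i2")
    if raw.size % n_ch:
        raise LoadError(
            f"{bin_path}: {raw.size} samples not divisible by {n_ch} channels"
        )
    samples = raw.reshape(-1, n_ch).T  # interleaved: time-major on disk
    return LfpRecording(
        samples=samples,
        fs=float(meta["fs"]),
        channel_depths=np.asarray(meta["channel_depths"], float),
        scale_uv=float(meta.get("scale_uv", 1.0)),
    )


def write_lfp(lfp: LfpRecording, bin_path: str | Path, meta_path: str | Path) -> None:
    lfp.samples.T.astype("<i2").tofile(bin_path)
    meta = {
        "fs": lfp.fs,
        "n_channels": lfp.n_channels,
        "scale_uv": lfp.scale_uv,
        "channel_depths": lfp.channel_depths.tolist(),
    }
    Path(meta_path).write_text(json.dumps(meta))


def read_epochs(path: str | Path) -> EpochTable:
    return EpochTable.from_frame(pd.read_csv(path))


def read_events(path: str | Path) -> EventTable:
    return EventTable.from_frame(pd.read_csv(path))


def read_unit_info(path: str | Path) -> list[UnitInfo]:
    df = pd.read_csv(path, dtype={"unit_id": str})
    out = []
    for _, row in df.iterrows():
        out.append(
            UnitInfo(
                unit_id=str(row["unit_id"]),
                putative_type=str(row.get("putative_type", "unknown")),
                tag_status=str(row.get("tag_status", "untagged")),
                peak_channel=(
                    int(row["peak_channel"]) if pd.notna(row.get("peak_channel")) else None
                ),
                depth_um=(
                    float(row["depth_um"]) if pd.notna(row.get("depth_um")) else None
                ),
            )
        )
    return out


def write_unit_info(units: Iterable[UnitInfo], path: str | Path) -> None:
    pd.DataFrame(
        [
            {
                "unit_id": u.unit_id,
                "putative_type": u.putative_type,
                "tag_status": u.tag_status,
                "peak_channel": u.peak_channel,
                "depth_um": u.depth_um,
            }
            for u in units
        ]
    ).to_csv(path, index=False)
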