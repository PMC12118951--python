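"""Core containers and interval algebra shared by every analysis stage.

All times are seconds from session start (t = 0), stored as float64.
Intervals are half-open ``[start, end)`` so that a spike sitting exactly on a
boundary is counted once, in the later interval.
"""

from __future__ import annotations

from dataclasses import dataclass, field

import numpy as np
import pandas as pd

NREM = "NREM"
REM = "REM"
WAKE = "WAKE"
MA = "MA"

STATES = (NREM, REM, WAKE, MA)


class ValidationError(ValueError):
    """Raised when a session artifact violates a structural invariant."""


# ---------------------------------------------------------------------------
# interval algebra on (n, 2) float arrays of [start, end) rows
# ---------------------------------------------------------------------------

def as_intervals(x) -> np.ndarray:
    """Coerce to an (n, 2) float64 array of [start, end) intervals."""
    arr = np.asarray(x, dtype=float)
    if arr.size == 0:
        return arr.reshape(0, 2)
    if arr.ndim != 2 or arr.shape[1] != 2:
        raise ValueError(f"expected (n, 2) intervals, got shape {arr.shape}")
    if np.any(arr[:, 0] >= arr[:, 1]):
        raise ValidationError("interval with start >= end")
    return arr


def total_duration(intervals) -> float:
    iv = as_intervals(intervals)
    return float(np.sum(iv[:, 1] - iv[:, 0]))


def intersect_intervals(a, b) -> np.ndarray:
    """Pairwise intersection of two sorted, non-overlapping interval sets."""
    a = as_intervals(a)
    b = as_intervals(b)
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
    return as_intervals(out) if out else np.empty((0, 2))


def subtract_intervals(a, b) -> np.ndarray:
    """Set difference a \\ b for sorted, non-overlapping interval sets."""
    a = as_intervals(a)
    b = as_intervals(b)
    out = []
    j = 0
    for lo, hi in a:
        cur = lo
        while j < len(b) and b[j, 1] <= cur:
            j += 1
        k = j
        while k < len(b) and b[k, 0] < hi:
            if b[k, 0] > cur:
                out.append((cur, b[k, 0]))
            cur = max(cur, b[k, 1])
            k += 1
        if cur < hi:
            out.append((cur, hi))
    return as_intervals(out) if out else np.empty((0, 2))


def merge_close_intervals(intervals, max_gap: float) -> np.ndarray:
    """Merge sorted intervals whose gap to the next one is < ``max_gap``."""
    iv = as_intervals(intervals)
    if len(iv) == 0:
        return iv
    out = [list(iv[0])]
    for lo, hi in iv[1:]:
        if lo - out[-1][1] < max_gap:
            out[-1][1] = max(out[-1][1], hi)
        else:
            out.append([lo, hi])
    return as_intervals(out)


def spikes_in_intervals(times: np.ndarray, intervals) -> np.ndarray:
    """Boolean mask of spikes falling inside any [start, end) interval."""
    iv = as_intervals(intervals)
    times = np.asarray(times, dtype=float)
    if len(iv) == 0 or times.size == 0:
        return np.zeros(times.shape, dtype=bool)
    starts = iv[:, 0]
    ends = iv[:, 1]
    idx = np.searchsorted(starts, times, side="right") - 1
    ok = idx >= 0
    ok[ok] &= times[ok] < ends[idx[ok]]
    return ok


def count_spikes_per_interval(times: np.ndarray, intervals) -> np.ndarray:
    iv = as_intervals(intervals)
    times = np.asarray(times, dtype=float)
    lo = np.searchsorted(times, iv[:, 0], side="left")
    hi = np.searchsorted(times, iv[:, 1], side="left")
    return hi - lo


# ---------------------------------------------------------------------------
# containers
# ---------------------------------------------------------------------------

@dataclass
class SpikeTrain:
    """Sorted spike times of one unit, the atom of all rate analyses.

    ``rates`` optionally carries the unit's true per-state rates (Hz);
    the synthetic-data generator uses it for exact event-gain superposition.
    """

    unit_id: str
    times: np.ndarray
    region: str = ""
    shank: int = 0
    rates: dict = None

    def __post_init__(self) -> None:
        self.times = np.asarray(self.times, dtype=float).ravel()
        if self.times.size > 1 and np.any(np.diff(self.times) <= 0):
            bad = int(np.flatnonzero(np.diff(self.times) <= 0)[0]) + 1
            raise ValidationError(
                f"unit {self.unit_id}: spike times not strictly increasing at index {bad}"
            )

    @property
    def n_spikes(self) -> int:
        return int(self.times.size)

    def mean_rate(self, duration: float) -> float:
        return self.n_spikes / duration if duration > 0 else float("nan")


@dataclass
class Hypnogram:
    """Ordered, non-overlapping state intervals covering the recording.

    ``usable`` flags epochs retained for analysis (short epochs are kept in
    the timeline but flagged unusable).
    """

    starts: np.ndarray
    ends: np.ndarray
    states: np.ndarray
    usable: np.ndarray = None

    def __post_init__(self) -> None:
        self.starts = np.asarray(self.starts, dtype=float).ravel()
        self.ends = np.asarray(self.ends, dtype=float).ravel()
        self.states = np.asarray(self.states, dtype=object).ravel()
        if self.usable is None:
            self.usable = np.ones(self.starts.shape, dtype=bool)
        else:
            self.usable = np.asarray(self.usable, dtype=bool).ravel()
        if not (len(self.starts) == len(self.ends) == len(self.states) == len(self.usable)):
            raise ValidationError("hypnogram column lengths differ")
        if np.any(self.starts >= self.ends):
            raise ValidationError("hypnogram epoch with start >= end")
        if len(self.starts) > 1:
            overlap = np.flatnonzero(self.starts[1:] < self.ends[:-1])
            if overlap.size:
                i = int(overlap[0])
                raise ValidationError(
                    f"overlapping hypnogram intervals at rows {i} and {i + 1}"
                )

    def __len__(self) -> int:
        return len(self.starts)

    @property
    def duration(self) -> float:
        return float(self.ends[-1] - self.starts[0]) if len(self) else 0.0

    def intervals(self, state: str, usable_only: bool = False) -> np.ndarray:
        sel = self.states == state
        if usable_only:
            sel &= self.usable
        return np.column_stack([self.starts[sel], self.ends[sel]])

    def state_duration(self, state: str, usable_only: bool = False) -> float:
        return total_duration(self.intervals(state, usable_only=usable_only))

    def to_dataframe(self) -> pd.DataFrame:
        return pd.DataFrame(
            {"start_s": self.starts, "end_s": self.ends, "label": self.states,
             "usable": self.usable.astype(int)}
        )

    @classmethod
    def from_dataframe(cls, df: pd.DataFrame) -> "Hypnogram":
        usable = df["usable"].to_numpy(dtype=bool) if "usable" in df else None
        return cls(df["start_s"].to_numpy(), df["end_s"].to_numpy(),
                   df["label"].to_numpy(dtype=object), usable)


@dataclass
class LfpSet:
    """Multi-channel LFP block: (n_channels, n_samples) float32 plus metadata.

    ``channels`` holds one dict per channel with keys name/region/shank/
    depth_order (0 = most superficial on its shank).
    """

    data: np.ndarray
    fs: float
    channels: list

    def __post_init__(self) -> None:
        self.data = np.asarray(self.data, dtype=np.float32)
        if self.data.ndim != 2:
            raise ValidationError("LFP data must be 2-D (channels x samples)")
        if len(self.channels) != self.data.shape[0]:
            raise ValidationError("channel metadata count != data rows")

    @property
    def n_samples(self) -> int:
        return int(self.data.shape[1])

    @property
    def times(self) -> np.ndarray:
        return np.arange(self.n_samples) / self.fs

    def channel_index(self, **query) -> list:
        out = []
        for i, meta in enumerate(self.channels):
            if all(meta.get(k) == v for k, v in query.items()):
                out.append(i)
        return out

    def shank_pair(self, region: str, shank: int) -> tuple:
        """(superficial, deep) channel indices for a shank; error if unpaired."""
        idx = self.channel_index(region=region, shank=shank)
        if len(idx) < 2:
            raise ValidationError(
                f"shank {shank} in {region} lacks a superficial/deep channel pair"
            )
        order = sorted(idx, key=lambda i: self.channels[i]["depth_order"])
        return order[0], order[-1]


@dataclass
class OscEvent:
    """One detected oscillatory event."""

    kind: str
    start: float
    end: float
    peak_time: float
    peak_z: float
    source: str = ""

    def __post_init__(self) -> None:
        if not (self.start < self.end):
            raise ValidationError("event start must precede end")
        if not (self.start <= self.peak_time < self.end):
            raise ValidationError("event peak_time outside [start, end)")

    @property
    def duration(self) -> float:
        return self.end - self.start


def events_to_frame(events) -> pd.DataFrame:
    rows = [(e.kind, e.start, e.end, e.peak_time, e.peak_z, e.source) for e in events]
    return pd.DataFrame(rows, columns=["kind", "start_s", "end_s", "peak_s", "peak_z", "source"])


def events_to_intervals(events) -> np.ndarray:
    if len(events) == 0:
        return np.empty((0, 2))
    return as_intervals([(e.start, e.end) for e in events])
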