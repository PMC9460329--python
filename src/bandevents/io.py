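"""Sample-series and event-stream containers plus file formats.

The band recorder produces a single voltage channel (mV) at a fixed sample
rate; downstream stages exchange either that waveform (:class:`SampleSeries`)
or the sparse event representation (:class:`EventStream`).  Each event is a
maximal falling segment of the waveform and is serialized as a fixed 16-byte
record: four 4-byte fields ``(T, H, V1, V2)`` — end-of-event timestamp, event
period in samples, and the amplitudes at the positive and negative edges.
"""

from __future__ import annotations

import csv
from dataclasses import dataclass, field
from fractions import Fraction
from pathlib import Path
from typing import Iterator, NamedTuple, Sequence

import numpy as np
from scipy import signal as _sig

__all__ = [
    "SampleSeries",
    "Event",
    "EventStream",
    "EVENT_RECORD_BYTES",
    "preprocess",
    "read_events",
    "write_events",
    "read_samples_csv",
    "write_samples_csv",
]

#: on-disk size of one event record (4 fields x 4 bytes, little-endian)
EVENT_RECORD_BYTES = 16

# little-endian wire layout: T and H as uint32 (T is a sample index on disk),
# V1/V2 as IEEE-754 single precision
_EVENT_DTYPE = np.dtype([("T", "<u4"), ("H", "<u4"), ("V1", "<f4"), ("V2", "<f4")])


class Event(NamedTuple):
    """One falling-segment event.

    T is the timestamp of the falling-edge sample (seconds), H the event
    period in samples, V1/V2 the waveform amplitude (mV) at the positive and
    negative edges.  The event spans ``[T - H/N, T]`` at sample rate N.
    """

    T: float
    H: int
    V1: float
    V2: float


@dataclass
class SampleSeries:
    """A uniformly sampled waveform Y(n) in mV."""

    values: np.ndarray
    sample_rate_hz: float
    start_time_s: float = 0.0

    def __post_init__(self) -> None:
        self.values = np.asarray(self.values, dtype=float)
        if self.sample_rate_hz <= 0:
            raise ValueError("sample_rate_hz must be positive")
        if self.values.ndim != 1:
            raise ValueError("values must be one-dimensional")
        if self.values.size and not np.all(np.isfinite(self.values)):
            raise ValueError("values must be finite")

    def __len__(self) -> int:
        return self.values.size

    @property
    def times(self) -> np.ndarray:
        return self.start_time_s + np.arange(len(self)) / self.sample_rate_hz

    @property
    def duration_s(self) -> float:
        return len(self) / self.sample_rate_hz


@dataclass
class EventStream:
    """Ordered event list with a common sample rate.

    Stored as parallel arrays for vectorized processing; iteration yields
    :class:`Event` tuples.
    """

    sample_rate_hz: float
    T: np.ndarray = field(default_factory=lambda: np.empty(0))
    H: np.ndarray = field(default_factory=lambda: np.empty(0, dtype=int))
    V1: np.ndarray = field(default_factory=lambda: np.empty(0))
    V2: np.ndarray = field(default_factory=lambda: np.empty(0))

    def __post_init__(self) -> None:
        self.T = np.asarray(self.T, dtype=float)
        self.H = np.asarray(self.H, dtype=int)
        self.V1 = np.asarray(self.V1, dtype=float)
        self.V2 = np.asarray(self.V2, dtype=float)
        n = len(self.T)
        if not (len(self.H) == len(self.V1) == len(self.V2) == n):
            raise ValueError("field arrays must have equal length")
        if self.sample_rate_hz <= 0:
            raise ValueError("sample_rate_hz must be positive")
        if n and np.any(self.H < 1):
            raise ValueError("event periods H must be >= 1 sample")
        if n > 1 and np.any(np.diff(self.T) <= 0):
            raise ValueError("event timestamps must be strictly increasing")

    def __len__(self) -> int:
        return len(self.T)

    def __iter__(self) -> Iterator[Event]:
        for t, h, v1, v2 in zip(self.T, self.H, self.V1, self.V2):
            yield Event(float(t), int(h), float(v1), float(v2))

    def __getitem__(self, i: int) -> Event:
        return Event(float(self.T[i]), int(self.H[i]), float(self.V1[i]), float(self.V2[i]))

    @classmethod
    def from_events(cls, events: Sequence[Event], sample_rate_hz: float) -> "EventStream":
        ev = sorted(events, key=lambda e: e.T)
        return cls(
            sample_rate_hz,
            np.array([e.T for e in ev], dtype=float),
            np.array([e.H for e in ev], dtype=int),
            np.array([e.V1 for e in ev], dtype=float),
            np.array([e.V2 for e in ev], dtype=float),
        )

    @property
    def start_times(self) -> np.ndarray:
        """Positive-edge times, T - H/N."""
        return self.T - self.H / self.sample_rate_hz


def preprocess(
    raw: SampleSeries,
    cutoff_hz: float = 100.0,
    order: int = 2,
    target_rate_hz: float = 200.0,
    zero_phase: bool = True,
) -> SampleSeries:
    """Anti-alias low-pass filter then resample, as done on the bench recordings.

    Defaults follow the acquisition chain used for the band data: a
    second-order Butterworth at 100 Hz applied to the high-rate recording,
    then resampling to 200 Hz.  ``zero_phase`` selects forward-backward
    filtering (offline use); a causal single pass is available for
    streaming-like processing.
    """
    if len(raw) == 0:
        raise ValueError("cannot preprocess an empty series")
    nyq = raw.sample_rate_hz / 2.0
    if cutoff_hz >= nyq:
        raise ValueError(f"cutoff {cutoff_hz} Hz must be below Nyquist {nyq} Hz")
    if target_rate_hz > raw.sample_rate_hz:
        raise ValueError("target rate must not exceed the input rate")

    sos = _sig.butter(order, cutoff_hz, btype="low", fs=raw.sample_rate_hz, output="sos")
    if zero_phase:
        filtered = _sig.sosfiltfilt(sos, raw.values)
    else:
        filtered = _sig.sosfilt(sos, raw.values)

    ratio = Fraction(target_rate_hz / raw.sample_rate_hz).limit_denominator(10_000)
    if ratio == 1:
        resampled = filtered
    else:
        resampled = _sig.resample_poly(filtered, ratio.numerator, ratio.denominator, padtype="line")
    return SampleSeries(resampled, target_rate_hz, raw.start_time_s)


def write_events(stream: EventStream, path: str | Path) -> int:
    """Serialize an event stream to 16-byte binary records; returns bytes written."""
    n = stream.sample_rate_hz
    rec = np.empty(len(stream), dtype=_EVENT_DTYPE)
    t_idx = np.rint(stream.T * n)
    if len(stream) and (np.any(t_idx < 0) or np.any(stream.H < 1)):
        raise ValueError("events must have non-negative times and H >= 1")
    rec["T"] = t_idx.astype(np.uint32)
    rec["H"] = stream.H.astype(np.uint32)
    rec["V1"] = stream.V1.astype(np.float32)
    rec["V2"] = stream.V2.astype(np.float32)
    data = rec.tobytes()
    Path(path).write_bytes(data)
    return len(data)


def read_events(path: str | Path, sample_rate_hz: float) -> EventStream:
    """Read a 16-byte-record event file written by :func:`write_events`."""
    data = Path(path).read_bytes()
    if len(data) % EVENT_RECORD_BYTES != 0:
        raise ValueError(
            f"truncated event file: {len(data)} bytes is not a multiple of {EVENT_RECORD_BYTES}"
        )
    rec = np.frombuffer(data, dtype=_EVENT_DTYPE)
    return EventStream(
        sample_rate_hz,
        rec["T"].astype(float) / sample_rate_hz,
        rec["H"].astype(int),
        rec["V1"].astype(float),
        rec["V2"].astype(float),
    )


def write_samples_csv(series: SampleSeries, path: str | Path) -> None:
    """Write a two-column CSV (time_s, amplitude_mv) with a header line."""
    with open(path, "w", newline="") as fh:
        w = csv.writer(fh)
        w.writerow(["time_s", "amplitude_mv"])
        for t, v in zip(series.times, series.values):
            w.writerow([f"{t:.9g}", f"{v:.9g}"])


def read_samples_csv(path: str | Path, sample_rate_hz: float | None = None) -> SampleSeries:
    """Read a (time_s, amplitude_mv) CSV; the rate is inferred from the time
    column unless given explicitly."""
    arr = np.loadtxt(path, delimiter=",", skiprows=1, ndmin=2)
    if arr.shape[1] != 2:
        raise ValueError("expected a two-column CSV (time_s, amplitude_mv)")
    t, v = arr[:, 0], arr[:, 1]
    if sample_rate_hz is None:
        if len(t) < 2:
            raise ValueError("cannot infer sample rate from fewer than two samples")
        sample_rate_hz = 1.0 / float(np.median(np.diff(t)))
    return SampleSeries(v, sample_rate_hz, start_time_s=float(t[0]))
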