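"""Delay-compare-integrate event generation.

The front end compares each sample with a delayed copy of itself: the binary
event signal is V(n) = 1 where Y(n+p) < Y(n) (the waveform is falling over
the delay p) and 0 otherwise.  A cumulative sum runs while V stays high and
resets at each falling edge of V; the final count before a reset, H, is the
event period.  Each maximal V = 1 run therefore becomes one event
(T, H, V1, V2): long runs come from respiratory falling flanks and short runs
from cardiac pulse notches.
"""

from __future__ import annotations

from dataclasses import dataclass

import numpy as np

from .io import EventStream, SampleSeries

__all__ = ["ComparatorTrace", "comparator", "integrate_to_events", "generate_events"]

#: default comparator delay in samples (50 ms at 200 Hz)
DEFAULT_DELAY = 10


@dataclass
class ComparatorTrace:
    """Binary event signal V(n) and its running sum C(n) for delay p."""

    p: int
    V: np.ndarray  # uint8, 0/1 per sample
    C: np.ndarray  # int, running count within each V = 1 run, 0 elsewhere


def comparator(series: SampleSeries, p: int = DEFAULT_DELAY) -> ComparatorTrace:
    """Compute V(n) = [Y(n+p) < Y(n)] and the per-run cumulative sum C(n).

    Ties (Y(n+p) == Y(n)) yield V = 0.  The last p samples, which have no
    delayed partner, carry V = 0.
    """
    if p < 1:
        raise ValueError("delay p must be >= 1 sample")
    y = series.values
    if len(y) < p + 2:
        raise ValueError(f"series of length {len(y)} is too short for delay p={p}")

    v = np.zeros(len(y), dtype=np.uint8)
    v[: len(y) - p] = (y[p:] < y[: len(y) - p]).astype(np.uint8)

    # running count within runs: cumulative ones minus the count at the most
    # recent reset (V = 0) position
    ones = np.cumsum(v)
    at_reset = np.where(v == 0, ones, 0)
    c = np.where(v == 1, ones - np.maximum.accumulate(at_reset), 0)
    return ComparatorTrace(p=p, V=v, C=c.astype(int))


def integrate_to_events(trace: ComparatorTrace, series: SampleSeries) -> EventStream:
    """Convert maximal V = 1 runs into events.

    For a run of length H starting at sample s: T is the time of the
    falling-edge sample s + H, V1 = Y(s) (positive edge), V2 = Y(s + H)
    (negative edge).  A run still open at the end of the record is discarded.
    """
    if len(trace.V) != len(series):
        raise ValueError("trace and series must be aligned (equal length)")
    v = trace.V
    n = series.sample_rate_hz
    edges = np.diff(np.concatenate(([0], v, [0])).astype(np.int8))
    starts = np.flatnonzero(edges == 1)
    ends = np.flatnonzero(edges == -1)  # first index after each run

    # a run reaching the last sample has no falling-edge sample to read
    keep = ends < len(series)
    starts, ends = starts[keep], ends[keep]

    y = series.values
    return EventStream(
        sample_rate_hz=n,
        T=series.start_time_s + ends / n,
        H=(ends - starts).astype(int),
        V1=y[starts],
        V2=y[ends],
    )


def generate_events(series: SampleSeries, p: int = DEFAULT_DELAY) -> EventStream:
    """Full front end: comparator followed by run integration."""
    return integrate_to_events(comparator(series, p), series)
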