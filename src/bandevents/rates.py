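"""RR and HR time series from classified / compensated event streams."""

from __future__ import annotations

from dataclasses import dataclass, field
from pathlib import Path

import numpy as np

from .compensation import PeriodSeries
from .io import EventStream

__all__ = [
    "RateSeries",
    "breath_to_breath_rr",
    "event_hr",
    "windowed_hr",
    "ground_truth_hr",
    "naive_mean_hr",
    "smooth_moving_average",
]

#: trailing window (events/beats) for the per-event HR mean
HR_EVENT_WINDOW = 30

#: length of the output smoothing filter (simple causal moving average)
HR_SMOOTH_TAPS = 6


@dataclass
class RateSeries:
    """Timestamped rate estimates (beats/min or breaths/min)."""

    times: np.ndarray
    rates: np.ndarray
    kind: str = "HR"  # "HR" | "RR"
    smoothing: str = "none"

    def __post_init__(self) -> None:
        self.times = np.asarray(self.times, dtype=float)
        self.rates = np.asarray(self.rates, dtype=float)
        if len(self.times) != len(self.rates):
            raise ValueError("times and rates must align")
        if len(self.times) > 1 and np.any(np.diff(self.times) <= 0):
            raise ValueError("times must be strictly increasing")
        if len(self.rates) and np.any(self.rates <= 0):
            raise ValueError("rates must be positive")

    def __len__(self) -> int:
        return len(self.rates)

    def write_csv(self, path: str | Path) -> None:
        with open(path, "w") as fh:
            fh.write("time_s,rate,kind\n")
            for t, r in zip(self.times, self.rates):
                fh.write(f"{t:.9g},{r:.9g},{self.kind}\n")


def smooth_moving_average(x: np.ndarray, taps: int = HR_SMOOTH_TAPS) -> np.ndarray:
    """Causal simple moving average; head values average what is available."""
    out = np.empty_like(np.asarray(x, dtype=float))
    csum = np.cumsum(np.concatenate(([0.0], x)))
    for i in range(len(out)):
        lo = max(0, i - taps + 1)
        out[i] = (csum[i + 1] - csum[lo]) / (i + 1 - lo)
    return out


def breath_to_breath_rr(resp_events: EventStream) -> RateSeries:
    """RR from consecutive respiratory event timestamps: 60/(T_{i+1} - T_i),
    reported at the later event."""
    if len(resp_events) < 2:
        return RateSeries(np.empty(0), np.empty(0), kind="RR")
    intervals = np.diff(resp_events.T)
    return RateSeries(resp_events.T[1:], 60.0 / intervals, kind="RR")


def _trailing_mean(x: np.ndarray, window: int) -> np.ndarray:
    """Means of each full trailing window (valid part only)."""
    return np.convolve(x, np.ones(window) / window, mode="valid")


def event_hr(
    compensated: PeriodSeries,
    window: int = HR_EVENT_WINDOW,
    smooth_taps: int = HR_SMOOTH_TAPS,
) -> RateSeries:
    """Per-event HR: mean of the last ``window`` instantaneous rates, then a
    causal ``smooth_taps``-sample moving average.  Events before the window
    fills produce no output."""
    if len(compensated) < window:
        return RateSeries(np.empty(0), np.empty(0), kind="HR")
    inst = 60.0 / compensated.periods
    windowed = _trailing_mean(inst, window)
    smoothed = smooth_moving_average(windowed, smooth_taps)
    return RateSeries(
        compensated.times[window - 1 :],
        smoothed,
        kind="HR",
        smoothing=f"{window}-event mean + {smooth_taps}-sample moving average",
    )


def windowed_hr(ps: PeriodSeries, window_s: float) -> RateSeries:
    """HR per nonoverlapping window aligned to t = 0: 60 / mean(periods in
    window), reported at the window end; empty windows are absent."""
    if window_s not in (15.0, 30.0, 60.0):
        raise ValueError("window_s must be 15, 30 or 60 seconds")
    times, rates = [], []
    if len(ps):
        for w in range(int(np.floor(ps.times.max() / window_s)) + 1):
            mask = (ps.times >= w * window_s) & (ps.times < (w + 1) * window_s)
            if mask.any():
                times.append((w + 1) * window_s)
                rates.append(60.0 / ps.periods[mask].mean())
    return RateSeries(np.asarray(times), np.asarray(rates), kind="HR", smoothing=f"{window_s:g}s window mean")


def ground_truth_hr(beat_times: np.ndarray, window: int = HR_EVENT_WINDOW, smooth_taps: int = 0) -> RateSeries:
    """Reference HR from true beat times: beat-to-beat rate averaged over the
    trailing ``window`` beats (optional smoothing off by default)."""
    beat_times = np.asarray(beat_times, dtype=float)
    if len(beat_times) < window + 1:
        return RateSeries(np.empty(0), np.empty(0), kind="HR")
    inst = 60.0 / np.diff(beat_times)
    windowed = _trailing_mean(inst, window)
    if smooth_taps > 1:
        windowed = smooth_moving_average(windowed, smooth_taps)
    return RateSeries(beat_times[window:], windowed, kind="HR", smoothing=f"{window}-beat mean")


def naive_mean_hr(ps: PeriodSeries) -> float:
    """HR from the raw mean period, with no missed-beat compensation."""
    if len(ps) == 0:
        raise ValueError("no periods")
    return 60.0 / ps.periods.mean()
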