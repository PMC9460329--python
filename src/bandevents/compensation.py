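"""Missed-heartbeat compensation for cardiac event-period series.

The band misses a substantial fraction of heartbeats, so the observed
cardiac event periods include values that are (near-)integer multiples of
the true beat period.  Three alternative correction strategies are provided:

* :func:`median_compensate` — streaming median-harmonics rule: each period is
  compared with 1x..5x the moving median of the previous 30 periods and
  divided by the best-matching integer.
* bucketing (:class:`BucketState` with :func:`bucket_update`,
  :func:`bucket_majority`, :func:`bucket_hr`) — a nonuniform histogram of the
  last 30 periods over fixed thresholds; majority buckets define the
  prevailing period and harmonic buckets are folded back in.
* :func:`kmeans_compensate` — windowed 3-cluster k-means seeded at the
  median and its multiples; non-dominant elements are scaled by 1/2, 1/3 or
  1/4 back toward the dominant-cluster mean.
"""

from __future__ import annotations

from collections import deque
from dataclasses import dataclass, field

import numpy as np

from .io import EventStream

__all__ = [
    "PeriodSeries",
    "median_compensate",
    "kmeans_compensate",
    "BucketState",
    "BUCKET_THRESHOLDS",
    "bucket_index",
    "bucket_update",
    "bucket_majority",
    "bucket_hr",
    "bucket_hr_series",
    "MEDIAN_HISTORY",
    "HARMONIC_FACTORS",
]

#: fixed bucket threshold array (seconds); bucket i holds periods in
#: (threshold[i-1], threshold[i]]
BUCKET_THRESHOLDS = np.array(
    [0.4, 0.45, 0.5, 0.6, 0.7, 0.8, 0.9, 1.0, 1.2, 1.6, 2.0, 2.4, 2.8, 3.2]
)

#: moving-median history length (cardiac events) for the median algorithm
MEDIAN_HISTORY = 30

#: candidate integer divisors for the median-harmonics rule
HARMONIC_FACTORS = (1, 2, 3, 4, 5)

#: FIFO capacity shared by the bucketing and median algorithms
FIFO_SIZE = 30


@dataclass
class PeriodSeries:
    """Cardiac event periods: ``periods[i] = times[i] - previous event time``."""

    times: np.ndarray
    periods: np.ndarray

    def __post_init__(self) -> None:
        self.times = np.asarray(self.times, dtype=float)
        self.periods = np.asarray(self.periods, dtype=float)
        if len(self.times) != len(self.periods):
            raise ValueError("times and periods must align")
        if len(self.periods) and np.any(self.periods <= 0):
            raise ValueError("periods must be positive")

    def __len__(self) -> int:
        return len(self.periods)

    @classmethod
    def from_event_stream(cls, stream: EventStream) -> "PeriodSeries":
        if len(stream) < 2:
            return cls(np.empty(0), np.empty(0))
        return cls(times=stream.T[1:], periods=np.diff(stream.T))

    def moving_median(self, window: int = 20) -> np.ndarray:
        """Trailing moving median of the periods (shorter head windows included),
        for diagnostics/plotting."""
        out = np.empty(len(self))
        for i in range(len(self)):
            out[i] = np.median(self.periods[max(0, i - window + 1) : i + 1])
        return out


# ---------------------------------------------------------------------------
# median-harmonics algorithm

def median_compensate(ps: PeriodSeries, history: int = MEDIAN_HISTORY) -> PeriodSeries:
    """Divide each period by the harmonic of the trailing median it best matches.

    For event period h with at least ``history`` earlier periods, the moving
    median x of those previous ``history`` periods defines candidate
    references k*x for k in 1..5; h is divided by the k minimizing
    |h - k*x|.  Events inside the warm-up region produce no output.
    """
    if len(ps) <= history:
        return PeriodSeries(np.empty(0), np.empty(0))
    times, periods = ps.times[history:], ps.periods[history:]
    out = np.empty_like(periods)
    for i, (h, j) in enumerate(zip(periods, range(history, len(ps)))):
        x = np.median(ps.periods[j - history : j])
        k = min(HARMONIC_FACTORS, key=lambda k: abs(h - k * x))
        out[i] = h / k
    return PeriodSeries(times, out)


# ---------------------------------------------------------------------------
# k-means algorithm

def _lloyd_1d(x: np.ndarray, seeds: np.ndarray, max_iter: int = 100, tol: float = 1e-6) -> np.ndarray:
    """Plain 1-D Lloyd iteration from fixed seeds; empty clusters keep their seed."""
    centers = seeds.astype(float).copy()
    for _ in range(max_iter):
        labels = np.argmin(np.abs(x[:, None] - centers[None, :]), axis=1)
        new = centers.copy()
        for j in range(len(centers)):
            members = x[labels == j]
            if len(members):
                new[j] = members.mean()
        if np.max(np.abs(new - centers)) < tol:
            centers = new
            break
        centers = new
    return np.argmin(np.abs(x[:, None] - centers[None, :]), axis=1)


@dataclass
class KMeansWindowResult:
    """Per-window HR estimates from the k-means correction."""

    window_end_s: float
    n_periods: int
    hr_dominant: float  # dominant cluster only, no compensation
    hr_compensated: float  # all periods after harmonic scaling


def kmeans_compensate(ps: PeriodSeries, window_s: float = 60.0) -> list[KMeansWindowResult]:
    """Windowed 3-cluster k-means missed-beat correction.

    Within each nonoverlapping window (aligned to t = 0): cluster the periods
    with seeds at the window median x, 2x and 3x; the largest cluster is
    dominant.  Each non-dominant period e is scaled by the factor in
    {1/2, 1/3, 1/4} minimizing |e*f - dominant mean|.  Windows with fewer
    than 3 periods yield no estimate.
    """
    if window_s not in (15.0, 30.0, 60.0):
        raise ValueError("window_s must be 15, 30 or 60 seconds")
    results: list[KMeansWindowResult] = []
    if len(ps) == 0:
        return results
    n_windows = int(np.floor(ps.times.max() / window_s)) + 1
    for w in range(n_windows):
        mask = (ps.times >= w * window_s) & (ps.times < (w + 1) * window_s)
        periods = ps.periods[mask]
        if len(periods) < 3:
            continue
        x = np.median(periods)
        labels = _lloyd_1d(periods, np.array([x, 2 * x, 3 * x]))
        counts = np.bincount(labels, minlength=3)
        dom = int(np.argmax(counts))
        dom_mean = periods[labels == dom].mean()

        adjusted = periods.copy()
        nondom = labels != dom
        for i in np.flatnonzero(nondom):
            factor = min((0.5, 1.0 / 3.0, 0.25), key=lambda f: abs(periods[i] * f - dom_mean))
            adjusted[i] = periods[i] * factor
        results.append(
            KMeansWindowResult(
                window_end_s=(w + 1) * window_s,
                n_periods=len(periods),
                hr_dominant=60.0 / dom_mean,
                hr_compensated=60.0 / adjusted.mean(),
            )
        )
    return results


# ---------------------------------------------------------------------------
# bucketing algorithm

def bucket_index(period_s: float) -> int:
    """1-based bucket index: the first threshold >= period (0.67 s -> 5);
    periods beyond the last threshold clamp to the last bucket."""
    if period_s <= 0:
        raise ValueError("period must be positive")
    pos = int(np.searchsorted(BUCKET_THRESHOLDS, period_s, side="left"))
    return min(pos, len(BUCKET_THRESHOLDS) - 1) + 1


@dataclass
class BucketState:
    """Streaming state: 30-period FIFO plus per-bucket counts and means."""

    fifo: deque = field(default_factory=lambda: deque(maxlen=None))
    counters: np.ndarray = field(default_factory=lambda: np.zeros(len(BUCKET_THRESHOLDS), dtype=int))
    means: np.ndarray = field(default_factory=lambda: np.zeros(len(BUCKET_THRESHOLDS)))
    last_valid_hr: float | None = None

    def check(self) -> None:
        assert int(self.counters.sum()) == len(self.fifo) <= FIFO_SIZE
        assert np.all(self.counters >= 0)
        assert np.all(self.means[self.counters == 0] == 0.0)


def bucket_update(state: BucketState, period_s: float) -> BucketState:
    """Insert a period into the FIFO/histogram, evicting the oldest if full."""
    idx = bucket_index(period_s) - 1
    if len(state.fifo) == FIFO_SIZE:
        old_p, old_i = state.fifo.popleft()
        c = state.counters[old_i]
        state.counters[old_i] = c - 1
        state.means[old_i] = 0.0 if c == 1 else (state.means[old_i] * c - old_p) / (c - 1)
    c = state.counters[idx]
    state.means[idx] = (state.means[idx] * c + period_s) / (c + 1)
    state.counters[idx] = c + 1
    state.fifo.append((period_s, idx))
    return state


@dataclass
class MajorityResult:
    """Prevailing bucket: ``index`` is the 0-based array position."""

    index: int
    mean_period_s: float
    rule: str  # "single" | "dual" | "triple"


def bucket_majority(state: BucketState) -> MajorityResult | None:
    """Find the prevailing period bucket by the priority rules.

    1. single majority: any counter > 20;
    2. dual combined majority: two adjacent counters summing > 15;
    3. triple combined majority: three adjacent counters summing > 15.

    Within a rule, the qualifying window with the largest count wins (ties:
    smallest index); for dual/triple windows the returned index is the
    heaviest bucket of the window and the mean is count-weighted.
    """
    c, m = state.counters, state.means

    def _best_window(width: int) -> tuple[int, float] | None:
        limit = 20 if width == 1 else 15
        sums = np.convolve(c, np.ones(width, dtype=int), mode="valid")
        qual = np.flatnonzero(sums > limit)
        if len(qual) == 0:
            return None
        start = int(qual[np.argmax(sums[qual])])  # argmax takes smallest on ties
        win = slice(start, start + width)
        idx = start + int(np.argmax(c[win]))
        mean = float(np.dot(c[win], m[win]) / c[win].sum())
        return idx, mean

    for width, rule in ((1, "single"), (2, "dual"), (3, "triple")):
        found = _best_window(width)
        if found is not None:
            return MajorityResult(index=found[0], mean_period_s=found[1], rule=rule)
    return None


def bucket_hr(state: BucketState) -> float | None:
    """HR (beats/min) from the current bucket state.

    With a majority at position i, the base period is the count-weighted mean
    over buckets i-1, i, i+1.  Buckets beyond i+1 holding more than three
    elements are folded in at half or a third of their mean period when the
    implied rate lands within 20 beats/min of the established rate (missed
    single or double beats).  Without a majority the last valid HR is
    returned; None if none exists yet.
    """
    maj = bucket_majority(state)
    if maj is None:
        return state.last_valid_hr
    c, m = state.counters, state.means
    i = maj.index
    lo, hi = max(i - 1, 0), min(i + 1, len(c) - 1)
    win = slice(lo, hi + 1)
    total = float(np.dot(c[win], m[win]))
    count = int(c[win].sum())
    established_hr = 60.0 * count / total

    for j in range(i + 2, len(c)):
        if c[j] > 3:
            for d in (2, 3):
                cand = m[j] / d
                if abs(60.0 / cand - established_hr) <= 20.0:
                    total += c[j] * cand
                    count += c[j]
                    break
    hr = 60.0 * count / total
    state.last_valid_hr = hr
    return hr


def bucket_hr_series(ps: PeriodSeries) -> tuple[np.ndarray, np.ndarray]:
    """Stream all periods through the bucketing algorithm.

    Returns (times, hr) at every event where an HR estimate exists (after the
    pre-filling period during which no majority can form).
    """
    state = BucketState()
    times, rates = [], []
    for t, h in zip(ps.times, ps.periods):
        bucket_update(state, h)
        hr = bucket_hr(state)
        if hr is not None:
            times.append(t)
            rates.append(hr)
    return np.asarray(times), np.asarray(rates)
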