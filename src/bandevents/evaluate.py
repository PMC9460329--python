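"""Detection metrics, rate-error statistics, and data-size budget arithmetic.

Detection scoring matches detected peak times against ground-truth times
within a tolerance and reports sensitivity / precision / miss rate / false
discovery rate.  The size arithmetic quantifies the storage and bus-transfer
budget of the event representation versus raw sampling (binary kB/MB, i.e.
1024-based, which is the convention the budget figures use).
"""

from __future__ import annotations

from dataclasses import dataclass
from decimal import ROUND_HALF_UP, Decimal

import numpy as np

from .rates import RateSeries

__all__ = [
    "DetectionReport",
    "match_events",
    "RateErrorStats",
    "rate_error",
    "SizeBudget",
    "recording_size",
    "stream_sizes",
    "bus_read_time_us",
    "mean_event_period_ms",
]

#: default matching tolerances (seconds)
BEAT_MATCH_TOL_S = 0.150
BREATH_MATCH_TOL_S = 0.500


@dataclass
class DetectionReport:
    """TP/FP/FN counts with the derived percentage metrics."""

    tp: int
    fp: int
    fn: int

    @property
    def sensitivity(self) -> float:
        return 100.0 * self.tp / (self.tp + self.fn) if self.tp + self.fn else float("nan")

    @property
    def precision(self) -> float:
        return 100.0 * self.tp / (self.tp + self.fp) if self.tp + self.fp else float("nan")

    @property
    def miss_rate(self) -> float:
        return 100.0 - self.sensitivity

    @property
    def false_discovery_rate(self) -> float:
        return 100.0 - self.precision

    def as_dict(self) -> dict:
        return {
            "tp": self.tp,
            "fp": self.fp,
            "fn": self.fn,
            "sensitivity_pct": self.sensitivity,
            "precision_pct": self.precision,
            "miss_rate_pct": self.miss_rate,
            "false_discovery_rate_pct": self.false_discovery_rate,
        }


def match_events(
    detected_times: np.ndarray,
    truth_times: np.ndarray,
    tolerance_s: float,
) -> DetectionReport:
    """Greedy one-to-one nearest matching within +/- tolerance.

    Candidate (detection, truth) pairs within tolerance are taken in order of
    increasing |dt|; each detection and each truth may be used once.  Matched
    pairs are TP, leftover detections FP, leftover truths FN.
    """
    det = np.asarray(detected_times, dtype=float)
    tru = np.asarray(truth_times, dtype=float)
    pairs = []
    for i, t in enumerate(det):
        lo = np.searchsorted(tru, t - tolerance_s, side="left")
        hi = np.searchsorted(tru, t + tolerance_s, side="right")
        for j in range(lo, hi):
            pairs.append((abs(t - tru[j]), i, j))
    pairs.sort()
    used_det: set[int] = set()
    used_tru: set[int] = set()
    for _, i, j in pairs:
        if i not in used_det and j not in used_tru:
            used_det.add(i)
            used_tru.add(j)
    tp = len(used_det)
    return DetectionReport(tp=tp, fp=len(det) - tp, fn=len(tru) - tp)


@dataclass
class RateErrorStats:
    """Absolute-error statistics of an estimate against a reference series."""

    mean_abs: float
    sd_abs: float
    median_abs: float
    n: int

    def as_dict(self) -> dict:
        return {
            "mean_abs": self.mean_abs,
            "sd_abs": self.sd_abs,
            "median_abs": self.median_abs,
            "n": self.n,
        }


def rate_error(estimate: RateSeries, truth: RateSeries) -> RateErrorStats:
    """Absolute error of ``estimate`` held (previous-value) onto truth times.

    Truth samples before the first estimate are excluded (no estimate exists
    yet to hold).
    """
    if len(estimate) == 0 or len(truth) == 0:
        raise ValueError("both series must be non-empty")
    idx = np.searchsorted(estimate.times, truth.times, side="right") - 1
    valid = idx >= 0
    if not valid.any():
        raise ValueError("no overlap between estimate and truth")
    err = np.abs(estimate.rates[idx[valid]] - truth.rates[valid])
    return RateErrorStats(
        mean_abs=float(err.mean()),
        sd_abs=float(err.std(ddof=0)),
        median_abs=float(np.median(err)),
        n=int(err.size),
    )


# ---------------------------------------------------------------------------
# size / bandwidth budget arithmetic

@dataclass(frozen=True)
class SizeBudget:
    """Record sizes: raw sample (timestamp + value), full event, result-only
    event (V1/V2 discarded)."""

    raw_record_bytes: int = 8
    event_record_bytes: int = 16
    result_record_bytes: int = 8

    def __post_init__(self) -> None:
        if min(self.raw_record_bytes, self.event_record_bytes, self.result_record_bytes) <= 0:
            raise ValueError("record sizes must be positive")


def _round2(x: float) -> float:
    return float(Decimal(repr(x)).quantize(Decimal("0.01"), rounding=ROUND_HALF_UP))


def recording_size(
    duration_s: float,
    rate_hz: float,
    sample_bits: int = 24,
    timestamp_bits: int = 32,
) -> dict:
    """Raw recording size: samples x (sample + timestamp bits).

    Returns bytes and MB (1 MB = 1024**2 bytes, rounded to 2 decimals).
    """
    if sample_bits % 8 or timestamp_bits % 8:
        raise ValueError("bit widths must be multiples of 8")
    samples = duration_s * rate_hz
    nbytes = samples * (sample_bits + timestamp_bits) / 8
    return {"samples": samples, "bytes": nbytes, "mb": _round2(nbytes / 1024**2)}


def stream_sizes(n_samples: int, n_events: int, budget: SizeBudget | None = None) -> dict:
    """Raw / event / result stream sizes in bytes and kB (1 kB = 1024 bytes,
    2 decimals, round half up)."""
    if n_samples < 0 or n_events < 0:
        raise ValueError("counts must be non-negative")
    budget = budget or SizeBudget()
    raw = n_samples * budget.raw_record_bytes
    events = n_events * budget.event_record_bytes
    results = n_events * budget.result_record_bytes
    return {
        "raw_bytes": raw,
        "event_bytes": events,
        "result_bytes": results,
        "raw_kb": _round2(raw / 1024),
        "event_kb": _round2(events / 1024),
        "result_kb": _round2(results / 1024),
        "reduction_events": raw / events if events else float("inf"),
        "reduction_results": raw / results if results else float("inf"),
    }


def bus_read_time_us(bits: int, clock_hz: float) -> float:
    """Pure transfer time of ``bits`` over a serial bus at ``clock_hz``, in
    microseconds (no protocol overhead)."""
    if clock_hz <= 0:
        raise ValueError("clock must be positive")
    if bits < 0:
        raise ValueError("bits must be non-negative")
    return bits / clock_hz * 1e6


def mean_event_period_ms(duration_s: float, n_events: int) -> float:
    """Average spacing between events over a record, in milliseconds."""
    if n_events <= 0:
        raise ValueError("n_events must be positive")
    return duration_s / n_events * 1e3
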