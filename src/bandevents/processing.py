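"""Event-stream repair, respiratory/cardiac classification, and FP rejection.

A heartbeat during inspiration can split one long respiratory event into two
long events separated by only a few samples; those pairs are re-merged and
the short gap re-emitted as a cardiac blip.  Classification then thresholds
on the event period H, and a physiological-rate check rejects false-positive
detections that would imply more than 60 breaths/min or 180 beats/min.
"""

from __future__ import annotations

from dataclasses import dataclass

import numpy as np

from .io import Event, EventStream

__all__ = [
    "ProcessingParams",
    "ClassifiedEvents",
    "merge_split_respiratory",
    "classify",
    "reject_false_positives",
    "process_events",
]


@dataclass(frozen=True)
class ProcessingParams:
    """Thresholds for repair, classification and rejection.

    ``h_split`` separates respiratory (H > h_split) from cardiac events and
    also bounds the merge gap, in samples at the stream's rate.  The minimum
    intervals come from physiological maxima of 60 breaths/min and 180
    beats/min.
    """

    h_split: int = 20
    min_resp_interval_s: float = 1.0
    min_card_interval_s: float = 1.0 / 3.0

    def __post_init__(self) -> None:
        if self.h_split <= 0 or self.min_resp_interval_s <= 0 or self.min_card_interval_s <= 0:
            raise ValueError("all processing parameters must be positive")


@dataclass
class ClassifiedEvents:
    """Event stream split into respiratory and cardiac lists."""

    respiratory: EventStream
    cardiac: EventStream

    @property
    def sample_rate_hz(self) -> float:
        return self.respiratory.sample_rate_hz


def merge_split_respiratory(stream: EventStream, params: ProcessingParams | None = None) -> EventStream:
    """Re-merge long events separated by a sub-threshold gap.

    For consecutive events E1, E2 with both periods above ``h_split``, the
    inter-event period is P = T2 - H2/N - T1.  When P*N < h_split the pair is
    replaced by a short cardiac blip covering the gap (H = P*N rounded, at
    least 1; T at the start of E2; V1 from E2, V2 from E1) and a merged
    respiratory event (H = H1 + H2, T = T2, V1 from E1, V2 from E2).  The
    scan is left-to-right and a merged event may merge again with its
    successor.  A negative P (overlapping events) is treated as a zero gap.
    """
    params = params or ProcessingParams()
    if len(stream) < 2:
        return stream
    n = stream.sample_rate_hz
    h_split = params.h_split

    out: list[Event] = []
    blips: list[Event] = []
    cur = stream[0]
    for i in range(1, len(stream)):
        nxt = stream[i]
        p_gap = nxt.T - nxt.H / n - cur.T
        if cur.H > h_split and nxt.H > h_split and p_gap * n < h_split:
            gap_samples = max(p_gap, 0.0) * n
            blips.append(
                Event(T=nxt.T - nxt.H / n, H=max(1, int(round(gap_samples))), V1=nxt.V1, V2=cur.V2)
            )
            cur = Event(T=nxt.T, H=cur.H + nxt.H, V1=cur.V1, V2=nxt.V2)
        else:
            out.append(cur)
            cur = nxt
    out.append(cur)

    merged = sorted(out + blips, key=lambda e: e.T)
    return _stream_from_list(merged, n)


def _stream_from_list(events: list[Event], sample_rate_hz: float) -> EventStream:
    # merged streams can carry overlapping spans, so bypass the strict
    # non-overlap validation while keeping T ordering
    return EventStream(
        sample_rate_hz,
        np.array([e.T for e in events], dtype=float),
        np.array([e.H for e in events], dtype=int),
        np.array([e.V1 for e in events], dtype=float),
        np.array([e.V2 for e in events], dtype=float),
    )


def classify(stream: EventStream, params: ProcessingParams | None = None) -> ClassifiedEvents:
    """Split by event period: H > h_split respiratory, H <= h_split cardiac."""
    params = params or ProcessingParams()
    resp = stream.H > params.h_split
    n = stream.sample_rate_hz

    def _sub(mask: np.ndarray) -> EventStream:
        return EventStream(n, stream.T[mask], stream.H[mask], stream.V1[mask], stream.V2[mask])

    return ClassifiedEvents(respiratory=_sub(resp), cardiac=_sub(~resp))


def _sweep_min_interval(stream: EventStream, min_interval_s: float) -> EventStream:
    """Left-to-right sweep dropping the smaller-H event of too-close pairs.

    When dropping the earlier survivor, the newcomer is re-checked against
    the remaining survivors, so the result is a fixed point of the rule
    (ties drop the later event).
    """
    survivors: list[Event] = []
    for ev in stream:
        keep = True
        while survivors and ev.T - survivors[-1].T < min_interval_s:
            if ev.H > survivors[-1].H:
                survivors.pop()
            else:
                keep = False
                break
        if keep:
            survivors.append(ev)
    return _stream_from_list(survivors, stream.sample_rate_hz)


def reject_false_positives(ce: ClassifiedEvents, params: ProcessingParams | None = None) -> ClassifiedEvents:
    """Enforce the per-class physiological minimum interval.

    Within each class independently, whenever two consecutive surviving
    events are closer in T than the class minimum interval, the one with the
    smaller H is dropped.  Idempotent.
    """
    params = params or ProcessingParams()
    return ClassifiedEvents(
        respiratory=_sweep_min_interval(ce.respiratory, params.min_resp_interval_s),
        cardiac=_sweep_min_interval(ce.cardiac, params.min_card_interval_s),
    )


def process_events(stream: EventStream, params: ProcessingParams | None = None) -> ClassifiedEvents:
    """merge -> classify -> reject, the standard repair chain."""
    params = params or ProcessingParams()
    return reject_false_positives(classify(merge_split_respiratory(stream, params), params), params)
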