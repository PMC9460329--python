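"""Waveform reconstruction from the sparse event representation.

Each event contributes two anchor points, (T - H/N, V1) at the positive edge
and (T, V2) at the negative edge; the waveform is rebuilt by piecewise-linear
interpolation through all anchors, held flat beyond the first and last.
"""

from __future__ import annotations

import warnings

import numpy as np

from .io import EventStream, SampleSeries

__all__ = ["reconstruct"]


def reconstruct(stream: EventStream, duration_s: float, rate_hz: float = 200.0) -> SampleSeries:
    """Rebuild an approximate band waveform on a uniform grid.

    An empty stream yields a flat zero series (with a warning).
    """
    if rate_hz <= 0 or duration_s <= 0:
        raise ValueError("duration and rate must be positive")
    n = int(round(duration_s * rate_hz))
    t = np.arange(n) / rate_hz
    if len(stream) == 0:
        warnings.warn("reconstructing from an empty event stream: flat zero output")
        return SampleSeries(np.zeros(n), rate_hz)

    # interleave (start, V1) and (end, V2) anchors per event, then sort by
    # time (merged respiratory events can overlap their cardiac blips)
    ax = np.column_stack([stream.start_times, stream.T]).ravel()
    ay = np.column_stack([stream.V1, stream.V2]).ravel()
    order = np.argsort(ax, kind="stable")
    values = np.interp(t, ax[order], ay[order])
    return SampleSeries(values, rate_hz)
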