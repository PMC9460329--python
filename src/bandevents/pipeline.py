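"""End-to-end orchestration: simulate -> events -> repair -> rates -> report.

`analyze` is the in-memory pipeline used by the CLI, the examples and the
acceptance checks; `run_pipeline` additionally writes every intermediate
artifact to disk so a run is fully reproducible from config + seed.
"""

from __future__ import annotations

import json
import logging
from dataclasses import asdict, dataclass, field
from pathlib import Path

import numpy as np

from . import evaluate as ev
from .compensation import PeriodSeries, kmeans_compensate, median_compensate, bucket_hr_series
from .events import DEFAULT_DELAY, generate_events
from .io import EventStream, SampleSeries, write_events, write_samples_csv
from .processing import ClassifiedEvents, ProcessingParams, process_events
from .rates import RateSeries, breath_to_breath_rr, event_hr, naive_mean_hr, smooth_moving_average
from .synthetic import GroundTruth, SyntheticConfig, generate_band_signal, write_ground_truth_csv

__all__ = ["PipelineConfig", "PipelineResult", "analyze", "hr_series", "run_pipeline"]

log = logging.getLogger("bandevents")


@dataclass(frozen=True)
class PipelineConfig:
    """All stage parameters in one validated bundle."""

    synthetic: SyntheticConfig = field(default_factory=lambda: SyntheticConfig(duration_s=600.0))
    delay_samples: int = DEFAULT_DELAY
    processing: ProcessingParams = field(default_factory=ProcessingParams)
    hr_method: str = "median"  # "median" | "bucket" | "kmeans"
    kmeans_window_s: float = 60.0
    beat_match_tol_s: float = ev.BEAT_MATCH_TOL_S
    breath_match_tol_s: float = ev.BREATH_MATCH_TOL_S

    def validate(self) -> None:
        self.synthetic.validate()
        if self.delay_samples < 1:
            raise ValueError("delay_samples must be >= 1")
        if self.hr_method not in ("median", "bucket", "kmeans"):
            raise ValueError(f"unknown hr_method {self.hr_method!r}")


@dataclass
class PipelineResult:
    series: SampleSeries
    truth: GroundTruth
    events: EventStream
    classified: ClassifiedEvents
    periods: PeriodSeries
    rr: RateSeries
    hr: RateSeries
    report: dict


def hr_series(periods: PeriodSeries, method: str = "median", kmeans_window_s: float = 60.0) -> RateSeries:
    """HR series from raw cardiac periods by the chosen compensation method."""
    if method == "median":
        return event_hr(median_compensate(periods))
    if method == "bucket":
        times, rates = bucket_hr_series(periods)
        rates = smooth_moving_average(rates) if len(rates) else rates
        return RateSeries(times, rates, kind="HR", smoothing="bucketing + 6-sample moving average")
    if method == "kmeans":
        res = kmeans_compensate(periods, kmeans_window_s)
        return RateSeries(
            np.array([r.window_end_s for r in res]),
            np.array([r.hr_compensated for r in res]),
            kind="HR",
            smoothing=f"k-means {kmeans_window_s:g}s windows",
        )
    raise ValueError(f"unknown hr_method {method!r}")


def analyze(config: PipelineConfig) -> PipelineResult:
    """Run the full chain on a synthetic recording and score it against truth."""
    config.validate()
    series, truth = generate_band_signal(config.synthetic)
    events = generate_events(series, config.delay_samples)
    classified = process_events(events, config.processing)
    periods = PeriodSeries.from_event_stream(classified.cardiac)

    rr = breath_to_breath_rr(classified.respiratory)
    hr = hr_series(periods, config.hr_method, config.kmeans_window_s)

    report: dict = {
        "n_samples": len(series),
        "n_events": len(events),
        "n_respiratory": len(classified.respiratory),
        "n_cardiac": len(classified.cardiac),
        "hr_method": config.hr_method,
    }
    if len(periods):
        report["naive_hr_bpm"] = naive_mean_hr(periods)
    if len(truth.breath_peak_times) > 1 and len(classified.respiratory):
        # a respiratory event's positive edge sits at the breath crest
        report["respiration_detection"] = ev.match_events(
            classified.respiratory.start_times, truth.breath_peak_times, config.breath_match_tol_s
        ).as_dict()
    if len(truth.beat_times) > 1 and len(classified.cardiac):
        report["pulse_detection"] = ev.match_events(
            classified.cardiac.T, truth.beat_times, config.beat_match_tol_s
        ).as_dict()
    report["sizes"] = ev.stream_sizes(len(series), len(events))
    log.info(
        "pipeline: %d samples -> %d events (%d resp / %d card), %d RR and %d HR estimates",
        len(series), len(events), len(classified.respiratory), len(classified.cardiac), len(rr), len(hr),
    )
    return PipelineResult(series, truth, events, classified, periods, rr, hr, report)


def run_pipeline(config: PipelineConfig, outdir: str | Path) -> PipelineResult:
    """Run `analyze` and write every intermediate artifact under ``outdir``."""
    outdir = Path(outdir)
    outdir.mkdir(parents=True, exist_ok=True)
    result = analyze(config)

    write_samples_csv(result.series, outdir / "samples.csv")
    write_ground_truth_csv(result.truth, outdir / "ground_truth.csv")
    write_events(result.events, outdir / "events.evt")
    write_events(result.classified.respiratory, outdir / "respiratory.evt")
    write_events(result.classified.cardiac, outdir / "cardiac.evt")
    result.rr.write_csv(outdir / "rr.csv")
    result.hr.write_csv(outdir / "hr.csv")
    with open(outdir / "report.json", "w") as fh:
        json.dump(result.report, fh, indent=2)
    with open(outdir / "config.json", "w") as fh:
        json.dump(asdict(config), fh, indent=2)
    log.info("artifacts written to %s", outdir)
    return result
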