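"""Synthetic chest-band waveform generator with known ground truth.

Emulates the single-channel resistive-band signal: a large respiratory
oscillation (~3120 mV peak-to-peak) with small superimposed cardiac pulses
(~84 mV peak-to-peak, i.e. ~37x smaller), additive white noise, beat-to-beat
and cycle-to-cycle rate variability, and random omission of cardiac pulses
from the waveform to emulate the sensor's substantial cardiac miss rate.
Every breath peak and every beat (including the omitted ones, flagged) is
returned as ground truth so detection and compensation stages can be scored.
"""

from __future__ import annotations

from dataclasses import dataclass, field, asdict
from pathlib import Path

import numpy as np

from .io import SampleSeries

__all__ = ["SyntheticConfig", "GroundTruth", "generate_band_signal", "write_ground_truth_csv"]

# Shape constants of the invented waveform model (the real band morphology is
# only known qualitatively).  Each breath is a fast inspiratory surge to a
# sharp crest, an exponential expiratory recoil, and a long end-expiratory
# pause with a slight pre-inspiratory drift.  The fast flank traversals keep
# the blind window (where the large respiratory slope buries cardiac pulses)
# short, so cardiac visibility is governed by the pulse-dropout parameter —
# the generator's model of the sensor's cardiac miss rate.
_INSP_FRACTION = 0.025  # inspiration duration as a fraction of the cycle
_RECOIL_TAU_FRACTION = 0.01  # expiratory recoil time constant / cycle
_PAUSE_DRIFT_PER_S = 0.036  # pause drift slope, fraction of p-p per second
_RISE_SHAPE = 1.2  # inspiration power-law exponent (nonzero crest slope)


@dataclass(frozen=True)
class SyntheticConfig:
    """Parameters of the simulated band recording.

    Amplitude defaults follow the band's observed morphology (3120 mV
    respiratory peak-to-peak, 84 mV pulse peak-to-peak); rate defaults follow
    the reference subject (~85.6 bpm, ~17.4 breaths/min); the default pulse
    dropout of 0.3 emulates the ~30% cardiac miss rate of the sensor chain.
    """

    duration_s: float
    sample_rate_hz: float = 200.0
    rr_mean: float = 17.41  # breaths/min
    rr_sd: float = 0.5  # cycle-to-cycle SD, breaths/min
    hr_mean: float = 85.59  # beats/min
    hr_sd: float = 1.5  # beat-to-beat SD, beats/min
    resp_pp_mv: float = 3120.0
    pulse_pp_mv: float = 84.0
    pulse_width_s: float = 0.15  # full support of the pulse template
    noise_sd_mv: float = 1.0
    pulse_dropout_prob: float = 0.3
    baseline_mv: float = 0.0
    seed: int = 0

    def validate(self) -> None:
        scalars = [
            self.duration_s, self.sample_rate_hz, self.rr_mean, self.rr_sd,
            self.hr_mean, self.hr_sd, self.resp_pp_mv, self.pulse_pp_mv,
            self.pulse_width_s, self.noise_sd_mv, self.pulse_dropout_prob,
            self.baseline_mv,
        ]
        if not all(np.isfinite(scalars)):
            raise ValueError("all configuration values must be finite")
        if self.duration_s <= 0:
            raise ValueError("duration_s must be positive")
        if self.sample_rate_hz <= 0:
            raise ValueError("sample_rate_hz must be positive")
        if not 0.0 <= self.pulse_dropout_prob <= 1.0:
            raise ValueError("pulse_dropout_prob must lie in [0, 1]")
        if min(self.resp_pp_mv, self.pulse_pp_mv, self.noise_sd_mv) < 0:
            raise ValueError("amplitudes must be non-negative")
        if self.rr_sd < 0 or self.hr_sd < 0:
            raise ValueError("rate SDs must be non-negative")
        if not 0 < self.rr_mean < 60:
            raise ValueError("rr_mean must lie in (0, 60) breaths/min")
        if not 0 < self.hr_mean < 180:
            raise ValueError("hr_mean must lie in (0, 180) beats/min")
        if self.pulse_width_s <= 0:
            raise ValueError("pulse_width_s must be positive")


@dataclass
class GroundTruth:
    """True breath-peak and beat times (seconds, ascending).

    ``beat_times`` lists ALL beats, including those omitted from the waveform;
    ``dropped_beat_flags`` marks the omitted ones.
    """

    breath_peak_times: np.ndarray
    beat_times: np.ndarray
    dropped_beat_flags: np.ndarray = field(default_factory=lambda: np.empty(0, dtype=bool))

    def __post_init__(self) -> None:
        self.breath_peak_times = np.asarray(self.breath_peak_times, dtype=float)
        self.beat_times = np.asarray(self.beat_times, dtype=float)
        self.dropped_beat_flags = np.asarray(self.dropped_beat_flags, dtype=bool)
        for name, t in (("breath", self.breath_peak_times), ("beat", self.beat_times)):
            if len(t) > 1 and np.any(np.diff(t) <= 0):
                raise ValueError(f"{name} times must be strictly increasing")
        if len(self.dropped_beat_flags) != len(self.beat_times):
            raise ValueError("dropped_beat_flags must align with beat_times")

    @property
    def visible_beat_times(self) -> np.ndarray:
        return self.beat_times[~self.dropped_beat_flags]


def _draw_peak_times(
    rng: np.random.Generator,
    duration_s: float,
    rate_mean: float,
    rate_sd: float,
    min_interval_s: float,
) -> np.ndarray:
    """Event times whose instantaneous rate is N(rate_mean, rate_sd) per min."""
    times = []
    mean_interval = 60.0 / rate_mean
    t = mean_interval * rng.uniform(0.3, 0.7)  # random phase at record start
    while t < duration_s:
        times.append(t)
        rate = rate_mean if rate_sd == 0 else rng.normal(rate_mean, rate_sd)
        rate = min(max(rate, 1e-3), 60.0 / min_interval_s)
        t += max(60.0 / rate, min_interval_s)
    return np.asarray(times)


def _respiratory_wave(t: np.ndarray, peaks: np.ndarray, cfg: SyntheticConfig) -> np.ndarray:
    """Respiratory shape in [0, 1], one crest per breath peak.

    Per cycle: a power-law inspiratory rise to the crest (nonzero slope at
    the crest, so the falling flank starts unambiguously), an exponential
    expiratory recoil, and a slowly drifting end-expiratory pause.  The
    sample value is the upper envelope of the three primitives.
    """
    if len(peaks) == 0:
        return np.zeros_like(t)
    mean_cycle = 60.0 / cfg.rr_mean

    # time since the previous crest and until the next crest, per sample
    nxt_i = np.searchsorted(peaks, t, side="left")
    prev_i = nxt_i - 1
    t_prev = np.where(prev_i >= 0, peaks[np.clip(prev_i, 0, None)], peaks[0] - mean_cycle)
    t_next = np.where(nxt_i < len(peaks), peaks[np.clip(nxt_i, None, len(peaks) - 1)],
                      peaks[-1] + mean_cycle)
    cycle = np.maximum(t_next - t_prev, 1.0)
    u = t - t_prev  # time into expiration
    v = t_next - t  # time to the next crest

    recoil = np.exp(-u / (_RECOIL_TAU_FRACTION * cycle))
    pause = _PAUSE_DRIFT_PER_S * u
    ti = _INSP_FRACTION * cycle
    rise = np.clip(1.0 - v / ti, 0.0, 1.0) ** _RISE_SHAPE
    return np.clip(np.maximum(np.maximum(recoil, pause), rise), 0.0, 1.0)


def _pulse_template(sample_rate_hz: float, width_s: float, pp_mv: float) -> np.ndarray:
    """Asymmetric cardiac notch: slow swell, sharp systolic fall, brisk recovery.

    Segment lengths are fixed fractions of ``width_s`` (swell 40%, fall 20%,
    recovery 25%, then a flat tail) joined by half-cosine ramps; the fall
    spans the full ``pp_mv`` peak-to-peak so its slope is steep relative to
    the swell, and the recovery is brisk so a pulse interrupting the
    expiratory recoil re-emerges quickly.
    """

    def _smooth(n: int) -> np.ndarray:
        return (1.0 - np.cos(np.pi * np.linspace(0.0, 1.0, n, endpoint=False))) / 2.0

    n_swell = max(int(round(0.40 * width_s * sample_rate_hz)), 2)
    n_fall = max(int(round(0.20 * width_s * sample_rate_hz)), 2)
    n_rec = max(int(round(0.25 * width_s * sample_rate_hz)), 2)
    n_tail = max(int(round(0.15 * width_s * sample_rate_hz)), 1)
    a = pp_mv / 2.0
    swell = a * _smooth(n_swell)
    fall = a - pp_mv * _smooth(n_fall)
    rec = -a + a * _smooth(n_rec)
    return np.concatenate([swell, fall, rec, np.zeros(n_tail)])


def generate_band_signal(cfg: SyntheticConfig) -> tuple[SampleSeries, GroundTruth]:
    """Generate a band-like waveform and its ground truth.

    The waveform is baseline + respiratory lobes (peak-to-peak
    ``resp_pp_mv``) + one pulse notch per non-dropped beat (peak-to-peak
    ``pulse_pp_mv``) + white Gaussian noise.  Reproducible for a fixed seed.
    """
    cfg.validate()
    rng = np.random.default_rng(cfg.seed)
    n_samples = int(round(cfg.duration_s * cfg.sample_rate_hz))
    t = np.arange(n_samples) / cfg.sample_rate_hz

    breath_peaks = _draw_peak_times(rng, cfg.duration_s, cfg.rr_mean, cfg.rr_sd, 1.0)
    beat_times = _draw_peak_times(rng, cfg.duration_s, cfg.hr_mean, cfg.hr_sd, 60.0 / 180.0)
    dropped = rng.random(len(beat_times)) < cfg.pulse_dropout_prob

    y = cfg.baseline_mv + cfg.resp_pp_mv * _respiratory_wave(t, breath_peaks, cfg)

    if cfg.pulse_pp_mv > 0 and len(beat_times):
        template = _pulse_template(cfg.sample_rate_hz, cfg.pulse_width_s, cfg.pulse_pp_mv)
        # align the systolic fall midpoint with the annotated beat time
        center = int(round(0.50 * cfg.pulse_width_s * cfg.sample_rate_hz))
        for bt in beat_times[~dropped]:
            c = int(round(bt * cfg.sample_rate_hz))
            lo, hi = c - center, c - center + len(template)
            tlo, thi = max(lo, 0), min(hi, n_samples)
            if tlo < thi:
                y[tlo:thi] += template[tlo - lo : thi - lo]

    if cfg.noise_sd_mv > 0:
        y = y + rng.normal(0.0, cfg.noise_sd_mv, n_samples)

    series = SampleSeries(y, cfg.sample_rate_hz)
    truth = GroundTruth(breath_peaks, beat_times, dropped)
    return series, truth


def write_ground_truth_csv(truth: GroundTruth, path: str | Path) -> None:
    """Write peak lists as CSV: kind (breath|beat), time_s, dropped (0/1)."""
    with open(path, "w") as fh:
        fh.write("kind,time_s,dropped\n")
        for bt in truth.breath_peak_times:
            fh.write(f"breath,{bt:.9g},0\n")
        for bt, dr in zip(truth.beat_times, truth.dropped_beat_flags):
            fh.write(f"beat,{bt:.9g},{int(dr)}\n")


def config_to_dict(cfg: SyntheticConfig) -> dict:
    return asdict(cfg)
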