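# Methods

This note documents the models and numerical choices behind `bandevents`:
what each stage assumes, which parameters matter, what the synthetic
generator does and does not emulate, and where the design was genuinely
open.

## Signal model and preprocessing

The input is a single voltage channel from a current-polarized resistive
fabric band across the chest: chest-volume change modulates band resistance,
so the waveform carries a large respiratory oscillation (nominally 3120 mV
peak-to-peak) with cardiac pulses superimposed (nominally 84 mV, a 37:1
ratio). Bench-style acquisitions at high rate are reduced with a
second-order low-pass Butterworth (default cut-off 100 Hz) and resampled to
200 Hz (`io.preprocess`). Filtering is zero-phase (forward–backward) by
default because this artifact processes records offline; a causal
single-pass mode (`zero_phase=False`) mimics streaming behaviour.
Resampling uses polyphase filtering with line-extension padding so constant
and slowly varying signals pass without edge ringing.

## Event generation

`events.comparator` implements V(n) = [Y(n+p) < Y(n)] with delay p = 10
samples (50 ms at 200 Hz). The delay is a compromise: shorter delays turn
noise into false events, longer ones ignore the narrow cardiac notch. Ties
(equality) yield V = 0, so only strict falls count. The per-run cumulative
sum C(n) resets at each falling edge of V; the pre-reset count H is the
event period. Each run yields an event with:

* T — time of the falling-edge sample (run start + H samples); the event
  span is exactly [T − H/N, T];
* V1 — amplitude at the run's first sample (positive edge);
* V2 — amplitude at the falling-edge sample (negative edge).

A run still open at end-of-record is discarded (its period is unknown). On
disk an event is 16 bytes, little-endian: T and H as 4-byte unsigned
integers (T as a sample index, for exact round-trips) and V1/V2 as 4-byte
IEEE-754 floats. The delay p is deliberately *not* rescaled with sample
rate; it is defined in samples at 200 Hz and exposed as a parameter.

## Event repair, classification, rejection

The split-breath repair considers consecutive events with both H > 20 and
inter-event period P×N < 20 samples; the pair becomes one respiratory event
(H summed, outer edges kept) plus a cardiac blip spanning the gap. The blip
H is P×N rounded to the nearest integer, floored at 1; a negative P
(possible after earlier merges) is treated as a zero gap. The scan is
left-to-right so chains of more than two fragments collapse correctly. The
blip amplitude fields follow the V1-from-E2 / V2-from-E1 assignment as
specified for this repair, although the subscripts look swapped; since the
blip spans the gap between E1's negative edge and E2's positive edge, those
are in fact the adjacent amplitudes.

Classification is a pure threshold: H > 20 respiratory, otherwise cardiac.
Rejection enforces per-class physiological minimum intervals (1 s from a
60 breaths/min ceiling; 1/3 s from 180 beats/min) with a left-to-right
sweep that keeps the larger-H event of any too-close pair (ties drop the
later event) and re-checks after each removal, making the operation
idempotent. Merging precedes rejection; the two subsections of the repair
stage are applied in that order.

## Missed-beat compensation

All three algorithms exploit the same fact: the number of true beats
between two detected beats is an integer, so an overlong cardiac period is
(nearly) an integer multiple of the prevailing period.

**Median harmonics** (streaming, warm-up 30 events): for each period h, the
moving median x̃ of the previous 30 periods defines candidates k·x̃ for
k = 1..5; h is divided by the argmin-k of |h − k·x̃|. Output periods
therefore lie in [h/5, h]. The 30-event history uses raw (uncompensated)
periods; a 20-sample moving median is also available purely for
diagnostics/plotting.

**Bucketing** (streaming, implicit warm-up): a FIFO of the last 30 periods
is histogrammed over the fixed thresholds [0.4, 0.45, 0.5, 0.6, 0.7, 0.8,
0.9, 1, 1.2, 1.6, 2, 2.4, 2.8, 3.2] s, a period belonging to the first
bucket whose threshold is ≥ the period (periods beyond 3.2 s clamp to the
last bucket so the counter invariant Σcounters = FIFO length holds).
Majority rules run in priority order: single (any counter > 20), dual
(two adjacent counters summing > 15), triple (three adjacent > 15); among
qualifying windows the largest count wins, ties to the smallest index, and
for dual/triple windows the reported index is the heaviest bucket and the
mean is count-weighted. Given a majority at i, the base period is the
count-weighted mean over buckets i−1, i, i+1 (capturing HR oscillation into
neighbours); buckets beyond i+1 with more than three elements are folded in
at mean/2 or mean/3 — first divisor that lands within ±20 beats/min of the
established rate — modelling single/double missed beats. Without a
majority the last valid HR is repeated; before any majority there is no
output. When i is the last bucket the forward scan is empty.

**k-means** (windowed, offline): per nonoverlapping 15/30/60 s window with
at least 3 periods, plain 1-D Lloyd iteration (max 100 iterations,
tolerance 1e-6) from seeds x̃, 2x̃, 3x̃ (x̃ = window median); an empty
cluster keeps its seed value. The largest cluster is dominant; each
non-dominant period is multiplied by the factor in {1/2, 1/3, 1/4}
minimizing the distance to the dominant mean. "Multiplied by the factor"
rather than by its denominator: scaling outliers *down* toward the dominant
mean is the only reading consistent with compensating missed beats. Both
the dominant-only and the compensated HR are reported.

## Rate series

* RR: 60/(Tᵢ₊₁ − Tᵢ) at each later respiratory event.
* HR per event: mean of the last 30 instantaneous rates (60/period),
  then a causal unweighted 6-sample moving average. Warm-up (< 30 periods)
  yields no output; the smoother's first five outputs average what exists.
* Windowed HR: 60/mean(periods) per nonoverlapping window aligned to t = 0
  (the record start), reported at the window end.
* Ground-truth HR uses the same 30-beat trailing mean on true beat times,
  without the 6-sample smoother by default (the reference should not be
  doubly smoothed; a flag enables it).

## Reconstruction

Linear interpolation through all event anchors (T − H/N, V1), (T, V2) in
time order, held flat outside the outermost anchors. Reconstruction error
at anchor coordinates is exactly zero. One bound is inherent to the front
end: the positive-edge anchor is set when the *delayed* comparison first
sees the fall, so it can lead the true crest by up to p samples — the
reconstruction preserves breath-peak timing to within the comparator delay,
not to one sample. Rising flanks between events are straight lines by
construction; pulse morphology inside the quiet pause is not restored
beyond the anchor geometry.

## Evaluation and size budgets

Detection scoring uses greedy one-to-one nearest matching within a
tolerance (defaults: 150 ms for beats, 500 ms for breaths; both
configurable — the matching procedure itself is a harness choice, and
greedy equals optimal bipartite matching when truth spacing is large
against the tolerance). Sensitivity, precision, miss rate and false
discovery rate follow the usual TP/FP/FN identities. Rate-error statistics
hold the estimate (previous value) onto the reference timestamps and report
mean/SD/median absolute error.

Size arithmetic uses binary units (1 kB = 1024 B, 1 MB = 1024² B), the only
convention consistent with the reference figures (e.g. 8 h × 200 Hz ×
(24+32) bits = 40,320,000 B = 38.45 MB; 1045 events × 16 B = 16.33 kB;
result-only records, with V1/V2 discarded, 8 B each = 8.16 kB). Raw
records are 8 B/sample (4-byte timestamp + 4-byte value). Bus transfer time
is the pure bits/clock quotient (24 bits at 6 MHz = 4 μs), with no protocol
overhead.

## The synthetic generator

`synthetic.generate_band_signal` exists so that every downstream stage has
exact ground truth. It emulates the band signal's *amplitudes and event
statistics*, not its detailed morphology:

* Breath crests and beats are drawn as point processes with normal
  cycle-to-cycle (rr_sd) and beat-to-beat (hr_sd) rate variability,
  bounded by the physiological ceilings (intervals ≥ 1 s and ≥ 1/3 s).
  Defaults follow the reference subject: 17.41 breaths/min, 85.59 beats/min.
* Each breath is a fast inspiratory surge (power-law rise, ~3% of the
  cycle) to a sharp crest, an exponential expiratory recoil (time constant
  ~1% of the cycle), and a long end-expiratory pause with a slight upward
  drift (~3.6% of p-p per second). The nonzero crest slope and the pause
  drift keep the comparator's chord sign deterministic against the noise
  floor, which suppresses noise-run false events at the extrema.
* Each non-dropped beat adds an asymmetric notch (slow swell, sharp
  systolic fall spanning the full 84 mV, brisk recovery; 150 ms support).
* White Gaussian noise (default SD 1 mV — a high-resolution ADC chain's
  floor, small against the 84 mV pulse) and a single seeded RNG for all
  draws.

**What the stylization means.** A 50 ms-chord argument shows that wherever
the respiratory slope exceeds ~1.7 V/s, an 84 mV pulse cannot flip the
comparator, so beats riding steep flanks are invisible *regardless of
morphology* — in real band data that structural hiding is the dominant
source of the ~30% cardiac miss rate. The generator instead compresses the
flank traversals into short transients (≲0.3 s per cycle) and assigns the
miss process to the explicit `pulse_dropout_prob` parameter (default 0.3):
beats are dropped from the waveform at random but kept, flagged, in the
ground truth. The shape constants were chosen so the front end's detection
statistics sit in the reported operating regime (respiratory
sensitivity/precision ≈ 99–100%, cardiac precision ≥ 95%, cardiac miss
governed by the dropout). Consequences for interpreting results: passing
tests demonstrate the event machinery and the compensation algorithms under
a realistic miss rate and exact truth; they do not demonstrate robustness
to the *phase-locked* miss pattern of real flanks (misses clustered at the
same respiratory phase), to motion artifact (excluded by design — the
method targets low-activity monitoring), or to baseline wander and sensor
drift.

## Numerical choices and degenerate inputs

* Tie-breaks: comparator equality → V = 0; rejection ties drop the later
  event; majority-window ties take the smallest index; harmonic argmin ties
  take the smallest k (Python `min` semantics).
* Bucket boundary: a period exactly equal to a threshold belongs to that
  bucket ("first threshold ≥ period"); 0.67 s → index 5.
* Warm-ups produce explicitly *absent* output (empty series), never zeros.
* Empty event streams reconstruct to flat zero with a warning; empty
  windows yield no windowed estimate; fewer than two respiratory events
  yield an empty RR series.
* Event T is stored on disk as a sample index (exact round trip) and
  exposed in seconds in memory; files with length not divisible by 16 are
  rejected.
* Merged respiratory events can overlap their cardiac blips in span; the
  stream invariant after merging is strict T ordering only.

## Problem sizes used in the checks

The reference synthetic conditions used by the test suite are 10 minutes at
200 Hz (120,000 samples, ~850 beats, ~174 breaths) with constant true rates
(85 beats/min, 17.4 breaths/min), 30% pulse dropout and a fixed seed —
large enough for ~470 post-warm-up HR estimates while keeping the whole
suite fast. Unit tests use 30 s–4 min records. Under these conditions the
median and bucketing HR estimates recover the true rate with mean absolute
errors well under 2 beats/min (typically ≈0.6 and ≈0.1), breath-to-breath
RR is exact to ≈0.04 breaths/min, and the uncompensated mean-period HR is
biased low by ≈35% — the bias the compensation stage exists to remove.

## Known limitations

* H-threshold classification only; no morphology features. Severe
  bradycardia below ~19 bpm would alias into the respiratory class.
* The compensators assume a quasi-stationary rhythm; they cannot (and must
  not be used to) detect arrhythmia or truly skipped beats — a physiological
  pause is indistinguishable from a sensor miss by design.
* k-means windows are aligned to the record start; window phase is not
  optimized.
* The greedy matcher can differ from optimal matching when detections are
  denser than the tolerance; evaluation defaults keep tolerances well below
  physiological spacing.
* Reconstruction quality in the pause region is limited by event sparsity:
  between events the waveform is a straight line.
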