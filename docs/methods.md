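# Methods

## The measurement model

The analysis targets one recording per subject × task × limb from a
wearable device: six surface-EMG channels (Pectoralis Major, Anterior/
Middle/Posterior Deltoid, Upper/Lower Trapezius) sampled at 1000 Hz on
a 12-bit ADC spanning 1.6 V, and one orientation-quaternion stream at
100 Hz from an IMU above the lateral epicondyle.  The two streams are
assumed hardware-synchronized; a constant inter-stream offset knob
exists for recordings where that fails.  Five movement cycles per
recording are delimited by phase annotations taken frame-by-frame from
30 fps video; each cycle is divided into seven contiguous phases
(start-to-reach, grasp, transport-to-mouth, in-mouth, return-to-table,
return-to-start, rest).

## Processing chain

**Phase schedule.**  For boundaries *b₀ < … < b₇* the per-phase
durations are `100·(bₖ−bₖ₋₁)/(b₇−b₀)` % of cycle; they sum to 100 by
construction.  Across trials the schedule reports the arithmetic mean
and the sample (n−1) standard deviation per phase; intervals are
cumulative sums of the means.  Phase intervals are half-open
`[start, end)` with phase 7 closed at 100 %, so every instant belongs
to exactly one phase.

**EMG.**  counts → mV around the bipolar mid-scale
(`(c − 2048)·1600/4095`); per-channel DC removal then full-wave
rectification; centred 1000-sample moving average.  Rectification
before smoothing is the only physically consistent reading of a
non-negative activation envelope: a plain moving average of the raw
bipolar interference signal would collapse toward zero.  No band-pass
filter is applied by default (a hook exists); no MVC normalization is
performed.  Cycles are cut from the smoothed recording (rest periods
discarded), resampled to 9000 points by linear interpolation over each
cycle's own start→end span, averaged within subject, min–max
normalized to [0, 1] as a *twin* of the mV cycle, and both scales are
averaged across subjects.  Peak summaries (peak mV and its % of cycle,
first occurrence on ties) are computed on the mV-scale group mean; the
normalized group mean is emitted alongside for figure-style plots.
Whether published mV peaks derive from pre- or post-normalization
averages is genuinely ambiguous, so both cycles are reported and the
choice is recorded in run metadata.

**IMU.**  Quaternions (w, x, y, z, renormalized at load) are
decomposed as intrinsic Z-Y-X Euler angles — yaw, pitch, roll, in
degrees.  The convention is fixed and config-selectable; near gimbal
lock (|pitch| → 90°) the residual rotation is assigned to yaw, roll is
set to 0 and the sample is flagged.  Yaw and roll are unwrapped across
±180° before the 100-sample smoother (averaging wrapped angles is
meaningless near the branch cut); smoothing precedes segmentation,
mirroring the EMG branch.  Euler angles map onto canonical anatomical
axes with fixed motion signs on both limbs — fe (Extension +, Flexion
−), abad (Abduction +, Adduction −), rot (Lateral Rotation +, Medial
Rotation −); on the non-dominant limb roll and pitch flip sign in this
mapping, reflecting the mirrored sensor orientation.  Cycles are
zero-aligned (first sample subtracted) so the resting orientation
cancels, resampled to 9000 points and averaged.  The "range of motion"
per motion is the *signed extremum* of the zero-aligned group
trajectory in that motion's direction (not max−min), matching the
signed values the field reports; both members of each motion pair are
always listed, so a one-sided excursion yields a near-zero opposite
entry.  Angle cycles are not min–max normalized (they are reported in
degrees).

## Key parameters

| parameter | default | units | role |
|---|---|---|---|
| `emg_rate` / `imu_rate` / `video_fps` | 1000 / 100 / 30 | Hz / fps | device clocks |
| `adc_bits` / `adc_range` | 12 / 1.6 | – / V | count→mV conversion (step ≈ 0.39 mV) |
| `emg_window` / `imu_window` | 1000 / 100 | samples | 1 s centred smoothers |
| `n_resample` | 9000 | samples | normalized 0–100 % cycle axis |
| ADC offset | 2048 | counts | bipolar mid-scale zero; exposed as a knob |

The moving average shrinks its centred window at the edges (no padding
values are invented), so output length equals input length and a
constant signal is a fixed point.  Resampling spans each cycle's own
time range with endpoints preserved exactly.  Percentages, millivolts
and degrees are kept at full precision internally and rounded to one
decimal only in serialized tables; serialized schedule intervals are
cumulative sums of the rounded durations so the written table is
self-consistent at printed precision.

## The synthetic cohort

The generator emulates the study conditions: 30 subjects × 5 cycles
with 5 s rests; ~10 s cycles (SD 1 s); phase durations drawn per trial
from the published drinking/eating templates.  The template means are
the published interval *widths* (they sum to exactly 100 %, unlike the
rounded duration column); SDs are as published.  Draws use a normal
truncated **symmetrically** at ±2.5 SD (narrowed to keep durations
above 0.5 %) so the sampled mean stays on the template — one-sided
truncation at zero would bias short phases upward by more than the
recovery tolerance — and are renormalized to sum to 100, which couples
phases only at second order.

EMG is modelled as amplitude-modulated Gaussian noise (the standard
surface-EMG interference model): `x(t) = σ(t)·n(t)` with
`σ(t) = baseline + amp·exp(−(p−peak)²/2w²)` in cycle percent, then
quantized to counts.  Because the injected amplitudes follow the
published millivolt magnitudes (0.1–0.9 mV) while the ADC step is
~0.39 mV, quantization is not negligible; the recovery target is
therefore the closed-form expectation of the *quantized* rectified
mean, `E|Δ·round(X/Δ)| = 2Δ·Σₖ Q((k−½)Δ/σ)`, which reduces to
`σ·√(2/π)` as Δ→0.  Burst width defaults to 10 % of cycle, baseline
noise to 0.05 mV.

Angles are sums of raised-cosine lobes per anatomical axis (smooth,
compactly supported), plus 0.1° Gaussian orientation jitter; lobe
defaults take the published signed peak magnitudes and times per
task/limb, floored at 0.5° so every injected parameter is resolvable
above the jitter.  A centred boxcar of duration T attenuates a lobe of
width w by `(1 + (w/πT)·sin(πT/w))/2` exactly, which sets the
recovery tolerances analytically.  Per-subject variability is a 1 %
peak-time jitter and a 10 % amplitude coefficient of variation on both
bursts and lobes.  Phase boundaries are snapped to the 30 fps frame
grid by default (annotations carry frame indices), adding ≤ 1 frame of
quantization per boundary.

What the simulator does **not** emulate — and hence what passing
recovery tests do not show about real data: realistic EMG spectra,
motion artefacts and electrode impedance drift; inter-muscle
correlation and co-contraction; multi-lobed or asymmetric real
trajectories; sensor drift and magnetometer disturbance in the
orientation estimate; true inter-subject variability structure.  The
published human peak tables are used only to seed plausible magnitudes
for comparability; the pipeline makes no claim of reproducing them.

## Validation

Unit oracles: brute-force windowed means, closed-form interpolation
values, rotation round trips, half-normal and quantized-expectation
statistics.  End-to-end, a default 30-subject drinking cohort must
recover (a) group phase-duration means within one standard error of
the template (SE = template SD/√30; the renormalization bias is an
order of magnitude below this), (b) per-muscle envelope peak times
within ±1.5 % of cycle of the injected means, and (c) per-motion
signed peak angles within ±10 % of the injected amplitude after the
analytic smoothing attenuation.  Determinism is byte-level: identical
seeds yield identical dataset files (SHA-256) and identical report
tables.  Problem sizes (200 random signals for the smoother oracle,
10⁴ orientations for rotation round trips, 30 × 5 trials for
recovery) keep the full suite under half a minute on one CPU.

## Known limitations

* The schedule audit works at printed (one-decimal) precision; it
  cannot distinguish a 0.1 rounding artefact from a 0.1 data error.
* Peak summaries report the global extremum only; secondary lobes
  (e.g. late reverse motions) appear in the cycle CSVs but not in the
  summary tables unless they are the extremum on their side of the
  axis.
* Gimbal-locked samples are flagged but not excluded; trajectories
  designed near |pitch| = 90° should be avoided (the simulator refuses
  them by construction).
* Whether the rest phase ends at a fixed window or at the next trial's
  onset is a convention of the annotation file (an explicit phase-7
  end is required), not something the pipeline infers.
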