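"""EMG branch: counts → mV → rectified envelope → normalized cycles → peaks.

Processing order mirrors the device workflow: convert 12-bit ADC counts
to millivolts around the bipolar mid-scale, remove each channel's DC
level and full-wave rectify, smooth with a 1 s (1000-sample) centred
moving average, cut the five annotated movement cycles out of the
continuous recording (the 5 s inter-trial rests are discarded), resample
every cycle to 9000 points on the 0–100 % cycle axis, average cycles
within a subject and then across subjects, and finally report each
muscle's peak amplitude and peak time against the phase schedule.

Rectification is applied before smoothing: the envelope of a zero-mean
interference-pattern signal is carried by its local amplitude, and a
plain moving average of the raw bipolar signal would collapse toward
zero.  Min–max normalization (0–1) is computed as a twin of the mV
cycle; peak summaries are taken on the mV scale.
"""

from __future__ import annotations

from dataclasses import dataclass
from typing import Sequence

import numpy as np

from .core import (
    AcquisitionSpec,
    AnnotationError,
    NormalizedCycle,
    ParameterError,
    PeakSummary,
    PhaseAnnotation,
    PhaseSchedule,
    locate_phase,
    moving_average,
    resample_cycle,
)
from .device_io import MUSCLE_ORDER, RawEMG

__all__ = [
    "EnvelopeCycle",
    "bits_to_mv",
    "rectify",
    "envelope",
    "extract_cycles",
    "subject_mean_cycle",
    "minmax_normalize",
    "group_mean_cycle",
    "emg_peak_summary",
    "process_subject_emg",
]


@dataclass(frozen=True)
class EnvelopeCycle:
    """A muscle's normalized-cycle envelope in mV with its 0–1 twin."""

    muscle: str
    limb: str
    mv: NormalizedCycle
    normalized: NormalizedCycle

    @property
    def subject(self) -> str:
        return self.mv.subject


def bits_to_mv(
    counts: np.ndarray, spec: AcquisitionSpec | None = None, offset: int | None = None
) -> np.ndarray:
    """Convert ADC counts to millivolts.

    ``mV = (count - offset) * 1000 * adc_range / (2**adc_bits - 1)``;
    the default offset is mid-scale (2048 at 12 bit), the zero-volt
    count of a bipolar analog front end.
    """
    spec = spec or AcquisitionSpec()
    if offset is None:
        offset = spec.adc_midscale
    return (np.asarray(counts, dtype=float) - offset) * spec.mv_per_count


def rectify(signal_mv: np.ndarray) -> np.ndarray:
    """DC-remove (per channel) then full-wave rectify.

    Subtracting the channel mean removes any residual ADC offset before
    taking absolute values, so a constant signal rectifies to zero.
    """
    x = np.asarray(signal_mv, dtype=float)
    return np.abs(x - x.mean(axis=0, keepdims=True))


def envelope(signal_mv: np.ndarray, spec: AcquisitionSpec | None = None) -> np.ndarray:
    """Smooth a rectified signal with the 1 s EMG moving average."""
    spec = spec or AcquisitionSpec()
    return moving_average(signal_mv, spec.emg_window)


def extract_cycles(
    time: np.ndarray,
    values: np.ndarray,
    annotations: Sequence[PhaseAnnotation],
) -> list[tuple[np.ndarray, np.ndarray]]:
    """Cut annotated movement cycles out of a continuous recording.

    Each returned segment spans its annotation's phase-1 start to
    phase-7 end with the clock restarted at zero; samples between
    annotations (the inter-trial rests) are excluded.  Annotations must
    lie inside the recording and must not overlap.
    """
    time = np.asarray(time, dtype=float)
    values = np.asarray(values, dtype=float)
    if values.shape[0] != time.size:
        raise ParameterError("time and values must have matching length")
    ordered = sorted(annotations, key=lambda a: a.start)
    for prev, nxt in zip(ordered, ordered[1:]):
        if nxt.start < prev.end:
            raise AnnotationError(
                f"annotations {prev.trial_id!r} and {nxt.trial_id!r} overlap"
            )
    segments = []
    for ann in annotations:
        if ann.start < time[0] - 1e-9 or ann.end > time[-1] + 1e-9:
            raise AnnotationError(
                f"annotation {ann.trial_id!r} outside the recording span"
            )
        i0 = int(np.searchsorted(time, ann.start, side="left"))
        i1 = int(np.searchsorted(time, ann.end, side="right"))
        if i1 - i0 < 2:
            raise AnnotationError(f"annotation {ann.trial_id!r} spans < 2 samples")
        segments.append((time[i0:i1] - time[i0], values[i0:i1]))
    return segments


def subject_mean_cycle(
    segments: Sequence[tuple[np.ndarray, np.ndarray]],
    spec: AcquisitionSpec | None = None,
) -> np.ndarray:
    """Resample each cycle to ``n_resample`` points and average pointwise."""
    spec = spec or AcquisitionSpec()
    if len(segments) == 0:
        raise ParameterError("need at least one cycle segment")
    resampled = [resample_cycle(t, v, spec.n_resample) for t, v in segments]
    return np.mean(resampled, axis=0)


def minmax_normalize(values: np.ndarray) -> np.ndarray:
    """Map a cycle onto [0, 1]; a flat cycle maps to all zeros."""
    v = np.asarray(values, dtype=float)
    lo = v.min(axis=0, keepdims=True)
    hi = v.max(axis=0, keepdims=True)
    span = hi - lo
    out = np.zeros_like(v)
    nonflat = np.broadcast_to(span > 0, v.shape)
    out[nonflat] = ((v - lo) / np.where(span > 0, span, 1.0))[nonflat]
    return out


def group_mean_cycle(cycles: Sequence[NormalizedCycle]) -> NormalizedCycle:
    """Pointwise mean across subjects' cycles of one channel and unit."""
    if len(cycles) == 0:
        raise ParameterError("need at least one subject cycle")
    units = {c.units for c in cycles}
    if len(units) != 1:
        raise ParameterError(f"cannot average cycles of mixed units {units}")
    lengths = {c.values.size for c in cycles}
    if len(lengths) != 1:
        raise ParameterError("cannot average cycles of mixed lengths")
    mean = np.mean([c.values for c in cycles], axis=0)
    return NormalizedCycle(
        mean,
        units=cycles[0].units,
        channel=cycles[0].channel,
        n_contributing=len(cycles),
        subject="group",
    )


def emg_peak_summary(
    cycle: NormalizedCycle, schedule: PhaseSchedule
) -> PeakSummary:
    """Peak amplitude and its cycle position for one muscle envelope.

    The first occurrence wins on exact ties; the phase at the peak is
    looked up in the schedule's half-open intervals.
    """
    idx = int(np.argmax(cycle.values))
    peak_time = float(cycle.axis[idx])
    return PeakSummary(
        channel=cycle.channel,
        peak_time=peak_time,
        peak_value=float(cycle.values[idx]),
        phase_at_peak=locate_phase(peak_time, schedule),
    )


def process_subject_emg(
    raw: RawEMG,
    annotations: Sequence[PhaseAnnotation],
    spec: AcquisitionSpec | None = None,
) -> list[EnvelopeCycle]:
    """Full EMG branch for one subject's recording → per-muscle cycles."""
    spec = spec or AcquisitionSpec()
    mv = bits_to_mv(raw.counts, spec)
    env = envelope(rectify(mv), spec)
    segments = extract_cycles(raw.time, env, annotations)
    mean = subject_mean_cycle(segments, spec)  # (n_resample, 6)
    normalized = minmax_normalize(mean)
    out = []
    for j, muscle in enumerate(MUSCLE_ORDER):
        out.append(
            EnvelopeCycle(
                muscle=muscle.value,
                limb=raw.limb,
                mv=NormalizedCycle(
                    mean[:, j], "mV", muscle.value, len(segments), subject="subject"
                ),
                normalized=NormalizedCycle(
                    normalized[:, j],
                    "normalized",
                    muscle.value,
                    len(segments),
                    subject="subject",
                ),
            )
        )
    return out
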