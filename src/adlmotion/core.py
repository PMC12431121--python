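"""Domain vocabulary and shared 1-D signal primitives.

This module defines the seven-phase model of a drinking/eating movement
cycle, the muscle and motion code sets used throughout the package, the
acquisition parameters of the wearable device (EMG at 1000 Hz, IMU at
100 Hz, 30 fps reference video, 12-bit ADC over 1.6 V), and the small
set of numeric primitives — centred moving average, linear cycle
resampling, phase-duration arithmetic — that both the EMG and the IMU
processing branches are built on.

Conventions fixed here (and relied on everywhere else):

* Phase intervals on the normalized 0–100 % cycle axis are half-open
  ``[start, end)``; phase 7 is closed at 100 % so every instant of the
  cycle belongs to exactly one phase.
* The moving average is centred and *shrinks* at the edges: the mean is
  taken over the part of the window that overlaps the signal, so no
  padding values are invented and output length equals input length.
* Resampling spans each cycle's own first→last time stamp with linear
  interpolation (endpoints preserved exactly).
"""

from __future__ import annotations

import enum
from dataclasses import dataclass, field
from typing import Sequence

import numpy as np

__all__ = [
    "AcquisitionSpec",
    "Phase",
    "PHASE_LABELS",
    "Muscle",
    "Motion",
    "MOTION_AXIS_SIGN",
    "ANATOMICAL_AXES",
    "PhaseAnnotation",
    "PhaseSchedule",
    "NormalizedCycle",
    "PeakSummary",
    "AnnotationError",
    "ParameterError",
    "DataFormatError",
    "durations_from_annotation",
    "aggregate_schedule",
    "locate_phase",
    "moving_average",
    "resample_cycle",
]


class AnnotationError(ValueError):
    """A phase annotation violates its contract (ordering, contiguity...)."""


class ParameterError(ValueError):
    """An operation was called with an invalid parameter."""


class DataFormatError(ValueError):
    """An on-disk file or in-memory table violates the expected schema."""


@dataclass(frozen=True)
class AcquisitionSpec:
    """Acquisition parameters of the wearable EMG+IMU device.

    Defaults mirror the prototype: EMG sampled at 1000 Hz on a 12-bit
    ADC spanning 1.6 V, orientation quaternions at 100 Hz, phase
    annotations from 30 fps video, 1 s moving-average windows on both
    branches, and 9000-point cycle resampling.
    """

    emg_rate: float = 1000.0  # Hz
    imu_rate: float = 100.0  # Hz
    video_fps: float = 30.0
    adc_bits: int = 12
    adc_range: float = 1.6  # volts, full scale
    emg_window: int = 1000  # samples (1 s at 1000 Hz)
    imu_window: int = 100  # samples (1 s at 100 Hz)
    n_resample: int = 9000

    def __post_init__(self) -> None:
        for name in ("emg_rate", "imu_rate", "video_fps", "adc_range"):
            if getattr(self, name) <= 0:
                raise ParameterError(f"{name} must be strictly positive")
        for name in ("adc_bits", "emg_window", "imu_window", "n_resample"):
            if int(getattr(self, name)) < 1:
                raise ParameterError(f"{name} must be a positive integer")

    @property
    def adc_max(self) -> int:
        """Largest representable ADC count (4095 at 12 bit)."""
        return 2 ** self.adc_bits - 1

    @property
    def mv_per_count(self) -> float:
        """ADC step in millivolts (1600/4095 ≈ 0.39 mV at defaults)."""
        return 1000.0 * self.adc_range / self.adc_max

    @property
    def adc_midscale(self) -> int:
        """Count representing 0 V in a bipolar front end (2048 at 12 bit)."""
        return 2 ** (self.adc_bits - 1)


class Phase(enum.IntEnum):
    """The seven sub-tasks of a drinking/eating cycle."""

    REACH = 1  # starting position to reaching
    GRASP = 2
    TRANSPORT = 3  # transporting to the mouth
    IN_MOUTH = 4
    RETURN_TO_TABLE = 5
    RETURN_TO_START = 6
    REST = 7


PHASE_LABELS: dict[Phase, str] = {
    Phase.REACH: "start-to-reach",
    Phase.GRASP: "grasp",
    Phase.TRANSPORT: "transport-to-mouth",
    Phase.IN_MOUTH: "in-mouth",
    Phase.RETURN_TO_TABLE: "return-to-table",
    Phase.RETURN_TO_START: "return-to-start",
    Phase.REST: "rest",
}


class Muscle(str, enum.Enum):
    """The six shoulder muscles recorded per limb."""

    PM = "PM"  # Pectoralis Major
    AD = "AD"  # Anterior Deltoid
    MD = "MD"  # Middle Deltoid
    PD = "PD"  # Posterior Deltoid
    UT = "UT"  # Upper Trapezius
    LT = "LT"  # Lower Trapezius


class Motion(str, enum.Enum):
    """The six shoulder motions of the arm segment (three signed pairs)."""

    F = "F"  # Flexion
    E = "E"  # Extension
    MR = "MR"  # Medial Rotation
    LR = "LR"  # Lateral Rotation
    ABD = "ABD"  # Abduction
    ADD = "ADD"  # Adduction


#: Canonical anatomical axes (column order used by the IMU branch).
#: Each motion maps to a fixed sign on one axis, on both limbs.
ANATOMICAL_AXES: tuple[str, str, str] = ("fe", "abad", "rot")

MOTION_AXIS_SIGN: dict[Motion, tuple[str, int]] = {
    Motion.E: ("fe", +1),
    Motion.F: ("fe", -1),
    Motion.ABD: ("abad", +1),
    Motion.ADD: ("abad", -1),
    Motion.LR: ("rot", +1),
    Motion.MR: ("rot", -1),
}


@dataclass(frozen=True)
class PhaseAnnotation:
    """Phase boundaries of one movement cycle, from frame-stepped video.

    ``boundaries`` holds 8 strictly increasing times in seconds: the
    start of phase 1 through the end of phase 7.  ``frames`` optionally
    records the source video frame index of each boundary.
    """

    trial_id: str
    boundaries: tuple[float, ...]
    frames: tuple[int, ...] | None = None

    def __post_init__(self) -> None:
        b = np.asarray(self.boundaries, dtype=float)
        if b.shape != (8,):
            raise AnnotationError(
                f"annotation {self.trial_id!r}: expected 8 boundaries, got {b.size}"
            )
        if np.any(b < 0):
            raise AnnotationError(f"annotation {self.trial_id!r}: negative time")
        if np.any(np.diff(b) <= 0):
            raise AnnotationError(
                f"annotation {self.trial_id!r}: boundaries not strictly increasing"
            )
        if self.frames is not None and len(self.frames) != 8:
            raise AnnotationError(
                f"annotation {self.trial_id!r}: expected 8 frame indices"
            )

    @classmethod
    def from_frames(
        cls, trial_id: str, frames: Sequence[int], fps: float
    ) -> "PhaseAnnotation":
        """Build an annotation from video frame indices at ``fps``."""
        frames = tuple(int(f) for f in frames)
        return cls(trial_id, tuple(f / fps for f in frames), frames)

    @property
    def start(self) -> float:
        return self.boundaries[0]

    @property
    def end(self) -> float:
        return self.boundaries[7]

    @property
    def duration(self) -> float:
        return self.end - self.start


@dataclass(frozen=True)
class PhaseSchedule:
    """Mean phase intervals and durations on the normalized cycle.

    ``mean_durations`` and ``sd_durations`` are per-phase percentages of
    the cycle; intervals are the cumulative sums of the means, so phase
    1 starts at 0 and phase 7 ends at the total (100 for any schedule
    aggregated from data).
    """

    task: str
    mean_durations: tuple[float, ...]
    sd_durations: tuple[float, ...]

    def __post_init__(self) -> None:
        if len(self.mean_durations) != 7 or len(self.sd_durations) != 7:
            raise ParameterError("a schedule needs exactly 7 phase entries")
        if any(d < 0 for d in self.mean_durations):
            raise ParameterError("phase durations must be non-negative")
        if any(s < 0 for s in self.sd_durations):
            raise ParameterError("phase SDs must be non-negative")

    @property
    def boundaries(self) -> np.ndarray:
        """8 cumulative boundaries starting at 0 (% of cycle)."""
        return np.concatenate(([0.0], np.cumsum(self.mean_durations)))

    @property
    def intervals(self) -> list[tuple[float, float]]:
        b = self.boundaries
        return [(float(b[i]), float(b[i + 1])) for i in range(7)]


@dataclass(frozen=True)
class NormalizedCycle:
    """A trajectory re-expressed on the 0–100 % cycle axis.

    ``values`` has ``n`` samples on a uniform axis from 0 to 100;
    ``units`` is one of ``"mV"``, ``"normalized"`` or ``"deg"``;
    ``channel`` names the muscle or anatomical axis; ``n_contributing``
    counts the cycles/subjects averaged into it.
    """

    values: np.ndarray
    units: str
    channel: str
    n_contributing: int = 1
    subject: str = "group"

    def __post_init__(self) -> None:
        v = np.asarray(self.values, dtype=float)
        if v.ndim != 1 or v.size < 2:
            raise ParameterError("cycle values must be a 1-D array of length >= 2")
        object.__setattr__(self, "values", v)

    @property
    def axis(self) -> np.ndarray:
        """Cycle positions in % — uniform, 0 to 100 inclusive."""
        return np.linspace(0.0, 100.0, self.values.size)


@dataclass(frozen=True)
class PeakSummary:
    """Peak location/amplitude of one channel on the normalized cycle."""

    channel: str
    peak_time: float  # % of cycle
    peak_value: float  # mV or degrees (signed for motions)
    phase_at_peak: Phase


def durations_from_annotation(ann: PhaseAnnotation) -> np.ndarray:
    """Per-phase durations as percentages of the annotated cycle.

    ``duration(k) = 100 * (b[k] - b[k-1]) / (b[7] - b[0])``; the seven
    values sum to 100 by construction.
    """
    b = np.asarray(ann.boundaries, dtype=float)
    total = b[7] - b[0]
    if total <= 0:
        raise AnnotationError(f"annotation {ann.trial_id!r}: zero-length cycle")
    return 100.0 * np.diff(b) / total


def aggregate_schedule(
    duration_lists: Sequence[Sequence[float]], task: str
) -> PhaseSchedule:
    """Aggregate per-trial phase durations into a mean ± SD schedule.

    The SD is the sample (n−1) standard deviation, 0 for a single
    trial.  Intervals are the cumulative sums of the mean durations.
    """
    try:
        arr = np.asarray(duration_lists, dtype=float)
    except ValueError as exc:
        raise ParameterError(f"ragged duration lists: {exc}") from exc
    if arr.ndim != 2 or arr.shape[1] != 7 or arr.shape[0] < 1:
        raise ParameterError(
            f"expected an (n_trials, 7) duration array, got shape {arr.shape}"
        )
    means = arr.mean(axis=0)
    sds = arr.std(axis=0, ddof=1) if arr.shape[0] > 1 else np.zeros(7)
    return PhaseSchedule(task, tuple(means), tuple(sds))


def locate_phase(t: float, schedule: PhaseSchedule) -> Phase:
    """Phase whose half-open interval [start, end) contains ``t`` (% cycle).

    ``t`` equal to the cycle end maps to phase 7 (closed on the right).
    """
    b = schedule.boundaries
    total = b[-1]
    eps = 1e-9 * max(total, 1.0)  # cumulative-sum rounding slack
    if t < -eps or t > total + eps:
        raise ParameterError(f"t={t} outside the cycle [0, {total}]")
    if t >= total - eps:
        return Phase.REST
    idx = int(np.searchsorted(b, t, side="right"))  # b[idx-1] <= t < b[idx]
    return Phase(idx)


def moving_average(x: np.ndarray, window: int) -> np.ndarray:
    """Centred moving average with shrinking windows at the edges.

    At sample ``i`` the mean is taken over indices
    ``[i - (window-1)//2, i + window//2]`` clipped to the signal, so the
    interior uses exactly ``window`` samples and the edges however many
    are available.  Works along axis 0 for 2-D input (one column per
    channel).
    """
    if int(window) < 1:
        raise ParameterError("window must be >= 1")
    window = int(window)
    x = np.asarray(x, dtype=float)
    if x.size == 0:
        raise ParameterError("signal must be non-empty")
    n = x.shape[0]
    csum = np.concatenate(
        [np.zeros((1,) + x.shape[1:]), np.cumsum(x, axis=0)], axis=0
    )
    i = np.arange(n)
    lo = np.maximum(0, i - (window - 1) // 2)
    hi = np.minimum(n, i + window // 2 + 1)
    counts = (hi - lo).reshape((n,) + (1,) * (x.ndim - 1))
    return (csum[hi] - csum[lo]) / counts


def resample_cycle(t: np.ndarray, x: np.ndarray, n: int) -> np.ndarray:
    """Linearly resample ``x(t)`` onto ``n`` uniform points over [t0, t_end].

    Endpoints are preserved exactly; interior points are linear
    interpolations (interp1-style).  2-D ``x`` is resampled per column.
    """
    t = np.asarray(t, dtype=float)
    x = np.asarray(x, dtype=float)
    if t.ndim != 1 or t.size < 2 or x.shape[0] != t.size:
        raise ParameterError("need >= 2 samples with matching time grid")
    if np.any(np.diff(t) <= 0):
        raise ParameterError("time grid must be strictly increasing")
    if int(n) < 2:
        raise ParameterError("target length must be >= 2")
    grid = np.linspace(t[0], t[-1], int(n))
    if x.ndim == 1:
        out = np.interp(grid, t, x)
    else:
        out = np.column_stack([np.interp(grid, t, x[:, j]) for j in range(x.shape[1])])
    # guarantee exact endpoint preservation against fp rounding
    out[0] = x[0]
    out[-1] = x[-1]
    return out
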