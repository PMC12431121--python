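"""IMU branch: quaternions → anatomical joint angles → normalized cycles.

Orientation quaternions from the arm-worn IMU are decomposed into
intrinsic Z-Y-X Euler angles (yaw, pitch, roll, in degrees), unwrapped
across the ±180° branch cut, smoothed with a 1 s (100-sample) centred
moving average, mapped onto anatomically signed axes, segmented into
the annotated cycles, zero-aligned at each cycle's start, resampled to
9000 points and averaged.  Each motion's signed extremum and its cycle
position are then reported against the phase schedule.

Sign conventions (canonical anatomical axes, identical on both limbs):
extension/flexion axis ``fe`` (E positive, F negative), abduction/
adduction axis ``abad`` (ABD positive, ADD negative), rotation axis
``rot`` (LR positive, MR negative).  The limb-specific mapping from
Euler angles follows the device placement: on the dominant arm
E = +yaw, ABD = +roll, LR = +pitch; on the non-dominant arm E = +yaw,
ADD = +roll and MR = +pitch, so roll and pitch flip sign when mapped
onto the canonical axes.
"""

from __future__ import annotations

from typing import Sequence

import numpy as np
from scipy.spatial.transform import Rotation

from .core import (
    ANATOMICAL_AXES,
    MOTION_AXIS_SIGN,
    AcquisitionSpec,
    Motion,
    NormalizedCycle,
    ParameterError,
    PeakSummary,
    PhaseAnnotation,
    PhaseSchedule,
    locate_phase,
    moving_average,
    resample_cycle,
)
from .emg import extract_cycles

__all__ = [
    "quat_to_euler",
    "euler_to_quat",
    "euler_to_anatomical",
    "anatomical_to_euler",
    "smooth_angles",
    "angle_cycles",
    "subject_mean_angle_cycle",
    "angle_peak_summary",
    "process_subject_imu",
]

#: |pitch| above this (degrees) is treated as gimbal lock and flagged.
GIMBAL_LOCK_DEG = 90.0 - 1e-4


def quat_to_euler(q: np.ndarray) -> tuple[np.ndarray, np.ndarray]:
    """Unit quaternions (w, x, y, z) → intrinsic Z-Y-X Euler angles.

    Returns ``(euler, gimbal)`` where ``euler`` has columns yaw, pitch,
    roll in degrees (yaw, roll ∈ (−180, 180], pitch ∈ [−90, 90]) and
    ``gimbal`` flags samples at |pitch| → 90° where the decomposition is
    degenerate; there the residual rotation is assigned to yaw and roll
    is set to 0.
    """
    q = np.asarray(q, dtype=float)
    single = q.ndim == 1
    q = np.atleast_2d(q)
    if q.shape[-1] != 4:
        raise ParameterError("quaternions must have 4 components (w, x, y, z)")
    norms = np.linalg.norm(q, axis=-1)
    if np.any(np.abs(norms - 1.0) > 1e-6):
        raise ParameterError("quaternions must be unit norm within 1e-6")
    rot = Rotation.from_quat(q, scalar_first=True)
    import warnings

    with warnings.catch_warnings():
        # scipy warns at gimbal lock; the degenerate convention it applies
        # (residual to the first angle, third angle 0) is exactly ours.
        warnings.simplefilter("ignore", UserWarning)
        euler = rot.as_euler("ZYX", degrees=True)
    euler = np.atleast_2d(euler)
    gimbal = np.abs(euler[:, 1]) >= GIMBAL_LOCK_DEG
    euler[gimbal, 2] = 0.0
    if single:
        return euler[0], gimbal[0]
    return euler, gimbal


def euler_to_quat(euler: np.ndarray) -> np.ndarray:
    """Inverse of :func:`quat_to_euler` (degrees in, (w,x,y,z) out)."""
    euler = np.asarray(euler, dtype=float)
    rot = Rotation.from_euler("ZYX", euler, degrees=True)
    return rot.as_quat(scalar_first=True)


def euler_to_anatomical(euler: np.ndarray, limb: str) -> np.ndarray:
    """Map (yaw, pitch, roll) onto the canonical (fe, abad, rot) axes.

    Dominant arm: fe = yaw, abad = roll, rot = pitch.  Non-dominant arm:
    fe = yaw, abad = −roll, rot = −pitch (its ADD/MR are positive on
    roll/pitch, so the canonical ABD/LR-positive axes flip sign).
    """
    euler = np.asarray(euler, dtype=float)
    yaw, pitch, roll = euler[..., 0], euler[..., 1], euler[..., 2]
    if limb == "dominant":
        return np.stack([yaw, roll, pitch], axis=-1)
    if limb == "non_dominant":
        return np.stack([yaw, -roll, -pitch], axis=-1)
    raise ParameterError(f"unknown limb {limb!r}")


def anatomical_to_euler(anat: np.ndarray, limb: str) -> np.ndarray:
    """Inverse of :func:`euler_to_anatomical` (used by the simulator)."""
    anat = np.asarray(anat, dtype=float)
    fe, abad, rot = anat[..., 0], anat[..., 1], anat[..., 2]
    if limb == "dominant":
        return np.stack([fe, rot, abad], axis=-1)
    if limb == "non_dominant":
        return np.stack([fe, -rot, -abad], axis=-1)
    raise ParameterError(f"unknown limb {limb!r}")


def smooth_angles(
    euler: np.ndarray, spec: AcquisitionSpec | None = None
) -> np.ndarray:
    """Unwrap yaw/roll across ±180° then apply the 1 s angle smoother.

    Pitch is bounded in [−90, 90] by the Z-Y-X decomposition and needs
    no unwrapping.  Averaging without unwrapping would produce spurious
    ~360° swings whenever a trajectory crosses the branch cut.
    """
    spec = spec or AcquisitionSpec()
    euler = np.asarray(euler, dtype=float).copy()
    euler[:, 0] = np.unwrap(euler[:, 0], period=360.0)
    euler[:, 2] = np.unwrap(euler[:, 2], period=360.0)
    return moving_average(euler, spec.imu_window)


def angle_cycles(
    time: np.ndarray,
    anat: np.ndarray,
    annotations: Sequence[PhaseAnnotation],
    spec: AcquisitionSpec | None = None,
) -> list[np.ndarray]:
    """Trim, zero-align and resample each annotated cycle.

    Every cycle's first sample is subtracted (zero-alignment) so all
    cycles start at 0° on every axis regardless of the resting
    orientation, then the cycle is resampled to ``n_resample`` points.
    """
    spec = spec or AcquisitionSpec()
    segments = extract_cycles(time, anat, annotations)
    out = []
    for t, v in segments:
        aligned = v - v[0]
        out.append(resample_cycle(t, aligned, spec.n_resample))
    return out


def subject_mean_angle_cycle(cycles: Sequence[np.ndarray]) -> np.ndarray:
    """Pointwise mean of a subject's zero-aligned cycles."""
    if len(cycles) == 0:
        raise ParameterError("need at least one angle cycle")
    return np.mean(cycles, axis=0)


def angle_peak_summary(
    cycle_values: np.ndarray, schedule: PhaseSchedule
) -> list[PeakSummary]:
    """Signed extremum per motion on the zero-aligned group trajectory.

    For each motion pair the positive-side label (E, ABD, LR) reports
    the axis maximum and the negative-side label (F, ADD, MR) the axis
    minimum, each with its cycle position (first occurrence on ties).
    Both pair members are always reported, so a one-sided excursion
    yields a near-zero value for the opposite label.
    """
    cycle_values = np.asarray(cycle_values, dtype=float)
    if cycle_values.ndim != 2 or cycle_values.shape[1] != 3:
        raise ParameterError("expected an (n, 3) anatomical-axis cycle")
    axis_pct = np.linspace(0.0, 100.0, cycle_values.shape[0])
    out = []
    for motion in Motion:
        axis_name, sign = MOTION_AXIS_SIGN[motion]
        col = cycle_values[:, ANATOMICAL_AXES.index(axis_name)]
        idx = int(np.argmax(sign * col))
        peak_time = float(axis_pct[idx])
        out.append(
            PeakSummary(
                channel=motion.value,
                peak_time=peak_time,
                peak_value=float(col[idx]),
                phase_at_peak=locate_phase(peak_time, schedule),
            )
        )
    return out


def process_subject_imu(
    raw_imu,
    annotations: Sequence[PhaseAnnotation],
    spec: AcquisitionSpec | None = None,
) -> np.ndarray:
    """Full IMU branch for one subject → mean (n_resample, 3) cycle."""
    spec = spec or AcquisitionSpec()
    euler, _ = quat_to_euler(raw_imu.quaternions)
    smoothed = smooth_angles(euler, spec)
    anat = euler_to_anatomical(smoothed, raw_imu.limb)
    cycles = angle_cycles(raw_imu.time, anat, annotations, spec)
    return subject_mean_angle_cycle(cycles)
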