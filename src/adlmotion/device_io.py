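"""Readers and writers for the device-style CSV dialect.

The wearable prototype exports one EMG stream (time + six muscle
channels as raw ADC counts) and one IMU stream (time + orientation
quaternion) per limb, plus per-trial phase annotations derived from
30 fps video.  The on-disk dialect is fixed here: comma-separated,
dot decimal, UTF-8, one ``# key=value`` metadata line followed by one
column-header line.

EMG file::

    # limb=dominant
    time_s,PM,AD,MD,PD,UT,LT
    0.000000,2048,2051,...

IMU file::

    # limb=dominant
    time_s,qw,qx,qy,qz
    0.000000,1.000000000,0.000000000,...

Annotation file (frame dialect; a seconds dialect with ``start_s`` /
``end_s`` columns is equivalent)::

    # fps=30
    trial_id,phase_index,start_frame,end_frame
    t1,1,0,52
    ...

EMG and IMU clocks are assumed already synchronized by the device's
hardware sync pulse; a constant inter-stream offset can be applied at
read time for recordings where that assumption fails.
"""

from __future__ import annotations

import json
import logging
from dataclasses import dataclass, field
from pathlib import Path
from typing import Sequence

import numpy as np
import pandas as pd

from .core import (
    AcquisitionSpec,
    AnnotationError,
    DataFormatError,
    Muscle,
    PhaseAnnotation,
)

__all__ = [
    "MUSCLE_ORDER",
    "RawEMG",
    "RawIMU",
    "TrialSet",
    "read_emg_csv",
    "write_emg_csv",
    "read_imu_csv",
    "write_imu_csv",
    "read_annotations",
    "write_annotations",
    "read_truth_json",
    "write_truth_json",
]

logger = logging.getLogger(__name__)

#: Canonical channel order in EMG files and arrays.
MUSCLE_ORDER: tuple[Muscle, ...] = (
    Muscle.PM,
    Muscle.AD,
    Muscle.MD,
    Muscle.PD,
    Muscle.UT,
    Muscle.LT,
)

LIMBS = ("dominant", "non_dominant")


@dataclass
class RawEMG:
    """One limb's raw EMG recording: ADC counts per muscle channel.

    ``counts`` is (n_samples, 6) int in canonical ``MUSCLE_ORDER``;
    ``n_clipped`` counts samples that were saturated to the ADC range
    at load time.
    """

    limb: str
    time: np.ndarray
    counts: np.ndarray
    n_clipped: int = 0

    def __post_init__(self) -> None:
        if self.limb not in LIMBS:
            raise DataFormatError(f"unknown limb {self.limb!r}")
        self.time = np.asarray(self.time, dtype=float)
        self.counts = np.asarray(self.counts)
        if self.counts.shape != (self.time.size, len(MUSCLE_ORDER)):
            raise DataFormatError(
                "EMG counts must be (n_samples, 6) matching the time vector"
            )
        if np.any(np.diff(self.time) < 0):
            raise DataFormatError("EMG time vector must be non-decreasing")


@dataclass
class RawIMU:
    """One limb's orientation stream: unit quaternions (w, x, y, z)."""

    limb: str
    time: np.ndarray
    quaternions: np.ndarray

    def __post_init__(self) -> None:
        if self.limb not in LIMBS:
            raise DataFormatError(f"unknown limb {self.limb!r}")
        self.time = np.asarray(self.time, dtype=float)
        self.quaternions = np.asarray(self.quaternions, dtype=float)
        if self.quaternions.shape != (self.time.size, 4):
            raise DataFormatError("quaternions must be (n_samples, 4)")
        if np.any(np.diff(self.time) < 0):
            raise DataFormatError("IMU time vector must be non-decreasing")
        norms = np.linalg.norm(self.quaternions, axis=1)
        if np.any(np.abs(norms - 1.0) > 1e-6):
            raise DataFormatError("quaternions must be unit norm within 1e-6")


@dataclass
class TrialSet:
    """One subject × task: per-limb recordings plus 5 cycle annotations."""

    subject_id: str
    task: str
    emg: dict[str, RawEMG]
    imu: dict[str, RawIMU]
    annotations: list[PhaseAnnotation]

    def __post_init__(self) -> None:
        if self.task not in ("drinking", "eating"):
            raise DataFormatError(f"unknown task {self.task!r}")
        for limb, rec in self.emg.items():
            t0, t1 = rec.time[0], rec.time[-1]
            for ann in self.annotations:
                if ann.start < t0 - 1e-9 or ann.end > t1 + 1e-9:
                    raise AnnotationError(
                        f"annotation {ann.trial_id!r} outside the {limb} recording"
                    )


def _read_header(path: Path) -> tuple[dict[str, str], int]:
    """Parse leading ``# key=value`` lines; return (meta, n_header_lines)."""
    meta: dict[str, str] = {}
    n = 0
    with open(path, "r", encoding="utf-8") as fh:
        for line in fh:
            if not line.startswith("#"):
                break
            for item in line[1:].strip().split():
                if "=" in item:
                    key, val = item.split("=", 1)
                    meta[key] = val
            n += 1
    return meta, n


def _numeric_frame(df: pd.DataFrame, path: Path, columns: Sequence[str]) -> pd.DataFrame:
    """Coerce columns to numeric, raising with the offending row number."""
    out = {}
    for col in columns:
        if col not in df.columns:
            raise DataFormatError(f"{path}: missing column {col!r}")
        vals = pd.to_numeric(df[col], errors="coerce")
        bad = vals.isna() & df[col].notna()
        if bad.any() or vals.isna().any():
            row = int(np.nonzero(vals.isna().to_numpy())[0][0])
            raise DataFormatError(
                f"{path}: non-numeric value in column {col!r} at data row {row}"
            )
        out[col] = vals.to_numpy()
    return pd.DataFrame(out)


def read_emg_csv(path: str | Path, spec: AcquisitionSpec | None = None) -> RawEMG:
    """Load an EMG counts file; out-of-range counts are clipped (logged)."""
    path = Path(path)
    spec = spec or AcquisitionSpec()
    meta, skip = _read_header(path)
    if "limb" not in meta:
        raise DataFormatError(f"{path}: header must declare limb=<dominant|non_dominant>")
    df = pd.read_csv(path, skiprows=skip)
    cols = ["time_s"] + [m.value for m in MUSCLE_ORDER]
    df = _numeric_frame(df, path, cols)
    counts = df[[m.value for m in MUSCLE_ORDER]].to_numpy()
    rounded = np.rint(counts).astype(np.int64)
    clipped = np.clip(rounded, 0, spec.adc_max)
    n_clipped = int(np.count_nonzero(clipped != rounded))
    if n_clipped:
        logger.warning("%s: clipped %d out-of-range EMG counts", path, n_clipped)
    return RawEMG(meta["limb"], df["time_s"].to_numpy(), clipped, n_clipped)


def write_emg_csv(path: str | Path, emg: RawEMG) -> None:
    """Write an EMG recording in the package dialect (round-trips exactly)."""
    path = Path(path)
    with open(path, "w", encoding="utf-8", newline="\n") as fh:
        fh.write(f"# limb={emg.limb}\n")
        fh.write("time_s," + ",".join(m.value for m in MUSCLE_ORDER) + "\n")
        for t, row in zip(emg.time, emg.counts):
            fh.write(f"{t:.6f}," + ",".join(str(int(c)) for c in row) + "\n")


def read_imu_csv(path: str | Path) -> RawIMU:
    """Load a quaternion stream; renormalizes to unit length at load."""
    path = Path(path)
    meta, skip = _read_header(path)
    if "limb" not in meta:
        raise DataFormatError(f"{path}: header must declare limb=<dominant|non_dominant>")
    df = pd.read_csv(path, skiprows=skip)
    df = _numeric_frame(df, path, ["time_s", "qw", "qx", "qy", "qz"])
    quat = df[["qw", "qx", "qy", "qz"]].to_numpy()
    norms = np.linalg.norm(quat, axis=1)
    zero = norms < 1e-12
    if np.any(zero):
        row = int(np.nonzero(zero)[0][0])
        raise DataFormatError(f"{path}: zero-norm quaternion at data row {row}")
    quat = quat / norms[:, None]
    return RawIMU(meta["limb"], df["time_s"].to_numpy(), quat)


def write_imu_csv(path: str | Path, imu: RawIMU) -> None:
    """Write a quaternion stream; 9-decimal quaternions, 6-decimal time."""
    path = Path(path)
    with open(path, "w", encoding="utf-8", newline="\n") as fh:
        fh.write(f"# limb={imu.limb}\n")
        fh.write("time_s,qw,qx,qy,qz\n")
        for t, q in zip(imu.time, imu.quaternions):
            fh.write(f"{t:.6f}," + ",".join(f"{v:.9f}" for v in q) + "\n")


def read_annotations(path: str | Path, fps: float | None = None) -> list[PhaseAnnotation]:
    """Load per-trial phase annotations (frame or seconds dialect).

    Each trial must contribute exactly 7 contiguous phases (end of
    phase k equals start of phase k+1); frame indices are converted at
    ``t = frame / fps`` with fps taken from the header unless given.
    """
    path = Path(path)
    meta, skip = _read_header(path)
    df = pd.read_csv(path, skiprows=skip)
    if "trial_id" not in df.columns or "phase_index" not in df.columns:
        raise DataFormatError(f"{path}: annotation file needs trial_id and phase_index")
    frame_dialect = "start_frame" in df.columns and "end_frame" in df.columns
    seconds_dialect = "start_s" in df.columns and "end_s" in df.columns
    if not frame_dialect and not seconds_dialect:
        raise DataFormatError(
            f"{path}: need start_frame/end_frame or start_s/end_s columns"
        )
    if frame_dialect:
        if fps is None:
            if "fps" not in meta:
                raise DataFormatError(f"{path}: fps missing from header and arguments")
            fps = float(meta["fps"])
        if fps <= 0:
            raise DataFormatError(f"{path}: fps must be positive")

    annotations = []
    for trial_id, grp in df.groupby("trial_id", sort=False):
        grp = grp.sort_values("phase_index")
        phases = grp["phase_index"].to_numpy()
        if not np.array_equal(phases, np.arange(1, 8)):
            raise DataFormatError(
                f"{path}: trial {trial_id!r} must have phases 1..7 exactly once"
            )
        if frame_dialect:
            starts = grp["start_frame"].to_numpy(dtype=float)
            ends = grp["end_frame"].to_numpy(dtype=float)
        else:
            starts = grp["start_s"].to_numpy(dtype=float)
            ends = grp["end_s"].to_numpy(dtype=float)
        if not np.allclose(starts[1:], ends[:-1], atol=1e-9):
            k = int(np.nonzero(~np.isclose(starts[1:], ends[:-1], atol=1e-9))[0][0]) + 1
            raise AnnotationError(
                f"{path}: trial {trial_id!r} phases {k} and {k + 1} are not contiguous"
            )
        bounds = np.concatenate([starts[:1], ends])
        if frame_dialect:
            frames = tuple(int(b) for b in bounds)
            annotations.append(PhaseAnnotation.from_frames(str(trial_id), frames, fps))
        else:
            annotations.append(PhaseAnnotation(str(trial_id), tuple(bounds)))
    if not annotations:
        raise DataFormatError(f"{path}: no trials found")
    return annotations


def write_annotations(
    path: str | Path, annotations: Sequence[PhaseAnnotation], fps: float
) -> None:
    """Write annotations in the frame dialect when frames are present.

    Annotations carrying frame indices are written as frames (lossless
    round trip through ``t = frame/fps``); others fall back to seconds.
    """
    path = Path(path)
    frame_dialect = all(a.frames is not None for a in annotations)
    with open(path, "w", encoding="utf-8", newline="\n") as fh:
        fh.write(f"# fps={fps:g}\n")
        if frame_dialect:
            fh.write("trial_id,phase_index,start_frame,end_frame\n")
            for ann in annotations:
                for k in range(7):
                    fh.write(
                        f"{ann.trial_id},{k + 1},{ann.frames[k]},{ann.frames[k + 1]}\n"
                    )
        else:
            fh.write("trial_id,phase_index,start_s,end_s\n")
            for ann in annotations:
                for k in range(7):
                    fh.write(
                        f"{ann.trial_id},{k + 1},"
                        f"{ann.boundaries[k]:.6f},{ann.boundaries[k + 1]:.6f}\n"
                    )


def write_truth_json(path: str | Path, truth: dict) -> None:
    """Serialize a ground-truth sidecar (plain JSON, lossless floats)."""
    with open(path, "w", encoding="utf-8") as fh:
        json.dump(truth, fh, indent=1, sort_keys=True)


def read_truth_json(path: str | Path) -> dict:
    with open(path, "r", encoding="utf-8") as fh:
        return json.load(fh)
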