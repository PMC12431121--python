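"""Dataset → pipeline → schedule/peak tables, with a run manifest.

`run_pipeline` orchestrates the whole analysis for one dataset: phase
schedules aggregated from the video-derived annotations, the EMG branch
(per-muscle group envelopes and peak summaries, on both the mV scale
and the 0–1 normalized scale) and the IMU branch (group joint-angle
trajectories and signed per-motion peak summaries), for each limb.
Subjects whose files cannot be processed are excluded subject-wise with
a logged reason, mirroring how connectivity dropouts are handled in
practice.

`check_schedule` audits a schedule table for internal consistency:
phase intervals must be contiguous, each interval width must equal the
stated mean duration to the printed one-decimal precision, and the
cycle must close at 100 %.  Run against the published drinking table it
flags the two known rounding/inconsistency discrepancies (phase 4 by
0.1, phase 6 by 0.8) and passes the other five phases.

All percentages, millivolts and degrees are kept at full precision in
memory and rounded to one decimal only in serialized tables.
"""

from __future__ import annotations

import json
import logging
import re
from dataclasses import dataclass, field
from pathlib import Path
from typing import Sequence

import numpy as np
import pandas as pd

from . import __version__ as _pkg_version
from .core import (
    ANATOMICAL_AXES,
    AcquisitionSpec,
    DataFormatError,
    NormalizedCycle,
    PhaseSchedule,
    aggregate_schedule,
    durations_from_annotation,
)
from .device_io import (
    MUSCLE_ORDER,
    TrialSet,
    read_annotations,
    read_emg_csv,
    read_imu_csv,
    read_truth_json,
)
from .emg import emg_peak_summary, group_mean_cycle, minmax_normalize, process_subject_emg
from .imu import angle_peak_summary, process_subject_imu
from .synth import LIMBS, SubjectRecording

__all__ = [
    "REFERENCE_SCHEDULE_TABLES",
    "ReportBundle",
    "load_dataset",
    "run_pipeline",
    "check_schedule",
    "schedule_to_table",
    "plot_report",
]

logger = logging.getLogger(__name__)

SCHEDULE_COLUMNS = ["Phases", "Interval of Mean Time (%)", "Mean Duration ± SDT (%)"]
EMG_COLUMNS = [
    "Arm",
    "Muscle",
    "Mean Time of Amplitude Peak (%)",
    "Mean Amplitude Contraction Peak (mV)",
]
MOTION_COLUMNS = [
    "Arm",
    "Motion",
    "Mean Time of Amplitude Peak (%)",
    "Mean Arm Joint Range of Motion (°)",
]

ARM_LABELS = {"dominant": "Dominant", "non_dominant": "Non-Dominant"}


def _schedule_table(rows: list[tuple[int, float, float, float, float]]) -> pd.DataFrame:
    data = [
        {
            SCHEDULE_COLUMNS[0]: phase,
            SCHEDULE_COLUMNS[1]: f"[{lo:.1f}, {hi:.1f}]",
            SCHEDULE_COLUMNS[2]: f"{mean:.1f} ± {sd:.1f}",
        }
        for phase, lo, hi, mean, sd in rows
    ]
    return pd.DataFrame(data, columns=SCHEDULE_COLUMNS)


#: Published phase-schedule tables (drinking/eating), kept verbatim as
#: consistency-check inputs.  Note the drinking table's printed phase-4
#: and phase-6 durations do not match their interval widths — that is a
#: property of the source, surfaced by ``check_schedule``.
REFERENCE_SCHEDULE_TABLES: dict[str, pd.DataFrame] = {
    "drinking": _schedule_table(
        [
            (1, 0.0, 17.2, 17.2, 3.5),
            (2, 17.2, 21.6, 4.4, 4.0),
            (3, 21.6, 31.4, 9.8, 4.8),
            (4, 31.4, 53.2, 21.7, 5.9),
            (5, 53.2, 66.8, 13.6, 2.6),
            (6, 66.8, 84.7, 17.1, 7.4),
            (7, 84.7, 100.0, 15.3, 2.4),
        ]
    ),
    "eating": _schedule_table(
        [
            (1, 0.0, 15.9, 15.9, 2.5),
            (2, 15.9, 21.1, 5.2, 1.7),
            (3, 21.1, 44.1, 23.0, 3.0),
            (4, 44.1, 55.7, 11.6, 2.7),
            (5, 55.7, 69.5, 13.7, 2.9),
            (6, 69.5, 86.2, 16.8, 3.9),
            (7, 86.2, 100.0, 13.8, 1.9),
        ]
    ),
}


@dataclass
class ReportBundle:
    """Everything one pipeline run produces, before serialization."""

    task: str
    schedule: PhaseSchedule
    schedule_table: pd.DataFrame
    emg_table: pd.DataFrame
    motion_table: pd.DataFrame
    emg_cycles: dict[tuple[str, str], NormalizedCycle]  # (limb, "mv"/"norm") → per muscle
    angle_cycles: dict[str, np.ndarray]  # limb → (n_resample, 3)
    n_subjects: int
    excluded: list[tuple[str, str]]
    manifest: dict

    def write(self, out_dir: str | Path) -> None:
        """Serialize tables, group cycles and the run manifest as CSV/JSON."""
        out_dir = Path(out_dir)
        out_dir.mkdir(parents=True, exist_ok=True)
        self.schedule_table.to_csv(out_dir / "schedule.csv", index=False)
        self.emg_table.to_csv(out_dir / "emg_peaks.csv", index=False)
        self.motion_table.to_csv(out_dir / "motion_peaks.csv", index=False)
        for limb in sorted({limb for limb, _ in self.emg_cycles}):
            for kind in ("mv", "norm"):
                cycles = self.emg_cycles[(limb, kind)]
                df = pd.DataFrame({"pct": cycles[MUSCLE_ORDER[0].value].axis})
                for muscle in MUSCLE_ORDER:
                    df[muscle.value] = cycles[muscle.value].values
                df.to_csv(
                    out_dir / f"cycles_emg_{kind}_{limb}.csv",
                    index=False,
                    float_format="%.6f",
                )
        for limb, arr in self.angle_cycles.items():
            df = pd.DataFrame({"pct": np.linspace(0.0, 100.0, arr.shape[0])})
            for a, name in enumerate(ANATOMICAL_AXES):
                df[name] = arr[:, a]
            df.to_csv(
                out_dir / f"cycles_angle_{limb}.csv", index=False, float_format="%.6f"
            )
        with open(out_dir / "run_manifest.json", "w", encoding="utf-8") as fh:
            json.dump(self.manifest, fh, indent=1, sort_keys=True)


def load_dataset(input_dir: str | Path) -> tuple[list[SubjectRecording], dict]:
    """Load a written dataset back into memory via its manifest."""
    input_dir = Path(input_dir)
    manifest_path = input_dir / "manifest.json"
    if not manifest_path.exists():
        raise DataFormatError(f"{input_dir}: no manifest.json found")
    with open(manifest_path, "r", encoding="utf-8") as fh:
        manifest = json.load(fh)
    subject_ids = sorted({rel.split("/")[0] for rel in manifest["files"]})
    recordings = []
    for sid in subject_ids:
        sub = input_dir / sid
        emg = {limb: read_emg_csv(sub / f"{limb}_emg.csv") for limb in LIMBS}
        imu = {limb: read_imu_csv(sub / f"{limb}_imu.csv") for limb in LIMBS}
        annotations = read_annotations(sub / "annotations.csv")
        truth = read_truth_json(sub / "truth.json")
        trial_set = TrialSet(sid, manifest["task"], emg, imu, annotations)
        recordings.append(SubjectRecording(trial_set, truth))
    return recordings, manifest


def run_pipeline(
    data: str | Path | Sequence[SubjectRecording] | Sequence[TrialSet],
    task: str | None = None,
    spec: AcquisitionSpec | None = None,
    limbs: Sequence[str] = LIMBS,
    seed: int | None = None,
) -> ReportBundle:
    """Run the full EMG+IMU analysis over a dataset.

    ``data`` may be a dataset directory (as produced by
    :func:`adlmotion.synth.write_dataset`) or an in-memory sequence of
    recordings.  Subjects that fail to process are excluded with a
    logged reason rather than aborting the run.
    """
    spec = spec or AcquisitionSpec()
    if isinstance(data, (str, Path)):
        recordings, manifest_in = load_dataset(data)
        task = task or manifest_in.get("task")
    else:
        recordings = [
            r if isinstance(r, SubjectRecording) else SubjectRecording(r, {})
            for r in data
        ]
    trial_sets = [r.trial_set for r in recordings]
    if task is None:
        task = trial_sets[0].task if trial_sets else "drinking"

    excluded: list[tuple[str, str]] = []
    duration_lists: list[np.ndarray] = []
    subject_emg: dict[str, list] = {limb: [] for limb in limbs}
    subject_angles: dict[str, list] = {limb: [] for limb in limbs}
    n_ok = 0
    for ts in trial_sets:
        try:
            durations = [durations_from_annotation(a) for a in ts.annotations]
            per_subject_emg = {}
            per_subject_ang = {}
            for limb in limbs:
                per_subject_emg[limb] = process_subject_emg(
                    ts.emg[limb], ts.annotations, spec
                )
                per_subject_ang[limb] = process_subject_imu(
                    ts.imu[limb], ts.annotations, spec
                )
        except Exception as exc:  # noqa: BLE001 — exclusion is the contract
            logger.warning("excluding subject %s: %s", ts.subject_id, exc)
            excluded.append((ts.subject_id, str(exc)))
            continue
        duration_lists.extend(durations)
        for limb in limbs:
            subject_emg[limb].append(per_subject_emg[limb])
            subject_angles[limb].append(per_subject_ang[limb])
        n_ok += 1
    if n_ok == 0:
        raise DataFormatError("no subject could be processed")

    schedule = aggregate_schedule(duration_lists, task)
    schedule_table = schedule_to_table(schedule)

    emg_rows = []
    emg_cycles: dict[tuple[str, str], dict[str, NormalizedCycle]] = {}
    motion_rows = []
    angle_group: dict[str, np.ndarray] = {}
    for limb in limbs:
        mv_group: dict[str, NormalizedCycle] = {}
        norm_group: dict[str, NormalizedCycle] = {}
        for j, muscle in enumerate(MUSCLE_ORDER):
            mv_cycles = [subj[j].mv for subj in subject_emg[limb]]
            norm_cycles = [subj[j].normalized for subj in subject_emg[limb]]
            mv_group[muscle.value] = group_mean_cycle(mv_cycles)
            norm_group[muscle.value] = group_mean_cycle(norm_cycles)
            peak = emg_peak_summary(mv_group[muscle.value], schedule)
            emg_rows.append(
                {
                    EMG_COLUMNS[0]: ARM_LABELS[limb],
                    EMG_COLUMNS[1]: muscle.value,
                    EMG_COLUMNS[2]: round(peak.peak_time, 1),
                    EMG_COLUMNS[3]: round(peak.peak_value, 1),
                }
            )
        emg_cycles[(limb, "mv")] = mv_group
        emg_cycles[(limb, "norm")] = norm_group

        group_angles = np.mean(subject_angles[limb], axis=0)
        angle_group[limb] = group_angles
        for peak in angle_peak_summary(group_angles, schedule):
            motion_rows.append(
                {
                    MOTION_COLUMNS[0]: ARM_LABELS[limb],
                    MOTION_COLUMNS[1]: peak.channel,
                    MOTION_COLUMNS[2]: round(peak.peak_time, 1),
                    MOTION_COLUMNS[3]: round(peak.peak_value, 1),
                }
            )

    manifest = {
        "package_version": _pkg_version,
        "task": task,
        "n_subjects": n_ok,
        "n_excluded": len(excluded),
        "excluded": [{"subject_id": s, "reason": r} for s, r in excluded],
        "limbs": list(limbs),
        "seed": seed,
        "spec": {
            "emg_rate": spec.emg_rate,
            "imu_rate": spec.imu_rate,
            "video_fps": spec.video_fps,
            "adc_bits": spec.adc_bits,
            "adc_range": spec.adc_range,
            "emg_window": spec.emg_window,
            "imu_window": spec.imu_window,
            "n_resample": spec.n_resample,
        },
    }
    return ReportBundle(
        task=task,
        schedule=schedule,
        schedule_table=schedule_table,
        emg_table=pd.DataFrame(emg_rows, columns=EMG_COLUMNS),
        motion_table=pd.DataFrame(motion_rows, columns=MOTION_COLUMNS),
        emg_cycles=emg_cycles,
        angle_cycles=angle_group,
        n_subjects=n_ok,
        excluded=excluded,
        manifest=manifest,
    )


def schedule_to_table(schedule: PhaseSchedule) -> pd.DataFrame:
    """Serialize a schedule in the published table layout (1 decimal).

    Interval endpoints are the cumulative sums of the *rounded* mean
    durations, so the serialized table is self-consistent at printed
    precision (every interval width equals its printed duration); the
    final endpoint may consequently sit within a few tenths of 100.
    """
    rows = []
    rounded = [round(m, 1) for m in schedule.mean_durations]
    lo = 0.0
    for k, width in enumerate(rounded):
        hi = round(lo + width, 1)
        rows.append((k + 1, lo, hi, rounded[k], schedule.sd_durations[k]))
        lo = hi
    return _schedule_table(rows)


_INTERVAL_RE = re.compile(r"\[\s*(-?\d+(?:\.\d+)?)\s*,\s*(-?\d+(?:\.\d+)?)\s*\]")
_DURATION_RE = re.compile(r"(-?\d+(?:\.\d+)?)\s*(?:±|\+/-)\s*(\d+(?:\.\d+)?)")


def check_schedule(table: pd.DataFrame, tol: float = 0.05) -> pd.DataFrame:
    """Audit a schedule table for internal consistency.

    Per phase: the interval must be contiguous with the previous one,
    and its width must equal the stated mean duration within ``tol``
    (default 0.05 — agreement at the printed one-decimal precision).
    Returns one row per phase with the measured discrepancy and a
    ``passed`` flag; the last interval must close at 100 %.
    """
    for col in SCHEDULE_COLUMNS:
        if col not in table.columns:
            raise DataFormatError(f"schedule table missing column {col!r}")
    if len(table) != 7:
        raise DataFormatError(f"schedule table must have 7 rows, got {len(table)}")
    rows = []
    prev_end = 0.0
    for _, row in table.iterrows():
        m = _INTERVAL_RE.search(str(row[SCHEDULE_COLUMNS[1]]))
        if not m:
            raise DataFormatError(
                f"phase {row[SCHEDULE_COLUMNS[0]]}: malformed interval "
                f"{row[SCHEDULE_COLUMNS[1]]!r}"
            )
        lo, hi = float(m.group(1)), float(m.group(2))
        d = _DURATION_RE.search(str(row[SCHEDULE_COLUMNS[2]]))
        if not d:
            raise DataFormatError(
                f"phase {row[SCHEDULE_COLUMNS[0]]}: malformed duration "
                f"{row[SCHEDULE_COLUMNS[2]]!r}"
            )
        mean, sd = float(d.group(1)), float(d.group(2))
        width = hi - lo
        discrepancy = width - mean
        contiguous = abs(lo - prev_end) <= tol + 1e-12
        passed = contiguous and abs(discrepancy) <= tol + 1e-12
        rows.append(
            {
                "phase": int(row[SCHEDULE_COLUMNS[0]]),
                "start": lo,
                "end": hi,
                "width": round(width, 6),
                "mean_duration": mean,
                "sd_duration": sd,
                "discrepancy": round(discrepancy, 6),
                "contiguous": contiguous,
                "passed": passed,
            }
        )
        prev_end = hi
    out = pd.DataFrame(rows)
    # allow one half-ULP of printed rounding per phase to accumulate
    closes = abs(out["end"].iloc[-1] - 100.0) <= 7 * tol + 1e-12
    out.attrs["closes_at_100"] = bool(closes)
    if not closes:
        out.loc[out.index[-1], "passed"] = False
    return out


def plot_report(bundle: ReportBundle, out_dir: str | Path) -> list[Path]:
    """Figure-style plots: group envelopes and joint angles per limb,
    with phase boundaries overlaid.  Returns the written paths."""
    import matplotlib

    matplotlib.use("Agg", force=False)
    import matplotlib.pyplot as plt

    out_dir = Path(out_dir)
    out_dir.mkdir(parents=True, exist_ok=True)
    written = []
    boundaries = bundle.schedule.boundaries
    for limb in sorted({limb for limb, _ in bundle.emg_cycles}):
        fig, axes = plt.subplots(2, 1, figsize=(8, 7), sharex=True)
        cycles = bundle.emg_cycles[(limb, "mv")]
        for muscle in MUSCLE_ORDER:
            c = cycles[muscle.value]
            axes[0].plot(c.axis, c.values, label=muscle.value, lw=1.0)
        axes[0].set_ylabel("envelope (mV)")
        axes[0].legend(ncol=3, fontsize=8)
        arr = bundle.angle_cycles[limb]
        pct = np.linspace(0.0, 100.0, arr.shape[0])
        labels = ("F(−)/E(+)", "ADD(−)/ABD(+)", "MR(−)/LR(+)")
        for a, lab in enumerate(labels):
            axes[1].plot(pct, arr[:, a], label=lab, lw=1.0)
        axes[1].set_ylabel("angle (°)")
        axes[1].set_xlabel("% of cycle")
        axes[1].legend(fontsize=8)
        for ax in axes:
            for b in boundaries[1:-1]:
                ax.axvline(b, color="0.8", lw=0.6, zorder=0)
        fig.suptitle(f"{bundle.task} — {ARM_LABELS[limb]} arm (n={bundle.n_subjects})")
        path = out_dir / f"report_{bundle.task}_{limb}.png"
        fig.savefig(path, dpi=120)
        plt.close(fig)
        written.append(path)
    return written
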