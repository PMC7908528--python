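"""CSV readers and writers for trial signals, manifests and cohorts."""

from __future__ import annotations

import os
from pathlib import Path

import numpy as np
import pandas as pd

from .cycling import CyclingRecord
from .isokinetic import IsokineticTrace
from .jump import ForceTrace
from .synthetic import Cohort

__all__ = [
    "read_jump_trial",
    "read_cycling_trial",
    "read_isokinetic_trial",
    "write_jump_trial",
    "write_cycling_trial",
    "write_isokinetic_trial",
    "write_cohort",
    "read_manifest",
]


def _read_columns(path, required: tuple[str, ...]) -> pd.DataFrame:
    df = pd.read_csv(path)
    missing = [c for c in required if c not in df.columns]
    if missing:
        raise ValueError(f"{path}: missing required columns {missing}")
    return df


def _infer_rate(time_s: np.ndarray) -> float:
    dt = np.median(np.diff(time_s))
    if dt <= 0:
        raise ValueError("time column must be strictly increasing")
    return 1.0 / float(dt)


def read_jump_trial(path, body_mass: float, added_load: float = 0.0) -> ForceTrace:
    df = _read_columns(path, ("time_s", "force_N"))
    return ForceTrace(
        force=df["force_N"].to_numpy(dtype=float),
        rate=_infer_rate(df["time_s"].to_numpy(dtype=float)),
        body_mass=body_mass,
        added_load=added_load,
    )


def read_cycling_trial(
    path, flywheel_load: float, crank_length: float = 0.170
) -> CyclingRecord:
    df = _read_columns(path, ("time_s", "power_W", "cadence_rpm"))
    return CyclingRecord(
        time=df["time_s"].to_numpy(dtype=float),
        power=df["power_W"].to_numpy(dtype=float),
        cadence=df["cadence_rpm"].to_numpy(dtype=float),
        flywheel_load=flywheel_load,
        crank_length=crank_length,
    )


def read_isokinetic_trial(
    path, angular_velocity: float, lever_arm: float
) -> IsokineticTrace:
    df = _read_columns(path, ("time_s", "force_N"))
    return IsokineticTrace(
        force=df["force_N"].to_numpy(dtype=float),
        angular_velocity=angular_velocity,
        lever_arm=lever_arm,
        rate=_infer_rate(df["time_s"].to_numpy(dtype=float)),
    )


def write_jump_trial(path, trace: ForceTrace) -> None:
    pd.DataFrame({"time_s": trace.time, "force_N": trace.force}).to_csv(
        path, index=False, float_format="%.6f"
    )


def write_cycling_trial(path, record: CyclingRecord) -> None:
    pd.DataFrame(
        {
            "time_s": record.time,
            "power_W": record.power,
            "cadence_rpm": record.cadence,
        }
    ).to_csv(path, index=False, float_format="%.6f")


def write_isokinetic_trial(path, trace: IsokineticTrace) -> None:
    time = np.arange(trace.n) / trace.rate
    pd.DataFrame({"time_s": time, "force_N": trace.force}).to_csv(
        path, index=False, float_format="%.6f"
    )


def write_cohort(cohort: Cohort, out_dir) -> Path:
    """Write a simulated cohort as a runnable manifest directory.

    Layout: ``subjects.csv``, ``trials.csv``, ``truth.csv`` and one CSV
    per trial under ``trials/``.
    """
    out_dir = Path(out_dir)
    trial_dir = out_dir / "trials"
    trial_dir.mkdir(parents=True, exist_ok=True)

    pd.DataFrame(
        [
            {
                "subject_id": s.subject_id,
                "body_mass_kg": s.body_mass,
                "lever_arm_m": s.lever_arm,
                "crank_length_m": s.crank_length,
            }
            for s in cohort.subjects
        ]
    ).to_csv(out_dir / "subjects.csv", index=False)

    pd.DataFrame(
        [
            {
                "subject_id": s.subject_id,
                "test": test,
                "true_F0_N": s.profiles[test].F0,
                "true_V0_mps": s.profiles[test].V0,
                "true_slope_Nspm": s.profiles[test].slope_a,
                "true_P0_W": s.profiles[test].P0,
            }
            for s in cohort.subjects
            for test in s.profiles
        ]
    ).to_csv(out_dir / "truth.csv", index=False)

    rows = []
    for rec in cohort.trials:
        name = (
            f"{rec.subject_id}_{rec.test}_"
            f"{rec.condition_label.replace(' ', '').replace('/', '')}_t{rec.trial_index}.csv"
        )
        path = trial_dir / name
        if rec.test == "jump":
            write_jump_trial(path, rec.data)
        elif rec.test == "cycling":
            write_cycling_trial(path, rec.data)
        else:
            write_isokinetic_trial(path, rec.data)
        rows.append(
            {
                "subject_id": rec.subject_id,
                "test": rec.test,
                "condition_label": rec.condition_label,
                "load": rec.load,
                "standard": int(rec.standard),
                "trial_index": rec.trial_index,
                "path": os.path.join("trials", name),
            }
        )
    pd.DataFrame(rows).to_csv(out_dir / "trials.csv", index=False)
    return out_dir


def read_manifest(manifest_dir) -> tuple[pd.DataFrame, pd.DataFrame]:
    """Read ``subjects.csv`` and ``trials.csv`` from a manifest directory.

    Validates that every trial references a known subject.
    """
    manifest_dir = Path(manifest_dir)
    subjects = _read_columns(
        manifest_dir / "subjects.csv",
        ("subject_id", "body_mass_kg", "lever_arm_m", "crank_length_m"),
    )
    trials = _read_columns(
        manifest_dir / "trials.csv",
        ("subject_id", "test", "condition_label", "load", "standard", "path"),
    )
    unknown = set(trials["subject_id"]) - set(subjects["subject_id"])
    if unknown:
        raise ValueError(f"trials reference unknown subjects: {sorted(unknown)}")
    bad_tests = set(trials["test"]) - {"jump", "cycling", "isokinetic"}
    if bad_tests:
        raise ValueError(f"unknown test names in manifest: {sorted(bad_tests)}")
    return subjects, trials
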