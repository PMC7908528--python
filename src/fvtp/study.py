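"""Batch orchestration: metrics per trial, two-point profiles per subject
and test, standard-test values, and the comparison statistics.

The same analysis core runs either on an in-memory simulated cohort
(:func:`process_cohort`) or on a manifest directory of trial CSVs
(:func:`run_study`), which additionally writes the report bundle
(profiles.csv, table1.csv, figure3.csv, comparisons.csv, run.log,
effective_config.yaml).
"""

from __future__ import annotations

import logging
from dataclasses import dataclass
from pathlib import Path
from typing import Iterable, Mapping

import pandas as pd

from . import io as fio
from .config import DEFAULT_CONFIG, dump_config, load_config, merge_config
from .cycling import extract_cycling_metrics
from .errors import FvtpError
from .isokinetic import extract_isokinetic_metrics
from .jump import extract_jump_metrics, select_best_trial
from .model import FVProfile, TrialMetrics, fit_two_point, point_from_metrics, profiles_to_csv
from .stats import ComparisonReport, build_comparison_table
from .synthetic import Cohort

__all__ = ["StudyResult", "Trial", "analyze_trials", "process_cohort", "run_study"]

logger = logging.getLogger("fvtp")


@dataclass(frozen=True)
class Trial:
    """One loaded trial ready for analysis."""

    subject_id: str
    test: str
    condition_label: str
    load: float
    standard: bool
    data: object


@dataclass(frozen=True)
class StudyResult:
    profiles_by_test: Mapping[str, Mapping[str, FVProfile]]
    standard_by_test: Mapping[str, Mapping[str, Mapping[str, float]]]
    metrics: Mapping[tuple[str, str], Mapping[str, TrialMetrics]]
    report: ComparisonReport
    exclusions: tuple[str, ...]


def _extract(trial: Trial, body_mass: float, config: dict) -> TrialMetrics:
    if trial.test == "jump":
        cfg = config["jump"]
        return extract_jump_metrics(
            trial.data,
            cutoff_hz=cfg["cutoff_hz"],
            onset_sd=cfg["onset_sd"],
            onset_floor_n=cfg["onset_floor_N"],
            flight_threshold_n=cfg["flight_threshold_N"],
            condition_label=trial.condition_label,
        )
    if trial.test == "cycling":
        return extract_cycling_metrics(
            trial.data,
            smooth_window_s=config["cycling"]["smooth_window_s"],
            condition_label=trial.condition_label,
        )
    if trial.test == "isokinetic":
        cfg = config["iso"]
        return extract_isokinetic_metrics(
            trial.data,
            cutoff_hz=cfg["cutoff_hz"],
            exclusion_fraction=cfg["exclusion_fraction"],
            condition_label=trial.condition_label,
        )
    raise ValueError(f"unknown test {trial.test!r}")


def analyze_trials(
    trials: Iterable[Trial],
    body_mass_by_subject: Mapping[str, float],
    config: dict | None = None,
) -> StudyResult:
    """Run the full per-trial/per-subject analysis and the statistics.

    Subjects whose extraction or fit fails for one test are excluded from
    that test only (pairwise-complete statistics); every exclusion is
    logged and returned.
    """
    config = merge_config(DEFAULT_CONFIG, config)
    exclusions: list[str] = []

    # best trial per subject x test x condition
    grouped: dict[tuple[str, str], dict[str, list]] = {}
    standard_flags: dict[tuple[str, str, str], bool] = {}
    loads: dict[tuple[str, str, str], float] = {}
    for trial in trials:
        metrics_list = grouped.setdefault((trial.subject_id, trial.test), {}).setdefault(
            trial.condition_label, []
        )
        try:
            metrics_list.append(
                _extract(trial, body_mass_by_subject[trial.subject_id], config)
            )
        except (FvtpError, ValueError) as exc:
            msg = (
                f"subject={trial.subject_id} test={trial.test} "
                f"condition={trial.condition_label!r} stage=extract event=excluded "
                f"reason={exc}"
            )
            logger.info(msg)
            exclusions.append(msg)
        standard_flags[(trial.subject_id, trial.test, trial.condition_label)] = (
            trial.standard
        )
        loads[(trial.subject_id, trial.test, trial.condition_label)] = trial.load

    metrics: dict[tuple[str, str], dict[str, TrialMetrics]] = {}
    for key, by_condition in grouped.items():
        best = {}
        for label, metric_list in by_condition.items():
            if metric_list:
                best[label] = select_best_trial(metric_list)
        if best:
            metrics[key] = best

    profiles_by_test: dict[str, dict[str, FVProfile]] = {}
    standard_by_test: dict[str, dict[str, dict[str, float]]] = {}
    for (subject_id, test), best in metrics.items():
        ordered = sorted(best, key=lambda lbl: loads[(subject_id, test, lbl)])
        # two-point fit from the extreme conditions
        try:
            if len(ordered) < 2:
                raise FvtpError(
                    f"only {len(ordered)} usable condition(s); two-point fit needs 2"
                )
            profile = fit_two_point(
                point_from_metrics(best[ordered[-1]]),
                point_from_metrics(best[ordered[0]]),
                body_mass=body_mass_by_subject.get(subject_id),
            )
            profiles_by_test.setdefault(test, {})[subject_id] = profile
        except (FvtpError, ValueError) as exc:
            msg = (
                f"subject={subject_id} test={test} stage=fit event=excluded "
                f"reason={exc}"
            )
            logger.info(msg)
            exclusions.append(msg)

        standard = _standard_values(subject_id, test, best, standard_flags)
        if standard is not None:
            standard_by_test.setdefault(test, {})[subject_id] = standard
        else:
            msg = (
                f"subject={subject_id} test={test} stage=standard event=excluded "
                "reason=no standard-condition trial"
            )
            logger.info(msg)
            exclusions.append(msg)

    tests = [t for t in ("jump", "cycling", "isokinetic") if t in profiles_by_test]
    report = build_comparison_table(
        {t: profiles_by_test[t] for t in tests if t in standard_by_test},
        {t: standard_by_test[t] for t in tests if t in standard_by_test},
        allow_pairwise=True,
    )
    return StudyResult(
        profiles_by_test=profiles_by_test,
        standard_by_test=standard_by_test,
        metrics=metrics,
        report=report,
        exclusions=tuple(exclusions),
    )


def _standard_values(subject_id, test, best, standard_flags):
    flagged = [
        lbl for lbl in best if standard_flags.get((subject_id, test, lbl), False)
    ]
    if not flagged:
        return None
    if test == "isokinetic":
        # force from the slow condition, power from the fast one
        by_velocity = sorted(flagged, key=lambda lbl: best[lbl].Vmax)
        slow, fast = by_velocity[0], by_velocity[-1]
        if slow == fast and len(by_velocity) < 2:
            return None
        return {"Fmax": best[slow].Fmax, "Pmax": best[fast].Pmax}
    label = flagged[0]
    return {"Fmax": best[label].Fmax, "Pmax": best[label].Pmax}


def process_cohort(cohort: Cohort, config: dict | None = None) -> StudyResult:
    """Analyze an in-memory simulated cohort end to end."""
    trials = [
        Trial(
            subject_id=r.subject_id,
            test=r.test,
            condition_label=r.condition_label,
            load=r.load,
            standard=r.standard,
            data=r.data,
        )
        for r in cohort.trials
    ]
    masses = {s.subject_id: s.body_mass for s in cohort.subjects}
    return analyze_trials(trials, masses, config)


def run_study(manifest_dir, out_dir, config_path=None) -> StudyResult:
    """Load a manifest directory, analyze it, and write the report bundle."""
    out_dir = Path(out_dir)
    out_dir.mkdir(parents=True, exist_ok=True)
    config = load_config(config_path)

    handler = logging.FileHandler(out_dir / "run.log", mode="w")
    handler.setFormatter(logging.Formatter("%(levelname)s %(message)s"))
    logger.addHandler(handler)
    logger.setLevel(logging.INFO)
    try:
        subjects, trials_df = fio.read_manifest(manifest_dir)
        meta = subjects.set_index("subject_id")
        manifest_dir = Path(manifest_dir)

        loaded: list[Trial] = []
        for row in trials_df.itertuples(index=False):
            path = manifest_dir / row.path
            try:
                if row.test == "jump":
                    data = fio.read_jump_trial(
                        path,
                        body_mass=float(meta.loc[row.subject_id, "body_mass_kg"]),
                        added_load=float(row.load),
                    )
                elif row.test == "cycling":
                    data = fio.read_cycling_trial(
                        path,
                        flywheel_load=float(row.load),
                        crank_length=float(meta.loc[row.subject_id, "crank_length_m"]),
                    )
                else:
                    data = fio.read_isokinetic_trial(
                        path,
                        angular_velocity=float(row.load),
                        lever_arm=float(meta.loc[row.subject_id, "lever_arm_m"]),
                    )
            except (OSError, ValueError) as exc:
                logger.info(
                    "subject=%s test=%s stage=load event=excluded reason=%s",
                    row.subject_id,
                    row.test,
                    exc,
                )
                continue
            loaded.append(
                Trial(
                    subject_id=row.subject_id,
                    test=row.test,
                    condition_label=str(row.condition_label),
                    load=float(row.load),
                    standard=bool(row.standard),
                    data=data,
                )
            )

        masses = {
            str(sid): float(meta.loc[sid, "body_mass_kg"]) for sid in meta.index
        }
        result = analyze_trials(loaded, masses, config)

        profile_rows = [
            (sid, test, prof)
            for test, by_subject in result.profiles_by_test.items()
            for sid, prof in sorted(by_subject.items())
        ]
        profiles_to_csv(profile_rows, out_dir / "profiles.csv")
        result.report.table1.to_csv(out_dir / "table1.csv", index=False)
        result.report.figure3.to_csv(out_dir / "figure3.csv", index=False)
        result.report.comparisons.to_csv(out_dir / "comparisons.csv", index=False)
        dump_config(config, out_dir / "effective_config.yaml")

        std_rows = [
            {"subject_id": sid, "test": test, **vals}
            for test, by_subject in result.standard_by_test.items()
            for sid, vals in sorted(by_subject.items())
        ]
        pd.DataFrame(std_rows).to_csv(out_dir / "standard_metrics.csv", index=False)
        logger.info(
            "event=done subjects=%d exclusions=%d", len(masses), len(result.exclusions)
        )
        return result
    finally:
        logger.removeHandler(handler)
        handler.close()
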