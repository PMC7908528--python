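"""Forward simulation of maximal-effort trials from known F-V profiles.

Every trial generator records its ground truth (event times, true peaks)
alongside the emitted signal so the processing pipelines and statistics
can be verified end to end without any recorded data.

Jump model
----------
The push-off force is prescribed as a smooth monotone rise
``F(t) = W + (Fpk - W) * smoothstep(t/T)`` whose endpoint is
self-consistent with the subject's linear F-V law: the peak force equals
the law evaluated at the takeoff velocity (``Fpk = F0 - a*v_to``), and
``(Fpk, T)`` are solved so the center of mass travels the prescribed
push-off distance.  A literal quasi-static actuator (force tracking the
law at every instant) would place the concentric force maximum at v = 0
under every load, making the independent-maxima two-point inputs
degenerate; the prescribed-endpoint model instead guarantees that each
trial's (Fmax, Vmax) pair lies exactly on the true line.

Cycling model
-------------
Friction-braked sprint: the resistive pedal force is proportional to the
flywheel load, cadence rises with first-order dynamics to the plateau
velocity where the F-V law balances the resistance, and reported power is
resistive force times pedal velocity.

Isokinetic model
----------------
Force ramps smoothly to the plateau given by the law at the device's
constant linear velocity, holds, and ramps down.
"""

from __future__ import annotations

import math
from dataclasses import dataclass, field
from typing import Mapping, Sequence

import numpy as np

from .cycling import CyclingRecord, pedal_velocity
from .errors import ConfigurationError, InfeasibleVelocityError
from .isokinetic import IsokineticTrace, angular_to_linear
from .jump import ForceTrace
from .model import FVProfile, predict_force

__all__ = [
    "SubjectTruth",
    "CohortConfig",
    "Cohort",
    "TrialRecord",
    "JumpTruth",
    "CyclingTruth",
    "IsokineticTruth",
    "simulate_jump_trace",
    "simulate_cycling_sprint",
    "simulate_isokinetic_trial",
    "generate_cohort",
]

GRAVITY = 9.81

TESTS = ("jump", "cycling", "isokinetic")


@dataclass(frozen=True)
class SubjectTruth:
    """Ground-truth profiles and anthropometry for one simulated subject."""

    subject_id: str
    body_mass: float
    lever_arm: float
    crank_length: float
    ability: float
    profiles: Mapping[str, FVProfile]

    def __post_init__(self):
        if not 40.0 < self.body_mass < 120.0:
            raise ValueError(f"body mass {self.body_mass!r} kg outside (40, 120)")
        missing = set(TESTS) - set(self.profiles)
        if missing:
            raise ValueError(f"missing profiles for tests: {sorted(missing)}")


@dataclass(frozen=True)
class JumpTruth:
    t_onset: float
    t_lowest: float
    t_takeoff: float
    Fmax: float
    Vmax: float
    Pmax: float
    no_takeoff: bool = False


@dataclass(frozen=True)
class CyclingTruth:
    F_plateau: float
    v_plateau: float
    Pmax: float
    peak_cadence: float


@dataclass(frozen=True)
class IsokineticTruth:
    F_plateau: float
    v_linear: float
    Pmax: float


def _smoothstep(u: np.ndarray) -> np.ndarray:
    return 3.0 * u**2 - 2.0 * u**3


def _minjerk_accel(u: np.ndarray) -> np.ndarray:
    # second derivative of the minimum-jerk position profile 10u^3-15u^4+6u^5
    return 60.0 * u - 180.0 * u**2 + 120.0 * u**3


def simulate_jump_trace(
    truth: SubjectTruth,
    added_load: float,
    noise_sd: float = 5.0,
    seed: int | Sequence[int] = 0,
    rate: float = 1000.0,
    quiet_s: float = 1.5,
    ecc_s: float = 0.6,
    depth: float = 0.40,
    extension: float = 0.25,
    flight_s: float = 0.35,
) -> tuple[ForceTrace, JumpTruth]:
    """Simulate one countermovement jump on the force plate.

    Returns the trace and the recorded ground truth.  A profile too weak
    to leave the ground under the given load yields a flagged truth with
    ``no_takeoff=True`` (the trace, without a flight phase, is still
    returned).
    """
    profile = truth.profiles["jump"]
    rng = np.random.default_rng(seed)
    mass = truth.body_mass + added_load
    weight = mass * GRAVITY
    dt = 1.0 / rate

    n_quiet = int(round(quiet_s * rate))
    n_ecc = int(round(ecc_s * rate))
    quiet = np.full(n_quiet, weight)

    # countermovement descent: minimum-jerk position 0 -> -depth
    u = np.arange(1, n_ecc + 1) / n_ecc
    ecc = weight - mass * depth * _minjerk_accel(u) / ecc_s**2

    feasible = profile.F0 > 1.02 * weight
    if not feasible:
        force = np.concatenate([quiet, ecc, np.full(n_quiet, weight)])
        force = force + rng.normal(0.0, noise_sd, force.size) if noise_sd > 0 else force
        trace = ForceTrace(
            force=force,
            rate=rate,
            body_mass=truth.body_mass,
            added_load=added_load,
            gravity=GRAVITY,
        )
        t0 = n_quiet * dt
        return trace, JumpTruth(
            t_onset=t0,
            t_lowest=t0 + ecc_s,
            t_takeoff=math.nan,
            Fmax=math.nan,
            Vmax=math.nan,
            Pmax=math.nan,
            no_takeoff=True,
        )

    # solve (Fpk, T) so the push-off travels depth+extension and ends on the
    # F-V line: Fpk = F0 - a*v_to with v_to = (Fpk - W) T / (2 M).  For the
    # smoothstep shape the travelled distance is 0.15*(Fpk - W)*T^2/M, so
    # eliminating T gives a quadratic in v_to:
    #   0.6*M*v_to^2 + travel*a*v_to - travel*(F0 - W) = 0
    travel = depth + extension
    a = profile.slope_a
    disc = (travel * a) ** 2 + 2.4 * mass * travel * (profile.F0 - weight)
    v_to = (-travel * a + math.sqrt(disc)) / (1.2 * mass)
    f_pk = profile.F0 - a * v_to
    surplus = f_pk - weight
    if surplus <= 0:  # pragma: no cover - guarded by feasibility above
        raise InfeasibleVelocityError("push-off cannot overcome system weight")
    t_con = math.sqrt(travel * mass / (0.15 * surplus))

    n_con = int(round(t_con * rate))
    uc = np.arange(1, n_con + 1) / n_con
    con = weight + (f_pk - weight) * _smoothstep(uc)
    flight = np.zeros(int(round(flight_s * rate)))

    force = np.concatenate([quiet, ecc, con, flight])
    if noise_sd > 0:
        force = force + rng.normal(0.0, noise_sd, force.size)
    trace = ForceTrace(
        force=force,
        rate=rate,
        body_mass=truth.body_mass,
        added_load=added_load,
        gravity=GRAVITY,
    )
    t0 = n_quiet * dt
    return trace, JumpTruth(
        t_onset=t0,
        t_lowest=t0 + n_ecc * dt,
        t_takeoff=t0 + (n_ecc + n_con) * dt,
        Fmax=f_pk,
        Vmax=v_to,
        Pmax=f_pk * v_to,
        no_takeoff=False,
    )


def simulate_cycling_sprint(
    truth: SubjectTruth,
    flywheel_load: float,
    duration: float = 6.0,
    seed: int | Sequence[int] = 0,
    rate: float = 50.0,
    cadence_cv: float = 0.02,
    load_factor: float = 2.5,
    tau: float = 0.9,
) -> tuple[CyclingRecord, CyclingTruth]:
    """Simulate one friction-braked all-out sprint.

    The resistive pedal force is ``load_factor * flywheel_load * g``;
    pedal velocity rises with time constant ``tau`` toward the plateau
    where the F-V law balances that resistance.  Reported power is
    resistance times (noisy) pedal velocity, so force recovered as P/V is
    exact.
    """
    profile = truth.profiles["cycling"]
    rng = np.random.default_rng(seed)
    f_res = load_factor * flywheel_load * GRAVITY
    if f_res >= profile.F0:
        raise InfeasibleVelocityError(
            f"resistive force {f_res:.0f} N exceeds the profile's F0 {profile.F0:.0f} N"
        )
    v_plateau = (profile.F0 - f_res) / profile.slope_a

    time = np.arange(0.0, duration + 0.5 / rate, 1.0 / rate)
    v = v_plateau * (1.0 - np.exp(-time / tau))
    if cadence_cv > 0:
        v = v * (1.0 + cadence_cv * rng.standard_normal(v.size))
        v = np.maximum(v, 0.0)
    cadence = v * 60.0 / (2.0 * math.pi * truth.crank_length)
    power = f_res * v
    record = CyclingRecord(
        time=time,
        power=power,
        cadence=cadence,
        flywheel_load=flywheel_load,
        crank_length=truth.crank_length,
    )
    v_end = v_plateau * (1.0 - math.exp(-duration / tau))
    return record, CyclingTruth(
        F_plateau=f_res,
        v_plateau=v_end,
        Pmax=f_res * v_end,
        peak_cadence=v_end * 60.0 / (2.0 * math.pi * truth.crank_length),
    )


def simulate_isokinetic_trial(
    truth: SubjectTruth,
    omega: float,
    noise_sd: float = 8.0,
    seed: int | Sequence[int] = 0,
    rate: float = 500.0,
    lead_s: float = 0.25,
    rise_s: float = 0.3,
    plateau_s: float = 1.0,
    fall_s: float = 0.3,
    tail_s: float = 0.25,
) -> tuple[IsokineticTrace, IsokineticTruth]:
    """Simulate one isokinetic knee-extension force-time curve."""
    profile = truth.profiles["isokinetic"]
    rng = np.random.default_rng(seed)
    v_lin = angular_to_linear(omega, truth.lever_arm)
    f_plateau = predict_force(profile, v_lin)
    if f_plateau <= 0:
        raise InfeasibleVelocityError(
            f"{omega:g} deg/s maps to {v_lin:.3f} m/s, at or beyond V0 = {profile.V0:.3f} m/s"
        )
    n = lambda s: int(round(s * rate))
    rise = f_plateau * _smoothstep(np.arange(1, n(rise_s) + 1) / n(rise_s))
    fall = f_plateau * _smoothstep(np.arange(n(fall_s), 0, -1) / n(fall_s))
    force = np.concatenate(
        [
            np.zeros(n(lead_s)),
            rise,
            np.full(n(plateau_s), f_plateau),
            fall,
            np.zeros(n(tail_s)),
        ]
    )
    if noise_sd > 0:
        force = force + rng.normal(0.0, noise_sd, force.size)
    trace = IsokineticTrace(
        force=force,
        angular_velocity=omega,
        lever_arm=truth.lever_arm,
        rate=rate,
    )
    return trace, IsokineticTruth(
        F_plateau=f_plateau, v_linear=v_lin, Pmax=f_plateau * v_lin
    )


# ---------------------------------------------------------------------------
# Cohort generation


@dataclass(frozen=True)
class CohortConfig:
    """Configuration of a synthetic cohort.

    Between-subject truth is log-normal: per-test log F0 (and log V0)
    vectors are drawn with equicorrelated correlation matrices whose
    coefficients are chosen to hit the requested between-test correlation
    targets of log F0 and log P0.
    """

    n_subjects: int = 12
    seed: int = 0
    body_mass_mean: float = 67.4
    body_mass_sd: float = 6.2
    corr_F0: float = 0.5
    corr_P0: float = 0.6
    cv_F0: float = 0.15
    cv_V0: float = 0.15
    F0_means: Mapping[str, float] = field(
        default_factory=lambda: {"jump": 2300.0, "cycling": 900.0, "isokinetic": 700.0}
    )
    V0_means: Mapping[str, float] = field(
        default_factory=lambda: {"jump": 3.0, "cycling": 2.2, "isokinetic": 2.0}
    )
    jump_loads: tuple[float, ...] = (1.0, 24.0)
    jump_standard_load: float = 1.0
    cycling_loads: tuple[float, ...] = (2.0, 10.0)
    cycling_standard_load: float = 6.0
    iso_omegas: tuple[float, ...] = (60.0, 180.0)
    trials_per_condition: int = 1
    jump_noise_sd: float = 5.0
    cadence_cv: float = 0.02
    iso_noise_sd: float = 8.0
    jump_rate: float = 1000.0
    cycling_rate: float = 50.0
    iso_rate: float = 500.0


@dataclass(frozen=True)
class TrialRecord:
    subject_id: str
    test: str
    condition_label: str
    load: float  # kg for jump/cycling, deg/s for isokinetic
    standard: bool
    trial_index: int
    data: object  # ForceTrace | CyclingRecord | IsokineticTrace
    truth: object


@dataclass(frozen=True)
class Cohort:
    config: CohortConfig
    subjects: tuple[SubjectTruth, ...]
    trials: tuple[TrialRecord, ...]


def _equicorr_cholesky(rho: float, dim: int) -> np.ndarray:
    if not -1.0 <= rho <= 1.0:
        raise ConfigurationError(f"correlation {rho!r} outside [-1, 1]")
    matrix = np.full((dim, dim), rho)
    np.fill_diagonal(matrix, 1.0)
    try:
        return np.linalg.cholesky(matrix)
    except np.linalg.LinAlgError as exc:
        raise ConfigurationError(
            f"equicorrelation {rho} is not positive semi-definite for {dim} tests"
        ) from exc


def _v0_correlation(config: CohortConfig) -> float:
    """Equicorrelation of log V0 implied by the F0 and P0 targets.

    With log F0 and log V0 independent, ``corr(log P0) = (rho_F s_F^2 +
    rho_V s_V^2) / (s_F^2 + s_V^2)``; invert for rho_V.
    """
    s_f2 = math.log(1.0 + config.cv_F0**2)
    s_v2 = math.log(1.0 + config.cv_V0**2)
    rho_v = (config.corr_P0 * (s_f2 + s_v2) - config.corr_F0 * s_f2) / s_v2
    if not -1.0 <= rho_v <= 1.0:
        raise ConfigurationError(
            f"P0 correlation target {config.corr_P0} is unreachable given the F0 "
            f"target {config.corr_F0} (implied V0 correlation {rho_v:.3f})"
        )
    return rho_v


def generate_cohort(config: CohortConfig) -> Cohort:
    """Draw subject truths and simulate every trial of the full protocol.

    All randomness descends from ``config.seed`` through per-subject,
    per-trial seed sequences, so any single trial is independently
    reproducible.
    """
    dim = len(TESTS)
    chol_f = _equicorr_cholesky(config.corr_F0, dim)
    chol_v = _equicorr_cholesky(_v0_correlation(config), dim)
    sigma_f = math.sqrt(math.log(1.0 + config.cv_F0**2))
    sigma_v = math.sqrt(math.log(1.0 + config.cv_V0**2))

    rng = np.random.default_rng([config.seed, 0])
    subjects = []
    for i in range(config.n_subjects):
        body_mass = float(
            np.clip(
                rng.normal(config.body_mass_mean, config.body_mass_sd), 55.0, 80.0
            )
        )
        lever_arm = float(np.clip(rng.normal(0.28, 0.015), 0.24, 0.33))
        z_f = chol_f @ rng.standard_normal(dim)
        z_v = chol_v @ rng.standard_normal(dim)
        profiles = {}
        for k, test in enumerate(TESTS):
            f0 = config.F0_means[test] * math.exp(sigma_f * z_f[k])
            v0 = config.V0_means[test] * math.exp(sigma_v * z_v[k])
            # feasibility screening (the study's participants completed the
            # protocol): jumps must leave the ground under the heaviest
            # load; isokinetic velocities must lie inside the profile
            if test == "jump":
                f0 = max(f0, 1.25 * (body_mass + max(config.jump_loads)) * GRAVITY)
            if test == "isokinetic":
                v_max_device = angular_to_linear(max(config.iso_omegas), lever_arm)
                v0 = max(v0, 1.3 * v_max_device)
            profiles[test] = FVProfile(F0=f0, V0=v0)
        subjects.append(
            SubjectTruth(
                subject_id=f"s{i + 1:03d}",
                body_mass=body_mass,
                lever_arm=lever_arm,
                crank_length=0.17,
                ability=float(z_f.mean()),
                profiles=profiles,
            )
        )

    trials = []
    for i, subject in enumerate(subjects):
        counter = 0
        for load in config.jump_loads:
            for k in range(config.trials_per_condition):
                counter += 1
                trace, truth = simulate_jump_trace(
                    subject,
                    added_load=load,
                    noise_sd=config.jump_noise_sd,
                    seed=[config.seed, 1 + i, counter],
                    rate=config.jump_rate,
                )
                trials.append(
                    TrialRecord(
                        subject_id=subject.subject_id,
                        test="jump",
                        condition_label=f"load {load:g} kg",
                        load=load,
                        standard=load == config.jump_standard_load,
                        trial_index=k,
                        data=trace,
                        truth=truth,
                    )
                )
        cycling_loads = sorted(
            set(config.cycling_loads) | {config.cycling_standard_load}
        )
        for load in cycling_loads:
            counter += 1
            record, truth = simulate_cycling_sprint(
                subject,
                flywheel_load=load,
                seed=[config.seed, 1 + i, counter],
                rate=config.cycling_rate,
                cadence_cv=config.cadence_cv,
            )
            trials.append(
                TrialRecord(
                    subject_id=subject.subject_id,
                    test="cycling",
                    condition_label=f"load {load:g} kg",
                    load=load,
                    standard=load == config.cycling_standard_load,
                    trial_index=0,
                    data=record,
                    truth=truth,
                )
            )
        for omega in config.iso_omegas:
            for k in range(config.trials_per_condition):
                counter += 1
                trace, truth = simulate_isokinetic_trial(
                    subject,
                    omega=omega,
                    noise_sd=config.iso_noise_sd,
                    seed=[config.seed, 1 + i, counter],
                    rate=config.iso_rate,
                )
                trials.append(
                    TrialRecord(
                        subject_id=subject.subject_id,
                        test="isokinetic",
                        condition_label=f"{omega:g} deg/s",
                        load=omega,
                        standard=True,
                        trial_index=k,
                        data=trace,
                        truth=truth,
                    )
                )
    return Cohort(config=config, subjects=tuple(subjects), trials=tuple(trials))
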