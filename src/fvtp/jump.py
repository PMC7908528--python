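"""Countermovement-jump force-plate processing.

The vertical ground-reaction force is low-pass filtered (2nd-order
recursive Butterworth, 10 Hz), movement phases are segmented from the
signal itself, center-of-mass kinematics are obtained by trapezoidal
integration of the net acceleration, and the maxima of force, velocity
and power are taken independently over the concentric phase (lowest
center-of-mass position to takeoff).
"""

from __future__ import annotations

import math
from dataclasses import dataclass, replace
from typing import Sequence

import numpy as np
from scipy import signal
from scipy.integrate import cumulative_trapezoid

from .errors import ConfigurationError, NoMovementError, NoTakeoffError
from .model import TrialMetrics

__all__ = [
    "ForceTrace",
    "JumpPhases",
    "Kinematics",
    "lowpass_jump",
    "quiet_standing_stats",
    "detect_phases",
    "compute_kinematics",
    "extract_jump_metrics",
    "select_best_trial",
]

DEFAULT_CUTOFF_HZ = 10.0
DEFAULT_ONSET_SD = 5.0
DEFAULT_ONSET_FLOOR_N = 10.0
DEFAULT_FLIGHT_THRESHOLD_N = 10.0
DEFAULT_QUIET_WINDOW_S = 1.0


@dataclass(frozen=True)
class ForceTrace:
    """Uniformly sampled vertical ground-reaction force with metadata."""

    force: np.ndarray
    rate: float
    body_mass: float
    added_load: float = 0.0
    gravity: float = 9.81

    def __post_init__(self):
        force = np.asarray(self.force, dtype=float)
        object.__setattr__(self, "force", force)
        if self.rate <= 0:
            raise ValueError(f"sampling rate must be positive, got {self.rate!r}")
        if not np.all(np.isfinite(force)):
            raise ValueError("force samples must be finite")

    @property
    def n(self) -> int:
        return self.force.size

    @property
    def time(self) -> np.ndarray:
        return np.arange(self.n) / self.rate

    @property
    def system_mass(self) -> float:
        """Nominal moving mass from metadata (body + added load)."""
        return self.body_mass + self.added_load


@dataclass(frozen=True)
class JumpPhases:
    onset_index: int
    lowest_com_index: int
    takeoff_index: int
    system_weight: float = math.nan  # quiet-standing estimate, N
    quiet_sd: float = math.nan

    def __post_init__(self):
        if not self.onset_index < self.lowest_com_index < self.takeoff_index:
            raise ValueError(
                "phase indices must satisfy onset < lowest_com < takeoff, got "
                f"{self.onset_index}, {self.lowest_com_index}, {self.takeoff_index}"
            )


@dataclass(frozen=True)
class Kinematics:
    """Full-length series; zero before the integration onset."""

    velocity: np.ndarray
    position: np.ndarray
    power: np.ndarray
    acceleration: np.ndarray
    mass: float


def lowpass_jump(trace: ForceTrace, cutoff_hz: float = DEFAULT_CUTOFF_HZ) -> ForceTrace:
    """Causal single-pass 2nd-order Butterworth low-pass filter.

    The filter state is initialized to the steady-state response of the
    first sample, so a trace that starts in quiet standing has no startup
    transient.
    """
    nyquist = trace.rate / 2.0
    if cutoff_hz >= nyquist:
        raise ConfigurationError(
            f"cutoff {cutoff_hz} Hz must lie below the Nyquist frequency {nyquist} Hz"
        )
    b, a = signal.butter(2, cutoff_hz / nyquist, btype="low")
    zi = signal.lfilter_zi(b, a) * trace.force[0]
    filtered, _ = signal.lfilter(b, a, trace.force, zi=zi)
    return replace(trace, force=filtered)


def quiet_standing_stats(
    trace: ForceTrace, window_s: float = DEFAULT_QUIET_WINDOW_S
) -> tuple[float, float]:
    """Mean and SD of the pre-movement quiet-standing segment (first second)."""
    n = int(round(window_s * trace.rate))
    if n < 2 or n > trace.n:
        raise ValueError("trace too short for the quiet-standing window")
    segment = trace.force[:n]
    return float(segment.mean()), float(segment.std(ddof=1))


def detect_phases(
    trace: ForceTrace,
    onset_sd: float = DEFAULT_ONSET_SD,
    onset_floor_n: float = DEFAULT_ONSET_FLOOR_N,
    flight_threshold_n: float = DEFAULT_FLIGHT_THRESHOLD_N,
    quiet_window_s: float = DEFAULT_QUIET_WINDOW_S,
) -> JumpPhases:
    """Segment a (filtered) trace into onset, lowest-COM and takeoff indices.

    Onset is the first sample where |F - system weight| exceeds
    ``max(onset_sd * quiet SD, onset_floor_n)``, backtracked to the last
    sample within one quiet SD of the weight.  Takeoff is the first
    subsequent sample below the flight threshold.  The lowest
    center-of-mass position is located by double integration between the
    two.
    """
    weight, sd = quiet_standing_stats(trace, quiet_window_s)
    deviation = np.abs(trace.force - weight)
    threshold = max(onset_sd * sd, onset_floor_n)

    start = int(round(quiet_window_s * trace.rate))
    crossings = np.flatnonzero(deviation[start:] > threshold)
    if crossings.size == 0:
        raise NoMovementError(
            f"|F - {weight:.1f} N| never exceeds the onset threshold {threshold:.1f} N"
        )
    first_cross = start + int(crossings[0])

    # backtrack to the last sample still within one quiet SD of the weight
    quiet_band = max(sd, 1e-12)
    before = np.flatnonzero(deviation[:first_cross] <= quiet_band)
    onset = int(before[-1]) if before.size else first_cross

    below = np.flatnonzero(trace.force[first_cross:] < flight_threshold_n)
    if below.size == 0:
        raise NoTakeoffError(
            f"force never drops below the flight threshold {flight_threshold_n:.1f} N"
        )
    takeoff = first_cross + int(below[0])

    mass = weight / trace.gravity
    accel = (trace.force[onset : takeoff + 1] - weight) / mass
    vel = cumulative_trapezoid(accel, dx=1.0 / trace.rate, initial=0.0)
    pos = cumulative_trapezoid(vel, dx=1.0 / trace.rate, initial=0.0)
    lowest = onset + int(np.argmin(pos))
    if not onset < lowest < takeoff:
        raise NoMovementError(
            "no countermovement minimum found between onset and takeoff"
        )
    return JumpPhases(
        onset_index=onset,
        lowest_com_index=lowest,
        takeoff_index=takeoff,
        system_weight=weight,
        quiet_sd=sd,
    )


def compute_kinematics(
    trace: ForceTrace, phases: JumpPhases, mass: float | None = None
) -> Kinematics:
    """Integrate net acceleration from onset (v(onset) = 0).

    ``mass`` defaults to the trace metadata (body mass + added load); the
    extraction pipeline instead passes the quiet-standing estimate
    ``system_weight / g`` so the kinematics are self-consistent with the
    recorded signal.
    """
    if mass is None:
        mass = trace.system_mass
    accel = (trace.force - mass * trace.gravity) / mass
    onset = phases.onset_index
    velocity = np.zeros(trace.n)
    position = np.zeros(trace.n)
    dt = 1.0 / trace.rate
    velocity[onset:] = cumulative_trapezoid(accel[onset:], dx=dt, initial=0.0)
    position[onset:] = cumulative_trapezoid(velocity[onset:], dx=dt, initial=0.0)
    power = trace.force * velocity
    return Kinematics(
        velocity=velocity,
        position=position,
        power=power,
        acceleration=accel,
        mass=float(mass),
    )


def extract_jump_metrics(
    trace: ForceTrace,
    cutoff_hz: float = DEFAULT_CUTOFF_HZ,
    onset_sd: float = DEFAULT_ONSET_SD,
    onset_floor_n: float = DEFAULT_ONSET_FLOOR_N,
    flight_threshold_n: float = DEFAULT_FLIGHT_THRESHOLD_N,
    condition_label: str | None = None,
) -> TrialMetrics:
    """Filter, segment and integrate one trial; return concentric maxima.

    Fmax, Vmax and Pmax are each the independent maximum of the
    corresponding series over the concentric window [lowest COM, takeoff];
    they need not occur at the same sample.
    """
    filtered = lowpass_jump(trace, cutoff_hz)
    phases = detect_phases(
        filtered,
        onset_sd=onset_sd,
        onset_floor_n=onset_floor_n,
        flight_threshold_n=flight_threshold_n,
    )
    kin = compute_kinematics(filtered, phases, mass=phases.system_weight / trace.gravity)
    lo, hi = phases.lowest_com_index, phases.takeoff_index + 1
    label = (
        condition_label
        if condition_label is not None
        else f"load {trace.added_load:g} kg"
    )
    return TrialMetrics(
        Fmax=float(filtered.force[lo:hi].max()),
        Vmax=float(kin.velocity[lo:hi].max()),
        Pmax=float(kin.power[lo:hi].max()),
        condition_label=label,
    )


def select_best_trial(metrics_list: Sequence[TrialMetrics]) -> TrialMetrics:
    """Trial with the highest peak power; ties go to the first occurrence."""
    metrics_list = list(metrics_list)
    if not metrics_list:
        raise ValueError("metrics_list must be non-empty")
    best = metrics_list[0]
    for m in metrics_list[1:]:
        if m.Pmax > best.Pmax:
            best = m
    return best
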