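"""Isokinetic knee-extension trial processing.

Force-time curves are zero-phase filtered (2nd-order Butterworth, 5 Hz,
forward-backward), the peak force is located away from the dynamometer's
acceleration/deceleration windows, and the device's constant angular
velocity is converted to a linear velocity via the individual lever arm.
"""

from __future__ import annotations

import math
from dataclasses import dataclass, replace

import numpy as np
from scipy import signal

from .errors import ConfigurationError
from .model import TrialMetrics

__all__ = [
    "IsokineticTrace",
    "zero_phase_lowpass",
    "angular_to_linear",
    "extract_isokinetic_metrics",
]

DEFAULT_CUTOFF_HZ = 5.0
DEFAULT_RATE_HZ = 500.0
DEFAULT_EXCLUSION_FRACTION = 0.1


@dataclass(frozen=True)
class IsokineticTrace:
    """Force samples recorded at constant angular velocity."""

    force: np.ndarray
    angular_velocity: float  # deg/s
    lever_arm: float  # m
    rate: float = DEFAULT_RATE_HZ

    def __post_init__(self):
        force = np.asarray(self.force, dtype=float)
        object.__setattr__(self, "force", force)
        if force.size == 0:
            raise ValueError("trace must be non-empty")
        if not np.all(np.isfinite(force)):
            raise ValueError("force samples must be finite")
        if self.angular_velocity <= 0:
            raise ValueError("angular velocity must be positive")
        if not 0.15 < self.lever_arm < 0.6:
            raise ValueError(
                f"lever arm {self.lever_arm!r} m outside the plausible (0.15, 0.6) range"
            )
        if self.rate <= 0:
            raise ValueError("sampling rate must be positive")

    @property
    def n(self) -> int:
        return self.force.size


def zero_phase_lowpass(
    trace: IsokineticTrace, cutoff_hz: float = DEFAULT_CUTOFF_HZ
) -> IsokineticTrace:
    """Forward-backward 2nd-order Butterworth low-pass (zero net phase).

    The trace is reflect-padded by one second at both ends before
    filtering to suppress edge transients, then trimmed back.
    """
    nyquist = trace.rate / 2.0
    if cutoff_hz >= nyquist:
        raise ConfigurationError(
            f"cutoff {cutoff_hz} Hz must lie below the Nyquist frequency {nyquist} Hz"
        )
    b, a = signal.butter(2, cutoff_hz / nyquist, btype="low")
    pad = min(int(round(trace.rate)), trace.n - 1)
    padded = np.pad(trace.force, pad, mode="reflect") if pad > 0 else trace.force
    filtered = signal.filtfilt(b, a, padded, padlen=0)
    if pad > 0:
        filtered = filtered[pad:-pad]
    return replace(trace, force=filtered)


def angular_to_linear(angular_velocity: float, lever_arm: float) -> float:
    """Linear velocity (m/s) at the lever tip from deg/s and lever length."""
    if angular_velocity <= 0 or lever_arm <= 0:
        raise ValueError("angular velocity and lever arm must be positive")
    return math.radians(angular_velocity) * lever_arm


def extract_isokinetic_metrics(
    trace: IsokineticTrace,
    cutoff_hz: float = DEFAULT_CUTOFF_HZ,
    exclusion_fraction: float = DEFAULT_EXCLUSION_FRACTION,
    condition_label: str | None = None,
) -> TrialMetrics:
    """Peak filtered force at the device's constant linear velocity.

    The first and last ``exclusion_fraction`` of the samples are excluded
    from the peak search (the dynamometer accelerates/decelerates there,
    so constant velocity does not hold).
    """
    if not 0 <= exclusion_fraction < 0.5:
        raise ConfigurationError("exclusion_fraction must lie in [0, 0.5)")
    filtered = zero_phase_lowpass(trace, cutoff_hz)
    skip = int(filtered.n * exclusion_fraction)
    window = filtered.force[skip : filtered.n - skip]
    if window.size == 0:
        raise ValueError("exclusion windows leave no samples to search")
    vmax = angular_to_linear(trace.angular_velocity, trace.lever_arm)
    fmax = float(window.max())
    label = (
        condition_label
        if condition_label is not None
        else f"{trace.angular_velocity:g} deg/s"
    )
    return TrialMetrics(
        Fmax=fmax,
        Vmax=vmax,
        Pmax=fmax * vmax,
        condition_label=label,
    )
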