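"""Maximal cycle-sprint processing.

The ergometer software reports power and pedalling frequency; linear
pedal velocity follows from cadence and crank length, and force is power
divided by velocity.
"""

from __future__ import annotations

import math
from dataclasses import dataclass

import numpy as np

from .errors import UndefinedForceError
from .model import TrialMetrics

__all__ = [
    "CyclingRecord",
    "pedal_velocity",
    "force_from_power",
    "smooth_cadence",
    "extract_cycling_metrics",
]

DEFAULT_CRANK_LENGTH_M = 0.170
DEFAULT_SMOOTH_WINDOW_S = 0.5


@dataclass(frozen=True)
class CyclingRecord:
    """Time-aligned power (W) and cadence (rpm) samples from one sprint."""

    time: np.ndarray
    power: np.ndarray
    cadence: np.ndarray
    flywheel_load: float
    crank_length: float = DEFAULT_CRANK_LENGTH_M

    def __post_init__(self):
        time = np.asarray(self.time, dtype=float)
        power = np.asarray(self.power, dtype=float)
        cadence = np.asarray(self.cadence, dtype=float)
        object.__setattr__(self, "time", time)
        object.__setattr__(self, "power", power)
        object.__setattr__(self, "cadence", cadence)
        if not (time.size == power.size == cadence.size):
            raise ValueError("time, power and cadence must have equal lengths")
        if time.size == 0:
            raise ValueError("record must be non-empty")
        if np.any(power < 0):
            raise ValueError("power must be non-negative")
        if np.any(cadence < 0):
            raise ValueError("cadence must be non-negative")
        if not 0.1 < self.crank_length < 0.25:
            raise ValueError(
                f"crank length {self.crank_length!r} m outside the plausible (0.1, 0.25) range"
            )


def pedal_velocity(cadence, crank_length: float = DEFAULT_CRANK_LENGTH_M):
    """Linear pedal velocity (m/s) from cadence (rev/min): ``2*pi*L*f``."""
    cadence = np.asarray(cadence, dtype=float)
    if np.any(cadence < 0):
        raise ValueError("cadence must be non-negative")
    out = 2.0 * math.pi * crank_length * cadence / 60.0
    return float(out) if out.ndim == 0 else out


def force_from_power(power, velocity):
    """Force (N) as power divided by velocity; undefined at v <= 0."""
    power = np.asarray(power, dtype=float)
    velocity = np.asarray(velocity, dtype=float)
    if np.any(velocity <= 0):
        raise UndefinedForceError("force is undefined at non-positive velocity")
    out = power / velocity
    return float(out) if out.ndim == 0 else out


def smooth_cadence(record: CyclingRecord, window_s: float = DEFAULT_SMOOTH_WINDOW_S) -> np.ndarray:
    """Centered moving average of cadence (device cadence is quantized).

    Edge samples average over the part of the window inside the record.
    """
    if window_s <= 0 or record.time.size < 2:
        return record.cadence.copy()
    dt = float(np.median(np.diff(record.time)))
    half = int(round(window_s / dt / 2.0))
    if half < 1:
        return record.cadence.copy()
    kernel = np.ones(2 * half + 1)
    counts = np.convolve(np.ones_like(record.cadence), kernel, mode="same")
    return np.convolve(record.cadence, kernel, mode="same") / counts


def extract_cycling_metrics(
    record: CyclingRecord,
    smooth_window_s: float = DEFAULT_SMOOTH_WINDOW_S,
    condition_label: str | None = None,
) -> TrialMetrics:
    """Peak power, the force at that instant, and peak pedal velocity.

    Fmax is evaluated at the peak-power sample (``max(P/V)`` over the whole
    trace would reward near-zero-velocity start-up samples).  Both the
    global peak velocity (``Vmax``) and the velocity at peak power
    (``extras['V_at_Pmax']``) are reported.
    """
    if not np.any(record.cadence > 0):
        raise UndefinedForceError("cadence is zero throughout the sprint")
    cadence = smooth_cadence(record, smooth_window_s)
    i_peak = int(np.argmax(record.power))
    pmax = float(record.power[i_peak])
    v_at_pmax = pedal_velocity(cadence[i_peak], record.crank_length)
    fmax = force_from_power(pmax, v_at_pmax)
    vmax = pedal_velocity(float(cadence.max()), record.crank_length)
    label = (
        condition_label
        if condition_label is not None
        else f"load {record.flywheel_load:g} kg"
    )
    return TrialMetrics(
        Fmax=fmax,
        Vmax=vmax,
        Pmax=pmax,
        condition_label=label,
        extras={"V_at_Pmax": v_at_pmax},
    )
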