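"""Linear force-velocity model: two-point and least-squares fits.

A maximal-effort test performed under two load conditions yields two
(force, velocity) observations.  The line through them is extrapolated to
its axis intercepts F0 (maximal force) and V0 (maximal velocity); the
parabola ``P(v) = v * (F0 - a*v)`` then peaks at ``P0 = F0*V0/4``.
"""

from __future__ import annotations

import math
import warnings
from dataclasses import dataclass, field
from typing import Iterable, Mapping, Sequence

import numpy as np

from .errors import DegenerateFitError, ExtrapolationWarning, InvalidProfileError

__all__ = [
    "FVPoint",
    "FVProfile",
    "TrialMetrics",
    "fit_two_point",
    "fit_linear",
    "predict_force",
    "apex_power",
    "point_from_metrics",
    "profiles_to_csv",
]

#: Velocity intercept beyond which a profile is flagged as an extreme
#: extrapolation (m/s).  Warning only, never an error.
V0_WARN_LIMIT = 20.0

#: Force intercept warning limit, in multiples of body weight.
F0_WARN_BODYWEIGHTS = 20.0

_GRAVITY = 9.81


@dataclass(frozen=True)
class FVPoint:
    """One (force, velocity) observation from a single load condition."""

    force: float
    velocity: float
    condition_label: str = ""

    def __post_init__(self):
        for name in ("force", "velocity"):
            value = getattr(self, name)
            if not math.isfinite(value) or value <= 0.0:
                raise ValueError(
                    f"{name} must be finite and strictly positive, got {value!r}"
                )


@dataclass(frozen=True)
class FVProfile:
    """Parameters of a linear force-velocity relationship.

    ``slope_a`` is stored as the positive magnitude ``F0 / V0``; the fitted
    regression coefficient of force on velocity is its negation.
    """

    F0: float
    V0: float

    def __post_init__(self):
        if not math.isfinite(self.F0) or self.F0 <= 0.0:
            raise InvalidProfileError(f"F0 must be positive and finite, got {self.F0!r}")
        if not math.isfinite(self.V0) or self.V0 <= 0.0:
            raise InvalidProfileError(f"V0 must be positive and finite, got {self.V0!r}")

    @property
    def slope_a(self) -> float:
        return self.F0 / self.V0

    @property
    def P0(self) -> float:
        return self.F0 * self.V0 / 4.0


@dataclass(frozen=True)
class TrialMetrics:
    """Maximal force, velocity and power extracted from one trial."""

    Fmax: float
    Vmax: float
    Pmax: float
    condition_label: str = ""
    extras: Mapping[str, float] = field(default_factory=dict)

    def __post_init__(self):
        for name in ("Fmax", "Vmax", "Pmax"):
            if not math.isfinite(getattr(self, name)):
                raise ValueError(f"{name} must be finite")
        # power cannot exceed the product of the two independent maxima
        bound = self.Fmax * self.Vmax
        if self.Pmax > bound * (1.0 + 1e-9) + 1e-9:
            raise ValueError(
                f"Pmax={self.Pmax} exceeds Fmax*Vmax={bound}; inconsistent metrics"
            )


def point_from_metrics(metrics: TrialMetrics) -> FVPoint:
    """Turn one trial's maxima into a model observation."""
    return FVPoint(
        force=metrics.Fmax,
        velocity=metrics.Vmax,
        condition_label=metrics.condition_label,
    )


def _profile_from_line(intercept: float, slope: float, body_mass: float | None) -> FVProfile:
    if slope >= 0.0:
        raise InvalidProfileError(
            f"force-on-velocity slope must be strictly negative, got {slope!r}"
        )
    if intercept <= 0.0:
        raise InvalidProfileError(
            f"force intercept must be strictly positive, got {intercept!r}"
        )
    F0 = float(intercept)
    V0 = float(-intercept / slope)
    profile = FVProfile(F0=F0, V0=V0)
    _warn_if_extreme(profile, body_mass)
    return profile


def _warn_if_extreme(profile: FVProfile, body_mass: float | None) -> None:
    if profile.V0 > V0_WARN_LIMIT:
        warnings.warn(
            f"V0 = {profile.V0:.2f} m/s is far beyond physiological range; "
            "the two conditions may be too close together",
            ExtrapolationWarning,
            stacklevel=3,
        )
    if body_mass is not None and profile.F0 > F0_WARN_BODYWEIGHTS * body_mass * _GRAVITY:
        warnings.warn(
            f"F0 = {profile.F0:.0f} N exceeds {F0_WARN_BODYWEIGHTS:g} body weights",
            ExtrapolationWarning,
            stacklevel=3,
        )


def fit_two_point(p1: FVPoint, p2: FVPoint, body_mass: float | None = None) -> FVProfile:
    """Fit the force-velocity line through exactly two observations.

    Parameters
    ----------
    p1, p2
        Observations from two distinct load conditions.
    body_mass
        Optional body mass (kg) used only to flag implausibly large F0.

    Raises
    ------
    DegenerateFitError
        If the two velocities coincide.
    InvalidProfileError
        If the line has non-negative slope or non-positive intercept.
    """
    dv = p2.velocity - p1.velocity
    if dv == 0.0:
        raise DegenerateFitError(
            f"equal velocities ({p1.velocity} m/s): two-point fit is degenerate"
        )
    slope = (p2.force - p1.force) / dv
    intercept = p1.force - slope * p1.velocity
    return _profile_from_line(intercept, slope, body_mass)


def fit_linear(points: Sequence[FVPoint], body_mass: float | None = None) -> FVProfile:
    """Ordinary least-squares force-on-velocity line through >= 2 observations.

    For ``n == 2`` this reduces (bit-for-bit in exact arithmetic) to
    :func:`fit_two_point`; for larger n a numerically stable linear solve
    is used.
    """
    points = list(points)
    if len(points) < 2:
        raise DegenerateFitError("at least two observations are required")
    v = np.array([p.velocity for p in points], dtype=float)
    f = np.array([p.force for p in points], dtype=float)
    if np.unique(v).size < 2:
        raise DegenerateFitError("at least two distinct velocities are required")
    if len(points) == 2:
        return fit_two_point(points[0], points[1], body_mass=body_mass)
    design = np.column_stack([np.ones_like(v), v])
    coef, *_ = np.linalg.lstsq(design, f, rcond=None)
    intercept, slope = float(coef[0]), float(coef[1])
    return _profile_from_line(intercept, slope, body_mass)


def predict_force(profile: FVProfile, velocity: float):
    """Evaluate the line ``F0 - a*v``; may be negative beyond V0."""
    velocity = np.asarray(velocity, dtype=float)
    if np.any(velocity < 0.0):
        raise ValueError("velocity must be non-negative")
    out = profile.F0 - profile.slope_a * velocity
    return float(out) if out.ndim == 0 else out


def apex_power(profile: FVProfile) -> tuple[float, float]:
    """Velocity and value of the maximum of ``v * predict_force(v)``.

    The power-velocity parabola peaks at ``V0/2`` with value ``F0*V0/4``.
    """
    return profile.V0 / 2.0, profile.P0


def profiles_to_csv(rows: Iterable[tuple[str, str, FVProfile]], path) -> None:
    """Serialize ``(subject_id, test, profile)`` rows to CSV."""
    import pandas as pd

    records = [
        {
            "subject_id": sid,
            "test": test,
            "F0_N": prof.F0,
            "V0_mps": prof.V0,
            "slope_Nspm": prof.slope_a,
            "P0_W": prof.P0,
        }
        for sid, test, prof in rows
    ]
    pd.DataFrame.from_records(
        records, columns=["subject_id", "test", "F0_N", "V0_mps", "slope_Nspm", "P0_W"]
    ).to_csv(path, index=False)
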