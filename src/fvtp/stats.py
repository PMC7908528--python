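"""Validity and generalizability statistics.

Pearson correlations with Fisher-z 95% confidence intervals, dependent-
samples t tests, Shapiro-Wilk normality screening, magnitude-averaged
correlations, and assembly of the cross-test comparison tables.
"""

from __future__ import annotations

import math
from dataclasses import dataclass
from typing import Mapping, Sequence

import numpy as np
import pandas as pd
from scipy import stats as sstats

from .errors import AlignmentError, UndefinedCorrelationError
from .model import FVProfile

__all__ = [
    "CorrelationResult",
    "PairedComparison",
    "ComparisonReport",
    "pearson",
    "fisher_ci",
    "paired_t",
    "shapiro_wilk",
    "average_correlations",
    "significance_stars",
    "build_comparison_table",
]


@dataclass(frozen=True)
class CorrelationResult:
    r: float
    n: int
    ci_low: float
    ci_high: float
    p: float

    @property
    def stars(self) -> str:
        return significance_stars(self.p)


@dataclass(frozen=True)
class PairedComparison:
    mean_diff: float
    t: float
    df: int
    p: float

    @property
    def stars(self) -> str:
        return significance_stars(self.p)


def significance_stars(p: float, one: float = 0.05, two: float = 0.01) -> str:
    if p < two:
        return "**"
    if p < one:
        return "*"
    return ""


def fisher_ci(r: float, n: int, level: float = 0.95) -> tuple[float, float]:
    """Fisher-z confidence interval for a Pearson correlation.

    ``atanh(r) +/- z_crit / sqrt(n - 3)``, back-transformed with tanh.
    """
    if n < 4:
        raise ValueError(f"n must be at least 4, got {n}")
    if not 0 < level < 1:
        raise ValueError("level must lie in (0, 1)")
    if abs(r) >= 1.0:
        raise UndefinedCorrelationError(
            f"|r| = {abs(r)} >= 1: the Fisher interval is degenerate"
        )
    z = math.atanh(r)
    half = sstats.norm.ppf(0.5 + level / 2.0) / math.sqrt(n - 3)
    return math.tanh(z - half), math.tanh(z + half)


def pearson(x, y, level: float = 0.95) -> CorrelationResult:
    """Product-moment correlation with t-based p-value and Fisher-z CI."""
    x = np.asarray(x, dtype=float)
    y = np.asarray(y, dtype=float)
    if x.shape != y.shape or x.ndim != 1:
        raise ValueError("x and y must be 1-D vectors of equal length")
    n = x.size
    if n < 4:
        raise ValueError(f"at least 4 paired observations are required, got {n}")
    sx = x - x.mean()
    sy = y - y.mean()
    denom = math.sqrt(float(sx @ sx) * float(sy @ sy))
    if denom == 0.0:
        raise UndefinedCorrelationError("zero variance in one of the inputs")
    r = float(sx @ sy) / denom
    r = max(-1.0, min(1.0, r))
    if abs(r) == 1.0:
        p = 0.0
        lo, hi = r, r
    else:
        t = r * math.sqrt(n - 2) / math.sqrt(1.0 - r * r)
        p = 2.0 * float(sstats.t.sf(abs(t), n - 2))
        lo, hi = fisher_ci(r, n, level)
    return CorrelationResult(r=r, n=n, ci_low=lo, ci_high=hi, p=p)


def paired_t(x, y) -> PairedComparison:
    """Student's t test for dependent samples (x - y), two-sided."""
    x = np.asarray(x, dtype=float)
    y = np.asarray(y, dtype=float)
    if x.shape != y.shape or x.ndim != 1:
        raise ValueError("x and y must be 1-D vectors of equal length")
    n = x.size
    if n < 2:
        raise ValueError("at least 2 pairs are required")
    d = x - y
    sd = float(d.std(ddof=1))
    if sd == 0.0:
        raise UndefinedCorrelationError("zero variance of the paired differences")
    t = float(d.mean()) / (sd / math.sqrt(n))
    p = 2.0 * float(sstats.t.sf(abs(t), n - 1))
    return PairedComparison(mean_diff=float(d.mean()), t=t, df=n - 1, p=p)


def shapiro_wilk(x) -> tuple[float, float]:
    """Shapiro-Wilk W and approximate p (standard published approximation)."""
    x = np.asarray(x, dtype=float)
    if not 3 <= x.size <= 5000:
        raise ValueError(f"Shapiro-Wilk requires 3 <= n <= 5000, got {x.size}")
    if np.ptp(x) == 0.0:
        raise UndefinedCorrelationError("constant vector: W is undefined")
    res = sstats.shapiro(x)
    return float(res.statistic), float(res.pvalue)


def average_correlations(rs: Sequence[float], use_magnitude: bool = True) -> float:
    """Arithmetic mean of correlation coefficients (magnitudes by default)."""
    rs = np.asarray(list(rs), dtype=float)
    if rs.size == 0:
        raise ValueError("at least one coefficient is required")
    if np.any(np.abs(rs) > 1.0):
        raise ValueError("coefficients must lie in [-1, 1]")
    values = np.abs(rs) if use_magnitude else rs
    return float(values.mean())


# ---------------------------------------------------------------------------
# Table assembly

_VARIABLES = {"F": ("Fmax", "F0"), "P": ("Pmax", "P0")}


@dataclass(frozen=True)
class ComparisonReport:
    """Cross-test correlation table plus per-test method comparisons."""

    table1: pd.DataFrame
    figure3: pd.DataFrame
    comparisons: pd.DataFrame


def _standard_value(entry, attr: str) -> float:
    if isinstance(entry, Mapping):
        return float(entry[attr])
    return float(getattr(entry, attr))


def _aligned(a: Mapping[str, float], b: Mapping[str, float]) -> tuple[np.ndarray, np.ndarray]:
    common = sorted(set(a) & set(b))
    return (
        np.array([a[s] for s in common], dtype=float),
        np.array([b[s] for s in common], dtype=float),
    )


def build_comparison_table(
    profiles_by_test: Mapping[str, Mapping[str, FVProfile]],
    standard_metrics_by_test: Mapping[str, Mapping[str, object]],
    allow_pairwise: bool = False,
    level: float = 0.95,
) -> ComparisonReport:
    """Assemble the generalizability and validity outputs.

    Parameters
    ----------
    profiles_by_test
        ``{test: {subject_id: FVProfile}}`` two-point profiles.
    standard_metrics_by_test
        ``{test: {subject_id: {"Fmax": ..., "Pmax": ...}}}`` (mappings or
        objects with those attributes).
    allow_pairwise
        If False (default) every subject must appear in every test;
        otherwise each statistic uses the pairwise-complete subjects and
        reports its own n.
    """
    tests = list(profiles_by_test)
    if set(standard_metrics_by_test) != set(tests):
        raise AlignmentError(
            "profiles and standard metrics cover different tests: "
            f"{sorted(profiles_by_test)} vs {sorted(standard_metrics_by_test)}"
        )
    if not allow_pairwise:
        all_ids = set().union(*(set(v) for v in profiles_by_test.values()))
        all_ids |= set().union(*(set(v) for v in standard_metrics_by_test.values()))
        missing = {}
        for test in tests:
            for source, mapping in (
                ("two_point", profiles_by_test[test]),
                ("standard", standard_metrics_by_test[test]),
            ):
                absent = sorted(all_ids - set(mapping))
                if absent:
                    missing[f"{test}/{source}"] = absent
        if missing:
            raise AlignmentError(f"subjects missing from some tests: {missing}", missing)

    # per-test per-variable value maps
    std_vals: dict[str, dict[str, dict[str, float]]] = {}
    tp_vals: dict[str, dict[str, dict[str, float]]] = {}
    for test in tests:
        std_vals[test] = {}
        tp_vals[test] = {}
        for var, (std_attr, tp_attr) in _VARIABLES.items():
            std_vals[test][var] = {
                sid: _standard_value(entry, std_attr)
                for sid, entry in standard_metrics_by_test[test].items()
            }
            tp_vals[test][var] = {
                sid: float(getattr(prof, tp_attr))
                for sid, prof in profiles_by_test[test].items()
            }

    table_rows = []
    for var in _VARIABLES:
        for i in range(len(tests)):
            for j in range(i + 1, len(tests)):
                pair = f"{tests[i]}-{tests[j]}"
                for method, vals in (("standard", std_vals), ("two_point", tp_vals)):
                    x, y = _aligned(vals[tests[i]][var], vals[tests[j]][var])
                    res = pearson(x, y, level)
                    table_rows.append(
                        {
                            "variable": var,
                            "pair": pair,
                            "method": method,
                            "r": res.r,
                            "ci_low": res.ci_low,
                            "ci_high": res.ci_high,
                            "n": res.n,
                            "p": res.p,
                            "stars": res.stars,
                        }
                    )
    table1 = pd.DataFrame(table_rows)

    fig_rows = []
    cmp_rows = []
    for test in tests:
        for var in _VARIABLES:
            std, tp = _aligned(std_vals[test][var], tp_vals[test][var])
            validity = pearson(std, tp, level)
            diff = paired_t(tp, std)
            fig_rows.append(
                {
                    "test": test,
                    "variable": var,
                    "standard_mean": std.mean(),
                    "standard_sd": std.std(ddof=1),
                    "two_point_mean": tp.mean(),
                    "two_point_sd": tp.std(ddof=1),
                    "n": std.size,
                    "r": validity.r,
                    "r_stars": validity.stars,
                    "diff_stars": diff.stars,
                }
            )
            cmp_rows.append(
                {
                    "test": test,
                    "variable": var,
                    "mean_diff": diff.mean_diff,
                    "t": diff.t,
                    "df": diff.df,
                    "p": diff.p,
                    "stars": diff.stars,
                }
            )
    return ComparisonReport(
        table1=table1,
        figure3=pd.DataFrame(fig_rows),
        comparisons=pd.DataFrame(cmp_rows),
    )
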