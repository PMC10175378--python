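"""Environmental vectors, z-score normalisation, Euclidean environmental
distance and percentile risk categories.

The baseline risk model summarises a port's environment as a 4-component
vector ``<Tmax, Tmin, Tavg, S>`` — mean temperature of the warmest month,
mean temperature of the coldest month, annual mean temperature, annual
mean salinity — z-scored against a reference port population.  Risk of
non-indigenous species survival is inversely related to the Euclidean
distance between the source and destination vectors: environmentally
similar port pairs (small distance) are high risk.

The monthly-scale variant keeps the same 4-slot geometry: the single
month's temperature fills all three temperature slots and the month's
salinity fills S.  This makes monthly and annual distances directly
comparable and exactly equal for ports with no seasonality.  A
2-component ``<T, S>`` mode is available for sensitivity checks but is
not the default.
"""

from __future__ import annotations

from dataclasses import dataclass
from typing import Iterable, Literal, Sequence

import numpy as np

from .data_io import MONTHS, PortEnvProfile
from .errors import UsageError, ValidationError

SLOT_NAMES = ("Tmax", "Tmin", "Tavg", "S")

MonthlyVectorMode = Literal["four_slot", "two_component"]

RISK_CATEGORIES = (
    "Very high risk",
    "High risk",
    "Moderate risk",
    "Low risk",
    "Very low risk",
)


# ---------------------------------------------------------------------------
# Raw vectors
# ---------------------------------------------------------------------------


def _shifted_mean(a: np.ndarray) -> float:
    """Arithmetic mean via the provisional-means (shifted) formulation.

    Numerically equivalent to ``a.mean()`` in general, but exact for
    constant input: a port with no seasonality then has an annual mean
    bit-identical to its monthly values, so the monthly and annual
    environmental vectors coincide exactly in that limit.
    """
    return float(a[0] + np.mean(a - a[0]))


def annual_raw_vector(profile: PortEnvProfile) -> np.ndarray:
    """Annual-scale raw vector (Tmax, Tmin, Tavg, S) from a 12-month profile."""
    return np.array(
        [profile.T.max(), profile.T.min(), _shifted_mean(profile.T), _shifted_mean(profile.S)]
    )


def monthly_raw_vector(
    profile: PortEnvProfile, month: int, mode: MonthlyVectorMode = "four_slot"
) -> np.ndarray:
    """Monthly-scale raw vector for one calendar month (1 = January).

    In the default ``four_slot`` mode the month's temperature occupies
    Tmax, Tmin and Tavg; in ``two_component`` mode the vector is just
    (T, S) for that month.
    """
    if month not in MONTHS:
        raise UsageError(f"month must be 1..12, got {month}")
    t = profile.T[month - 1]
    s = profile.S[month - 1]
    if mode == "four_slot":
        return np.array([t, t, t, s])
    if mode == "two_component":
        return np.array([t, s])
    raise UsageError(f"unknown monthly vector mode {mode!r}")


# ---------------------------------------------------------------------------
# Normalisation
# ---------------------------------------------------------------------------


@dataclass(frozen=True)
class NormParams:
    """Per-slot mean and sample standard deviation of the reference set."""

    mean: np.ndarray
    sd: np.ndarray

    def __post_init__(self):
        object.__setattr__(self, "mean", np.asarray(self.mean, dtype=float))
        object.__setattr__(self, "sd", np.asarray(self.sd, dtype=float))
        if np.any(self.sd <= 0):
            bad = [SLOT_NAMES[i] if i < len(SLOT_NAMES) else str(i)
                   for i in np.nonzero(self.sd <= 0)[0]]
            raise ValidationError(
                f"degenerate normalisation: zero variance in slot(s) {bad}"
            )

    def normalize(self, raw: np.ndarray) -> np.ndarray:
        return (np.asarray(raw, dtype=float) - self.mean) / self.sd


def fit_norm_params(raw_vectors: Iterable[np.ndarray]) -> NormParams:
    """Fit z-score parameters on a reference population of raw vectors.

    For the annual scale the population is one vector per reference port;
    for the monthly scale it is the pooled 12 x n_ports monthly vectors, so
    a single shared scaling applies to every month.  Sample (n-1) standard
    deviations are used.
    """
    arr = np.asarray(list(raw_vectors), dtype=float)
    if arr.ndim != 2 or arr.shape[0] < 2:
        raise UsageError("need at least two raw vectors to fit normalisation")
    return NormParams(mean=arr.mean(axis=0), sd=arr.std(axis=0, ddof=1))


def fit_annual_norm(profiles: Sequence[PortEnvProfile]) -> NormParams:
    return fit_norm_params(annual_raw_vector(p) for p in profiles)


def fit_monthly_norm(
    profiles: Sequence[PortEnvProfile], mode: MonthlyVectorMode = "four_slot"
) -> NormParams:
    return fit_norm_params(
        monthly_raw_vector(p, m, mode) for p in profiles for m in MONTHS
    )


# ---------------------------------------------------------------------------
# Distance
# ---------------------------------------------------------------------------


def env_distance(v_s: np.ndarray, v_d: np.ndarray) -> float:
    """Euclidean environmental distance between two normalised vectors."""
    v_s = np.asarray(v_s, dtype=float)
    v_d = np.asarray(v_d, dtype=float)
    if v_s.shape != v_d.shape:
        raise UsageError(f"vector shapes differ: {v_s.shape} vs {v_d.shape}")
    return float(np.sqrt(np.sum((v_s - v_d) ** 2)))


def annual_distance(
    source: PortEnvProfile, dest: PortEnvProfile, norm: NormParams
) -> float:
    return env_distance(
        norm.normalize(annual_raw_vector(source)),
        norm.normalize(annual_raw_vector(dest)),
    )


def monthly_distance(
    source: PortEnvProfile,
    dest: PortEnvProfile,
    source_month: int,
    dest_month: int,
    norm: NormParams,
    mode: MonthlyVectorMode = "four_slot",
) -> float:
    """Monthly-scale distance: source vector at its uptake month, destination
    vector at its discharge month."""
    return env_distance(
        norm.normalize(monthly_raw_vector(source, source_month, mode)),
        norm.normalize(monthly_raw_vector(dest, dest_month, mode)),
    )


# ---------------------------------------------------------------------------
# Risk categories
# ---------------------------------------------------------------------------


@dataclass(frozen=True)
class RiskThresholds:
    """Four ascending distance boundaries splitting port pairs into quintile
    risk classes.

    Defaults are the global calibration of the baseline model: the 20/40/
    60/80th percentiles of environmental distances over all pairwise
    combinations of global ports.
    """

    b20: float = 0.787
    b40: float = 1.500
    b60: float = 2.778
    b80: float = 4.020

    def __post_init__(self):
        bs = (self.b20, self.b40, self.b60, self.b80)
        if any(b < 0 for b in bs):
            raise ValidationError("risk thresholds must be non-negative")
        if not (self.b20 <= self.b40 <= self.b60 <= self.b80):
            raise ValidationError(f"risk thresholds must be ascending, got {bs}")

    def as_tuple(self) -> tuple[float, float, float, float]:
        return (self.b20, self.b40, self.b60, self.b80)


DEFAULT_RISK_THRESHOLDS = RiskThresholds()


def percentile_thresholds(distances) -> RiskThresholds:
    """Calibrate risk thresholds as the 20/40/60/80th percentiles of a
    distance collection (linear interpolation between order statistics)."""
    arr = np.asarray(list(distances), dtype=float)
    if arr.size < 5:
        raise UsageError(f"need at least 5 distances to calibrate, got {arr.size}")
    b20, b40, b60, b80 = np.percentile(arr, [20, 40, 60, 80])
    return RiskThresholds(float(b20), float(b40), float(b60), float(b80))


def risk_category(d: float, thresholds: RiskThresholds = DEFAULT_RISK_THRESHOLDS) -> str:
    """Map a distance to its quintile risk class (lower bound inclusive).

    Smaller distance means a closer environmental match and therefore
    higher risk.
    """
    if d < 0:
        raise UsageError(f"distance must be non-negative, got {d}")
    if d < thresholds.b20:
        return "Very high risk"
    if d < thresholds.b40:
        return "High risk"
    if d < thresholds.b60:
        return "Moderate risk"
    if d < thresholds.b80:
        return "Low risk"
    return "Very low risk"
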