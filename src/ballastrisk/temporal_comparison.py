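"""Monthly-versus-annual comparison of environmental distances.

For every ballast tank record the risk model is run twice — once with
annual-scale vectors and once with monthly-scale vectors (source port at
the uptake month, destination port at the discharge month) — and the
difference

    diff = d_month - d_annual

is the object of study.  Negative differences mean the monthly assessment
sees the port pair as environmentally *closer*, i.e. at higher risk, than
the annual assessment.  Differences are categorised against the 75th and
90th percentiles of the positive and negative sides, averaged per
destination port, and compared region by region with the Wilcoxon
signed-rank test and its effect size r = |z| / sqrt(N).
"""

from __future__ import annotations

import math
from dataclasses import dataclass
from typing import Mapping, Sequence

import numpy as np
import pandas as pd
from scipy import stats

from .data_io import PortEnvProfile, TankRecord
from .env_distance import (
    MonthlyVectorMode,
    NormParams,
    annual_distance,
    monthly_distance,
)
from .errors import UsageError

PAIR_COLUMNS = (
    "tank_id",
    "source_port_id",
    "dest_port_id",
    "dest_coast",
    "year",
    "d_month",
    "d_annual",
    "diff",
)


def pair_distances(
    records: Sequence[TankRecord],
    profiles: Mapping[str, PortEnvProfile],
    annual_norm: NormParams,
    monthly_norm: NormParams,
    mode: MonthlyVectorMode = "four_slot",
    coasts: Mapping[str, str] | None = None,
) -> tuple[pd.DataFrame, list[dict]]:
    """One DistancePair row per tank record whose ports are both profiled.

    Returns the pair table and the list of skipped records (port missing a
    profile, typically because the matcher excluded it).
    """
    coasts = coasts or {}
    rows: list[dict] = []
    skipped: list[dict] = []
    # annual distance depends only on the port pair; cache per route
    annual_cache: dict[tuple[str, str], float] = {}
    monthly_cache: dict[tuple[str, int, str, int], float] = {}
    for rec in records:
        src = profiles.get(rec.source_port_id)
        dst = profiles.get(rec.dest_port_id)
        if src is None or dst is None:
            missing = rec.source_port_id if src is None else rec.dest_port_id
            skipped.append({"tank_id": rec.tank_id, "reason": f"no profile for port {missing!r}"})
            continue
        route = (rec.source_port_id, rec.dest_port_id)
        if route not in annual_cache:
            annual_cache[route] = annual_distance(src, dst, annual_norm)
        mkey = (rec.source_port_id, rec.uptake_month, rec.dest_port_id, rec.discharge_month)
        if mkey not in monthly_cache:
            monthly_cache[mkey] = monthly_distance(
                src, dst, rec.uptake_month, rec.discharge_month, monthly_norm, mode
            )
        d_a = annual_cache[route]
        d_m = monthly_cache[mkey]
        rows.append(
            {
                "tank_id": rec.tank_id,
                "source_port_id": rec.source_port_id,
                "dest_port_id": rec.dest_port_id,
                "dest_coast": coasts.get(rec.dest_port_id, ""),
                "year": rec.year,
                "d_month": d_m,
                "d_annual": d_a,
                "diff": d_m - d_a,
            }
        )
    return pd.DataFrame(rows, columns=list(PAIR_COLUMNS)), skipped


# ---------------------------------------------------------------------------
# Difference categorisation
# ---------------------------------------------------------------------------


@dataclass(frozen=True)
class DiffThresholds:
    """75/90th-percentile cutoffs of the positive and negative difference
    sets.

    Defaults are the published calibration for Canadian ballast discharges
    in 2019-2020.  A side may be ``None`` when the data used for
    calibration had no differences of that sign; categorisation then
    degrades gracefully (that side is never flagged).
    """

    pos75: float | None = 0.835
    pos90: float | None = 1.586
    neg75: float | None = -1.720
    neg90: float | None = -2.248

    def __post_init__(self):
        # equality allowed: degenerate (tiny or constant) calibration sets
        if self.pos75 is not None and self.pos90 is not None:
            if not 0 < self.pos75 <= self.pos90:
                raise UsageError(f"need 0 < pos75 <= pos90, got {self.pos75}, {self.pos90}")
        if self.neg75 is not None and self.neg90 is not None:
            if not self.neg90 <= self.neg75 < 0:
                raise UsageError(f"need neg90 <= neg75 < 0, got {self.neg75}, {self.neg90}")


DEFAULT_DIFF_THRESHOLDS = DiffThresholds()

DIFF_CATEGORIES = ("much lower risk", "lower risk", "higher risk", "much higher risk")


def diff_thresholds_from_data(diffs) -> DiffThresholds:
    """Calibrate difference cutoffs from observed diffs.

    The positive and negative sets are handled separately (zeros belong to
    neither): pos75/pos90 are percentiles of the positives, neg75/neg90 the
    negated percentiles of the negatives' magnitudes.
    """
    arr = np.asarray(list(diffs), dtype=float)
    pos = arr[arr > 0]
    neg = arr[arr < 0]
    pos75 = pos90 = neg75 = neg90 = None
    if pos.size:
        pos75, pos90 = (float(v) for v in np.percentile(pos, [75, 90]))
    if neg.size:
        m75, m90 = np.percentile(np.abs(neg), [75, 90])
        neg75, neg90 = -float(m75), -float(m90)
    return DiffThresholds(pos75=pos75, pos90=pos90, neg75=neg75, neg90=neg90)


def diff_category(diff: float, t: DiffThresholds = DEFAULT_DIFF_THRESHOLDS) -> str | None:
    """Label a monthly-minus-annual difference, or None inside the neutral
    band.

    Boundary values belong to the inner (75-90th percentile) band.
    """
    if t.pos90 is not None and diff > t.pos90:
        return "much lower risk"
    if t.pos75 is not None and t.pos90 is not None and t.pos75 <= diff <= t.pos90:
        return "lower risk"
    if t.neg75 is not None and t.neg90 is not None and t.neg90 <= diff <= t.neg75:
        return "higher risk"
    if t.neg90 is not None and diff < t.neg90:
        return "much higher risk"
    return None


def per_port_average_diff(
    pairs: pd.DataFrame, thresholds: DiffThresholds = DEFAULT_DIFF_THRESHOLDS
) -> pd.DataFrame:
    """Mean difference per destination port, with its category.

    Mirrors the map view of cumulative risk change at recipient ports:
    the mean of all tank diffs discharged at a port is categorised, so a
    port only stands out when its whole discharge mix shifts.
    """
    if pairs.empty:
        raise UsageError("no distance pairs to average")
    out = (
        pairs.groupby("dest_port_id", as_index=False)
        .agg(mean_diff=("diff", "mean"), n_tanks=("diff", "size"))
        .sort_values("dest_port_id", ignore_index=True)
    )
    out["category"] = [
        diff_category(d, thresholds) or "" for d in out["mean_diff"]
    ]
    return out


# ---------------------------------------------------------------------------
# Wilcoxon signed-rank with effect size
# ---------------------------------------------------------------------------


@dataclass
class WilcoxonResult:
    n: int                  # paired records entering the test
    n_nonzero: int          # after dropping zero differences
    p_value: float
    z_statistic: float      # signed: >0 when monthly distances exceed annual
    degenerate: bool = False


def wilcoxon_paired(
    d_month: Sequence[float] | None = None,
    d_annual: Sequence[float] | None = None,
    diffs: Sequence[float] | None = None,
    exact_n_max: int = 25,
) -> WilcoxonResult:
    """Two-sided Wilcoxon signed-rank test of monthly vs annual distances.

    Zero differences are dropped before ranking (signed-rank convention).
    The p-value uses the exact null distribution when the nonzero sample is
    small (<= ``exact_n_max``) and tie-free, and the tie-corrected normal
    approximation otherwise.  The signed z statistic is always computed
    from the rank sum so an effect size is available for either branch.
    """
    if diffs is None:
        if d_month is None or d_annual is None:
            raise UsageError("provide diffs or both d_month and d_annual")
        d_month = np.asarray(d_month, dtype=float)
        d_annual = np.asarray(d_annual, dtype=float)
        if d_month.shape != d_annual.shape:
            raise UsageError("paired samples differ in length")
        diffs = d_month - d_annual
    d = np.asarray(diffs, dtype=float)
    n_total = d.size
    d = d[d != 0]
    n = d.size
    if n == 0:
        return WilcoxonResult(
            n=n_total, n_nonzero=0, p_value=1.0, z_statistic=0.0, degenerate=True
        )

    ranks = stats.rankdata(np.abs(d))
    w_plus = float(ranks[d > 0].sum())
    mu = n * (n + 1) / 4.0
    # tie-corrected variance of W+ under the symmetric null
    _, counts = np.unique(np.abs(d), return_counts=True)
    tie_term = float(np.sum(counts**3 - counts)) / 48.0
    sigma2 = n * (n + 1) * (2 * n + 1) / 24.0 - tie_term
    z = 0.0 if sigma2 <= 0 else (w_plus - mu) / math.sqrt(sigma2)

    has_ties = np.any(counts > 1)
    method = "exact" if (n <= exact_n_max and not has_ties) else "approx"
    res = stats.wilcoxon(d, zero_method="wilcox", correction=False, method=method)
    return WilcoxonResult(
        n=n_total, n_nonzero=n, p_value=float(res.pvalue), z_statistic=z
    )


MAGNITUDE_LABELS = ("small", "moderate", "large")


def effect_size_r(z: float, n: int) -> tuple[float, str]:
    """Wilcoxon effect size r = |z| / sqrt(N) with its magnitude label.

    Bands follow the convention of the standard effect-size tooling:
    r < 0.3 small, 0.3 <= r < 0.5 moderate, r >= 0.5 large.
    """
    if n < 1:
        raise UsageError("need at least one paired record")
    r = abs(z) / math.sqrt(n)
    if r < 0.3:
        mag = "small"
    elif r < 0.5:
        mag = "moderate"
    else:
        mag = "large"
    return r, mag


REGION_RESULT_COLUMNS = (
    "region",
    "year",
    "N",
    "n_nonzero",
    "p_value",
    "z_statistic",
    "r",
    "magnitude",
    "significant",
    "mean_diff",
)


def regional_comparison(
    pairs: pd.DataFrame, alpha: float = 0.05
) -> pd.DataFrame:
    """Wilcoxon test and effect size per (destination region, year).

    Years are processed separately so the stability of the regional pattern
    across years can be judged.  Region-years with no pairs are simply
    absent from the output.
    """
    rows = []
    for (region, year), grp in pairs.groupby(["dest_coast", "year"], sort=True):
        res = wilcoxon_paired(diffs=grp["diff"].to_numpy())
        r, mag = effect_size_r(res.z_statistic, res.n)
        rows.append(
            {
                "region": region,
                "year": int(year),
                "N": res.n,
                "n_nonzero": res.n_nonzero,
                "p_value": res.p_value,
                "z_statistic": res.z_statistic,
                "r": r,
                "magnitude": mag if not res.degenerate else "degenerate",
                "significant": bool(res.p_value < alpha) and not res.degenerate,
                "mean_diff": float(grp["diff"].mean()),
            }
        )
    return pd.DataFrame(rows, columns=list(REGION_RESULT_COLUMNS))


def histogram_table(values, bins: int = 50) -> pd.DataFrame:
    """Density-distribution export: bin edges and counts as a plain table."""
    counts, edges = np.histogram(np.asarray(list(values), dtype=float), bins=bins)
    return pd.DataFrame(
        {"bin_left": edges[:-1], "bin_right": edges[1:], "count": counts}
    )
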