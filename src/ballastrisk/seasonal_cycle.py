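"""Within-year variability: per-port monthly STDEV maps and the
standardised 12-start-month voyage-cycled distance analysis.

The cycled analysis removes the shipping-intensity bias of the tank-level
comparison: replicate tanks are collapsed to unique source-destination
port pairs, each pair gets its mean voyage time tau, and the voyage is
then re-run with departure cycled over the twelve calendar months.  The
standard deviation of the twelve resulting monthly-scale distances
measures how much a route's assessed risk moves through the year; the
top decile of routes by that spread, intersected with high-traffic
routes, identifies the high-intensity/high-variability corridors.
"""

from __future__ import annotations

import datetime as dt
from dataclasses import dataclass
from typing import Mapping, Sequence

import numpy as np
import pandas as pd

from .data_io import MONTHS, PortEnvProfile, TankRecord
from .env_distance import MonthlyVectorMode, NormParams, monthly_distance
from .errors import UsageError

# ---------------------------------------------------------------------------
# Per-port seasonal spread
# ---------------------------------------------------------------------------


@dataclass
class PortEnvStats:
    """Sample standard deviation of a port's 12 monthly values, per variable,
    plus equal-interval bin indices once binned against a cohort."""

    port_id: str
    stdev_T: float
    stdev_S: float
    bin_T: int | None = None
    bin_S: int | None = None


def port_env_stdev(profile: PortEnvProfile) -> PortEnvStats:
    """Seasonal spread of one port's profile (sample sd, n-1)."""
    return PortEnvStats(
        port_id=profile.port_id,
        stdev_T=float(np.std(profile.T, ddof=1)),
        stdev_S=float(np.std(profile.S, ddof=1)),
    )


def equal_interval_bins(values, k: int) -> tuple[np.ndarray, np.ndarray]:
    """Split [min, max] into k bins of identical width.

    Returns (edges, indices): ``edges`` has k+1 entries; ``indices`` maps
    every value to its bin in [0, k-1], with the maximum assigned to the
    top bin (closed upper boundary).  Degenerate input (all values equal)
    collapses to a single effective bin at index 0.
    """
    if k < 1:
        raise UsageError(f"need k >= 1 bins, got {k}")
    arr = np.asarray(list(values), dtype=float)
    lo, hi = float(arr.min()), float(arr.max())
    edges = np.linspace(lo, hi, k + 1)
    if hi == lo:
        return edges, np.zeros(arr.size, dtype=int)
    idx = np.floor((arr - lo) / (hi - lo) * k).astype(int)
    return edges, np.clip(idx, 0, k - 1)


def port_stats_table(
    profiles: Sequence[PortEnvProfile], k_bins: int = 5
) -> pd.DataFrame:
    """STDEV table behind the temperature/salinity variability maps."""
    stats = [port_env_stdev(p) for p in profiles]
    df = pd.DataFrame(
        {
            "port_id": [s.port_id for s in stats],
            "stdev_T": [s.stdev_T for s in stats],
            "stdev_S": [s.stdev_S for s in stats],
        }
    )
    _, df["bin_T"] = equal_interval_bins(df["stdev_T"], k_bins)
    _, df["bin_S"] = equal_interval_bins(df["stdev_S"], k_bins)
    return df


# ---------------------------------------------------------------------------
# Unique port pairs and voyage cycling
# ---------------------------------------------------------------------------


def unique_port_pairs(records: Sequence[TankRecord]) -> pd.DataFrame:
    """Collapse tank records to unique (source, destination) routes.

    Returns one row per route with the tank-connection count ``n_tanks``
    and the mean voyage time ``tau`` in days.
    """
    if not records:
        return pd.DataFrame(columns=["source_port_id", "dest_port_id", "n_tanks", "tau"])
    df = pd.DataFrame(
        {
            "source_port_id": [r.source_port_id for r in records],
            "dest_port_id": [r.dest_port_id for r in records],
            "voyage_days": [r.voyage_days for r in records],
        }
    )
    return (
        df.groupby(["source_port_id", "dest_port_id"], as_index=False)
        .agg(n_tanks=("voyage_days", "size"), tau=("voyage_days", "mean"))
        .sort_values(["source_port_id", "dest_port_id"], ignore_index=True)
    )


def arrival_month(start_month: int, tau: float, anchor_day: int = 1) -> int:
    """Calendar month reached by departing on ``anchor_day`` of
    ``start_month`` and sailing round(tau) days, with year wrap-around."""
    if start_month not in MONTHS:
        raise UsageError(f"month must be 1..12, got {start_month}")
    if tau < 0:
        raise UsageError(f"voyage time must be non-negative, got {tau}")
    # non-leap anchor year; only the month of arrival matters
    depart = dt.date(2001, start_month, anchor_day)
    arrive = depart + dt.timedelta(days=round(tau))
    return arrive.month


def cycle_monthly_distances(
    source: PortEnvProfile,
    dest: PortEnvProfile,
    tau: float,
    monthly_norm: NormParams,
    mode: MonthlyVectorMode = "four_slot",
    anchor_day: int = 1,
) -> np.ndarray:
    """12 monthly-scale distances for one route, departure cycled Jan-Dec.

    For start month m the source vector is taken at m and the destination
    vector at the month reached after a fixed tau-day voyage.
    """
    return np.array(
        [
            monthly_distance(
                source, dest, m, arrival_month(m, tau, anchor_day), monthly_norm, mode
            )
            for m in MONTHS
        ]
    )


PAIR_SUMMARY_COLUMNS = (
    "source_port_id",
    "dest_port_id",
    "source_region",
    "n_tanks",
    "tau",
    *[f"d{m:02d}" for m in MONTHS],
    "stdev_cycle",
    "top_decile",
)


def summarize_port_pairs(
    records: Sequence[TankRecord],
    profiles: Mapping[str, PortEnvProfile],
    monthly_norm: NormParams,
    source_regions: Mapping[str, str] | None = None,
    mode: MonthlyVectorMode = "four_slot",
    anchor_day: int = 1,
) -> pd.DataFrame:
    """Full standardised-analysis table: one row per unique profiled route
    with its 12 cycled distances, their standard deviation, and the
    top-decile flag."""
    source_regions = source_regions or {}
    pairs = unique_port_pairs(records)
    rows = []
    for _, p in pairs.iterrows():
        src = profiles.get(p["source_port_id"])
        dst = profiles.get(p["dest_port_id"])
        if src is None or dst is None:
            continue
        dists = cycle_monthly_distances(src, dst, p["tau"], monthly_norm, mode, anchor_day)
        row = {
            "source_port_id": p["source_port_id"],
            "dest_port_id": p["dest_port_id"],
            "source_region": source_regions.get(p["source_port_id"], ""),
            "n_tanks": int(p["n_tanks"]),
            "tau": float(p["tau"]),
            "stdev_cycle": float(np.std(dists, ddof=1)),
            "top_decile": False,
        }
        row.update({f"d{m:02d}": dists[m - 1] for m in MONTHS})
        rows.append(row)
    df = pd.DataFrame(rows, columns=list(PAIR_SUMMARY_COLUMNS))
    if len(df):
        df = flag_top_decile(df)
    return df


def flag_top_decile(summaries: pd.DataFrame) -> pd.DataFrame:
    """Mark routes whose cycled-distance STDEV reaches the cohort's 90th
    percentile (all routes flagged when every STDEV is identical)."""
    df = summaries.copy()
    p90 = float(np.percentile(df["stdev_cycle"], 90))
    df["top_decile"] = df["stdev_cycle"] >= p90
    return df


def high_intensity_high_variability(
    summaries: pd.DataFrame, min_tanks: int = 250
) -> pd.DataFrame:
    """Routes that are both heavily trafficked and in the top variability
    decile — the corridors deserving management attention."""
    return summaries[
        summaries["top_decile"] & (summaries["n_tanks"] > min_tanks)
    ].reset_index(drop=True)


def region_month_means(summaries: pd.DataFrame) -> pd.DataFrame:
    """Mean cycled distance per (source region, start month), unweighted by
    tank counts (replicate-tank bias is exactly what the standardised
    analysis removes)."""
    cols = [f"d{m:02d}" for m in MONTHS]
    rows = []
    for region, grp in summaries.groupby("source_region", sort=True):
        means = grp[cols].mean(axis=0)
        for m in MONTHS:
            rows.append(
                {
                    "source_region": region,
                    "start_month": m,
                    "mean_distance": float(means[f"d{m:02d}"]),
                    "n_pairs": len(grp),
                }
            )
    return pd.DataFrame(rows, columns=["source_region", "start_month", "mean_distance", "n_pairs"])
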