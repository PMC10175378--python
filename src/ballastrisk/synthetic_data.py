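"""Synthetic ports, seasonal climatology fields and ballast tank traffic.

The generator emulates the statistical structure the analysis assumes so
every stage can run, and be tested against known ground truth, without
external downloads:

* ports span both hemispheres across labelled climate-zone regions;
* sea-surface temperature follows a sinusoidal seasonal cycle whose
  amplitude peaks in the temperate band (largest month-to-month spread
  around ±45 latitude) and whose phase is shifted six months in the
  southern hemisphere (peak month 7 north, month 1 south);
* salinity is near-oceanic (~34) with a fraction of estuary-like ports
  showing a depressed mean and elevated seasonal variance;
* the one-degree grid has an explicit land margin (masking inland ports
  away from data) plus a small random missing fraction per layer;
* tank traffic concentrates on a few high-intensity routes with a heavy
  tail of low-intensity ones, voyages lasting days to weeks, discharges
  spread over two assessment years.

Everything is a pure function of the scenario seed: identical
configuration gives byte-identical outputs.
"""

from __future__ import annotations

import datetime as dt
from dataclasses import dataclass, field
from pathlib import Path
from typing import Mapping, Sequence

import numpy as np
from scipy import stats

from .data_io import (
    MONTHS,
    EnvGridStack,
    GridVariable,
    Port,
    PortEnvProfile,
    PortRegistry,
    TankRecord,
    save_env_grid_long,
    save_ports,
    save_profiles,
    save_tank_records,
)
from .errors import UsageError

#: latitude bands (deg) for the synthetic source regions
DEFAULT_SOURCE_REGIONS: dict[str, tuple[float, float]] = {
    "Northern Europe": (50.0, 65.0),
    "Eastern Asia": (25.0, 45.0),
    "Southern Asia": (5.0, 20.0),
    "Latin America and the Caribbean": (-25.0, 10.0),
    "Australia and New Zealand": (-45.0, -15.0),
}

#: destination coast -> (latitude band, number of ports); the Arctic gets
#: few ports and little traffic, as in real Canadian discharge data
DEFAULT_DEST_COASTS: dict[str, tuple[tuple[float, float], int]] = {
    "Pacific": ((48.0, 54.0), 5),
    "Atlantic": ((44.0, 50.0), 5),
    "Arctic": ((60.0, 69.0), 2),
}


@dataclass
class ScenarioConfig:
    """Knobs of the synthetic world.  Defaults are the study conditions."""

    seed: int = 0
    n_source_ports: int = 48
    source_regions: dict[str, tuple[float, float]] = field(
        default_factory=lambda: dict(DEFAULT_SOURCE_REGIONS)
    )
    dest_coasts: dict[str, tuple[tuple[float, float], int]] = field(
        default_factory=lambda: dict(DEFAULT_DEST_COASTS)
    )
    inland_fraction: float = 0.08   # source ports placed deep in the land margin
    estuary_fraction: float = 0.15  # ports with river-influenced salinity

    # grid geometry: one meridional ocean basin with a land margin east of
    # ocean_lon_max
    resolution: float = 1.0
    lat_range: tuple[float, float] = (-70.0, 70.0)
    lon_range: tuple[float, float] = (-30.0, 10.0)
    ocean_lon_max: float = 0.0
    missing_fraction: float = 0.02
    noise_sd: float = 0.3

    # seasonal temperature model
    base_temp_equator: float = 28.0
    base_temp_pole: float = -2.0
    amp_max: float = 8.0            # deg C, at the temperate-band peak
    amp_peak_lat: float = 45.0
    amp_width: float = 20.0
    peak_month_north: int = 7
    peak_month_south: int = 1

    # salinity model
    sal_mean: float = 34.0
    sal_lat_slope: float = 1.2      # gentle latitudinal gradient
    estuary_sal_drop: float = 3.0
    estuary_amp: float = 2.5        # seasonal salinity amplitude at estuaries

    # traffic model
    n_routes: int = 120
    traffic_tail_alpha: float = 0.9  # pareto tail of tanks-per-route
    traffic_scale: float = 3.0
    max_tanks_per_route: int = 400
    voyage_mean_range: tuple[float, float] = (5.0, 45.0)
    voyage_sd: float = 2.0
    years: tuple[int, int] = (2019, 2020)

    def __post_init__(self):
        if not 0.0 <= self.missing_fraction <= 0.05:
            raise UsageError("missing_fraction must be in [0, 0.05]")
        if self.n_source_ports <= 0 or self.n_routes <= 0:
            raise UsageError("counts must be positive")


def constant_seasonality_config(seed: int = 0, **overrides) -> ScenarioConfig:
    """A degenerate scenario with month-constant profiles: no seasonal
    amplitude, no estuary oscillation, no noise.  In this limit monthly and
    annual environmental vectors coincide for every port."""
    kw = dict(amp_max=0.0, estuary_amp=0.0, noise_sd=0.0, missing_fraction=0.0)
    kw.update(overrides)
    return ScenarioConfig(seed=seed, **kw)


# ---------------------------------------------------------------------------
# Environmental model (shared by grid and ground-truth profiles)
# ---------------------------------------------------------------------------


def _peak_month(lat: float, cfg: ScenarioConfig) -> int:
    return cfg.peak_month_north if lat >= 0 else cfg.peak_month_south


def seasonal_temperature(lat: float, month: int, cfg: ScenarioConfig) -> float:
    """Noise-free temperature at a latitude and month (deg C)."""
    c = np.cos(np.radians(lat)) ** 2
    base = cfg.base_temp_pole + (cfg.base_temp_equator - cfg.base_temp_pole) * c
    amp = cfg.amp_max * np.exp(-(((abs(lat) - cfg.amp_peak_lat) / cfg.amp_width) ** 2))
    phase = 2.0 * np.pi * (month - _peak_month(lat, cfg)) / 12.0
    return float(base + amp * np.cos(phase))


def base_salinity(lat: float, cfg: ScenarioConfig) -> float:
    return cfg.sal_mean + cfg.sal_lat_slope * np.sin(np.radians(lat))


def seasonal_salinity(lat: float, month: int, cfg: ScenarioConfig, estuary: bool) -> float:
    """Noise-free salinity; estuary locations get a depressed mean and a
    seasonal oscillation (river discharge cycle)."""
    s = base_salinity(lat, cfg)
    if estuary:
        phase = 2.0 * np.pi * (month - _peak_month(lat, cfg)) / 12.0
        s = s - cfg.estuary_sal_drop + cfg.estuary_amp * np.cos(phase)
    return float(s)


def true_profile(port: Port, cfg: ScenarioConfig, estuary: bool) -> PortEnvProfile:
    """Ground-truth monthly profile at the port's own coordinates."""
    T = np.array([seasonal_temperature(port.lat, m, cfg) for m in MONTHS])
    S = np.array([seasonal_salinity(port.lat, m, cfg, estuary) for m in MONTHS])
    return PortEnvProfile(
        port_id=port.port_id,
        T=T,
        S=S,
        matched_grid_point=(port.lat, port.lon),
        match_distance_km=0.0,
    )


# ---------------------------------------------------------------------------
# Generators
# ---------------------------------------------------------------------------


def _rng(cfg: ScenarioConfig, stream: int) -> np.random.Generator:
    return np.random.default_rng([cfg.seed, stream])


@dataclass
class ScenarioData:
    """Everything one synthetic world produces."""

    config: ScenarioConfig
    ports: PortRegistry
    stack: EnvGridStack
    truth_profiles: dict[str, PortEnvProfile]
    records: list[TankRecord]
    estuary_ports: set[str]


def generate_ports(cfg: ScenarioConfig) -> tuple[PortRegistry, set[str]]:
    """Source and destination ports, plus the set flagged estuary-like.

    Coastal ports sit within two cells of the synthetic coastline
    (``ocean_lon_max``); an ``inland_fraction`` of source ports is placed
    deep inside the land margin, more than two grid cells from any ocean
    cell, so the matcher's exclusion rule is exercised.
    """
    rng = _rng(cfg, 1)
    ports: list[Port] = []
    estuaries: set[str] = set()
    region_names = sorted(cfg.source_regions)
    n_inland = int(round(cfg.inland_fraction * cfg.n_source_ports))
    for i in range(cfg.n_source_ports):
        region = region_names[i % len(region_names)]
        lo, hi = cfg.source_regions[region]
        lat = float(rng.uniform(lo, hi))
        inland = i < n_inland
        if inland:
            lon = float(rng.uniform(cfg.ocean_lon_max + 7.5, cfg.ocean_lon_max + 9.0))
        else:
            lon = float(rng.uniform(cfg.ocean_lon_max - 2.0, cfg.ocean_lon_max))
        pid = f"S{i:03d}"
        ports.append(
            Port(
                port_id=pid,
                name=f"Source {i}",
                lat=lat,
                lon=lon,
                country="XX",
                region=region,
            )
        )
        if not inland and rng.uniform() < cfg.estuary_fraction:
            estuaries.add(pid)
    k = 0
    for coast in sorted(cfg.dest_coasts):
        (lo, hi), n = cfg.dest_coasts[coast]
        for _ in range(n):
            pid = f"D{k:02d}"
            ports.append(
                Port(
                    port_id=pid,
                    name=f"Destination {k}",
                    lat=float(rng.uniform(lo, hi)),
                    lon=float(rng.uniform(cfg.ocean_lon_max - 2.0, cfg.ocean_lon_max)),
                    country="CA",
                    region="Northern America",
                    coast=coast,
                )
            )
            if rng.uniform() < cfg.estuary_fraction:
                estuaries.add(pid)
            k += 1
    return PortRegistry(ports), estuaries


def generate_env_fields(
    cfg: ScenarioConfig,
    ports: PortRegistry,
    estuary_ports: set[str] | None = None,
) -> tuple[EnvGridStack, dict[str, PortEnvProfile]]:
    """Gridded monthly fields plus ground-truth profiles for oracle tests.

    Grid values are the seasonal model evaluated at each cell centre plus
    independent Gaussian noise; estuary ports imprint their salinity
    signature on their nearest ocean cell.  Land-margin cells are masked in
    every layer; an additional random ``missing_fraction`` of ocean cells
    is masked independently per layer.
    """
    estuary_ports = estuary_ports or set()
    rng = _rng(cfg, 2)
    res = cfg.resolution
    lats = np.arange(cfg.lat_range[0], cfg.lat_range[1] + res / 2, res)
    lons = np.arange(cfg.lon_range[0], cfg.lon_range[1] + res / 2, res)
    ocean = lons <= cfg.ocean_lon_max  # per-column land/sea mask

    T = np.empty((12, lats.size, lons.size))
    S = np.empty((12, lats.size, lons.size))
    for m in MONTHS:
        for i, la in enumerate(lats):
            T[m - 1, i, :] = seasonal_temperature(la, m, cfg)
            S[m - 1, i, :] = seasonal_salinity(la, m, cfg, estuary=False)

    # estuary signature at each estuary port's nearest ocean cell
    ocean_lons = lons[ocean]
    for pid in sorted(estuary_ports):
        p = ports[pid]
        i = int(np.argmin(np.abs(lats - p.lat)))
        j = int(np.argmin(np.abs(lons - ocean_lons[np.argmin(np.abs(ocean_lons - p.lon))])))
        for m in MONTHS:
            S[m - 1, i, j] = seasonal_salinity(p.lat, m, cfg, estuary=True)

    if cfg.noise_sd > 0:
        T += rng.normal(0.0, cfg.noise_sd, T.shape)
        S += rng.normal(0.0, cfg.noise_sd, S.shape)

    T[:, :, ~ocean] = np.nan
    S[:, :, ~ocean] = np.nan
    if cfg.missing_fraction > 0:
        for arr in (T, S):
            for m in range(12):
                gaps = rng.uniform(size=(lats.size, lons.size)) < cfg.missing_fraction
                arr[m][gaps & ocean[np.newaxis, :].repeat(lats.size, 0)] = np.nan

    stack = EnvGridStack(
        temperature=GridVariable("temperature", lats, lons, T),
        salinity=GridVariable("salinity", lats, lons, S),
        resolution=res,
    )
    truth = {
        p.port_id: true_profile(p, cfg, estuary=p.port_id in estuary_ports)
        for p in ports
    }
    return stack, truth


def generate_tank_records(
    cfg: ScenarioConfig, ports: PortRegistry
) -> list[TankRecord]:
    """Ballast tank discharge records on a heavy-tailed route network.

    Routes connect coastal source ports to destination ports; the
    tanks-per-route distribution is Pareto-tailed so a handful of
    high-intensity corridors carry most tanks.  Each route has its own
    mean voyage time; discharge dates are uniform over the assessment
    years and uptake dates follow backwards from the voyage length.
    """
    rng = _rng(cfg, 3)
    sources = [p for p in ports if p.coast is None and p.lon <= cfg.ocean_lon_max]
    dests = [p for p in ports if p.coast is not None]
    if not sources or not dests:
        raise UsageError("need at least one coastal source and one destination port")

    n_routes = min(cfg.n_routes, len(sources) * len(dests))
    all_routes = [(s.port_id, d.port_id) for s in sources for d in dests]
    # Arctic routes down-weighted: most traffic heads to Pacific/Atlantic
    weights = np.array(
        [0.08 if ports[d].coast == "Arctic" else 1.0 for _, d in all_routes]
    )
    idx = rng.choice(len(all_routes), size=n_routes, replace=False, p=weights / weights.sum())
    routes = [all_routes[i] for i in sorted(idx)]

    counts = 1 + (cfg.traffic_scale * rng.pareto(cfg.traffic_tail_alpha, n_routes)).astype(int)
    counts = np.minimum(counts, cfg.max_tanks_per_route)
    route_voyage_mean = rng.uniform(*cfg.voyage_mean_range, n_routes)

    y0, y1 = cfg.years
    span_start = dt.date(y0, 1, 1)
    span_days = (dt.date(y1, 12, 31) - span_start).days
    records: list[TankRecord] = []
    tank_no = 0
    for (src, dst), n_tanks, vmean in zip(routes, counts, route_voyage_mean):
        for _ in range(int(n_tanks)):
            voyage = max(1, int(round(rng.normal(vmean, cfg.voyage_sd))))
            discharge = span_start + dt.timedelta(days=int(rng.integers(0, span_days + 1)))
            uptake = discharge - dt.timedelta(days=voyage)
            records.append(
                TankRecord(
                    tank_id=f"T{tank_no:06d}",
                    source_port_id=src,
                    dest_port_id=dst,
                    uptake_date=uptake,
                    discharge_date=discharge,
                )
            )
            tank_no += 1
    return records


def generate_scenario(cfg: ScenarioConfig | None = None) -> ScenarioData:
    """Run all three generators under one configuration."""
    cfg = cfg or ScenarioConfig()
    ports, estuaries = generate_ports(cfg)
    stack, truth = generate_env_fields(cfg, ports, estuaries)
    records = generate_tank_records(cfg, ports)
    return ScenarioData(
        config=cfg,
        ports=ports,
        stack=stack,
        truth_profiles=truth,
        records=records,
        estuary_ports=estuaries,
    )


def write_scenario(data: ScenarioData, out_dir: str | Path) -> dict[str, Path]:
    """Write the scenario as the pipeline's three input CSVs plus the
    ground-truth profiles (long-form grid dialect for the climatology)."""
    out = Path(out_dir)
    out.mkdir(parents=True, exist_ok=True)
    paths = {
        "ports": out / "ports.csv",
        "grid_temperature": out / "grid_temperature.csv",
        "grid_salinity": out / "grid_salinity.csv",
        "tanks": out / "tank_records.csv",
        "truth_profiles": out / "truth_profiles.csv",
    }
    save_ports(data.ports, paths["ports"])
    save_env_grid_long(data.stack.temperature, paths["grid_temperature"])
    save_env_grid_long(data.stack.salinity, paths["grid_salinity"])
    save_tank_records(data.records, paths["tanks"])
    save_profiles(data.truth_profiles.values(), paths["truth_profiles"])
    return paths


# ---------------------------------------------------------------------------
# Designed-effect paired samples (for power / recovery studies)
# ---------------------------------------------------------------------------


def shift_for_target_r(r: float) -> float:
    """Location shift delta of unit-variance Gaussian paired differences
    whose asymptotic Wilcoxon signed-rank effect size is ``r``.

    For diffs ~ N(delta, 1) the large-sample effect size is
    r = sqrt(3) * (P(d_i + d_j > 0) - 1/2), giving
    delta = Phi^{-1}(r / sqrt(3) + 1/2) / sqrt(2).
    """
    if not 0 <= r < np.sqrt(3) / 2:
        raise UsageError(f"target r must be in [0, sqrt(3)/2), got {r}")
    return float(stats.norm.ppf(r / np.sqrt(3) + 0.5) / np.sqrt(2))


#: class-midpoint effect sizes used when designing recovery studies
DESIGNED_EFFECTS = {"small": 0.15, "moderate": 0.40, "large": 0.70}


def generate_paired_distances_with_shift(
    n: int, delta: float, rng: np.random.Generator
) -> tuple[np.ndarray, np.ndarray]:
    """Paired (annual, monthly) distances whose differences are
    N(-delta, 1): the monthly assessment sees systematically smaller
    distances (higher risk), as observed for most regions."""
    d_annual = np.abs(rng.normal(5.0, 1.0, n))
    diffs = rng.normal(-delta, 1.0, n)
    d_month = np.maximum(d_annual + diffs, 0.0)
    return d_annual, d_month
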