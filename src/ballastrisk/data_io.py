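"""Tabular and gridded input/output plus the core domain types.

The pipeline's substrate is a registry of shipping ports, a stack of 24
monthly sea-surface climatology layers (12 months x {temperature,
salinity}), and ballast tank discharge records.  Loaders follow a
drop-and-report policy: rows that violate record-level invariants
(coordinates out of range, unparseable dates, unresolvable ports) are
dropped and counted rather than aborting the load, while structural
problems (a missing column, fewer than 12 months of data) raise.

Month indexing is 1-based (January = 1) throughout.  Longitudes are
normalised to [-180, 180) on load; grids delivered on [0, 360) are
converted by the reader.
"""

from __future__ import annotations

import datetime as dt
from dataclasses import dataclass, field
from pathlib import Path
from typing import Iterable, Mapping, Sequence

import numpy as np
import pandas as pd

from .errors import FormatError, UsageError, ValidationError

MONTHS = tuple(range(1, 13))

#: canonical column names for the port registry CSV
PORT_COLUMNS = ("port_id", "name", "lat", "lon", "country", "region")
#: canonical column names for tank record CSV
TANK_COLUMNS = (
    "tank_id",
    "source_port_id",
    "dest_port_id",
    "uptake_date",
    "discharge_date",
)


def normalize_lon(lon):
    """Wrap longitude(s) into [-180, 180); values already in range pass
    through bit-identically."""
    arr = np.asarray(lon, dtype=float)
    wrapped = (arr + 180.0) % 360.0 - 180.0
    return np.where((arr >= -180.0) & (arr < 180.0), arr, wrapped)


# ---------------------------------------------------------------------------
# Ports
# ---------------------------------------------------------------------------


@dataclass(frozen=True)
class Port:
    """One shipping port with position and regional labels.

    ``coast`` is only populated for destination (Canadian) ports and names
    the receiving coast: "Pacific", "Atlantic" or "Arctic".
    """

    port_id: str
    name: str
    lat: float
    lon: float
    country: str = ""
    region: str = ""
    coast: str | None = None

    def __post_init__(self):
        if not -90.0 <= self.lat <= 90.0:
            raise ValidationError(f"port {self.port_id}: lat {self.lat} out of [-90, 90]")
        if not -180.0 <= self.lon < 180.0:
            raise ValidationError(f"port {self.port_id}: lon {self.lon} out of [-180, 180)")


class PortRegistry:
    """Validated collection of ports, unique by ``port_id``."""

    def __init__(self, ports: Iterable[Port], rejections: pd.DataFrame | None = None):
        self._ports: dict[str, Port] = {}
        for p in ports:
            if p.port_id in self._ports:
                raise ValidationError(f"duplicate port_id {p.port_id!r}")
            self._ports[p.port_id] = p
        self.rejections = (
            rejections
            if rejections is not None
            else pd.DataFrame(columns=["row", "port_id", "reason"])
        )

    def __len__(self) -> int:
        return len(self._ports)

    def __contains__(self, port_id: str) -> bool:
        return port_id in self._ports

    def __getitem__(self, port_id: str) -> Port:
        return self._ports[port_id]

    def __iter__(self):
        return iter(self._ports.values())

    @property
    def port_ids(self) -> list[str]:
        return list(self._ports)

    def to_frame(self) -> pd.DataFrame:
        rows = [
            {
                "port_id": p.port_id,
                "name": p.name,
                "lat": p.lat,
                "lon": p.lon,
                "country": p.country,
                "region": p.region,
                "coast": p.coast if p.coast is not None else "",
            }
            for p in self
        ]
        return pd.DataFrame(rows, columns=list(PORT_COLUMNS) + ["coast"])


def load_ports(
    path: str | Path,
    column_map: Mapping[str, str] | None = None,
) -> PortRegistry:
    """Read a port registry CSV.

    ``column_map`` maps canonical names (``port_id``, ``lat``, ...) to the
    file's actual headers when they differ.  Rows with out-of-range
    coordinates are rejected and reported in ``registry.rejections``;
    duplicate identifiers raise :class:`ValidationError` and a missing
    required column raises :class:`FormatError`.
    """
    df = pd.read_csv(path, dtype={0: str}, float_precision="round_trip")
    colmap = {c: c for c in PORT_COLUMNS}
    if column_map:
        colmap.update(column_map)
    for canonical, actual in colmap.items():
        if actual not in df.columns:
            raise FormatError(f"port table is missing required column {actual!r} ({canonical})")

    ports: list[Port] = []
    rejected: list[dict] = []
    for i, row in df.iterrows():
        pid = str(row[colmap["port_id"]])
        try:
            lat = float(row[colmap["lat"]])
            lon = float(row[colmap["lon"]])
        except (TypeError, ValueError):
            rejected.append({"row": i, "port_id": pid, "reason": "non-numeric coordinate"})
            continue
        if not -90.0 <= lat <= 90.0:
            rejected.append({"row": i, "port_id": pid, "reason": f"lat {lat} out of range"})
            continue
        lon = float(normalize_lon(lon))
        coast = None
        if "coast" in df.columns:
            c = row["coast"]
            if isinstance(c, str) and c.strip():
                coast = c.strip()
        ports.append(
            Port(
                port_id=pid,
                name=str(row[colmap["name"]]),
                lat=lat,
                lon=lon,
                country=str(row[colmap["country"]]),
                region=str(row[colmap["region"]]),
                coast=coast,
            )
        )
    rej = pd.DataFrame(rejected, columns=["row", "port_id", "reason"])
    return PortRegistry(ports, rejections=rej)


def save_ports(registry: PortRegistry, path: str | Path) -> None:
    registry.to_frame().to_csv(path, index=False)


# ---------------------------------------------------------------------------
# Gridded climatology
# ---------------------------------------------------------------------------

VARIABLES = ("temperature", "salinity")


@dataclass
class GridVariable:
    """12 monthly layers of one environmental variable on a regular grid.

    ``values`` has shape (12, nlat, nlon) with NaN marking missing cells.
    """

    name: str
    lats: np.ndarray
    lons: np.ndarray
    values: np.ndarray

    def __post_init__(self):
        self.lats = np.asarray(self.lats, dtype=float)
        self.lons = np.asarray(self.lons, dtype=float)
        self.values = np.asarray(self.values, dtype=float)
        if self.values.shape != (12, self.lats.size, self.lons.size):
            raise FormatError(
                f"{self.name}: expected shape (12, {self.lats.size}, {self.lons.size}), "
                f"got {self.values.shape}"
            )

    @property
    def missing_mask(self) -> np.ndarray:
        return np.isnan(self.values)

    def missing_fraction(self, month: int | None = None) -> float:
        """Fraction of missing cells, overall or for one month (1-based)."""
        if month is None:
            return float(np.mean(self.missing_mask))
        return float(np.mean(self.missing_mask[month - 1]))

    def layer(self, month: int) -> np.ndarray:
        if month not in MONTHS:
            raise UsageError(f"month must be 1..12, got {month}")
        return self.values[month - 1]


@dataclass
class EnvGridStack:
    """The 24-layer stack: 12 months x {temperature, salinity}.

    Both variables share one grid geometry; missing cells are explicit NaNs,
    never silent zeros.
    """

    temperature: GridVariable
    salinity: GridVariable
    resolution: float = 1.0

    def __post_init__(self):
        t, s = self.temperature, self.salinity
        if t.lats.shape != s.lats.shape or t.lons.shape != s.lons.shape:
            raise FormatError("temperature and salinity grids differ in geometry")
        if not (np.allclose(t.lats, s.lats) and np.allclose(t.lons, s.lons)):
            raise FormatError("temperature and salinity grids differ in coordinates")

    @property
    def lats(self) -> np.ndarray:
        return self.temperature.lats

    @property
    def lons(self) -> np.ndarray:
        return self.temperature.lons

    def variable(self, name: str) -> GridVariable:
        if name == "temperature":
            return self.temperature
        if name == "salinity":
            return self.salinity
        raise UsageError(f"unknown variable {name!r}; expected one of {VARIABLES}")

    def layers(self):
        """Iterate the 24 (variable, month, 2-D values) layers."""
        for name in VARIABLES:
            var = self.variable(name)
            for m in MONTHS:
                yield name, m, var.layer(m)


def _grid_from_long_frame(df: pd.DataFrame, name: str) -> GridVariable:
    months = sorted(df["month"].unique())
    if list(months) != list(MONTHS):
        raise FormatError(f"long-form grid for {name}: need months 1..12, got {months}")
    df = df.copy()
    df["lon"] = normalize_lon(df["lon"].to_numpy())
    lats = np.sort(df["lat"].unique())
    lons = np.sort(df["lon"].unique())
    values = np.full((12, lats.size, lons.size), np.nan)
    lat_idx = {v: i for i, v in enumerate(lats)}
    lon_idx = {v: i for i, v in enumerate(lons)}
    for m, la, lo, v in df[["month", "lat", "lon", "value"]].itertuples(index=False):
        values[int(m) - 1, lat_idx[la], lon_idx[lo]] = v
    return GridVariable(name=name, lats=lats, lons=lons, values=values)


def load_env_grid(path: str | Path, variable: str) -> GridVariable:
    """Read 12 monthly layers of one variable.

    Two on-disk dialects are accepted:

    * a gridded scientific file readable by :mod:`xarray` (NetCDF/zarr) with
      a 12-entry month/time dimension and ``lat``/``lon`` coordinates;
    * the long-form CSV dialect used for fixtures, with columns
      ``month, lat, lon, value`` (missing cells simply absent or NaN).
    """
    if variable not in VARIABLES:
        raise UsageError(f"unknown variable {variable!r}; expected one of {VARIABLES}")
    path = Path(path)
    if path.suffix.lower() == ".csv":
        df = pd.read_csv(path, float_precision="round_trip")
        needed = {"month", "lat", "lon", "value"}
        if not needed.issubset(df.columns):
            raise FormatError(
                f"long-form grid CSV is missing columns {sorted(needed - set(df.columns))}"
            )
        return _grid_from_long_frame(df.dropna(subset=["value"]), variable)

    import xarray as xr

    ds = xr.open_dataset(path)
    try:
        if variable not in ds:
            raise FormatError(f"gridded file has no variable {variable!r}")
        da = ds[variable]
        month_dim = next((d for d in da.dims if d in ("month", "time")), None)
        if month_dim is None or da.sizes[month_dim] != 12:
            raise FormatError(f"variable {variable!r} needs a 12-entry month/time dimension")
        da = da.transpose(month_dim, "lat", "lon")
        lats = da["lat"].to_numpy()
        lons = normalize_lon(da["lon"].to_numpy())
        order_la = np.argsort(lats)
        order_lo = np.argsort(lons)
        values = da.to_numpy()[:, order_la][:, :, order_lo]
        return GridVariable(
            name=variable, lats=lats[order_la], lons=lons[order_lo], values=values
        )
    finally:
        ds.close()


def save_env_grid_long(var: GridVariable, path: str | Path) -> None:
    """Write a GridVariable in the long-form CSV dialect (missing cells omitted)."""
    rows = []
    for m in MONTHS:
        layer = var.layer(m)
        for i, la in enumerate(var.lats):
            for j, lo in enumerate(var.lons):
                if not np.isnan(layer[i, j]):
                    rows.append((m, la, lo, layer[i, j]))
    pd.DataFrame(rows, columns=["month", "lat", "lon", "value"]).to_csv(path, index=False)


# ---------------------------------------------------------------------------
# Port environmental profiles
# ---------------------------------------------------------------------------


@dataclass
class PortEnvProfile:
    """12 monthly temperatures and salinities for one matched port.

    All 24 values are present by construction; ports with unfixable gaps are
    excluded upstream by the matcher.  ``matched_grid_point`` is the nearest
    climatology cell in the shared grid geometry and ``match_distance_km``
    the geodesic distance to it (individual months may have been served by a
    neighbouring cell when that cell's value was missing).
    """

    port_id: str
    T: np.ndarray
    S: np.ndarray
    matched_grid_point: tuple[float, float]
    match_distance_km: float

    def __post_init__(self):
        self.T = np.asarray(self.T, dtype=float)
        self.S = np.asarray(self.S, dtype=float)
        if self.T.shape != (12,) or self.S.shape != (12,):
            raise ValidationError(f"profile {self.port_id}: need 12 monthly values per variable")
        if np.isnan(self.T).any() or np.isnan(self.S).any():
            raise ValidationError(f"profile {self.port_id}: missing monthly values")

    def temperature(self, month: int) -> float:
        if month not in MONTHS:
            raise UsageError(f"month must be 1..12, got {month}")
        return float(self.T[month - 1])

    def salinity(self, month: int) -> float:
        if month not in MONTHS:
            raise UsageError(f"month must be 1..12, got {month}")
        return float(self.S[month - 1])


def profiles_to_frame(profiles: Iterable[PortEnvProfile]) -> pd.DataFrame:
    rows = []
    for p in profiles:
        row: dict = {"port_id": p.port_id}
        row.update({f"T{m:02d}": p.T[m - 1] for m in MONTHS})
        row.update({f"S{m:02d}": p.S[m - 1] for m in MONTHS})
        row["grid_lat"], row["grid_lon"] = p.matched_grid_point
        row["match_distance_km"] = p.match_distance_km
        rows.append(row)
    return pd.DataFrame(rows)


def frame_to_profiles(df: pd.DataFrame) -> list[PortEnvProfile]:
    tcols = [f"T{m:02d}" for m in MONTHS]
    scols = [f"S{m:02d}" for m in MONTHS]
    missing = [c for c in ["port_id", *tcols, *scols] if c not in df.columns]
    if missing:
        raise FormatError(f"profile table is missing columns {missing}")
    out = []
    for _, row in df.iterrows():
        out.append(
            PortEnvProfile(
                port_id=str(row["port_id"]),
                T=row[tcols].to_numpy(dtype=float),
                S=row[scols].to_numpy(dtype=float),
                matched_grid_point=(
                    float(row.get("grid_lat", np.nan)),
                    float(row.get("grid_lon", np.nan)),
                ),
                match_distance_km=float(row.get("match_distance_km", np.nan)),
            )
        )
    return out


def save_profiles(profiles: Iterable[PortEnvProfile], path: str | Path) -> None:
    profiles_to_frame(profiles).to_csv(path, index=False)


def load_profiles(path: str | Path) -> list[PortEnvProfile]:
    return frame_to_profiles(
        pd.read_csv(path, dtype={"port_id": str}, float_precision="round_trip")
    )


# ---------------------------------------------------------------------------
# Tank records
# ---------------------------------------------------------------------------


@dataclass(frozen=True)
class TankRecord:
    """One ballast tank's source/destination/date record — the unit of risk
    assessment."""

    tank_id: str
    source_port_id: str
    dest_port_id: str
    uptake_date: dt.date
    discharge_date: dt.date

    def __post_init__(self):
        if self.discharge_date < self.uptake_date:
            raise ValidationError(
                f"tank {self.tank_id}: discharge {self.discharge_date} precedes "
                f"uptake {self.uptake_date}"
            )

    @property
    def year(self) -> int:
        """Assessment year = year of discharge in the recipient's waters."""
        return self.discharge_date.year

    @property
    def uptake_month(self) -> int:
        return self.uptake_date.month

    @property
    def discharge_month(self) -> int:
        return self.discharge_date.month

    @property
    def voyage_days(self) -> int:
        return (self.discharge_date - self.uptake_date).days


@dataclass
class TankLoadReport:
    """Reconciliation of a tank-record load: input = retained + dropped."""

    n_input: int = 0
    n_retained: int = 0
    dropped: list[dict] = field(default_factory=list)

    @property
    def n_dropped(self) -> int:
        return len(self.dropped)

    def reconciles(self) -> bool:
        return self.n_input == self.n_retained + self.n_dropped


def _parse_date(value) -> dt.date:
    if isinstance(value, dt.date):
        return value
    ts = pd.Timestamp(str(value))
    if pd.isna(ts):
        raise ValueError(f"unparseable date {value!r}")
    return ts.date()


def load_tank_records(
    path: str | Path,
    registry: PortRegistry,
    recipient_ports: set[str] | None = None,
) -> tuple[list[TankRecord], TankLoadReport]:
    """Read tank records, dropping (and counting) unusable rows.

    A row is dropped when its source or destination port cannot be resolved
    in ``registry``, when the destination is outside ``recipient_ports``
    (if given — this mirrors restricting the analysis to a recipient
    country's waters), when a date fails to parse, or when discharge
    precedes uptake.
    """
    df = pd.read_csv(path, dtype=str)
    for col in TANK_COLUMNS:
        if col not in df.columns:
            raise FormatError(f"tank table is missing required column {col!r}")
    records: list[TankRecord] = []
    report = TankLoadReport(n_input=len(df))
    for i, row in df.iterrows():
        src, dst = str(row["source_port_id"]), str(row["dest_port_id"])
        reason = None
        if src not in registry:
            reason = f"unresolvable source port {src!r}"
        elif dst not in registry:
            reason = f"unresolvable destination port {dst!r}"
        elif recipient_ports is not None and dst not in recipient_ports:
            reason = f"destination {dst!r} outside recipient set"
        if reason is None:
            try:
                up = _parse_date(row["uptake_date"])
                dis = _parse_date(row["discharge_date"])
            except (ValueError, TypeError):
                reason = "unparseable date"
            else:
                if dis < up:
                    reason = "discharge before uptake"
        if reason is not None:
            report.dropped.append({"row": i, "tank_id": str(row["tank_id"]), "reason": reason})
            continue
        records.append(
            TankRecord(
                tank_id=str(row["tank_id"]),
                source_port_id=src,
                dest_port_id=dst,
                uptake_date=up,
                discharge_date=dis,
            )
        )
    report.n_retained = len(records)
    return records, report


def tank_records_to_frame(records: Sequence[TankRecord]) -> pd.DataFrame:
    return pd.DataFrame(
        [
            {
                "tank_id": r.tank_id,
                "source_port_id": r.source_port_id,
                "dest_port_id": r.dest_port_id,
                "uptake_date": r.uptake_date.isoformat(),
                "discharge_date": r.discharge_date.isoformat(),
            }
            for r in records
        ],
        columns=list(TANK_COLUMNS),
    )


def save_tank_records(records: Sequence[TankRecord], path: str | Path) -> None:
    tank_records_to_frame(records).to_csv(path, index=False)
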