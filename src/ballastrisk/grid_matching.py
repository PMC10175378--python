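"""Match ports to their nearest climatology grid cells.

Each port is assigned the non-missing grid cell minimising geodesic
distance, separately for each of the 24 monthly layers: when a cell's
value is missing in one layer, that layer's match is rerun against the
remaining cells, so different months may be served by different
neighbouring cells.  Ports farther than ``max_cells`` grid cells
(2 cells = 222 km at one-degree resolution) from data in any layer are
excluded from the analysis — in real climatologies these are inland
ports such as the Laurentian Great Lakes.

Distances use the haversine formula on a sphere of radius 6371 km;
at one-degree grid scale the difference from an ellipsoidal geodesic
is negligible.  Ties are broken deterministically by lowest latitude,
then lowest longitude.
"""

from __future__ import annotations

from dataclasses import dataclass
from enum import Enum

import numpy as np
import pandas as pd

from .data_io import EnvGridStack, GridVariable, Port, PortEnvProfile, PortRegistry
from .errors import PipelineError, UsageError

EARTH_RADIUS_KM = 6371.0
#: approximate meridional extent of one degree, used to convert the
#: cell-count cutoff into kilometres (2 cells -> 222 km)
KM_PER_CELL = 111.0
DEFAULT_MAX_CELLS = 2.0


def haversine_km(lat1, lon1, lat2, lon2) -> np.ndarray:
    """Great-circle distance in km between points given in decimal degrees.

    Vectorised: any argument may be an array; standard numpy broadcasting
    applies.
    """
    lat1, lon1, lat2, lon2 = (np.radians(np.asarray(x, dtype=float)) for x in (lat1, lon1, lat2, lon2))
    dlat = lat2 - lat1
    dlon = lon2 - lon1
    a = np.sin(dlat / 2.0) ** 2 + np.cos(lat1) * np.cos(lat2) * np.sin(dlon / 2.0) ** 2
    return 2.0 * EARTH_RADIUS_KM * np.arcsin(np.sqrt(np.clip(a, 0.0, 1.0)))


class MatchStatus(str, Enum):
    MATCHED = "matched"
    EXCLUDED_TOO_FAR = "excluded_too_far"
    EXCLUDED_MISSING = "excluded_missing"


@dataclass
class MatchResult:
    """Outcome of matching one port against one grid layer."""

    port_id: str
    status: MatchStatus
    grid_point: tuple[float, float] | None
    distance_km: float
    km_per_cell: float = KM_PER_CELL

    @property
    def distance_cells(self) -> float:
        return self.distance_km / self.km_per_cell


def _port_cell_distances(port: Port, lats: np.ndarray, lons: np.ndarray) -> np.ndarray:
    """(nlat, nlon) matrix of geodesic distances from the port to every cell."""
    glat, glon = np.meshgrid(lats, lons, indexing="ij")
    return haversine_km(port.lat, port.lon, glat, glon)


def _nearest_cell(
    dist: np.ndarray, valid: np.ndarray, lats: np.ndarray, lons: np.ndarray
) -> tuple[float, float, float]:
    """Nearest valid cell with deterministic (lat, lon) tie-break.

    Returns (lat, lon, distance_km).  ``valid`` marks cells that carry data.
    """
    d = np.where(valid, dist, np.inf)
    dmin = d.min()
    # exact-equality candidates; float distances from identical geometry are
    # bit-identical for genuinely symmetric ties
    ii, jj = np.nonzero(d == dmin)
    order = np.lexsort((lons[jj], lats[ii]))
    k = order[0]
    return float(lats[ii[k]]), float(lons[jj[k]]), float(dmin)


def nearest_grid_point(port: Port, layer: GridVariable | np.ndarray, month: int = 1,
                       lats: np.ndarray | None = None,
                       lons: np.ndarray | None = None) -> MatchResult:
    """Match one port to the nearest non-missing cell of one layer.

    ``layer`` may be a :class:`GridVariable` (with ``month`` selecting the
    layer) or a bare 2-D array accompanied by ``lats``/``lons``.
    """
    if isinstance(layer, GridVariable):
        values = layer.layer(month)
        lats, lons = layer.lats, layer.lons
    else:
        values = np.asarray(layer, dtype=float)
        if lats is None or lons is None:
            raise UsageError("bare-array layer requires lats and lons")
    valid = ~np.isnan(values)
    if not valid.any():
        raise UsageError("layer has no non-missing cells")
    dist = _port_cell_distances(port, lats, lons)
    la, lo, d = _nearest_cell(dist, valid, lats, lons)
    return MatchResult(
        port_id=port.port_id, status=MatchStatus.MATCHED, grid_point=(la, lo), distance_km=d
    )


def apply_distance_cutoff(
    result: MatchResult,
    max_cells: float = DEFAULT_MAX_CELLS,
    km_per_cell: float = KM_PER_CELL,
) -> MatchResult:
    """Exclude a match strictly farther than ``max_cells`` grid cells.

    The boundary is kept: a port exactly ``max_cells * km_per_cell`` km from
    its cell remains matched (exclusion is strictly-greater).
    """
    cutoff_km = max_cells * km_per_cell
    if result.status is MatchStatus.MATCHED and result.distance_km > cutoff_km:
        return MatchResult(
            port_id=result.port_id,
            status=MatchStatus.EXCLUDED_TOO_FAR,
            grid_point=None,
            distance_km=result.distance_km,
            km_per_cell=km_per_cell,
        )
    return result


def build_profiles(
    ports: PortRegistry,
    stack: EnvGridStack,
    max_cells: float = DEFAULT_MAX_CELLS,
    km_per_cell: float = KM_PER_CELL,
) -> tuple[list[PortEnvProfile], pd.DataFrame]:
    """Match every port against all 24 layers and assemble profiles.

    Per layer, missing cells are dropped and the nearest-cell search rerun,
    so a month with a gap at the port's primary cell is served by the
    nearest cell that does carry data.  A port whose match in *any* layer
    exceeds the distance cutoff is excluded overall, keeping every retained
    profile complete.

    Returns the profiles plus a per-port match report with columns
    ``port_id, status, grid_lat, grid_lon, distance_km, max_distance_km``.
    """
    lats, lons = stack.lats, stack.lons
    cutoff_km = max_cells * km_per_cell
    profiles: list[PortEnvProfile] = []
    report_rows: list[dict] = []

    layer_valid = {
        (name, m): ~np.isnan(values) for name, m, values in stack.layers()
    }

    for port in ports:
        dist = _port_cell_distances(port, lats, lons)
        # primary match against the full geometry (for reporting)
        any_valid = np.zeros(dist.shape, dtype=bool)
        for v in layer_valid.values():
            any_valid |= v
        if not any_valid.any():
            raise PipelineError("climatology stack has no non-missing cells")

        T = np.full(12, np.nan)
        S = np.full(12, np.nan)
        max_d = 0.0
        excluded = False
        primary: tuple[float, float, float] | None = None
        for (name, m), valid in layer_valid.items():
            if not valid.any():
                excluded = True
                break
            la, lo, d = _nearest_cell(dist, valid, lats, lons)
            if d > cutoff_km:
                excluded = True
                max_d = max(max_d, d)
                break
            max_d = max(max_d, d)
            if primary is None or d < primary[2]:
                primary = (la, lo, d)
            i = int(np.searchsorted(lats, la))
            j = int(np.searchsorted(lons, lo))
            value = stack.variable(name).layer(m)[i, j]
            if name == "temperature":
                T[m - 1] = value
            else:
                S[m - 1] = value

        if excluded or np.isnan(T).any() or np.isnan(S).any():
            report_rows.append(
                {
                    "port_id": port.port_id,
                    "status": MatchStatus.EXCLUDED_TOO_FAR.value,
                    "grid_lat": np.nan,
                    "grid_lon": np.nan,
                    "distance_km": np.nan,
                    "max_distance_km": max_d,
                }
            )
            continue
        assert primary is not None
        profiles.append(
            PortEnvProfile(
                port_id=port.port_id,
                T=T,
                S=S,
                matched_grid_point=(primary[0], primary[1]),
                match_distance_km=primary[2],
            )
        )
        report_rows.append(
            {
                "port_id": port.port_id,
                "status": MatchStatus.MATCHED.value,
                "grid_lat": primary[0],
                "grid_lon": primary[1],
                "distance_km": primary[2],
                "max_distance_km": max_d,
            }
        )

    if not profiles:
        raise PipelineError("no port matched the climatology grid")
    report = pd.DataFrame(
        report_rows,
        columns=["port_id", "status", "grid_lat", "grid_lon", "distance_km", "max_distance_km"],
    )
    return profiles, report
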