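"""Geodesic cell geometry for regular lon/lat grids.

On a geographic (plate carrée) grid every cell spans the same number of
degrees, but its ground area shrinks with the cosine of latitude.  Cell
areas are computed as ``height × width`` where the height (north–south
extent) is constant — degrees × 60 minutes × 1852 m per minute of arc —
and the width is the Earth's perimeter at the cell-center latitude divided
by the number of cells around a full parallel.  This cylindrical-strip
approximation is accurate to well under 0.5% away from the poles and is
cheap enough to evaluate for global grids at arc-second resolutions.
"""

from __future__ import annotations

from dataclasses import dataclass, field

import numpy as np
import pandas as pd

__all__ = [
    "GeodesyConstants",
    "GridSpec",
    "DEFAULT_GEODESY",
    "cell_height_m",
    "cell_width_m",
    "cell_area_km2",
    "cell_area_grid_km2",
    "zonal_sum",
]


@dataclass(frozen=True)
class GeodesyConstants:
    """Constants of the spherical-Earth cell-size model.

    ``n_cells_lon`` is the number of grid cells around a full parallel;
    ``None`` means "derive from the grid resolution" (``360 / resolution``),
    which keeps coarse test grids self-consistent.  At the 0.004166°
    resolution of global bathymetry products the derived value is 86,400.
    """

    earth_radius_km: float = 6378.0
    minutes_per_degree: float = 60.0
    meters_per_minute: float = 1852.0
    n_cells_lon: int | None = None

    def __post_init__(self) -> None:
        if self.earth_radius_km <= 0 or self.minutes_per_degree <= 0 or self.meters_per_minute <= 0:
            raise ValueError("geodesy constants must be positive")
        if self.n_cells_lon is not None and self.n_cells_lon <= 0:
            raise ValueError("n_cells_lon must be positive")

    def resolve_n_cells(self, resolution_deg: float | None) -> float:
        if self.n_cells_lon is not None:
            return float(self.n_cells_lon)
        if resolution_deg is None:
            raise ValueError("n_cells_lon unset and no resolution given to derive it")
        return 360.0 / resolution_deg


DEFAULT_GEODESY = GeodesyConstants()


@dataclass(frozen=True)
class GridSpec:
    """Regular lon/lat grid; ``(lat0, lon0)`` is the south-west corner.

    Rows index latitude from south to north, columns longitude from west
    to east.  Cells are half-open ``[west, east) × [south, north)`` so a
    point on a shared edge belongs to exactly one cell.
    """

    resolution_deg: float
    lat0: float
    lon0: float
    n_rows: int
    n_cols: int

    def __post_init__(self) -> None:
        if self.resolution_deg <= 0:
            raise ValueError("resolution_deg must be positive")
        if self.n_rows <= 0 or self.n_cols <= 0:
            raise ValueError("grid must have at least one row and column")
        if not (-90.0 <= self.lat0 and self.lat_max <= 90.0):
            raise ValueError("grid latitude range must lie within [-90, 90]")
        if not (-180.0 <= self.lon0 and self.lon_max <= 180.0):
            raise ValueError("grid longitude range must lie within [-180, 180]")

    @property
    def lat_max(self) -> float:
        return self.lat0 + self.n_rows * self.resolution_deg

    @property
    def lon_max(self) -> float:
        return self.lon0 + self.n_cols * self.resolution_deg

    @property
    def shape(self) -> tuple[int, int]:
        return (self.n_rows, self.n_cols)

    def lat_centers(self) -> np.ndarray:
        return self.lat0 + (np.arange(self.n_rows) + 0.5) * self.resolution_deg

    def lon_centers(self) -> np.ndarray:
        return self.lon0 + (np.arange(self.n_cols) + 0.5) * self.resolution_deg

    def lat_edges(self) -> np.ndarray:
        return self.lat0 + np.arange(self.n_rows + 1) * self.resolution_deg

    def lon_edges(self) -> np.ndarray:
        return self.lon0 + np.arange(self.n_cols + 1) * self.resolution_deg

    def locate(self, lon, lat):
        """Map points to (row, col); -1 where the point falls off the grid."""
        lon = np.asarray(lon, dtype=float)
        lat = np.asarray(lat, dtype=float)
        col = np.floor((lon - self.lon0) / self.resolution_deg).astype(int)
        row = np.floor((lat - self.lat0) / self.resolution_deg).astype(int)
        bad = (col < 0) | (col >= self.n_cols) | (row < 0) | (row >= self.n_rows)
        row = np.where(bad, -1, row)
        col = np.where(bad, -1, col)
        return row, col


def cell_height_m(spec: GridSpec | float, constants: GeodesyConstants = DEFAULT_GEODESY) -> float:
    """North–south extent of a cell in meters (constant over the grid)."""
    res = spec.resolution_deg if isinstance(spec, GridSpec) else float(spec)
    return res * constants.minutes_per_degree * constants.meters_per_minute


def cell_width_m(
    latitude_deg,
    constants: GeodesyConstants = DEFAULT_GEODESY,
    resolution_deg: float | None = None,
):
    """East–west extent of a cell at ``latitude_deg``, in meters.

    Earth perimeter at that latitude (2πR·cos φ) divided by the number of
    cells around the parallel.  Accepts scalars or arrays.
    """
    lat = np.asarray(latitude_deg, dtype=float)
    if np.any(np.abs(lat) > 90.0):
        raise ValueError("latitude out of [-90, 90]")
    n_cells = constants.resolve_n_cells(resolution_deg)
    perimeter_m = 2.0 * np.pi * constants.earth_radius_km * 1000.0 * np.cos(np.radians(lat))
    # cos(±90°) is only zero to rounding; the poles are degenerate exactly
    perimeter_m = np.where(np.abs(lat) == 90.0, 0.0, np.maximum(perimeter_m, 0.0))
    width = perimeter_m / n_cells
    return width if width.ndim else float(width)


def cell_area_km2(latitude_deg, spec: GridSpec, constants: GeodesyConstants = DEFAULT_GEODESY):
    """Area of a cell whose center sits at ``latitude_deg``, in km²."""
    h = cell_height_m(spec, constants)
    w = cell_width_m(latitude_deg, constants, resolution_deg=spec.resolution_deg)
    return h * w * 1e-6


def cell_area_grid_km2(spec: GridSpec, constants: GeodesyConstants = DEFAULT_GEODESY) -> np.ndarray:
    """Per-cell areas for the whole grid, shape (n_rows, n_cols)."""
    row_areas = cell_area_km2(spec.lat_centers(), spec, constants)
    return np.broadcast_to(np.asarray(row_areas)[:, None], spec.shape).copy()


def zonal_sum(values, zones, areas) -> pd.Series:
    """Sum ``value × area`` per zone label.

    All three inputs must share one shape.  Cells whose zone is ``None``,
    NaN, or a negative integer code are ignored; zones absent from the
    input are absent from the output (no zero rows).
    """
    values = np.asarray(values, dtype=float)
    zones = np.asarray(zones)
    areas = np.asarray(areas, dtype=float)
    if not (values.shape == zones.shape == areas.shape):
        raise ValueError("values, zones and areas must share the same shape")
    flat_zone = zones.ravel()
    if flat_zone.dtype.kind in "iu":
        keep = flat_zone >= 0
    elif flat_zone.dtype.kind == "f":
        keep = ~np.isnan(flat_zone)
    else:
        keep = np.array([z is not None for z in flat_zone])
    weighted = (values * areas).ravel()[keep]
    out = pd.Series(weighted).groupby(flat_zone[keep]).sum()
    return out[out != 0.0]
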