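"""Depth-realm schemes and the ecoregion × depth-realm 3D typology.

The ocean is zoned vertically into benthic realms (properties of the
seafloor at a given depth: euphotic, mesophotic, rariphotic, bathyal,
abyssal, hadal) and pelagic realms (layers of the water column:
epipelagic down to hadopelagic).  Crossing these depth bands with 2D
marine ecoregions yields "3D realms" — the unit at which protection
coverage and fishing pressure are assessed.

Conventions used throughout:

* depths are positive-down meters; bathymetry rasters store *elevation*
  (negative below sea level) and are negated on ingest;
* cells with elevation >= 0 are land and are excluded everywhere;
* bands are deep-inclusive half-open intervals ``(shallow, deep]``, so a
  30 m seabed is euphotic and every positive depth belongs to exactly
  one benthic band.
"""

from __future__ import annotations

import json
import math
from dataclasses import dataclass, field
from typing import Iterable, Sequence

import numpy as np
import pandas as pd
import shapely
from shapely.geometry import mapping, shape
from shapely.geometry.base import BaseGeometry

from .grid_geometry import DEFAULT_GEODESY, GeodesyConstants, GridSpec, cell_area_grid_km2

__all__ = [
    "DepthBand",
    "DepthRealmScheme",
    "BathymetryGrid",
    "EcoregionMap",
    "Realm3D",
    "default_benthic_scheme",
    "default_pelagic_scheme",
    "classify_benthic",
    "classify_benthic_grid",
    "pelagic_column",
    "enumerate_realms3d",
]


@dataclass(frozen=True)
class DepthBand:
    """One depth band; ``deep_m = inf`` marks the unbounded deepest band."""

    name: str
    shallow_m: float
    deep_m: float

    def __post_init__(self) -> None:
        if self.shallow_m < 0:
            raise ValueError(f"band {self.name!r}: depths must be non-negative")
        if not self.shallow_m < self.deep_m:
            raise ValueError(f"band {self.name!r}: shallow_m must be < deep_m")

    def contains(self, depth_m: float) -> bool:
        return self.shallow_m < depth_m <= self.deep_m


@dataclass(frozen=True)
class DepthRealmScheme:
    """Ordered, contiguous, non-overlapping bands starting at 0 m."""

    domain: str
    bands: tuple[DepthBand, ...]

    def __post_init__(self) -> None:
        if self.domain not in ("benthic", "pelagic"):
            raise ValueError("domain must be 'benthic' or 'pelagic'")
        if not self.bands:
            raise ValueError("scheme needs at least one band")
        if self.bands[0].shallow_m != 0.0:
            raise ValueError("first band must start at 0 m")
        for a, b in zip(self.bands, self.bands[1:]):
            if a.deep_m != b.shallow_m:
                raise ValueError(f"bands {a.name!r} and {b.name!r} are not contiguous")
        names = [b.name for b in self.bands]
        if len(set(names)) != len(names):
            raise ValueError("band names must be unique")

    @property
    def names(self) -> tuple[str, ...]:
        return tuple(b.name for b in self.bands)

    def band(self, name: str) -> DepthBand:
        for b in self.bands:
            if b.name == name:
                return b
        raise KeyError(name)

    def deep_bounds(self) -> np.ndarray:
        return np.array([b.deep_m for b in self.bands])

    def shallow_bounds(self) -> np.ndarray:
        return np.array([b.shallow_m for b in self.bands])

    def to_config(self) -> dict:
        return {
            "domain": self.domain,
            "bands": [
                {"name": b.name, "shallow_m": b.shallow_m,
                 "deep_m": None if math.isinf(b.deep_m) else b.deep_m}
                for b in self.bands
            ],
        }

    @classmethod
    def from_config(cls, cfg: dict) -> "DepthRealmScheme":
        bands = tuple(
            DepthBand(b["name"], float(b["shallow_m"]),
                      math.inf if b["deep_m"] is None else float(b["deep_m"]))
            for b in cfg["bands"]
        )
        return cls(cfg["domain"], bands)

    def to_json(self, path) -> None:
        with open(path, "w", encoding="utf-8") as fh:
            json.dump(self.to_config(), fh, indent=2)

    @classmethod
    def from_json(cls, path) -> "DepthRealmScheme":
        with open(path, encoding="utf-8") as fh:
            return cls.from_config(json.load(fh))


def default_benthic_scheme() -> DepthRealmScheme:
    """The eight-band benthic zonation, euphotic (0–30 m) to hadal (>6000 m).

    The mesophotic is always carried as its upper (30–60 m) and lower
    (60–150 m) subdivisions.
    """
    bounds = [
        ("euphotic", 0, 30),
        ("upper_mesophotic", 30, 60),
        ("lower_mesophotic", 60, 150),
        ("rariphotic", 150, 300),
        ("upper_bathyal", 300, 1000),
        ("lower_bathyal", 1000, 3500),
        ("abyssal", 3500, 6000),
        ("hadal", 6000, math.inf),
    ]
    return DepthRealmScheme("benthic", tuple(DepthBand(n, s, d) for n, s, d in bounds))


def default_pelagic_scheme(merge_deepest: bool = False) -> DepthRealmScheme:
    """The five-band pelagic zonation, epipelagic (0–200 m) to hadopelagic.

    ``merge_deepest=True`` merges the abyssopelagic and hadopelagic into a
    single ``abyssopelagic`` band (>3500 m), the four-realm variant.
    """
    bounds = [
        ("epipelagic", 0, 200),
        ("mesopelagic", 200, 1000),
        ("bathypelagic", 1000, 3500),
        ("abyssopelagic", 3500, 6000),
        ("hadopelagic", 6000, math.inf),
    ]
    if merge_deepest:
        bounds = bounds[:3] + [("abyssopelagic", 3500, math.inf)]
    return DepthRealmScheme("pelagic", tuple(DepthBand(n, s, d) for n, s, d in bounds))


# ---------------------------------------------------------------------------
# classification

def classify_benthic(depth_m: float, scheme: DepthRealmScheme | None = None) -> str:
    """Benthic band containing a seabed depth (positive-down meters)."""
    if scheme is None:
        scheme = default_benthic_scheme()
    if depth_m <= 0:
        raise ValueError("non-positive depth: land or invalid cell")
    idx = int(np.searchsorted(scheme.deep_bounds(), depth_m, side="left"))
    return scheme.bands[idx].name


def classify_benthic_grid(depth_m: np.ndarray, scheme: DepthRealmScheme) -> np.ndarray:
    """Vectorized band index per cell; -1 where depth <= 0 or NaN (land)."""
    depth = np.asarray(depth_m, dtype=float)
    idx = np.searchsorted(scheme.deep_bounds(), depth, side="left")
    ocean = np.isfinite(depth) & (depth > 0)
    return np.where(ocean, idx, -1).astype(int)


def pelagic_column(seabed_depth_m: float, scheme: DepthRealmScheme | None = None) -> set[str]:
    """All pelagic bands present between the surface and the seabed.

    A band occurs in the column whenever its shallow bound lies above the
    seabed, so the set is nested: deeper seabeds only add bands.
    """
    if scheme is None:
        scheme = default_pelagic_scheme()
    if seabed_depth_m <= 0:
        raise ValueError("non-positive depth: land or invalid cell")
    return {b.name for b in scheme.bands if b.shallow_m < seabed_depth_m}


# ---------------------------------------------------------------------------
# gridded containers

@dataclass
class BathymetryGrid:
    """Elevation raster on a regular lon/lat grid (negative below sea level)."""

    spec: GridSpec
    elevation: np.ndarray

    def __post_init__(self) -> None:
        self.elevation = np.asarray(self.elevation, dtype=float)
        if self.elevation.shape != self.spec.shape:
            raise ValueError("elevation shape does not match grid spec")

    @property
    def ocean_mask(self) -> np.ndarray:
        return self.elevation < 0

    def depth(self) -> np.ndarray:
        """Seabed depth in positive-down meters; NaN on land."""
        return np.where(self.ocean_mask, -self.elevation, np.nan)

    def depth_at(self, lon, lat):
        """Nearest-cell seabed depth at point locations; NaN off-grid/land."""
        row, col = self.spec.locate(lon, lat)
        d = self.depth()
        out = np.full(np.shape(row), np.nan, dtype=float)
        ok = np.asarray(row) >= 0
        out[ok] = d[np.asarray(row)[ok], np.asarray(col)[ok]]
        return out if out.ndim else float(out)


@dataclass
class EcoregionMap:
    """Labelled coastal/offshore polygons in geographic lon/lat degrees."""

    labels: list[str]
    classes: list[str]
    geometries: list[BaseGeometry]

    def __post_init__(self) -> None:
        if not (len(self.labels) == len(self.classes) == len(self.geometries)):
            raise ValueError("labels, classes and geometries must align")
        if len(set(self.labels)) != len(self.labels):
            raise ValueError("ecoregion labels must be unique")
        bad = {c for c in self.classes} - {"coastal", "offshore"}
        if bad:
            raise ValueError(f"unknown ecoregion classes: {sorted(bad)}")
        self.geometries = [shapely.make_valid(g) for g in self.geometries]

    def rasterize(self, spec: GridSpec) -> np.ndarray:
        """Ecoregion index per cell by cell-center test; -1 where unassigned."""
        lon = spec.lon_centers()
        lat = spec.lat_centers()
        lon_grid, lat_grid = np.meshgrid(lon, lat)
        out = np.full(spec.shape, -1, dtype=int)
        for i, geom in enumerate(self.geometries):
            hit = shapely.intersects_xy(geom, lon_grid.ravel(), lat_grid.ravel()).reshape(spec.shape)
            out = np.where((out == -1) & hit, i, out)
        return out

    def class_of(self, label: str) -> str:
        return self.classes[self.labels.index(label)]

    def to_geojson(self, path) -> None:
        feats = [
            {"type": "Feature",
             "properties": {"label": lab, "class": cls},
             "geometry": mapping(geom)}
            for lab, cls, geom in zip(self.labels, self.classes, self.geometries)
        ]
        with open(path, "w", encoding="utf-8") as fh:
            json.dump({"type": "FeatureCollection", "features": feats}, fh)

    @classmethod
    def from_geojson(cls, path) -> "EcoregionMap":
        with open(path, encoding="utf-8") as fh:
            gj = json.load(fh)
        labels, classes, geoms = [], [], []
        for feat in gj["features"]:
            labels.append(str(feat["properties"]["label"]))
            classes.append(str(feat["properties"]["class"]))
            geoms.append(shape(feat["geometry"]))
        return cls(labels, classes, geoms)


class Realm3D(tuple):
    """(ecoregion, band, domain) identity of a 3D realm."""

    __slots__ = ()

    def __new__(cls, ecoregion: str, band: str, domain: str):
        return super().__new__(cls, (ecoregion, band, domain))

    ecoregion = property(lambda self: self[0])
    band = property(lambda self: self[1])
    domain = property(lambda self: self[2])


# ---------------------------------------------------------------------------
# 3D enumeration

def enumerate_realms3d(
    bathymetry: BathymetryGrid,
    ecoregions: EcoregionMap,
    benthic_scheme: DepthRealmScheme | None = None,
    pelagic_scheme: DepthRealmScheme | None = None,
    constants: GeodesyConstants = DEFAULT_GEODESY,
    ecoregion_index: np.ndarray | None = None,
) -> pd.DataFrame:
    """Enumerate the 3D realms present and their areas.

    Returns one row per (ecoregion, band, domain) with a positive area in
    km²; depth bands that do not occur in an ecoregion yield no row.  The
    benthic area of a band is the summed area of ocean cells whose seabed
    lies in the band; the pelagic area of a band is the area of cells whose
    seabed depth exceeds the band's shallow bound (the band exists in the
    water column there).
    """
    benthic_scheme = benthic_scheme or default_benthic_scheme()
    pelagic_scheme = pelagic_scheme or default_pelagic_scheme()
    spec = bathymetry.spec
    depth = bathymetry.depth()
    areas = cell_area_grid_km2(spec, constants)
    eco_idx = ecoregions.rasterize(spec) if ecoregion_index is None else ecoregion_index
    ocean = bathymetry.ocean_mask & (eco_idx >= 0)

    rows: list[tuple[str, str, str, float]] = []
    band_idx = classify_benthic_grid(depth, benthic_scheme)
    for b, band in enumerate(benthic_scheme.bands):
        sel = ocean & (band_idx == b)
        if not sel.any():
            continue
        totals = pd.Series(areas[sel]).groupby(eco_idx[sel]).sum()
        rows.extend(
            (ecoregions.labels[int(e)], band.name, "benthic", float(a))
            for e, a in totals.items()
        )
    for band in pelagic_scheme.bands:
        sel = ocean & (depth > band.shallow_m)
        if not sel.any():
            continue
        totals = pd.Series(areas[sel]).groupby(eco_idx[sel]).sum()
        rows.extend(
            (ecoregions.labels[int(e)], band.name, "pelagic", float(a))
            for e, a in totals.items()
        )
    out = pd.DataFrame(rows, columns=["ecoregion", "band", "domain", "area_km2"])
    return out.sort_values(["domain", "ecoregion", "band"], ignore_index=True)
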