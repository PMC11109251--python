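"""Protected-area flattening and per-3D-realm coverage.

Protected-area databases contain overlapping designations: the same
stretch of sea can sit inside a strict no-take reserve and a larger
multiple-use park.  To avoid double counting, overlaps are flattened so
every point keeps only its highest level of protection, ordered along the
IUCN management gradient Ia (strict nature reserve) → VI (sustainable
use) → Unknown.  Coverage of a 3D realm is then the protected area within
it divided by its total area, as a percentage:

    coverage_i = 100 × protected_area_i / realm_area_i

computed both for all categories together ("all") and for strict
protection only ("Ia_Ib": MPAs of categories Ia/Ib).
"""

from __future__ import annotations

import json
from dataclasses import dataclass, replace

import numpy as np
import pandas as pd
import shapely
from shapely.geometry import mapping, shape
from shapely.geometry.base import BaseGeometry
from shapely.ops import unary_union

from .grid_geometry import DEFAULT_GEODESY, GeodesyConstants, GridSpec, cell_area_grid_km2
from .realms import (
    BathymetryGrid,
    DepthRealmScheme,
    EcoregionMap,
    classify_benthic_grid,
    default_benthic_scheme,
    default_pelagic_scheme,
)

__all__ = [
    "CATEGORIES",
    "DEFAULT_PRIORITY",
    "ProtectedAreaRecord",
    "flatten_by_priority",
    "rasterize_protection",
    "coverage_by_realm",
    "read_protected_areas_geojson",
    "write_protected_areas_geojson",
]

CATEGORIES: tuple[str, ...] = ("Ia", "Ib", "II", "III", "IV", "V", "VI", "Unknown")
#: Highest protection first; OECMs compete in the same ordering.
DEFAULT_PRIORITY: tuple[str, ...] = CATEGORIES
KINDS = ("MPA", "OECM")


@dataclass(frozen=True)
class ProtectedAreaRecord:
    """One designation: polygon, IUCN category, and MPA/OECM kind.

    Categories reported as Not Applicable / Not Reported / Not Assigned
    must be mapped to ``Unknown`` before construction.  Point-only records
    (reported area but unknown boundary) are not representable: a real
    polygon geometry is required, since a buffered circle would fabricate
    bathymetric coverage.
    """

    id: str
    geometry: BaseGeometry
    category: str
    kind: str = "MPA"

    def __post_init__(self) -> None:
        if self.category not in CATEGORIES:
            raise ValueError(f"unknown IUCN category {self.category!r}")
        if self.kind not in KINDS and self.kind != "mixed":
            raise ValueError(f"kind must be one of {KINDS}")
        geom = self.geometry
        if geom.geom_type not in ("Polygon", "MultiPolygon", "GeometryCollection"):
            raise ValueError(
                f"record {self.id!r}: polygon geometry required, got {geom.geom_type}"
            )
        if not geom.is_valid:
            repaired = shapely.make_valid(geom)
            if not repaired.is_valid or repaired.is_empty:
                raise ValueError(f"record {self.id!r}: geometry could not be repaired")
            object.__setattr__(self, "geometry", repaired)


def flatten_by_priority(
    records: list[ProtectedAreaRecord],
    order: tuple[str, ...] = DEFAULT_PRIORITY,
    simplify_tolerance_deg: float | None = None,
) -> list[ProtectedAreaRecord]:
    """Resolve overlaps, keeping the highest-priority designation everywhere.

    Dissolves the records of each category into one layer, then subtracts
    the union of all higher-priority layers, mirroring the sequential
    Ia − Ib − II … differencing used to de-duplicate protected-area
    databases.  The output layers are pairwise disjoint, cover exactly the
    union of the inputs, and are independent of input record order.
    """
    present = {r.category for r in records}
    missing = present - set(order)
    if missing:
        raise ValueError(f"priority order does not cover categories {sorted(missing)}")
    if sorted(order) != sorted(set(order)):
        raise ValueError("priority order contains duplicates")

    out: list[ProtectedAreaRecord] = []
    claimed: BaseGeometry | None = None
    for cat in order:
        geoms = [r.geometry for r in records if r.category == cat]
        if not geoms:
            continue
        if simplify_tolerance_deg:
            geoms = [g.simplify(simplify_tolerance_deg) for g in geoms]
        layer = unary_union(geoms)
        if claimed is not None:
            layer = layer.difference(claimed)
        if not layer.is_empty:
            kinds = {r.kind for r in records if r.category == cat}
            kind = kinds.pop() if len(kinds) == 1 else "mixed"
            out.append(ProtectedAreaRecord(f"flat_{cat}", layer, cat, kind))
        claimed = layer if claimed is None else unary_union([claimed, layer])
    return out


def rasterize_protection(
    flat: list[ProtectedAreaRecord], spec: GridSpec
) -> np.ndarray:
    """Category index (into ``CATEGORIES``) per cell; -1 where unprotected.

    A cell belongs to the polygon covering its center.  Cell centers that
    land exactly on a shared boundary of the (disjoint) flattened layers
    resolve to the higher-priority layer.
    """
    lon, lat = np.meshgrid(spec.lon_centers(), spec.lat_centers())
    out = np.full(spec.shape, -1, dtype=int)
    by_cat = {r.category: r.geometry for r in flat}
    for cat in CATEGORIES:
        if cat not in by_cat:
            continue
        hit = shapely.intersects_xy(by_cat[cat], lon.ravel(), lat.ravel()).reshape(spec.shape)
        out = np.where((out == -1) & hit, CATEGORIES.index(cat), out)
    return out


def _coverage_rows(
    protected: np.ndarray,
    group: str,
    depth: np.ndarray,
    eco_idx: np.ndarray,
    areas: np.ndarray,
    ecoregions: EcoregionMap,
    benthic_scheme: DepthRealmScheme,
    pelagic_scheme: DepthRealmScheme,
    realm_areas: pd.DataFrame,
) -> list[tuple]:
    ocean = np.isfinite(depth) & (depth > 0) & (eco_idx >= 0)
    band_idx = classify_benthic_grid(depth, benthic_scheme)
    prot_area: dict[tuple[str, str, str], float] = {}
    for b, band in enumerate(benthic_scheme.bands):
        sel = ocean & protected & (band_idx == b)
        if sel.any():
            for e, a in pd.Series(areas[sel]).groupby(eco_idx[sel]).sum().items():
                prot_area[(ecoregions.labels[int(e)], band.name, "benthic")] = float(a)
    for band in pelagic_scheme.bands:
        sel = ocean & protected & (depth > band.shallow_m)
        if sel.any():
            for e, a in pd.Series(areas[sel]).groupby(eco_idx[sel]).sum().items():
                prot_area[(ecoregions.labels[int(e)], band.name, "pelagic")] = float(a)
    rows = []
    for _, r in realm_areas.iterrows():
        key = (r["ecoregion"], r["band"], r["domain"])
        pa = prot_area.get(key, 0.0)
        rows.append(
            (*key, group, pa, float(r["area_km2"]), 100.0 * pa / float(r["area_km2"]))
        )
    return rows


def coverage_by_realm(
    records: list[ProtectedAreaRecord],
    bathymetry: BathymetryGrid,
    ecoregions: EcoregionMap,
    benthic_scheme: DepthRealmScheme | None = None,
    pelagic_scheme: DepthRealmScheme | None = None,
    order: tuple[str, ...] = DEFAULT_PRIORITY,
    realm_areas: pd.DataFrame | None = None,
    constants: GeodesyConstants = DEFAULT_GEODESY,
    simplify_tolerance_deg: float | None = None,
    per_category: bool = True,
) -> pd.DataFrame:
    """Protection coverage per 3D realm and category group.

    The depth realms protected by a cell follow its bathymetry: the cell's
    benthic band, plus every pelagic band above the seabed.  Groups:

    * ``all`` — every category including Unknown, MPAs and OECMs flattened
      in a single pass;
    * ``Ia_Ib`` — strict protection: MPAs of categories Ia/Ib only;
    * ``cat:<C>`` (optional) — area whose *highest-priority* designation
      is category C, from the all-records flattening.

    Returns rows (ecoregion, band, domain, group, protected_area_km2,
    realm_area_km2, coverage_pct); realms of zero area are absent.
    """
    from .realms import enumerate_realms3d

    benthic_scheme = benthic_scheme or default_benthic_scheme()
    pelagic_scheme = pelagic_scheme or default_pelagic_scheme()
    spec = bathymetry.spec
    depth = bathymetry.depth()
    areas = cell_area_grid_km2(spec, constants)
    eco_idx = ecoregions.rasterize(spec)
    if realm_areas is None:
        realm_areas = enumerate_realms3d(
            bathymetry, ecoregions, benthic_scheme, pelagic_scheme,
            constants, ecoregion_index=eco_idx,
        )

    flat_all = flatten_by_priority(records, order, simplify_tolerance_deg)
    cat_all = rasterize_protection(flat_all, spec)
    strict_records = [
        r for r in records if r.kind == "MPA" and r.category in ("Ia", "Ib")
    ]
    flat_strict = flatten_by_priority(strict_records, order, simplify_tolerance_deg)
    cat_strict = rasterize_protection(flat_strict, spec)

    common = (depth, eco_idx, areas, ecoregions, benthic_scheme, pelagic_scheme, realm_areas)
    rows = _coverage_rows(cat_all >= 0, "all", *common)
    rows += _coverage_rows(cat_strict >= 0, "Ia_Ib", *common)
    if per_category:
        for c, cat in enumerate(CATEGORIES):
            if (cat_all == c).any():
                rows += _coverage_rows(cat_all == c, f"cat:{cat}", *common)
    out = pd.DataFrame(
        rows,
        columns=["ecoregion", "band", "domain", "group",
                 "protected_area_km2", "realm_area_km2", "coverage_pct"],
    )
    return out.sort_values(["group", "domain", "ecoregion", "band"], ignore_index=True)


# ---------------------------------------------------------------------------
# I/O

def write_protected_areas_geojson(records: list[ProtectedAreaRecord], path) -> None:
    feats = [
        {"type": "Feature",
         "properties": {"id": r.id, "category": r.category, "kind": r.kind},
         "geometry": mapping(r.geometry)}
        for r in records
    ]
    with open(path, "w", encoding="utf-8") as fh:
        json.dump({"type": "FeatureCollection", "features": feats}, fh)


#: WDPA-style attribute spellings accepted on read.
_CATEGORY_ALIASES = {
    "not applicable": "Unknown",
    "not reported": "Unknown",
    "not assigned": "Unknown",
    "unknown": "Unknown",
}


def read_protected_areas_geojson(
    path, column_map: dict[str, str] | None = None
) -> list[ProtectedAreaRecord]:
    """Read records from GeoJSON; ``column_map`` renames WDPA-style
    property names (e.g. ``{"IUCN_CAT": "category", "WDPAID": "id"}``)."""
    column_map = column_map or {}
    with open(path, encoding="utf-8") as fh:
        gj = json.load(fh)
    records = []
    for i, feat in enumerate(gj["features"]):
        props = {column_map.get(k, k): v for k, v in feat["properties"].items()}
        cat = str(props.get("category", "Unknown"))
        cat = _CATEGORY_ALIASES.get(cat.lower(), cat)
        records.append(
            ProtectedAreaRecord(
                id=str(props.get("id", i)),
                geometry=shape(feat["geometry"]),
                category=cat,
                kind=str(props.get("kind", "MPA")),
            )
        )
    return records
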