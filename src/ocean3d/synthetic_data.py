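"""Seeded synthetic seascapes with generator-known ground truth.

Real inputs for a 3D ocean assessment are multi-gigabyte downloads
(global bathymetry, protected-area databases, vessel-tracking effort
grids).  This module fabricates small seascapes with the same structure —
a shelf-to-abyss bathymetry grid, coastal/offshore ecoregion polygons,
overlapping protected-area rectangles with IUCN categories, and
bathymetry-structured fishing events — while recording, by direct
per-cell and per-event bookkeeping that never touches the analysis
modules, the realm areas, protection coverages, and fishing effort the
pipeline is expected to recover.

Everything is driven by one integer seed; a fixed seed reproduces the
seascape bit for bit.  Fishing hours are quantized to 1/64 h so that
effort sums are exact in floating point regardless of summation order.
"""

from __future__ import annotations

import json
import math
from dataclasses import asdict, dataclass, field, replace
from pathlib import Path

import numpy as np
import pandas as pd
from scipy import ndimage
from shapely.geometry import box

from .fishing import GearCatalog, GearSpec, default_gear_catalog
from .grid_geometry import GridSpec
from .protection import CATEGORIES, ProtectedAreaRecord, write_protected_areas_geojson
from .realms import BathymetryGrid, EcoregionMap
from ._io import write_ascii_grid

__all__ = [
    "GearNiche",
    "SeascapeParams",
    "GroundTruth",
    "Seascape",
    "simulate_bathymetry",
    "simulate_ecoregions",
    "simulate_protected_areas",
    "simulate_fishing_events",
    "simulate_seascape",
    "write_seascape",
]

# band bounds restated locally so ground-truth tallies share no code with
# the classification modules they are used to check
_BENTHIC_BOUNDS = [
    ("euphotic", 0.0, 30.0),
    ("upper_mesophotic", 30.0, 60.0),
    ("lower_mesophotic", 60.0, 150.0),
    ("rariphotic", 150.0, 300.0),
    ("upper_bathyal", 300.0, 1000.0),
    ("lower_bathyal", 1000.0, 3500.0),
    ("abyssal", 3500.0, 6000.0),
    ("hadal", 6000.0, math.inf),
]
_PELAGIC_BOUNDS = [
    ("epipelagic", 0.0, 200.0),
    ("mesopelagic", 200.0, 1000.0),
    ("bathypelagic", 1000.0, 3500.0),
    ("abyssopelagic", 3500.0, 6000.0),
    ("hadopelagic", 6000.0, math.inf),
]
_HOURS_QUANTUM = 1.0 / 64.0


@dataclass(frozen=True)
class GearNiche:
    """Bathymetric niche of a simulated gear.

    Event locations are drawn with weight ``exp(-decay · |ln d − ln
    preferred_depth|)`` over seabed depth d, so ``decay = 0`` is uniform
    over the ocean and larger values concentrate the gear around its
    preferred depth.  ``weight`` is the gear's share of events.
    """

    preferred_depth_m: float
    decay: float
    weight: float


def _default_protection_targets() -> dict[str, float]:
    # depth profile anchored on reported global coverages (euphotic 15%,
    # abyssal 5.8%) with uncovered rariphotic gaps, well-protected but
    # lightly fished deep realms, and one well-protected heavily fished
    # band (lower mesophotic) so every priority profile occurs
    return {
        "euphotic": 0.15,
        "upper_mesophotic": 0.08,
        "lower_mesophotic": 0.25,
        "rariphotic": 0.05,
        "upper_bathyal": 0.09,
        "lower_bathyal": 0.25,
        "abyssal": 0.058,
        "hadal": 0.30,
    }


def _default_category_mix() -> dict[str, float]:
    # most coverage under category VI or Unknown, little under Ia/Ib
    return {
        "Ia": 0.04, "Ib": 0.04, "II": 0.10, "III": 0.05,
        "IV": 0.15, "V": 0.12, "VI": 0.30, "Unknown": 0.20,
    }


def _default_gear_niches() -> dict[str, GearNiche]:
    # trawling dominates shallow seabeds, drifting longlines deep water;
    # generic labels ("trawlers", "fishing") carry the unspecified share
    return {
        "bottom_trawl": GearNiche(100.0, 1.2, 0.18),
        "set_longline": GearNiche(300.0, 1.0, 0.07),
        "pot": GearNiche(50.0, 1.5, 0.05),
        "drifting_longline": GearNiche(4000.0, 1.0, 0.15),
        "midwater_trawl": GearNiche(4000.0, 0.8, 0.10),
        "trawlers": GearNiche(150.0, 1.0, 0.25),
        "fishing": GearNiche(1000.0, 0.5, 0.20),
    }


@dataclass(frozen=True)
class SeascapeParams:
    """All knobs of the synthetic seascape; defaults give a 100 × 100
    grid at 0.05° spanning every benthic band, three years of events, and
    45% of fishing hours under depth-unspecified gear labels."""

    resolution_deg: float = 0.05
    lat0: float = 0.0
    lon0: float = 0.0
    n_rows: int = 100
    n_cols: int = 100
    seed: int = 0
    land_cols: int = 3
    shelf_width_cells: int = 25
    min_depth_m: float = 5.0
    shelf_break_m: float = 200.0
    max_depth_m: float = 7500.0
    noise_sigma: float = 0.05
    noise_scale_cells: float = 6.0
    n_coastal: int = 2
    n_offshore: int = 2
    protection_targets: dict[str, float] = field(default_factory=_default_protection_targets)
    category_mix: dict[str, float] = field(default_factory=_default_category_mix)
    oecm_fraction: float = 0.15
    overlap_rate: float = 0.2
    years: tuple[int, ...] = (2018, 2019, 2020)
    n_events_per_year: int = 2000
    unspecified_fraction: float = 0.45
    gear_niches: dict[str, GearNiche] = field(default_factory=_default_gear_niches)
    hours_median: float = 2.0
    hours_sigma: float = 1.0

    def __post_init__(self) -> None:
        for name, frac in self.protection_targets.items():
            if not 0.0 <= frac <= 1.0:
                raise ValueError(f"protection target for {name!r} outside [0, 1]")
        for frac in (self.oecm_fraction, self.overlap_rate, self.unspecified_fraction):
            if not 0.0 <= frac <= 1.0:
                raise ValueError("fractions must lie in [0, 1]")
        if not 0 < self.min_depth_m < self.shelf_break_m < self.max_depth_m:
            raise ValueError("need 0 < min_depth < shelf_break < max_depth")

    def grid_spec(self) -> GridSpec:
        return GridSpec(self.resolution_deg, self.lat0, self.lon0, self.n_rows, self.n_cols)

    def to_json(self, path) -> None:
        d = asdict(self)
        d["gear_niches"] = {k: asdict(v) for k, v in self.gear_niches.items()}
        with open(path, "w", encoding="utf-8") as fh:
            json.dump(d, fh, indent=2)

    @classmethod
    def from_json(cls, path) -> "SeascapeParams":
        with open(path, encoding="utf-8") as fh:
            d = json.load(fh)
        d["gear_niches"] = {k: GearNiche(**v) for k, v in d["gear_niches"].items()}
        d["years"] = tuple(d["years"])
        return cls(**d)


# ---------------------------------------------------------------------------
# ground-truth helpers (deliberately self-contained)

def _gt_cell_areas(spec: GridSpec) -> np.ndarray:
    """Per-cell km² by the height × width formula, restated locally."""
    res = spec.resolution_deg
    height_m = res * 60.0 * 1852.0
    lat = spec.lat0 + (np.arange(spec.n_rows) + 0.5) * res
    perimeter_m = 2.0 * np.pi * 6378.0 * 1000.0 * np.cos(np.radians(lat))
    width_m = np.maximum(perimeter_m, 0.0) / (360.0 / res)
    return np.broadcast_to((height_m * width_m * 1e-6)[:, None], spec.shape).copy()


def _gt_benthic_index(depth: np.ndarray) -> np.ndarray:
    deeps = np.array([d for _, _, d in _BENTHIC_BOUNDS])
    idx = np.searchsorted(deeps, depth, side="left")
    return np.where(np.isfinite(depth) & (depth > 0), idx, -1).astype(int)


@dataclass
class GroundTruth:
    """What the generator knows the pipeline should recover."""

    eco_index: np.ndarray          # per-cell ecoregion index, -1 = land
    eco_labels: list[str]
    cell_areas_km2: np.ndarray
    realm_areas: pd.DataFrame      # ecoregion, band, domain, area_km2
    coverage: pd.DataFrame         # + group, coverage_pct
    pressure: pd.DataFrame         # ecoregion, band, domain, gear, year, effort, pressure
    unspecified_fraction: float
    protected_all: np.ndarray | None = None
    protected_strict: np.ndarray | None = None


def _gt_realm_areas(depth, eco_index, eco_labels, areas) -> pd.DataFrame:
    rows = []
    bidx = _gt_benthic_index(depth)
    ocean = np.isfinite(depth) & (depth > 0) & (eco_index >= 0)
    for b, (name, _, _) in enumerate(_BENTHIC_BOUNDS):
        sel = ocean & (bidx == b)
        if sel.any():
            for e, a in pd.Series(areas[sel]).groupby(eco_index[sel]).sum().items():
                rows.append((eco_labels[int(e)], name, "benthic", float(a)))
    for name, shallow, _ in _PELAGIC_BOUNDS:
        sel = ocean & (depth > shallow)
        if sel.any():
            for e, a in pd.Series(areas[sel]).groupby(eco_index[sel]).sum().items():
                rows.append((eco_labels[int(e)], name, "pelagic", float(a)))
    return pd.DataFrame(rows, columns=["ecoregion", "band", "domain", "area_km2"])


# ---------------------------------------------------------------------------
# generators

def simulate_bathymetry(params: SeascapeParams) -> BathymetryGrid:
    """Shelf-to-abyss elevation grid spanning all eight benthic bands.

    A land margin of ``land_cols`` columns sits at the western edge; ocean
    depth then increases eastward, log-uniformly from ``min_depth_m`` to
    the shelf break over ``shelf_width_cells`` columns and on to
    ``max_depth_m`` over the rest.  Seeded smooth multiplicative noise
    (log-normal, spatially correlated over ``noise_scale_cells``) adds
    within-column relief; with ``noise_sigma = 0`` depth is strictly
    monotone with distance from the coast.
    """
    spec = params.grid_spec()
    rng = np.random.default_rng(params.seed)
    n_ocean = params.n_cols - params.land_cols
    if n_ocean < 2:
        raise ValueError("grid too narrow for an ocean")
    n_shelf = min(params.shelf_width_cells, n_ocean - 1)
    j = np.arange(n_ocean, dtype=float)
    log_depth = np.empty(n_ocean)
    shelf = j[: n_shelf] / n_shelf
    log_depth[: n_shelf] = (
        math.log(params.min_depth_m)
        + shelf * (math.log(params.shelf_break_m) - math.log(params.min_depth_m))
    )
    slope = (j[n_shelf:] - n_shelf) / (n_ocean - 1 - n_shelf)
    log_depth[n_shelf:] = (
        math.log(params.shelf_break_m)
        + slope * (math.log(params.max_depth_m) - math.log(params.shelf_break_m))
    )
    base = np.broadcast_to(np.exp(log_depth)[None, :], (params.n_rows, n_ocean)).copy()
    if params.noise_sigma > 0:
        raw = rng.standard_normal((params.n_rows, n_ocean))
        smooth = ndimage.gaussian_filter(raw, sigma=params.noise_scale_cells, mode="reflect")
        smooth /= max(smooth.std(), 1e-12)
        base *= np.exp(params.noise_sigma * smooth)
    else:
        rng.standard_normal((params.n_rows, n_ocean))  # keep the seed stream aligned
    elevation = np.full(spec.shape, 30.0)
    elevation[:, params.land_cols:] = -base
    return BathymetryGrid(spec, elevation)


def _coastal_boundary_col(params: SeascapeParams, bathymetry: BathymetryGrid) -> int:
    """First column east of every cell shallower than the shelf break."""
    depth = bathymetry.depth()
    shallow_cols = np.where(np.nanmax(np.where(depth <= params.shelf_break_m, 1, 0), axis=0))[0]
    last = int(shallow_cols.max()) if shallow_cols.size else params.land_cols
    return min(last + 1, params.n_cols - 1)


def _row_splits(n_rows: int, n_parts: int) -> list[int]:
    return [round(i * n_rows / n_parts) for i in range(n_parts + 1)]


def simulate_ecoregions(params: SeascapeParams, bathymetry: BathymetryGrid) -> EcoregionMap:
    """Tile the seascape into coastal and offshore ecoregion rectangles.

    Coastal ecoregions span from the western (land) edge to the first
    column beyond which no cell is shallower than the shelf break, so
    they contain every cell shallower than 200 m; offshore ecoregions
    tile the remaining columns.  Each group is split into latitudinal
    strips along cell edges, so the polygons tile the ocean exactly.
    """
    spec = params.grid_spec()
    cb = _coastal_boundary_col(params, bathymetry)
    lon_edges = spec.lon_edges()
    lat_edges = spec.lat_edges()
    labels, classes, geoms = [], [], []
    splits = _row_splits(params.n_rows, params.n_coastal)
    for i, (r0, r1) in enumerate(zip(splits, splits[1:])):
        labels.append(f"coastal_{i}")
        classes.append("coastal")
        geoms.append(box(lon_edges[0], lat_edges[r0], lon_edges[cb], lat_edges[r1]))
    splits = _row_splits(params.n_rows, params.n_offshore)
    for i, (r0, r1) in enumerate(zip(splits, splits[1:])):
        labels.append(f"offshore_{i}")
        classes.append("offshore")
        geoms.append(box(lon_edges[cb], lat_edges[r0], lon_edges[-1], lat_edges[r1]))
    return EcoregionMap(labels, classes, geoms)


def _gt_eco_index(params: SeascapeParams, bathymetry: BathymetryGrid) -> tuple[np.ndarray, list[str]]:
    """Generator's own per-cell ecoregion assignment (no geometry tests)."""
    cb = _coastal_boundary_col(params, bathymetry)
    out = np.full(params.grid_spec().shape, -1, dtype=int)
    splits_c = _row_splits(params.n_rows, params.n_coastal)
    splits_o = _row_splits(params.n_rows, params.n_offshore)
    labels = [f"coastal_{i}" for i in range(params.n_coastal)] + [
        f"offshore_{i}" for i in range(params.n_offshore)
    ]
    for i, (r0, r1) in enumerate(zip(splits_c, splits_c[1:])):
        out[r0:r1, :cb] = i
    for i, (r0, r1) in enumerate(zip(splits_o, splits_o[1:])):
        out[r0:r1, cb:] = params.n_coastal + i
    out[~bathymetry.ocean_mask] = -1
    return out, labels


def simulate_protected_areas(
    params: SeascapeParams, bathymetry: BathymetryGrid
) -> tuple[list[ProtectedAreaRecord], dict[str, np.ndarray]]:
    """Place protected rectangles to hit per-band coverage targets.

    For each benthic band, contiguous cell runs are selected (rows in
    seeded random order) until ``round(target × band cells)`` cells are
    protected, and each run becomes a cell-edge-aligned rectangle with a
    category drawn from the configured mix and an MPA/OECM kind.  A
    fraction ``overlap_rate`` of rectangles gets a second, overlapping
    designation of a different category to exercise flattening without
    changing the union.  Returns the records plus the generator's own
    per-cell truth masks ``{"all": …, "strict": …}`` (strict = covered by
    an Ia/Ib MPA).  Raises if a target exceeds the band's extent.
    """
    spec = params.grid_spec()
    rng = np.random.default_rng(params.seed + 1)
    depth = bathymetry.depth()
    bidx = _gt_benthic_index(depth)
    lon_edges, lat_edges = spec.lon_edges(), spec.lat_edges()
    cats = list(params.category_mix)
    probs = np.array([params.category_mix[c] for c in cats], dtype=float)
    probs /= probs.sum()

    records: list[ProtectedAreaRecord] = []
    all_mask = np.zeros(spec.shape, dtype=bool)
    strict_mask = np.zeros(spec.shape, dtype=bool)
    rec_id = 0
    for b, (band, _, _) in enumerate(_BENTHIC_BOUNDS):
        target = params.protection_targets.get(band, 0.0)
        cells = bidx == b
        n_band = int(cells.sum())
        if n_band == 0:
            if target > 0:
                raise ValueError(f"band {band!r} absent from the seascape but has a target")
            continue
        n_target = round(target * n_band)
        if n_target > n_band:
            raise ValueError(f"target for {band!r} exceeds the band's extent")
        remaining = n_target
        for r in rng.permutation(params.n_rows):
            if remaining <= 0:
                break
            cols = np.where(cells[r])[0]
            if cols.size == 0:
                continue
            # contiguous runs of band cells in this row
            breaks = np.where(np.diff(cols) > 1)[0]
            runs = np.split(cols, breaks + 1)
            for run in runs:
                if remaining <= 0:
                    break
                take = run[: remaining]
                remaining -= take.size
                c0, c1 = int(take[0]), int(take[-1])
                geom = box(lon_edges[c0], lat_edges[r], lon_edges[c1 + 1], lat_edges[r + 1])
                category = cats[rng.choice(len(cats), p=probs)]
                kind = "OECM" if rng.random() < params.oecm_fraction else "MPA"
                records.append(ProtectedAreaRecord(f"pa_{rec_id}", geom, category, kind))
                rec_id += 1
                all_mask[r, c0 : c1 + 1] = True
                if kind == "MPA" and category in ("Ia", "Ib"):
                    strict_mask[r, c0 : c1 + 1] = True
                if rng.random() < params.overlap_rate:
                    # conflicting overlapping designation, same footprint
                    other = cats[rng.choice(len(cats), p=probs)]
                    records.append(
                        ProtectedAreaRecord(f"pa_{rec_id}", geom, other, "MPA")
                    )
                    rec_id += 1
                    if other in ("Ia", "Ib"):
                        strict_mask[r, c0 : c1 + 1] = True
    return records, {"all": all_mask, "strict": strict_mask}


def _gt_coverage(
    masks: dict[str, np.ndarray],
    depth: np.ndarray,
    eco_index: np.ndarray,
    eco_labels: list[str],
    areas: np.ndarray,
    realm_areas: pd.DataFrame,
) -> pd.DataFrame:
    bidx = _gt_benthic_index(depth)
    ocean = np.isfinite(depth) & (depth > 0) & (eco_index >= 0)
    rows = []
    for group, mask in (("all", masks["all"]), ("Ia_Ib", masks["strict"])):
        prot: dict[tuple[str, str, str], float] = {}
        for b, (band, _, _) in enumerate(_BENTHIC_BOUNDS):
            sel = ocean & mask & (bidx == b)
            if sel.any():
                for e, a in pd.Series(areas[sel]).groupby(eco_index[sel]).sum().items():
                    prot[(eco_labels[int(e)], band, "benthic")] = float(a)
        for band, shallow, _ in _PELAGIC_BOUNDS:
            sel = ocean & mask & (depth > shallow)
            if sel.any():
                for e, a in pd.Series(areas[sel]).groupby(eco_index[sel]).sum().items():
                    prot[(eco_labels[int(e)], band, "pelagic")] = float(a)
        for _, r in realm_areas.iterrows():
            key = (r["ecoregion"], r["band"], r["domain"])
            pa = prot.get(key, 0.0)
            rows.append((*key, group, pa, float(r["area_km2"]),
                         100.0 * pa / float(r["area_km2"])))
    return pd.DataFrame(
        rows, columns=["ecoregion", "band", "domain", "group",
                       "protected_area_km2", "realm_area_km2", "coverage_pct"],
    )


def simulate_fishing_events(
    params: SeascapeParams, bathymetry: BathymetryGrid
) -> tuple[pd.DataFrame, pd.DataFrame, float]:
    """Sample fishing events with bathymetry-structured gear niches.

    Events are placed on ocean cells with per-gear log-depth weights (see
    :class:`GearNiche`), uniformly jittered within the cell, with
    log-normal hours quantized to 1/64 h.  Hours of depth-unspecified
    gears are rescaled (then re-quantized) so their share of total hours
    hits ``unspecified_fraction``.  Returns ``(events,
    ground-truth effort table, realized unspecified fraction)``; the
    effort table holds hours per (ecoregion, band, domain, gear, year)
    under the impacted (surface-to-seabed) attribution, tallied directly
    from the sampled cells.
    """
    spec = params.grid_spec()
    rng = np.random.default_rng(params.seed + 2)
    depth = bathymetry.depth()
    ocean_rows, ocean_cols = np.where(bathymetry.ocean_mask)
    d_ocean = depth[ocean_rows, ocean_cols]
    catalog = default_gear_catalog()

    frames = []
    for gear in sorted(params.gear_niches):
        niche = params.gear_niches[gear]
        w = np.exp(-niche.decay * np.abs(np.log(d_ocean) - math.log(niche.preferred_depth_m)))
        p = w / w.sum()
        for year in params.years:
            n = round(params.n_events_per_year * niche.weight)
            if n == 0:
                continue
            pick = rng.choice(d_ocean.size, size=n, p=p)
            u = rng.uniform(0.1, 0.9, size=(2, n))
            lon = spec.lon0 + (ocean_cols[pick] + u[0]) * spec.resolution_deg
            lat = spec.lat0 + (ocean_rows[pick] + u[1]) * spec.resolution_deg
            hours = rng.lognormal(math.log(params.hours_median), params.hours_sigma, n)
            frames.append(
                pd.DataFrame(
                    {
                        "lon": lon, "lat": lat, "year": year,
                        "hours": np.round(hours / _HOURS_QUANTUM) * _HOURS_QUANTUM,
                        "gear": gear,
                        "vessel_id": rng.integers(10**8, 10**9, n).astype(str),
                        "_row": ocean_rows[pick], "_col": ocean_cols[pick],
                    }
                )
            )
    events = pd.concat(frames, ignore_index=True)
    events.loc[events["hours"] <= 0, "hours"] = _HOURS_QUANTUM

    # rescale unspecified-gear hours to the configured share of total hours
    modes = events["gear"].map(lambda g: catalog[g].mode if g in catalog else "unspecified")
    unspec = (modes == "unspecified").to_numpy()
    s_spec = float(events.loc[~unspec, "hours"].sum())
    s_unspec = float(events.loc[unspec, "hours"].sum())
    f = params.unspecified_fraction
    if unspec.any() and s_unspec > 0 and 0 < f < 1:
        factor = f * s_spec / ((1.0 - f) * s_unspec)
        scaled = events.loc[unspec, "hours"] * factor
        events.loc[unspec, "hours"] = np.maximum(
            np.round(scaled / _HOURS_QUANTUM) * _HOURS_QUANTUM, _HOURS_QUANTUM
        )
    realized = float(events.loc[unspec, "hours"].sum()) / float(events["hours"].sum())

    # ground-truth effort tally under impacted attribution
    eco_index, eco_labels = _gt_eco_index(params, bathymetry)
    ev_depth = depth[events["_row"], events["_col"]]
    ev_eco = eco_index[events["_row"], events["_col"]]
    deeps = np.array([d for _, _, d in _BENTHIC_BOUNDS])
    ev_band = np.searchsorted(deeps, ev_depth, side="left")
    keep = ev_eco >= 0
    rows = []
    tally = events.loc[keep, ["gear", "year", "hours"]].copy()
    tally["eco"] = ev_eco[keep]
    tally["bband"] = ev_band[keep]
    g = tally.groupby(["eco", "bband", "gear", "year"], sort=True)["hours"].sum()
    for (e, b, gear, year), h in g.items():
        rows.append((eco_labels[int(e)], _BENTHIC_BOUNDS[int(b)][0], "benthic",
                     gear, int(year), float(h)))
    for band, shallow, _ in _PELAGIC_BOUNDS:
        sub = tally[ev_depth[keep] > shallow]
        g = sub.groupby(["eco", "gear", "year"], sort=True)["hours"].sum()
        for (e, gear, year), h in g.items():
            rows.append((eco_labels[int(e)], band, "pelagic", gear, int(year), float(h)))
    effort = pd.DataFrame(
        rows, columns=["ecoregion", "band", "domain", "gear", "year", "effort_hours"]
    )
    events = events.drop(columns=["_row", "_col"])
    # shuffle so downstream order-invariance is actually exercised
    events = events.sample(frac=1.0, random_state=int(rng.integers(2**31))).reset_index(drop=True)
    return events, effort, realized


# ---------------------------------------------------------------------------
# full seascape

@dataclass
class Seascape:
    params: SeascapeParams
    bathymetry: BathymetryGrid
    ecoregions: EcoregionMap
    protected_areas: list[ProtectedAreaRecord]
    events: pd.DataFrame
    gear_catalog: GearCatalog
    truth: GroundTruth


def simulate_seascape(params: SeascapeParams | None = None, seed: int | None = None) -> Seascape:
    """Generate a full seascape and its ground truth from one seed."""
    params = params or SeascapeParams()
    if seed is not None:
        params = replace(params, seed=seed)
    bathy = simulate_bathymetry(params)
    ecoregions = simulate_ecoregions(params, bathy)
    records, masks = simulate_protected_areas(params, bathy)
    events, effort, realized = simulate_fishing_events(params, bathy)

    depth = bathy.depth()
    eco_index, eco_labels = _gt_eco_index(params, bathy)
    areas = _gt_cell_areas(params.grid_spec())
    realm_areas = _gt_realm_areas(depth, eco_index, eco_labels, areas)
    coverage = _gt_coverage(masks, depth, eco_index, eco_labels, areas, realm_areas)
    area_lookup = realm_areas.set_index(["ecoregion", "band", "domain"])["area_km2"]
    key = pd.MultiIndex.from_frame(effort[["ecoregion", "band", "domain"]])
    pressure = effort.copy()
    pressure["pressure_hr_per_km2"] = (
        effort["effort_hours"].to_numpy() / area_lookup.reindex(key).to_numpy()
    )
    truth = GroundTruth(
        eco_index=eco_index,
        eco_labels=eco_labels,
        cell_areas_km2=areas,
        realm_areas=realm_areas,
        coverage=coverage,
        pressure=pressure,
        unspecified_fraction=realized,
        protected_all=masks["all"],
        protected_strict=masks["strict"],
    )
    return Seascape(params, bathy, ecoregions, records, events, default_gear_catalog(), truth)


def write_seascape(seascape: Seascape, directory) -> dict[str, Path]:
    """Write the seascape as the text formats the pipeline readers consume."""
    directory = Path(directory)
    directory.mkdir(parents=True, exist_ok=True)
    paths = {
        "bathymetry": directory / "bathymetry.asc",
        "ecoregions": directory / "ecoregions.geojson",
        "protected_areas": directory / "protected_areas.geojson",
        "events": directory / "events.csv",
        "gear_catalog": directory / "gear_catalog.csv",
        "params": directory / "params.json",
    }
    write_ascii_grid(seascape.bathymetry, paths["bathymetry"])
    seascape.ecoregions.to_geojson(paths["ecoregions"])
    write_protected_areas_geojson(seascape.protected_areas, paths["protected_areas"])
    seascape.events.to_csv(paths["events"], index=False)
    seascape.gear_catalog.to_csv(paths["gear_catalog"])
    seascape.params.to_json(paths["params"])
    return paths
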