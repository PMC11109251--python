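"""Depth attribution and aggregation of fishing effort.

Two attribution rules relate a fishing event (a located, timed number of
fishing hours with a gear label) to depth realms:

* **impacted** — every realm in the vertical column at the fishing
  location, surface to seabed: exactly one benthic band (the band of the
  local bathymetry) and all pelagic bands above the seabed.  Vertical
  connectivity (migrations, trophic cascades, by-catch, debris) justifies
  counting the whole column.
* **targeted** — only the realms a gear can actually reach.  Benthic
  gears target the benthic band of the seabed; pelagic gears target the
  pelagic bands intersecting their operating depth range clipped to the
  local bathymetry.  Gears that do not discriminate benthic from pelagic
  operation ("unspecified") are reported separately.

Fishing pressure on a 3D realm is effort divided by realm area
(hours km⁻² per year); effort totals are conserved exactly under the
impacted rule across benthic realms.
"""

from __future__ import annotations

import math
import warnings
from dataclasses import dataclass

import numpy as np
import pandas as pd
from scipy import stats

from .realms import (
    BathymetryGrid,
    DepthRealmScheme,
    EcoregionMap,
    classify_benthic,
    classify_benthic_grid,
    default_benthic_scheme,
    default_pelagic_scheme,
    pelagic_column,
)

__all__ = [
    "GearSpec",
    "GearCatalog",
    "default_gear_catalog",
    "impacted_realms",
    "targeted_realms",
    "pressure_by_realm",
    "interannual_stats",
    "gear_disaggregation_report",
]

EVENT_COLUMNS = ["lon", "lat", "year", "hours", "gear", "vessel_id"]

#: GFW-style event column spellings accepted on read.
GFW_COLUMN_MAP = {
    "cell_ll_lon": "lon",
    "cell_ll_lat": "lat",
    "fishing_hours": "hours",
    "geartype": "gear",
    "mmsi": "vessel_id",
    "date": "year",
}


@dataclass(frozen=True)
class GearSpec:
    """Operating mode and, for pelagic gears, depth range in meters."""

    name: str
    mode: str  # benthic | pelagic | unspecified
    depth_min_m: float | None = None
    depth_max_m: float | None = None

    def __post_init__(self) -> None:
        if self.mode not in ("benthic", "pelagic", "unspecified"):
            raise ValueError(f"gear {self.name!r}: unknown mode {self.mode!r}")
        if self.mode == "pelagic":
            if self.depth_min_m is None or self.depth_max_m is None:
                raise ValueError(f"pelagic gear {self.name!r} needs a depth range")
            if not (0 <= self.depth_min_m < self.depth_max_m):
                raise ValueError(f"gear {self.name!r}: need 0 <= depth_min < depth_max")


class GearCatalog(dict):
    """Mapping gear label → GearSpec with CSV round-trip."""

    def to_csv(self, path) -> None:
        pd.DataFrame(
            [
                {"name": g.name, "mode": g.mode,
                 "depth_min_m": g.depth_min_m, "depth_max_m": g.depth_max_m}
                for g in self.values()
            ]
        ).to_csv(path, index=False)

    @classmethod
    def from_csv(cls, path) -> "GearCatalog":
        df = pd.read_csv(path)
        cat = cls()
        for _, r in df.iterrows():
            dmin = None if pd.isna(r.get("depth_min_m")) else float(r["depth_min_m"])
            dmax = None if pd.isna(r.get("depth_max_m")) else float(r["depth_max_m"])
            cat[str(r["name"])] = GearSpec(str(r["name"]), str(r["mode"]), dmin, dmax)
        return cat


def default_gear_catalog() -> GearCatalog:
    """Default gear-depth catalog (editable; ship as CSV for review).

    Depth ranges for pelagic gears follow typical technical descriptions
    of each gear; generic labels that mix benthic and pelagic operation
    ("trawlers", "purse seines", "fishing") stay unspecified because the
    public activity data cannot disambiguate them.
    """
    specs = [
        GearSpec("bottom_trawl", "benthic"),
        GearSpec("set_longline", "benthic"),
        GearSpec("set_gillnet", "benthic"),
        GearSpec("pot", "benthic"),
        GearSpec("dredge", "benthic"),
        GearSpec("drifting_longline", "pelagic", 0.0, 400.0),
        GearSpec("midwater_trawl", "pelagic", 30.0, 1000.0),
        GearSpec("squid_jigger", "pelagic", 0.0, 400.0),
        GearSpec("pole_and_line", "pelagic", 0.0, 100.0),
        GearSpec("trawlers", "unspecified"),
        GearSpec("purse_seine", "unspecified"),
        GearSpec("fishing", "unspecified"),
    ]
    return GearCatalog({g.name: g for g in specs})


# ---------------------------------------------------------------------------
# single-event attribution

def impacted_realms(
    lon: float,
    lat: float,
    bathymetry: BathymetryGrid,
    benthic_scheme: DepthRealmScheme | None = None,
    pelagic_scheme: DepthRealmScheme | None = None,
) -> tuple[str, set[str]]:
    """Realms in the surface-to-seabed column at an event location."""
    depth = bathymetry.depth_at(lon, lat)
    if not np.isfinite(depth) or depth <= 0:
        raise ValueError(f"event at ({lon}, {lat}) falls on land or off the grid")
    return (
        classify_benthic(depth, benthic_scheme),
        pelagic_column(depth, pelagic_scheme),
    )


def targeted_realms(
    lon: float,
    lat: float,
    gear: GearSpec,
    bathymetry: BathymetryGrid,
    benthic_scheme: DepthRealmScheme | None = None,
    pelagic_scheme: DepthRealmScheme | None = None,
) -> tuple[set[str], str]:
    """Realms directly targeted by a gear at a location → (bands, domain).

    Benthic gears target the seabed's benthic band.  Pelagic gears target
    the pelagic bands whose open interval overlaps the gear range clipped
    to the water column, ``(depth_min, min(depth_max, seabed))``; a range
    touching a band only at its boundary point does not select it.  If the
    gear's minimum depth reaches the seabed the clipped range is empty —
    a catalog/bathymetry inconsistency — and the event is attributed to
    the pelagic band containing the seabed (the deepest reachable band),
    with a warning; an empty set is never returned.  Unspecified gears
    return ``(set(), "unspecified")``.
    """
    pelagic_scheme = pelagic_scheme or default_pelagic_scheme()
    if gear.mode == "unspecified":
        return set(), "unspecified"
    depth = bathymetry.depth_at(lon, lat)
    if not np.isfinite(depth) or depth <= 0:
        raise ValueError(f"event at ({lon}, {lat}) falls on land or off the grid")
    if gear.mode == "benthic":
        return {classify_benthic(depth, benthic_scheme)}, "benthic"
    eff_max = min(gear.depth_max_m, depth)
    if gear.depth_min_m >= eff_max:
        warnings.warn(
            f"gear {gear.name!r} range ({gear.depth_min_m}-{gear.depth_max_m} m) "
            f"does not overlap the water column at seabed depth {depth:.0f} m; "
            "attributing to the deepest reachable pelagic band",
            stacklevel=2,
        )
        reach = min(depth, gear.depth_max_m)
        idx = int(np.searchsorted(pelagic_scheme.deep_bounds(), reach, side="left"))
        return {pelagic_scheme.bands[idx].name}, "pelagic"
    bands = {
        b.name
        for b in pelagic_scheme.bands
        if gear.depth_min_m < b.deep_m and b.shallow_m < eff_max
    }
    return bands, "pelagic"


# ---------------------------------------------------------------------------
# aggregation

def _prepare_events(events: pd.DataFrame, bathymetry: BathymetryGrid, eco_idx: np.ndarray):
    """Locate events on the grid; returns (frame with row/col/depth/eco, counts)."""
    ev = events.reset_index(drop=True).copy()
    row, col = bathymetry.spec.locate(ev["lon"].to_numpy(), ev["lat"].to_numpy())
    depth = np.full(len(ev), np.nan)
    eco = np.full(len(ev), -1, dtype=int)
    on_grid = row >= 0
    d = bathymetry.depth()
    depth[on_grid] = d[row[on_grid], col[on_grid]]
    eco[on_grid] = eco_idx[row[on_grid], col[on_grid]]
    ocean = on_grid & np.isfinite(depth) & (depth > 0) & (eco >= 0)
    counts = {
        "events_total": int(len(ev)),
        "events_off_grid": int((~on_grid).sum()),
        "events_on_land": int((on_grid & ~(np.isfinite(depth) & (depth > 0))).sum()),
        "events_no_ecoregion": int(
            (on_grid & np.isfinite(depth) & (depth > 0) & (eco < 0)).sum()
        ),
    }
    ev["depth"] = depth
    ev["eco"] = eco
    return ev[ocean], counts


def _group_effort(ev: pd.DataFrame, labels: list[str], band: str, domain: str) -> pd.DataFrame:
    g = (
        ev.groupby(["eco", "gear", "year"], sort=True)["hours"]
        .sum()
        .reset_index()
    )
    g["ecoregion"] = [labels[int(e)] for e in g["eco"]]
    g["band"] = band
    g["domain"] = domain
    return g[["ecoregion", "band", "domain", "gear", "year", "hours"]]


def pressure_by_realm(
    events: pd.DataFrame,
    bathymetry: BathymetryGrid,
    ecoregions: EcoregionMap,
    benthic_scheme: DepthRealmScheme | None = None,
    pelagic_scheme: DepthRealmScheme | None = None,
    realm_areas: pd.DataFrame | None = None,
    attribution: str = "impacted",
    gear_catalog: GearCatalog | None = None,
    split_hours: bool = False,
    ecoregion_index: np.ndarray | None = None,
) -> tuple[pd.DataFrame, dict]:
    """Aggregate fishing effort and pressure per (3D realm, gear, year).

    Under ``impacted`` attribution every event contributes its full hours
    to exactly one benthic realm and to each pelagic realm in its column.
    Under ``targeted``, contributions follow :func:`targeted_realms`;
    events of unspecified or unknown gears appear with band and domain
    ``unspecified`` (effort only, no pressure).  By default an event
    targeting several pelagic bands counts its full hours in each band;
    ``split_hours=True`` divides them equally instead.

    Returns ``(table, excluded)`` where table rows are (ecoregion, band,
    domain, gear, year, effort_hours, pressure_hr_per_km2) and excluded
    counts land/off-grid/unknown-gear events.
    """
    from .realms import enumerate_realms3d

    benthic_scheme = benthic_scheme or default_benthic_scheme()
    pelagic_scheme = pelagic_scheme or default_pelagic_scheme()
    if attribution not in ("impacted", "targeted"):
        raise ValueError("attribution must be 'impacted' or 'targeted'")
    eco_idx = ecoregions.rasterize(bathymetry.spec) if ecoregion_index is None else ecoregion_index
    if realm_areas is None:
        realm_areas = enumerate_realms3d(
            bathymetry, ecoregions, benthic_scheme, pelagic_scheme,
            ecoregion_index=eco_idx,
        )
    ev, excluded = _prepare_events(events, bathymetry, eco_idx)
    labels = ecoregions.labels
    parts: list[pd.DataFrame] = []

    if attribution == "impacted":
        band_idx = classify_benthic_grid(ev["depth"].to_numpy(), benthic_scheme)
        for b, band in enumerate(benthic_scheme.bands):
            sub = ev[band_idx == b]
            if len(sub):
                parts.append(_group_effort(sub, labels, band.name, "benthic"))
        for band in pelagic_scheme.bands:
            sub = ev[ev["depth"].to_numpy() > band.shallow_m]
            if len(sub):
                parts.append(_group_effort(sub, labels, band.name, "pelagic"))
        excluded["events_unknown_gear"] = 0
    else:
        gear_catalog = gear_catalog or default_gear_catalog()
        unknown = ~ev["gear"].isin(gear_catalog.keys())
        excluded["events_unknown_gear"] = int(unknown.sum())
        modes = ev["gear"].map(
            lambda g: gear_catalog[g].mode if g in gear_catalog else "unspecified"
        )
        benthic_ev = ev[modes == "benthic"]
        if len(benthic_ev):
            band_idx = classify_benthic_grid(benthic_ev["depth"].to_numpy(), benthic_scheme)
            for b, band in enumerate(benthic_scheme.bands):
                sub = benthic_ev[band_idx == b]
                if len(sub):
                    parts.append(_group_effort(sub, labels, band.name, "benthic"))
        pelagic_ev = ev[modes == "pelagic"]
        for gear_name, sub in pelagic_ev.groupby("gear", sort=True):
            spec = gear_catalog[gear_name]
            depth = sub["depth"].to_numpy()
            eff_max = np.minimum(spec.depth_max_m, depth)
            degenerate = spec.depth_min_m >= eff_max
            if degenerate.any():
                warnings.warn(
                    f"{int(degenerate.sum())} event(s) of gear {gear_name!r} at seabeds "
                    "shallower than the gear's minimum depth; attributed to the deepest "
                    "reachable pelagic band",
                    stacklevel=2,
                )
            selected = []
            for band in pelagic_scheme.bands:
                hit = (~degenerate) & (spec.depth_min_m < band.deep_m) & (band.shallow_m < eff_max)
                reach = np.minimum(depth, spec.depth_max_m)
                hit |= degenerate & (band.shallow_m < reach) & (reach <= band.deep_m)
                selected.append(hit)
            selected = np.array(selected)  # (n_bands, n_events)
            n_bands_hit = selected.sum(axis=0)
            for k, band in enumerate(pelagic_scheme.bands):
                hit = selected[k]
                if hit.any():
                    part = sub[hit].copy()
                    if split_hours:
                        part["hours"] = part["hours"] / n_bands_hit[hit]
                    parts.append(_group_effort(part, labels, band.name, "pelagic"))
        unspec_ev = ev[modes == "unspecified"]
        if len(unspec_ev):
            parts.append(_group_effort(unspec_ev, labels, "unspecified", "unspecified"))

    if not parts:
        table = pd.DataFrame(
            columns=["ecoregion", "band", "domain", "gear", "year",
                     "effort_hours", "pressure_hr_per_km2"]
        )
        return table, excluded
    table = pd.concat(parts, ignore_index=True).rename(columns={"hours": "effort_hours"})
    table = (
        table.groupby(["ecoregion", "band", "domain", "gear", "year"], sort=True)[
            "effort_hours"
        ]
        .sum()
        .reset_index()
    )
    areas = realm_areas.set_index(["ecoregion", "band", "domain"])["area_km2"]
    key = pd.MultiIndex.from_frame(table[["ecoregion", "band", "domain"]])
    realm_area = areas.reindex(key).to_numpy()
    table["pressure_hr_per_km2"] = table["effort_hours"] / realm_area
    return table, excluded


def interannual_stats(
    yearly_values, confidence: float = 0.95
) -> tuple[float, float, float]:
    """Mean and symmetric t-based confidence interval across years.

    With fewer than two values the interval is undefined and returned as
    ``(mean, nan, nan)``.
    """
    v = np.asarray(list(yearly_values), dtype=float)
    if v.size == 0:
        raise ValueError("no yearly values")
    mean = float(v.mean())
    if v.size < 2:
        return mean, math.nan, math.nan
    half = float(
        stats.t.ppf((1 + confidence) / 2, df=v.size - 1) * v.std(ddof=1) / math.sqrt(v.size)
    )
    return mean, mean - half, mean + half


def gear_disaggregation_report(
    events: pd.DataFrame, catalog: GearCatalog | None = None
) -> dict[str, float]:
    """Fractions of total fishing hours by gear mode.

    Returns ``{"benthic": f, "pelagic": f, "unspecified": f}`` summing to 1;
    gears absent from the catalog count as unspecified.  With zero total
    hours the fractions are undefined and returned as NaN.
    """
    catalog = catalog or default_gear_catalog()
    modes = events["gear"].map(lambda g: catalog[g].mode if g in catalog else "unspecified")
    total = float(events["hours"].sum())
    out = {}
    for mode in ("benthic", "pelagic", "unspecified"):
        h = float(events.loc[modes == mode, "hours"].sum())
        out[mode] = h / total if total > 0 else math.nan
    return out


def read_events_csv(path, column_map: dict[str, str] | None = None) -> pd.DataFrame:
    """Read a fishing-event table from CSV, accepting GFW-style names."""
    df = pd.read_csv(path)
    df = df.rename(columns={**GFW_COLUMN_MAP, **(column_map or {})})
    missing = [c for c in ("lon", "lat", "year", "hours", "gear") if c not in df.columns]
    if missing:
        raise ValueError(f"event table missing columns: {missing}")
    if df["year"].dtype == object:  # ISO dates → calendar year
        df["year"] = pd.to_datetime(df["year"]).dt.year
    if "vessel_id" not in df.columns:
        df["vessel_id"] = ""
    if (df["hours"] < 0).any():
        raise ValueError("fishing hours must be non-negative")
    return df[EVENT_COLUMNS]
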