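"""End-to-end pipeline: realms → areas → protection → fishing → priorities.

``run_pipeline`` validates a :class:`PipelineConfig`, loads the four
inputs (bathymetry, ecoregions, protected areas, fishing events), runs
each stage in order, and writes five CSV tables plus a JSON run log to
the output directory.  Stage functions are importable on their own; the
pipeline only sequences them, so composing the CLI subcommands stage by
stage yields byte-identical outputs.
"""

from __future__ import annotations

import json
from dataclasses import asdict, dataclass, field
from pathlib import Path

import pandas as pd

from . import __version__
from ._io import read_ascii_grid
from .fishing import GearCatalog, default_gear_catalog, pressure_by_realm, read_events_csv
from .prioritization import build_summary, loglog_regression, prioritize, profile_shares
from .protection import coverage_by_realm, read_protected_areas_geojson
from .realms import (
    EcoregionMap,
    default_benthic_scheme,
    default_pelagic_scheme,
    enumerate_realms3d,
    DepthRealmScheme,
)

__all__ = ["PipelineConfig", "PipelineError", "run_pipeline"]

TABLES = ("realm_areas", "coverage", "pressure", "summary", "priority")


class PipelineError(RuntimeError):
    """A stage failed; the message names the stage."""

    def __init__(self, stage: str, message: str):
        super().__init__(f"[{stage}] {message}")
        self.stage = stage


@dataclass
class PipelineConfig:
    bathymetry: str
    ecoregions: str
    protected_areas: str
    events: str
    output_dir: str
    gear_catalog: str | None = None
    benthic_scheme: str | None = None      # JSON scheme file; None = default
    pelagic_scheme: str | None = None
    merge_deepest_pelagic: bool = False
    attribution: str = "impacted"          # impacted | targeted
    assessment: str = "all"                # all | strict
    halfway_pct: float | None = None
    simplify_tolerance_deg: float | None = None
    split_hours: bool = False
    seed: int = 0

    def validate(self) -> None:
        if self.attribution not in ("impacted", "targeted"):
            raise PipelineError("config", f"unknown attribution {self.attribution!r}")
        if self.assessment not in ("all", "strict"):
            raise PipelineError("config", f"unknown assessment {self.assessment!r}")
        for name in ("bathymetry", "ecoregions", "protected_areas", "events"):
            path = getattr(self, name)
            if not Path(path).is_file():
                raise PipelineError("config", f"{name} path does not exist: {path}")
        for name in ("gear_catalog", "benthic_scheme", "pelagic_scheme"):
            path = getattr(self, name)
            if path is not None and not Path(path).is_file():
                raise PipelineError("config", f"{name} path does not exist: {path}")

    @classmethod
    def from_json(cls, path) -> "PipelineConfig":
        with open(path, encoding="utf-8") as fh:
            raw = json.load(fh)
        known = set(cls.__dataclass_fields__)
        unknown = set(raw) - known
        if unknown:
            raise PipelineError("config", f"unknown config keys: {sorted(unknown)}")
        return cls(**raw)


def _write_csv(df: pd.DataFrame, path: Path) -> None:
    df.to_csv(path, index=False, lineterminator="\n")


def run_pipeline(config: PipelineConfig) -> dict[str, Path]:
    """Run every stage and write the output tables; returns their paths."""
    config.validate()
    out_dir = Path(config.output_dir)
    out_dir.mkdir(parents=True, exist_ok=True)
    log: dict = {"ocean3d_version": __version__, "config": asdict(config), "stages": {}}

    try:
        bathy = read_ascii_grid(config.bathymetry)
        ecoregions = EcoregionMap.from_geojson(config.ecoregions)
        records = read_protected_areas_geojson(config.protected_areas)
        events = read_events_csv(config.events)
        catalog = (
            GearCatalog.from_csv(config.gear_catalog)
            if config.gear_catalog
            else default_gear_catalog()
        )
        benthic = (
            DepthRealmScheme.from_json(config.benthic_scheme)
            if config.benthic_scheme
            else default_benthic_scheme()
        )
        pelagic = (
            DepthRealmScheme.from_json(config.pelagic_scheme)
            if config.pelagic_scheme
            else default_pelagic_scheme(merge_deepest=config.merge_deepest_pelagic)
        )
    except PipelineError:
        raise
    except Exception as exc:  # noqa: BLE001 - rewrap with the stage name
        raise PipelineError("load", str(exc)) from exc

    paths = {name: out_dir / f"{name}.csv" for name in TABLES}
    try:
        eco_idx = ecoregions.rasterize(bathy.spec)
        realm_areas = enumerate_realms3d(
            bathy, ecoregions, benthic, pelagic, ecoregion_index=eco_idx
        )
        _write_csv(realm_areas, paths["realm_areas"])
        log["stages"]["realms"] = {"n_realms": int(len(realm_areas))}
    except Exception as exc:  # noqa: BLE001
        raise PipelineError("realms", str(exc)) from exc

    try:
        coverage = coverage_by_realm(
            records, bathy, ecoregions, benthic, pelagic,
            realm_areas=realm_areas,
            simplify_tolerance_deg=config.simplify_tolerance_deg,
        )
        _write_csv(coverage, paths["coverage"])
        log["stages"]["protection"] = {"n_records": len(records)}
    except Exception as exc:  # noqa: BLE001
        raise PipelineError("protection", str(exc)) from exc

    try:
        pressure, excluded = pressure_by_realm(
            events, bathy, ecoregions, benthic, pelagic,
            realm_areas=realm_areas, attribution=config.attribution,
            gear_catalog=catalog, split_hours=config.split_hours,
            ecoregion_index=eco_idx,
        )
        _write_csv(pressure, paths["pressure"])
        log["stages"]["fishing"] = excluded
    except Exception as exc:  # noqa: BLE001
        raise PipelineError("fishing", str(exc)) from exc

    try:
        summary = build_summary(coverage, pressure)
        _write_csv(summary, paths["summary"])
        priority = prioritize(summary, config.assessment, config.halfway_pct)
        _write_csv(priority, paths["priority"])
        shares = profile_shares(priority["profile"], priority["area_km2"])
        log["stages"]["prioritization"] = {
            "n_realms": int(len(priority)),
            "profile_shares": shares.set_index("profile")["realm_share"].to_dict(),
        }
        try:
            reg = loglog_regression(summary)
            log["stages"]["prioritization"]["regression"] = asdict(reg)
        except ValueError as exc:
            log["stages"]["prioritization"]["regression"] = {"undefined": str(exc)}
    except PipelineError:
        raise
    except Exception as exc:  # noqa: BLE001
        raise PipelineError("prioritization", str(exc)) from exc

    log_path = out_dir / "run_log.json"
    with open(log_path, "w", encoding="utf-8") as fh:
        json.dump(log, fh, indent=2, sort_keys=True)
    paths["run_log"] = log_path
    return paths
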