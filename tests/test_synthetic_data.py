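"""Seascape generator: determinism, structure, and ground-truth recovery."""

import dataclasses

import numpy as np
import pandas as pd
import pytest
from shapely.ops import unary_union

from ocean3d import flatten_by_priority, pressure_by_realm
from ocean3d.synthetic_data import (
    GearNiche,
    SeascapeParams,
    simulate_bathymetry,
    simulate_ecoregions,
    simulate_fishing_events,
    simulate_protected_areas,
    simulate_seascape,
)


class TestBathymetry:
    def test_all_eight_benthic_bands_present(self, seascape):
        depth = seascape.bathymetry.depth()
        bounds = [0, 30, 60, 150, 300, 1000, 3500, 6000, np.inf]
        for lo, hi in zip(bounds, bounds[1:]):
            assert ((depth > lo) & (depth <= hi)).sum() > 0, (lo, hi)

    def test_same_seed_reproduces_bit_identically(self):
        a = simulate_bathymetry(SeascapeParams(seed=3))
        b = simulate_bathymetry(SeascapeParams(seed=3))
        assert np.array_equal(a.elevation, b.elevation)

    def test_different_seed_differs(self):
        a = simulate_bathymetry(SeascapeParams(seed=3))
        b = simulate_bathymetry(SeascapeParams(seed=4))
        assert not np.array_equal(a.elevation, b.elevation)

    def test_zero_noise_gives_monotone_shelf(self):
        params = SeascapeParams(noise_sigma=0.0)
        depth = simulate_bathymetry(params).depth()
        ocean = depth[:, params.land_cols:]
        assert (np.diff(ocean, axis=1) > 0).all()

    def test_land_margin_has_nonnegative_elevation(self, seascape):
        params = seascape.params
        assert (seascape.bathymetry.elevation[:, : params.land_cols] >= 0).all()


class TestEcoregions:
    def test_tiling_assigns_every_ocean_cell_exactly_once(self, seascape):
        spec = seascape.bathymetry.spec
        idx = seascape.ecoregions.rasterize(spec)
        assert (idx[seascape.bathymetry.ocean_mask] >= 0).all()
        # strips are disjoint: total polygon area equals the union area
        geoms = seascape.ecoregions.geometries
        assert sum(g.area for g in geoms) == pytest.approx(unary_union(geoms).area, rel=1e-9)

    def test_requested_counts(self, seascape):
        classes = seascape.ecoregions.classes
        assert classes.count("coastal") == seascape.params.n_coastal
        assert classes.count("offshore") == seascape.params.n_offshore

    def test_coastal_ecoregions_contain_all_shelf_cells(self, seascape):
        spec = seascape.bathymetry.spec
        depth = seascape.bathymetry.depth()
        idx = seascape.ecoregions.rasterize(spec)
        shelf = seascape.bathymetry.ocean_mask & (depth <= 200.0)
        classes = np.array(seascape.ecoregions.classes)
        assert (classes[idx[shelf]] == "coastal").all()

    def test_generator_assignment_matches_polygon_rasterization(self, seascape):
        # land cells are -1 in the truth; the polygon test only has to agree
        # over the ocean, where all downstream tallies happen
        idx = seascape.ecoregions.rasterize(seascape.bathymetry.spec)
        ocean = seascape.bathymetry.ocean_mask
        assert np.array_equal(idx[ocean], seascape.truth.eco_index[ocean])
        assert (seascape.truth.eco_index[~ocean] == -1).all()


class TestProtectedAreas:
    def test_band_targets_hit_within_one_cell(self, seascape):
        from ocean3d.synthetic_data import _gt_benthic_index, _BENTHIC_BOUNDS

        depth = seascape.bathymetry.depth()
        bidx = _gt_benthic_index(depth)
        mask = seascape.truth.protected_all
        for b, (band, _, _) in enumerate(_BENTHIC_BOUNDS):
            n_band = (bidx == b).sum()
            n_prot = (mask & (bidx == b)).sum()
            target = seascape.params.protection_targets[band]
            assert abs(n_prot - target * n_band) <= 1.0

    def test_unreachable_target_rejected(self):
        with pytest.raises(ValueError):
            SeascapeParams(protection_targets={"euphotic": 1.5})

    def test_no_overlap_leaves_flattening_area_neutral(self):
        params = SeascapeParams(overlap_rate=0.0, seed=5)
        bathy = simulate_bathymetry(params)
        records, _ = simulate_protected_areas(params, bathy)
        flat = flatten_by_priority(records)
        raw_union = unary_union([r.geometry for r in records])
        per_cat_raw = {
            cat: unary_union([r.geometry for r in records if r.category == cat]).area
            for cat in {r.category for r in records}
        }
        for r in flat:
            assert r.geometry.area <= per_cat_raw[r.category] + 1e-9
        assert unary_union([r.geometry for r in flat]).area == pytest.approx(
            raw_union.area, rel=1e-9
        )

    def test_coverage_recovered_by_protection_module(self, seascape):
        from ocean3d import coverage_by_realm

        cov = coverage_by_realm(
            seascape.protected_areas, seascape.bathymetry, seascape.ecoregions,
            per_category=False,
        )
        key = ["group", "domain", "ecoregion", "band"]
        got = cov.sort_values(key, ignore_index=True)
        want = seascape.truth.coverage.sort_values(key, ignore_index=True)
        pd.testing.assert_frame_equal(got, want, check_exact=True)


class TestFishingEvents:
    def test_unspecified_share_matches_configuration(self, seascape):
        assert seascape.truth.unspecified_fraction == pytest.approx(0.45, abs=1e-3)

    def test_uniform_niche_gives_uniform_pressure(self):
        params = SeascapeParams(
            seed=12,
            years=(2019,),
            n_events_per_year=10_000,
            unspecified_fraction=0.0,
            hours_sigma=0.3,
            gear_niches={"bottom_trawl": GearNiche(100.0, 0.0, 1.0)},
            n_coastal=1,
            n_offshore=1,
        )
        sea = simulate_seascape(params)
        table, _ = pressure_by_realm(sea.events, sea.bathymetry, sea.ecoregions)
        benthic = table[table["domain"] == "benthic"]
        effort = benthic.groupby("band")["effort_hours"].sum()
        areas = (
            sea.truth.realm_areas.query("domain == 'benthic'")
            .groupby("band")["area_km2"]
            .sum()
        )
        pressures = effort / areas
        # uniform sampling over cells → pressure equal across bands up to
        # Monte-Carlo error (relative error shrinks like 1/sqrt(events per band))
        assert pressures.max() / pressures.min() < 1.6

    def test_effort_table_matches_pipeline_exactly(self, seascape):
        table, _ = pressure_by_realm(
            seascape.events, seascape.bathymetry, seascape.ecoregions,
            attribution="impacted",
        )
        key = ["ecoregion", "band", "domain", "gear", "year"]
        got = table.sort_values(key, ignore_index=True)
        got["year"] = got["year"].astype(int)
        want = seascape.truth.pressure.sort_values(key, ignore_index=True)
        pd.testing.assert_frame_equal(got, want, check_exact=True)


class TestDeterminism:
    def test_full_seascape_reproducible(self, small_params):
        a = simulate_seascape(small_params)
        b = simulate_seascape(small_params)
        assert np.array_equal(a.bathymetry.elevation, b.bathymetry.elevation)
        pd.testing.assert_frame_equal(a.events, b.events)
        assert [r.geometry.wkt for r in a.protected_areas] == [
            r.geometry.wkt for r in b.protected_areas
        ]
        pd.testing.assert_frame_equal(a.truth.pressure, b.truth.pressure)

    def test_params_json_round_trip(self, small_params, tmp_path):
        path = tmp_path / "params.json"
        small_params.to_json(path)
        assert SeascapeParams.from_json(path) == small_params


def test_seascape_exercises_every_category_and_profile(seascape):
    cats = {r.category for r in seascape.protected_areas}
    assert cats == {"Ia", "Ib", "II", "III", "IV", "V", "VI", "Unknown"}
    from ocean3d import build_summary, prioritize

    summary = build_summary(seascape.truth.coverage, seascape.truth.pressure)
    out = prioritize(summary, "all")
    assert set(out["profile"]) == {
        "highest_priority", "lowest_priority",
        "fills_conservation_gaps", "mitigates_fishing_pressure",
    }
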