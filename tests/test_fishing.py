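"""Fishing-event depth attribution and pressure aggregation."""

import numpy as np
import pandas as pd
import pytest

from ocean3d import (
    GearSpec,
    default_gear_catalog,
    gear_disaggregation_report,
    impacted_realms,
    interannual_stats,
    pressure_by_realm,
    targeted_realms,
)
from ocean3d.fishing import GearCatalog, read_events_csv

from conftest import flat_grid, one_ecoregion


@pytest.fixture(scope="module")
def step_grid():
    """Depths 3000, 100, 7000, 400, 150 m plus a land cell."""
    return flat_grid([3000.0, 100.0, 7000.0, 400.0, 150.0, -1.0])


def lon_of(grid, col):
    return grid.spec.lon0 + (col + 0.5) * grid.spec.resolution_deg


LAT = 0.005  # row-center latitude of the 1-row fixture grids


class TestImpacted:
    def test_column_over_3000_m(self, step_grid):
        benthic, pelagic = impacted_realms(lon_of(step_grid, 0), LAT, step_grid)
        assert benthic == "lower_bathyal"
        assert pelagic == {"epipelagic", "mesopelagic", "bathypelagic"}

    def test_column_over_100_m(self, step_grid):
        benthic, pelagic = impacted_realms(lon_of(step_grid, 1), LAT, step_grid)
        assert benthic == "lower_mesophotic"
        assert pelagic == {"epipelagic"}

    def test_column_over_7000_m(self, step_grid):
        benthic, pelagic = impacted_realms(lon_of(step_grid, 2), LAT, step_grid)
        assert benthic == "hadal"
        assert len(pelagic) == 5

    def test_land_event_rejected(self, step_grid):
        with pytest.raises(ValueError):
            impacted_realms(lon_of(step_grid, 5), LAT, step_grid)


class TestTargeted:
    GEAR = GearSpec("test_pelagic", "pelagic", 30.0, 350.0)

    def test_pelagic_gear_at_400_m_seabed(self, step_grid):
        bands, domain = targeted_realms(lon_of(step_grid, 3), LAT, self.GEAR, step_grid)
        assert domain == "pelagic"
        assert bands == {"epipelagic", "mesopelagic"}

    def test_same_gear_at_150_m_seabed(self, step_grid):
        bands, _ = targeted_realms(lon_of(step_grid, 4), LAT, self.GEAR, step_grid)
        assert bands == {"epipelagic"}

    def test_benthic_gear_targets_seabed_band(self, step_grid):
        gear = GearSpec("bottom_trawl", "benthic")
        bands, domain = targeted_realms(lon_of(step_grid, 0), LAT, gear, step_grid)
        assert (bands, domain) == ({"lower_bathyal"}, "benthic")

    def test_unspecified_gear_flagged(self, step_grid):
        gear = GearSpec("fishing", "unspecified")
        bands, domain = targeted_realms(lon_of(step_grid, 0), LAT, gear, step_grid)
        assert (bands, domain) == (set(), "unspecified")

    def test_range_touching_band_boundary_does_not_select_it(self, step_grid):
        # gear reaching exactly 200 m never selects the mesopelagic
        gear = GearSpec("shallow", "pelagic", 0.0, 200.0)
        bands, _ = targeted_realms(lon_of(step_grid, 0), LAT, gear, step_grid)
        assert bands == {"epipelagic"}

    def test_gear_deeper_than_seabed_warns_and_keeps_deepest_band(self, step_grid):
        gear = GearSpec("deep_only", "pelagic", 500.0, 800.0)
        with pytest.warns(UserWarning, match="does not overlap"):
            bands, _ = targeted_realms(lon_of(step_grid, 3), LAT, gear, step_grid)
        assert bands == {"mesopelagic"}  # seabed 400 m sits in the mesopelagic

    def test_targeted_subset_of_impacted(self, seascape):
        catalog = seascape.gear_catalog
        sample = seascape.events.head(300)
        for _, ev in sample.iterrows():
            gear = catalog[ev["gear"]]
            if gear.mode != "pelagic":
                continue
            bands, _ = targeted_realms(ev["lon"], ev["lat"], gear, seascape.bathymetry)
            _, impacted = impacted_realms(ev["lon"], ev["lat"], seascape.bathymetry)
            assert bands <= impacted


class TestPressure:
    def test_pressure_is_effort_over_area(self, step_grid):
        ecos = one_ecoregion(step_grid.spec)
        events = pd.DataFrame(
            {"lon": [lon_of(step_grid, 0)], "lat": [LAT], "year": [2019],
             "hours": [10.0], "gear": ["bottom_trawl"], "vessel_id": ["v"]}
        )
        table, excluded = pressure_by_realm(events, step_grid, ecos)
        row = table[(table["band"] == "lower_bathyal")].iloc[0]
        from ocean3d import enumerate_realms3d

        areas = enumerate_realms3d(step_grid, ecos).set_index(["band", "domain"])
        area = areas.loc[("lower_bathyal", "benthic"), "area_km2"]
        assert row["effort_hours"] == 10.0
        assert row["pressure_hr_per_km2"] == pytest.approx(10.0 / area, rel=1e-12)
        assert excluded["events_on_land"] == 0

    def test_no_events_gives_empty_table(self, step_grid):
        ecos = one_ecoregion(step_grid.spec)
        events = pd.DataFrame(columns=["lon", "lat", "year", "hours", "gear", "vessel_id"])
        table, _ = pressure_by_realm(events, step_grid, ecos)
        assert table.empty

    def test_matches_per_event_loop(self, small_seascape):
        from ocean3d import classify_benthic, pelagic_column

        sea = small_seascape
        table, _ = pressure_by_realm(
            sea.events, sea.bathymetry, sea.ecoregions, attribution="impacted"
        )
        eco_idx = sea.ecoregions.rasterize(sea.bathymetry.spec)
        expected: dict[tuple, float] = {}
        for _, ev in sea.events.iterrows():
            row, col = sea.bathymetry.spec.locate(ev["lon"], ev["lat"])
            d = sea.bathymetry.depth()[int(row), int(col)]
            eco = sea.ecoregions.labels[eco_idx[int(row), int(col)]]
            key = (eco, classify_benthic(d), "benthic", ev["gear"], ev["year"])
            expected[key] = expected.get(key, 0.0) + ev["hours"]
            for band in pelagic_column(d):
                key = (eco, band, "pelagic", ev["gear"], ev["year"])
                expected[key] = expected.get(key, 0.0) + ev["hours"]
        got = table.set_index(["ecoregion", "band", "domain", "gear", "year"])[
            "effort_hours"
        ].to_dict()
        assert got == expected  # hours are 1/64-quantized, sums are exact

    def test_hours_conserved_over_benthic_realms(self, seascape):
        table, excluded = pressure_by_realm(
            seascape.events, seascape.bathymetry, seascape.ecoregions
        )
        benthic_total = table[table["domain"] == "benthic"]["effort_hours"].sum()
        assert excluded["events_on_land"] == 0
        assert benthic_total == seascape.events["hours"].sum()

    def test_event_order_does_not_matter(self, small_seascape):
        sea = small_seascape
        a, _ = pressure_by_realm(sea.events, sea.bathymetry, sea.ecoregions)
        shuffled = sea.events.sample(frac=1.0, random_state=9).reset_index(drop=True)
        b, _ = pressure_by_realm(shuffled, sea.bathymetry, sea.ecoregions)
        pd.testing.assert_frame_equal(a, b)

    def test_land_events_excluded_and_counted(self, step_grid):
        ecos = one_ecoregion(step_grid.spec)
        events = pd.DataFrame(
            {"lon": [lon_of(step_grid, 0), lon_of(step_grid, 5)], "lat": [LAT, LAT],
             "year": [2019, 2019], "hours": [1.0, 2.0],
             "gear": ["fishing", "fishing"], "vessel_id": ["a", "b"]}
        )
        table, excluded = pressure_by_realm(events, step_grid, ecos)
        assert excluded["events_on_land"] == 1
        assert table[table["domain"] == "benthic"]["effort_hours"].sum() == 1.0

    def test_unknown_gear_reported_unspecified_under_targeted(self, step_grid):
        ecos = one_ecoregion(step_grid.spec)
        events = pd.DataFrame(
            {"lon": [lon_of(step_grid, 0)], "lat": [LAT], "year": [2019],
             "hours": [3.0], "gear": ["mystery_gear"], "vessel_id": ["v"]}
        )
        table, excluded = pressure_by_realm(events, step_grid, ecos, attribution="targeted")
        assert excluded["events_unknown_gear"] == 1
        assert list(table["domain"]) == ["unspecified"]
        assert table["effort_hours"].iloc[0] == 3.0

    def test_split_hours_divides_among_targeted_bands(self, step_grid):
        ecos = one_ecoregion(step_grid.spec)
        events = pd.DataFrame(
            {"lon": [lon_of(step_grid, 3)], "lat": [LAT], "year": [2019],
             "hours": [10.0], "gear": ["deep_drifter"], "vessel_id": ["v"]}
        )
        catalog = GearCatalog({"deep_drifter": GearSpec("deep_drifter", "pelagic", 30.0, 350.0)})
        full, _ = pressure_by_realm(
            events, step_grid, ecos, attribution="targeted", gear_catalog=catalog
        )
        assert sorted(full["band"]) == ["epipelagic", "mesopelagic"]
        assert (full["effort_hours"] == 10.0).all()  # full hours in each band
        split, _ = pressure_by_realm(
            events, step_grid, ecos, attribution="targeted",
            gear_catalog=catalog, split_hours=True,
        )
        assert (split["effort_hours"] == 5.0).all()


class TestStats:
    def test_constant_years(self):
        mean, lo, hi = interannual_stats([2, 2, 2])
        assert (mean, lo, hi) == (2.0, 2.0, 2.0)

    def test_three_year_confidence_interval(self):
        # t(0.975, df=2) = 4.3027; sd = 1; half-width = 4.3027 / sqrt(3)
        mean, lo, hi = interannual_stats([1, 2, 3], confidence=0.95)
        assert mean == 2.0
        assert hi - mean == pytest.approx(2.484, abs=1e-3)
        assert mean - lo == pytest.approx(hi - mean, rel=1e-12)

    def test_single_year_has_no_interval(self):
        mean, lo, hi = interannual_stats([5.0])
        assert mean == 5.0 and np.isnan(lo) and np.isnan(hi)


class TestDisaggregation:
    def test_all_benthic(self):
        events = pd.DataFrame({"gear": ["bottom_trawl"] * 3, "hours": [1, 2, 3]})
        report = gear_disaggregation_report(events)
        assert report == {"benthic": 1.0, "pelagic": 0.0, "unspecified": 0.0}

    def test_even_benthic_unspecified_split(self):
        events = pd.DataFrame(
            {"gear": ["bottom_trawl", "fishing"], "hours": [4.0, 4.0]}
        )
        report = gear_disaggregation_report(events)
        assert report == {"benthic": 0.5, "pelagic": 0.0, "unspecified": 0.5}

    def test_zero_hours_undefined(self):
        events = pd.DataFrame({"gear": ["fishing"], "hours": [0.0]})
        report = gear_disaggregation_report(events)
        assert all(np.isnan(v) for v in report.values())

    def test_generator_fraction_recovered(self, seascape):
        report = gear_disaggregation_report(seascape.events, seascape.gear_catalog)
        assert report["unspecified"] == seascape.truth.unspecified_fraction
        assert report["unspecified"] == pytest.approx(0.45, abs=1e-3)
        assert sum(report.values()) == pytest.approx(1.0, rel=1e-12)


def test_events_csv_round_trip(small_seascape, tmp_path):
    path = tmp_path / "events.csv"
    small_seascape.events.to_csv(path, index=False)
    back = read_events_csv(path)
    pd.testing.assert_frame_equal(
        back.astype({"vessel_id": str}), small_seascape.events
    )


def test_gear_catalog_csv_round_trip(tmp_path):
    catalog = default_gear_catalog()
    path = tmp_path / "gears.csv"
    catalog.to_csv(path)
    assert GearCatalog.from_csv(path) == catalog
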