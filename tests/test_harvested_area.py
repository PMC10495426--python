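"""Reference-map extension, disintegration re-attribution, gridding, and
national matching of harvested areas."""

import numpy as np
import pandas as pd
import pytest

from nfert.grid import DisintegrationEvent
from nfert.harvested_area import (
    HareaCube, county_sums, disaggregate_to_grid, extend_harvested_area,
    handle_disintegration, match_national_totals,
)
from nfert.vocab import DEFAULT_VOCAB

from _toys import panel, toy_cropland, toy_hierarchy

YEARS = [1999, 2000, 2001]


class TestExtendHarvestedArea:
    def setup_method(self):
        self.grid, self.h = toy_hierarchy(n_countries=1, counties_per_country=2)
        self.ref = pd.DataFrame([[100.0, 40.0]], index=["Wheat"],
                                columns=list(self.h.counties))

    def test_reference_year_reproduces_reference_map(self):
        nat = panel([("Wheat", "C00")], YEARS, [[140.0, 140.0, 140.0]])
        out = extend_harvested_area(self.ref, nat, self.h)
        np.testing.assert_allclose(out[2000].to_numpy(), [100.0, 40.0])

    def test_national_ratio_scales_counties(self):
        nat = panel([("Wheat", "C00")], YEARS, [[100.0, 100.0, 150.0]])
        out = extend_harvested_area(self.ref, nat, self.h)
        # 100 ha x 150/100 national ratio -> 150 ha
        assert out.loc[("Wheat", "C00-00"), 2001] == pytest.approx(150.0)
        # both counties share the same national factor
        factors = out[2001] / out[2000]
        np.testing.assert_allclose(factors.to_numpy(), 1.5)

    def test_zero_reference_year_spreads_uniformly(self, caplog):
        nat = panel([("Wheat", "C00")], YEARS, [[0.0, 0.0, 80.0]])
        ref = pd.DataFrame([[0.0, 0.0]], index=["Wheat"],
                           columns=list(self.h.counties))
        out = extend_harvested_area(ref, nat, self.h)
        np.testing.assert_allclose(out[2001].to_numpy(), [40.0, 40.0])
        np.testing.assert_allclose(out[2000].to_numpy(), [0.0, 0.0])


class TestHandleDisintegration:
    def test_single_successor_inherits_everything(self):
        ev = DisintegrationEvent(parent="P", year=1991, successors=("A",))
        nat = panel(
            [("Wheat", "P"), ("Wheat", "A")], [1990, 1991],
            [[70.0, np.nan], [np.nan, 65.0]],
        )
        out = handle_disintegration(nat, (ev,))
        assert out.loc[("Wheat", "A"), 1990] == pytest.approx(70.0)
        assert "P" not in out.index.get_level_values(1)

    def test_split_by_first_post_split_shares(self):
        ev = DisintegrationEvent(parent="P", year=1991, successors=("A", "B"))
        nat = panel(
            [("Wheat", "P"), ("Wheat", "A"), ("Wheat", "B")],
            [1989, 1990, 1991],
            [[200.0, 100.0, np.nan], [np.nan, np.nan, 30.0], [np.nan, np.nan, 70.0]],
        )
        out = handle_disintegration(nat, (ev,))
        # parent-era totals split 30% / 70%
        assert out.loc[("Wheat", "A"), 1990] == pytest.approx(30.0)
        assert out.loc[("Wheat", "B"), 1990] == pytest.approx(70.0)
        assert out.loc[("Wheat", "A"), 1989] == pytest.approx(60.0)
        # post-split years untouched
        assert out.loc[("Wheat", "A"), 1991] == pytest.approx(30.0)

    def test_all_zero_successors_split_equally(self, caplog):
        ev = DisintegrationEvent(parent="P", year=1991, successors=("A", "B"))
        nat = panel(
            [("Wheat", "P"), ("Wheat", "A"), ("Wheat", "B")],
            [1990, 1991],
            [[100.0, np.nan], [np.nan, 0.0], [np.nan, 0.0]],
        )
        out = handle_disintegration(nat, (ev,))
        assert out.loc[("Wheat", "A"), 1990] == pytest.approx(50.0)
        assert out.loc[("Wheat", "B"), 1990] == pytest.approx(50.0)


class TestDisaggregateToGrid:
    def test_single_cell_county_gets_everything(self):
        grid, h = toy_hierarchy(n_countries=1, counties_per_country=2,
                                rows_per=1, cols_per=1)
        cropland = toy_cropland(grid, [2000])
        table = panel([("Wheat", "C00-00"), ("Wheat", "C00-01")], [2000],
                      [[80.0], [20.0]])
        cube = disaggregate_to_grid(table, cropland, h, grid)
        np.testing.assert_allclose(cube.values[0, 0], [[80.0, 20.0]])

    def test_proportional_to_upland_cropland(self):
        grid, h = toy_hierarchy(n_countries=1, counties_per_country=1,
                                rows_per=1, cols_per=2)
        upland = np.array([[30.0, 70.0]])
        cropland = toy_cropland(grid, [2000], upland=upland)
        table = panel([("Wheat", "C00-00")], [2000], [[100.0]])
        cube = disaggregate_to_grid(table, cropland, h, grid)
        np.testing.assert_allclose(cube.values[0, 0], [[30.0, 70.0]])

    def test_rice_follows_rice_layer(self):
        grid, h = toy_hierarchy(n_countries=1, counties_per_country=1,
                                rows_per=1, cols_per=2)
        cropland = toy_cropland(grid, [2000], rice=np.array([[90.0, 10.0]]),
                                upland=np.array([[10.0, 90.0]]))
        table = panel([("Rice", "C00-00"), ("Wheat", "C00-00")], [2000],
                      [[100.0], [100.0]])
        cube = disaggregate_to_grid(table, cropland, h, grid)
        rice = cube.values[cube.crops.index("Rice"), 0]
        wheat = cube.values[cube.crops.index("Wheat"), 0]
        np.testing.assert_allclose(rice, [[90.0, 10.0]])
        np.testing.assert_allclose(wheat, [[10.0, 90.0]])

    def test_zero_cropland_falls_back_to_uniform(self):
        grid, h = toy_hierarchy(n_countries=1, counties_per_country=1,
                                rows_per=1, cols_per=2)
        cropland = toy_cropland(grid, [2000], upland=np.zeros((1, 2)))
        table = panel([("Wheat", "C00-00")], [2000], [[100.0]])
        cube = disaggregate_to_grid(table, cropland, h, grid)
        np.testing.assert_allclose(cube.values[0, 0], [[50.0, 50.0]])


class TestMatchNationalTotals:
    def _cube(self, values, grid):
        return HareaCube(crops=("Wheat",), years=np.array([2000]),
                         values=np.asarray(values, dtype=float))

    def test_matching_cube_unchanged(self):
        grid, h = toy_hierarchy(n_countries=1, counties_per_country=1,
                                rows_per=1, cols_per=2)
        cube = self._cube([[[[40.0, 60.0]]]], grid)
        nat = panel([("Wheat", "C00")], [2000], [[100.0]])
        out = match_national_totals(cube, nat, h)
        np.testing.assert_allclose(out.values, cube.values)

    def test_single_factor_rescale(self):
        grid, h = toy_hierarchy(n_countries=1, counties_per_country=1,
                                rows_per=1, cols_per=2)
        cube = self._cube([[[[40.0, 50.0]]]], grid)     # sums to 90
        nat = panel([("Wheat", "C00")], [2000], [[99.0]])
        out = match_national_totals(cube, nat, h)
        np.testing.assert_allclose(out.values[0, 0], [[44.0, 55.0]])
        assert out.values.sum() == pytest.approx(99.0)

    def test_zero_target_zeroes_cells(self):
        grid, h = toy_hierarchy(n_countries=1, counties_per_country=1,
                                rows_per=1, cols_per=2)
        cube = self._cube([[[[40.0, 50.0]]]], grid)
        nat = panel([("Wheat", "C00")], [2000], [[0.0]])
        out = match_national_totals(cube, nat, h)
        np.testing.assert_allclose(out.values, 0.0)


class TestPipelineProperties:
    def test_mass_conservation_under_noise(self, noisy_result):
        """National sums of the matched cube equal the statistics to 1e-9
        for every crop and year."""
        report = noisy_result.report.conservation
        assert report.loc["harea_vs_national", "max_rel_err"] <= 1e-9

    def test_doubling_national_series_doubles_cube(self):
        grid, h = toy_hierarchy(n_countries=1, counties_per_country=2)
        cropland = toy_cropland(grid, YEARS)
        ref = pd.DataFrame([[100.0, 40.0]], index=["Wheat"],
                           columns=list(h.counties))
        nat = panel([("Wheat", "C00")], YEARS, [[100.0, 120.0, 150.0]])
        c1 = match_national_totals(
            disaggregate_to_grid(extend_harvested_area(ref, nat, h),
                                 cropland, h, grid), nat, h, cropland)
        nat2 = nat * 2
        c2 = match_national_totals(
            disaggregate_to_grid(extend_harvested_area(ref, nat2, h),
                                 cropland, h, grid), nat2, h, cropland)
        np.testing.assert_allclose(c2.values, 2 * c1.values, rtol=1e-12)

    def test_noise_free_recovery_of_truth(self, clean_world, clean_result):
        truth = clean_world.ground_truth.harea_grid.values
        got = clean_result.harea_cube.values
        np.testing.assert_allclose(got, truth, rtol=1e-9, atol=1e-9)
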