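"""No-till prediction, eligibility, logit ranking, greedy allocation, and
the deep/surface placement rules."""

import numpy as np
import pandas as pd
import pytest
from hypothesis import given, settings, strategies as st

from nfert.grid import ConfigError
from nfert.harvested_area import HareaCube
from nfert.placement import (
    LogitParams, NoTillDrivers, NoTillSurface, allocate_potential_notill,
    crop_notill_fraction, downscale_notill, notill_probability,
    placement_shares, predict_national_notill,
)
from nfert.vocab import DEFAULT_VOCAB

from _toys import toy_hierarchy


def _drivers(grid, *, erosion=1.0, aridity=1.0, crop_mix=0.5, field_size=10.0,
             income=None, threshold=8.0):
    shape = grid.shape
    return NoTillDrivers(
        field_size=np.full(shape, field_size),
        erosion=np.full(shape, erosion),
        aridity=np.full(shape, aridity),
        income_class=income or {},
        rural_population=pd.DataFrame(),
        crop_mix=np.full(shape, crop_mix),
        large_field_threshold=threshold,
    )


def _params(k=1.0, xmid=None):
    xmid = xmid or {"erosion": 1.0, "aridity": 1.0, "crop_mix": 0.5,
                    "field_size": 10.0}
    return LogitParams(k={n: k for n in xmid}, xmid=xmid)


class TestNotillProbability:
    def test_midpoints_give_one_half(self):
        grid, h = toy_hierarchy()
        prob = notill_probability(_drivers(grid), _params())
        np.testing.assert_allclose(prob, 0.5)

    def test_single_predictor_ln3_gives_three_quarters(self):
        grid, h = toy_hierarchy()
        d = _drivers(grid, erosion=1.0 + np.log(3.0))
        prob = notill_probability(d, _params())
        np.testing.assert_allclose(prob, 0.75)

    def test_large_slope_saturates(self):
        grid, h = toy_hierarchy()
        d = _drivers(grid, erosion=2.0)
        params = LogitParams(
            k={"erosion": 1e4, "aridity": 0.0, "crop_mix": 0.0, "field_size": 0.0},
            xmid={"erosion": 1.0, "aridity": 1.0, "crop_mix": 0.5, "field_size": 10.0},
        )
        prob = notill_probability(d, params)
        np.testing.assert_allclose(prob, 1.0)

    def test_missing_driver_gives_zero(self):
        grid, h = toy_hierarchy()
        d = _drivers(grid)
        d.erosion = d.erosion.copy()
        d.erosion[0, 0] = np.nan
        prob = notill_probability(d, _params())
        assert prob[0, 0] == 0.0
        assert prob[0, 1] == pytest.approx(0.5)

    def test_incomplete_params_rejected(self):
        with pytest.raises(ConfigError, match="logit parameters"):
            LogitParams(k={"erosion": 1.0}, xmid={"erosion": 1.0})


class TestPotentialArea:
    def _cube(self, grid, crop, area):
        crops = tuple(DEFAULT_VOCAB.crop_groups)
        values = np.zeros((len(crops), 1, *grid.shape))
        values[crops.index(crop)] = area
        return HareaCube(crops=crops, years=np.array([2000]), values=values)

    def test_high_income_small_fields_retained(self):
        grid, h = toy_hierarchy()
        cube = self._cube(grid, "Wheat", 10.0)
        d = _drivers(grid, field_size=1.0, income={"C00": "high"})
        pot = allocate_potential_notill(cube, d, h)
        assert (pot > 0).all()

    def test_low_income_small_fields_zeroed(self):
        grid, h = toy_hierarchy()
        cube = self._cube(grid, "Wheat", 10.0)
        d = _drivers(grid, field_size=1.0, income={"C00": "low"})
        pot = allocate_potential_notill(cube, d, h)
        np.testing.assert_allclose(pot, 0.0)

    def test_low_income_large_fields_retained(self):
        grid, h = toy_hierarchy()
        cube = self._cube(grid, "Wheat", 10.0)
        d = _drivers(grid, field_size=20.0, income={"C00": "low"})
        pot = allocate_potential_notill(cube, d, h)
        assert (pot > 0).all()

    def test_rice_only_cell_has_no_potential(self):
        grid, h = toy_hierarchy()
        cube = self._cube(grid, "Rice", 10.0)
        d = _drivers(grid, income={"C00": "high"})
        pot = allocate_potential_notill(cube, d, h)
        np.testing.assert_allclose(pot, 0.0)


def greedy_oracle(potential, probability, target):
    """Exhaustive reference allocator: rank by probability (ties by index),
    take potential x probability until the target is met, cut the last cell."""
    contrib = [p * q for p, q in zip(potential, probability)]
    order = sorted(range(len(potential)), key=lambda i: (-probability[i], i))
    alloc = [0.0] * len(potential)
    remaining = target
    for i in order:
        take = min(contrib[i], remaining)
        alloc[i] = take
        remaining -= take
        if remaining <= 0:
            break
    return alloc


class TestDownscale:
    def _run(self, potential, probability, target):
        n = len(potential)
        grid, h = toy_hierarchy(n_countries=1, counties_per_country=1,
                                rows_per=1, cols_per=n)
        targets = pd.DataFrame({2000: [target]}, index=["C00"])
        pot = np.array(potential, dtype=float).reshape(1, 1, n)
        prob = np.array(probability, dtype=float).reshape(1, 1, n)
        surf = downscale_notill(targets, pot, prob, h)
        return surf.cell_area[0, 0]

    def test_zero_target_allocates_nothing(self):
        np.testing.assert_allclose(self._run([5, 5, 5], [0.9, 0.5, 0.1], 0.0), 0.0)

    def test_saturation_selects_every_cell_fully(self):
        pot, prob = [5.0, 5.0, 5.0], [0.9, 0.5, 0.1]
        total = sum(p * q for p, q in zip(pot, prob))
        got = self._run(pot, prob, total)
        np.testing.assert_allclose(got, [4.5, 2.5, 0.5])

    def test_three_cell_partial_cut(self):
        pot, prob = [5.0, 5.0, 5.0], [0.9, 0.5, 0.1]
        got = self._run(pot, prob, 6.0)
        # cells in order 1, 2, 3: 4.5 + 1.5 partial from the second
        np.testing.assert_allclose(got, [4.5, 1.5, 0.0])
        assert got.sum() == pytest.approx(6.0)

    def test_target_above_potential_capped(self):
        pot, prob = [5.0, 5.0], [0.5, 0.5]
        got = self._run(pot, prob, 100.0)
        np.testing.assert_allclose(got, [2.5, 2.5])

    @settings(max_examples=200, deadline=None, derandomize=True)
    @given(
        data=st.lists(
            st.tuples(st.floats(0.0, 50.0), st.floats(0.0, 1.0)),
            min_size=1, max_size=12,
        ),
        frac=st.floats(0.0, 1.2),
    )
    def test_matches_brute_force_oracle(self, data, frac):
        potential = [p for p, _ in data]
        probability = [q for _, q in data]
        total = sum(p * q for p, q in zip(potential, probability))
        target = frac * total
        got = self._run(potential, probability, target)
        want = greedy_oracle(potential, probability, target)
        np.testing.assert_allclose(got, want, atol=1e-9)


class TestCropFraction:
    def _cube(self, grid, areas):
        crops = tuple(DEFAULT_VOCAB.crop_groups)
        values = np.zeros((len(crops), 1, *grid.shape))
        for crop, a in areas.items():
            values[crops.index(crop)] = a
        return HareaCube(crops=crops, years=np.array([2000]), values=values)

    def test_single_crop_cell_inherits_cell_fraction(self):
        grid, h = toy_hierarchy(n_countries=1, counties_per_country=1,
                                rows_per=1, cols_per=1)
        cube = self._cube(grid, {"Wheat": 20.0})
        surf = NoTillSurface(years=np.array([2000]),
                             cell_area=np.full((1, 1, 1), 10.0),
                             cell_fraction=np.zeros((1, 1, 1)))
        out = crop_notill_fraction(surf, cube)
        wi = cube.crops.index("Wheat")
        assert out.crop_fraction[wi, 0, 0, 0] == pytest.approx(0.5)

    def test_proportional_split_and_conservation(self):
        grid, h = toy_hierarchy(n_countries=1, counties_per_country=1,
                                rows_per=1, cols_per=1)
        cube = self._cube(grid, {"Wheat": 20.0, "Maize": 80.0})
        surf = NoTillSurface(years=np.array([2000]),
                             cell_area=np.full((1, 1, 1), 10.0),
                             cell_fraction=np.zeros((1, 1, 1)))
        out = crop_notill_fraction(surf, cube)
        wi, mi = cube.crops.index("Wheat"), cube.crops.index("Maize")
        # 10 ha split 2 / 8; fractions 2/20 and 8/80
        assert out.crop_fraction[wi, 0, 0, 0] == pytest.approx(0.1)
        assert out.crop_fraction[mi, 0, 0, 0] == pytest.approx(0.1)
        crop_area = (out.crop_fraction[:, 0, 0, 0] * cube.values[:, 0, 0, 0]).sum()
        assert crop_area == pytest.approx(10.0)


class TestPlacementShares:
    def _placement(self, notill_value):
        crops = tuple(DEFAULT_VOCAB.crop_groups)
        nt = np.full((len(crops), 1, 1, 1), float(notill_value))
        surf = NoTillSurface(years=np.array([2000]),
                             cell_area=np.zeros((1, 1, 1)),
                             cell_fraction=np.zeros((1, 1, 1)),
                             crop_fraction=nt, crops=crops)
        return placement_shares(surf)

    def test_injected_fertilizers_fully_deep(self):
        p = self._placement(0.3)
        for f in ("AA", "NS"):
            np.testing.assert_allclose(p.deep("Wheat", f), 1.0)
            np.testing.assert_allclose(p.surface("Wheat", f), 0.0)

    def test_other_synthetic_uses_base_topdressing_ratio(self):
        p = self._placement(0.5)
        np.testing.assert_allclose(p.deep("Wheat", "Urea"), 0.35)

    def test_residues_fully_incorporated_under_tillage(self):
        p = self._placement(0.0)
        np.testing.assert_allclose(p.deep("Wheat", "MA"), 1.0)
        np.testing.assert_allclose(p.deep("Wheat", "CR"), 1.0)

    def test_surface_plus_deep_is_one_everywhere(self, noisy_result):
        cons = noisy_result.report.conservation
        assert cons.loc["placement_sum", "max_rel_err"] == 0.0

    def test_monotonicity_in_notill(self):
        lo, hi = self._placement(0.2), self._placement(0.8)
        assert (hi.deep("Wheat", "Urea") >= lo.deep("Wheat", "Urea")).all()
        assert (hi.deep("Wheat", "MA") <= lo.deep("Wheat", "MA")).all()

    def test_literal_injected_grouping_switch(self):
        crops = tuple(DEFAULT_VOCAB.crop_groups)
        nt = np.full((len(crops), 1, 1, 1), 0.5)
        surf = NoTillSurface(years=np.array([2000]),
                             cell_area=np.zeros((1, 1, 1)),
                             cell_fraction=np.zeros((1, 1, 1)),
                             crop_fraction=nt, crops=crops)
        p = placement_shares(surf, injected=frozenset({"AA", "AN"}))
        np.testing.assert_allclose(p.deep("Wheat", "AN"), 1.0)
        np.testing.assert_allclose(p.deep("Wheat", "NS"), 0.35)


class TestNationalPrediction:
    def test_census_values_used_directly(self, noisy_world, noisy_result):
        w = noisy_world
        census = w.notill_drivers.census_notill
        nat = census.groupby(level=0).sum(min_count=1)
        targets_years = list(noisy_result.notill.years)
        # recompute targets as the pipeline does
        cl = w.cropland_cube.total()
        country_r = w.hierarchy.country_raster()
        land = country_r >= 0
        cropland = pd.DataFrame(
            {y: np.bincount(country_r[land], weights=cl[yi][land],
                            minlength=len(w.hierarchy.countries))
             for yi, y in enumerate(targets_years)},
            index=list(w.hierarchy.countries))
        targets = predict_national_notill(
            w.notill_drivers.rural_population, cropland, census, w.hierarchy)
        for j in nat.index:
            for y in nat.columns:
                if np.isfinite(nat.loc[j, y]):
                    assert targets.loc[j, y] == pytest.approx(nat.loc[j, y])

    def test_fractions_bounded_and_monotone(self, noisy_world):
        w = noisy_world
        years = [2000]
        countries = list(w.hierarchy.countries)
        sweep = np.geomspace(0.01, 100.0, len(countries))
        cropland = pd.DataFrame({2000: sweep * 1000.0}, index=countries)
        rural = pd.DataFrame({2000: np.full(len(countries), 1000.0)},
                             index=countries)
        area = predict_national_notill(rural, cropland, None, w.hierarchy,
                                       curve_params=(0.4, 0.0, 0.5))
        frac = (area[2000] / cropland[2000]).to_numpy()
        assert ((frac >= 0) & (frac <= 1)).all()
        assert (np.diff(frac) >= -1e-12).all()
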