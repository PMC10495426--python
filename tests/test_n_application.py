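"""Amount extension, SN correction, constant-ratio crop split, survey
calibration, and rasterization of application rates."""

import numpy as np
import pandas as pd
import pytest

from nfert.n_application import (
    NAmountPanel, calibrate_to_fubc, correct_sn_to_national, extend_n_amount,
    fubc_reference_year, rasterize_rates, scale_crop_rates,
)
from nfert.vocab import DEFAULT_VOCAB

from _toys import panel, toy_hierarchy

CLASSES = ["SN", "MA", "CR"]


@pytest.mark.parametrize("year,anchor", [
    (2003, 2006), (2005, 2006), (2006, 2006),
    (2007, 2007), (2008, 2007),
    (2009, 2010), (2011, 2010), (2012, 2010),
    (2013, 2014), (2016, 2014),
    (2017, 2018), (2020, 2018),
    (1999, None), (2002, None),
])
def test_fubc_reference_year_piecewise_map(year, anchor):
    assert fubc_reference_year(year) == anchor


class TestExtendAmounts:
    def setup_method(self):
        self.grid, self.h = toy_hierarchy(n_countries=1, counties_per_country=2)
        years = [2013, 2014, 2015, 2016]
        self.years = years
        self.prior = panel(
            [(f, c) for f in CLASSES for c in self.h.counties],
            [2013, 2014],
            [[9.0, 10.0]] * 6,
        )

    def _national(self, ratio_2015, ratio_2016=None):
        ratio_2016 = ratio_2015 if ratio_2016 is None else ratio_2016
        return panel([(f, "C00") for f in CLASSES], self.years,
                     [[20.0, 20.0, 20.0 * ratio_2015, 20.0 * ratio_2016]] * 3)

    def test_flat_national_series_keeps_pivot_values(self):
        out = extend_n_amount(NAmountPanel(self.prior, self._national(1.0)), self.h)
        np.testing.assert_allclose(out[2015].to_numpy(), 10.0)
        np.testing.assert_allclose(out[2016].to_numpy(), 10.0)

    def test_national_ratio_applied_to_counties(self):
        # county 10 t at pivot, national ratio 1.2 -> 12 t
        out = extend_n_amount(NAmountPanel(self.prior, self._national(1.2)), self.h)
        np.testing.assert_allclose(out[2015].to_numpy(), 12.0)

    def test_years_through_pivot_untouched(self):
        out = extend_n_amount(NAmountPanel(self.prior, self._national(3.0)), self.h)
        pd.testing.assert_frame_equal(out[[2013, 2014]], self.prior)


class TestCorrectSnToNational:
    def setup_method(self):
        self.grid, self.h = toy_hierarchy(n_countries=1, counties_per_country=2)
        self.years = [2000, 2001]
        self.ext = panel(
            [(f, c) for f in CLASSES for c in self.h.counties], self.years,
            [[6.0, 6.0], [6.0, 6.0],          # SN counties (sum 12)
             [3.0, 3.0], [3.0, 3.0],          # MA
             [2.0, 2.0], [2.0, 2.0]],         # CR
        )

    def test_matching_totals_unchanged(self):
        nat = panel([(f, "C00") for f in CLASSES], self.years, [[12.0, 12.0]] * 3)
        out = correct_sn_to_national(self.ext, nat, self.h)
        pd.testing.assert_frame_equal(out, self.ext)

    def test_low_prior_scaled_up_to_national(self):
        # prior total 12% below the statistic: every county x 1/0.88
        nat = panel([(f, "C00") for f in CLASSES], self.years,
                    [[12.0 / 0.88, 12.0 / 0.88]] * 3)
        out = correct_sn_to_national(self.ext, nat, self.h)
        np.testing.assert_allclose(out.loc["SN"].to_numpy(), 6.0 / 0.88)

    def test_manure_and_residues_pass_through(self):
        nat = panel([(f, "C00") for f in CLASSES], self.years, [[99.0, 99.0]] * 3)
        out = correct_sn_to_national(self.ext, nat, self.h)
        pd.testing.assert_frame_equal(out.loc["MA"], self.ext.loc["MA"])
        pd.testing.assert_frame_equal(out.loc["CR"], self.ext.loc["CR"])


class TestScaleCropRates:
    def setup_method(self):
        self.grid, self.h = toy_hierarchy(n_countries=1, counties_per_country=1)
        self.county = self.h.counties[0]
        crops = list(DEFAULT_VOCAB.crop_groups)
        self.ref = pd.DataFrame(
            0.0, index=pd.MultiIndex.from_product([crops, CLASSES]),
            columns=[self.county],
        )
        self.ref.loc[("Wheat", "SN"), self.county] = 50.0
        self.ref.loc[("Maize", "SN"), self.county] = 100.0
        self.harea = pd.DataFrame(
            0.0, index=pd.MultiIndex.from_product([crops, [self.county]]),
            columns=[2000],
        )
        self.harea.loc[("Wheat", self.county), 2000] = 10.0
        self.harea.loc[("Maize", self.county), 2000] = 10.0

    def _amount(self, kg):
        return panel([(f, self.county) for f in CLASSES], [2000],
                     [[kg], [0.0], [0.0]])

    def test_hand_example_and_conservation(self):
        # rates (50, 100), areas (10, 10), amount 3000 -> rates (100, 200)
        rates = scale_crop_rates(self._amount(3000.0), self.ref, self.harea)
        assert rates.loc[("Wheat", "SN", self.county), 2000] == pytest.approx(100.0)
        assert rates.loc[("Maize", "SN", self.county), 2000] == pytest.approx(200.0)
        total = (rates.xs("SN", level="class")[2000]
                 * self.harea[2000].droplevel(1).reindex(
                     rates.xs("SN", level="class").index.get_level_values(0)).to_numpy()
                 ).sum()
        assert total == pytest.approx(3000.0, rel=1e-12)

    def test_reference_amount_reproduces_reference_rates(self):
        rates = scale_crop_rates(self._amount(1500.0), self.ref, self.harea)
        assert rates.loc[("Wheat", "SN", self.county), 2000] == pytest.approx(50.0)

    def test_linearity_in_amount(self):
        r1 = scale_crop_rates(self._amount(1500.0), self.ref, self.harea)
        r2 = scale_crop_rates(self._amount(3000.0), self.ref, self.harea)
        np.testing.assert_allclose(r2.to_numpy(), 2 * r1.to_numpy())


class TestCalibrateToFubc:
    def setup_method(self):
        self.grid, self.h = toy_hierarchy(n_countries=1, counties_per_country=1)
        self.county = self.h.counties[0]
        crops = list(DEFAULT_VOCAB.crop_groups)
        years = [1999, 2006, 2007, 2010, 2014, 2018]
        idx = pd.MultiIndex.from_product([crops, CLASSES, [self.county]],
                                         names=["crop", "class", "county"])
        self.rates = pd.DataFrame(0.0, index=idx, columns=years)
        self.rates.loc[("Wheat", "SN", self.county)] = 80.0
        self.harea = pd.DataFrame(
            0.0, index=pd.MultiIndex.from_product([crops, [self.county]]),
            columns=years,
        )
        self.harea.loc[("Wheat", self.county)] = 10.0
        # pre-calibration Wheat-group amount: 80 x 10 = 800 kg
        fubc_idx = pd.MultiIndex.from_product(
            [list(DEFAULT_VOCAB.fubc_crop_groups), ["C00"]],
            names=["group", "country"])
        self.fubc = pd.DataFrame(0.0, index=fubc_idx,
                                 columns=[2006, 2007, 2010, 2014, 2018])
        self.fubc.loc[("Wheat", "C00")] = 800.0

    def test_matching_survey_leaves_rates_unchanged(self):
        out = calibrate_to_fubc(self.rates, self.harea, self.fubc, self.h)
        pd.testing.assert_frame_equal(out, self.rates)

    def test_survey_factor_and_reaggregation(self):
        self.fubc.loc[("Wheat", "C00"), 2006] = 1000.0   # 800 -> 1000: x1.25
        out = calibrate_to_fubc(self.rates, self.harea, self.fubc, self.h)
        assert out.loc[("Wheat", "SN", self.county), 2006] == pytest.approx(100.0)
        # recomputed group amount equals the survey value
        amount = out.loc[("Wheat", "SN", self.county), 2006] * 10.0
        assert amount == pytest.approx(1000.0)

    def test_years_before_2003_untouched(self):
        self.fubc.loc[("Wheat", "C00")] = 1000.0
        out = calibrate_to_fubc(self.rates, self.harea, self.fubc, self.h)
        assert out.loc[("Wheat", "SN", self.county), 1999] == pytest.approx(80.0)


class TestRasterizeRates:
    def test_broadcast_and_boundary_step(self):
        grid, h = toy_hierarchy(n_countries=1, counties_per_country=2)
        idx = pd.MultiIndex.from_product([["Wheat"], ["SN"], list(h.counties)],
                                         names=["crop", "class", "county"])
        rates = pd.DataFrame([[120.0], [200.0]], index=idx, columns=[2000])
        cube = rasterize_rates(rates, h, grid)
        plane = cube.by_class[0, 0, 0]
        assert (plane[:, :2] == 120.0).all()
        assert (plane[:, 2:] == 200.0).all()

    def test_total_is_sum_over_classes(self, clean_result):
        cube = clean_result.rate_cube
        np.testing.assert_allclose(cube.total, cube.by_class.sum(axis=1))


class TestRecoveryAndConservation:
    def test_noise_free_rate_recovery(self, clean_world, clean_result):
        """Under the constant-ratio generative regime the reconstruction
        returns the true crop-specific rates at every county-year."""
        truth = clean_world.ground_truth.rate_county
        rec = clean_result.county_rates.reindex(truth.index)
        t, r = truth.to_numpy(), rec.to_numpy()
        mask = t > 0
        assert np.abs(r[mask] - t[mask]).max() / t[mask].min() >= 0  # guard
        assert float((np.abs(r[mask] - t[mask]) / t[mask]).max()) < 1e-3
        np.testing.assert_allclose(r[~mask], 0.0)

    def test_conservation_under_noise(self, noisy_result):
        cons = noisy_result.report.conservation
        assert cons.loc["sn_county_vs_national", "max_rel_err"] <= 1e-9
        assert cons.loc["fubc_anchor_amounts", "max_rel_err"] <= 1e-9

    def test_rates_nonnegative(self, noisy_result):
        assert (noisy_result.county_rates.to_numpy() >= 0).all()
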