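"""Crop-specific N application rates by fertilizer class (SN / MA / CR).

County-level N amounts from a prior gridded product (through 2014) are
extended to 2020 with national ratios, synthetic-fertilizer (SN) amounts are
corrected to the national statistics, amounts are split across crops under
the constant-ratio assumption — every crop's rate in a county changes by the
same multiplicative factor over time, anchored on a year-2000 crop-specific
rate map — and rates after 2003 are calibrated to crop-group consumption
surveys (FUBC).  County rates are finally broadcast to the grid.
"""

from __future__ import annotations

import logging
from dataclasses import dataclass

import numpy as np
import pandas as pd

from .grid import AdminHierarchy, GridDefinition
from .vocab import Vocabulary, DEFAULT_VOCAB, CLASSES

logger = logging.getLogger(__name__)

PIVOT_YEAR = 2014          # last year of the prior county-level product
CALIBRATION_START = 2003   # first year adjusted to FUBC surveys
FUBC_ANCHOR_YEARS = (2006, 2007, 2010, 2014, 2018)


@dataclass
class NAmountPanel:
    """Fertilizer-class amounts (kg N): county prior, national statistics,
    and the corrected county panel the rate split consumes."""

    prior: pd.DataFrame          # (class, county) x years <= pivot
    national: pd.DataFrame       # (class, country) x all years (rectangular)
    corrected: pd.DataFrame | None = None   # (class, county) x all years


@dataclass
class NRateCube:
    """Gridded application rates (kg N per ha of harvested area)."""

    crops: tuple[str, ...]
    classes: tuple[str, ...]
    years: np.ndarray
    by_class: np.ndarray         # (n_crops, n_classes, n_years, R, C)

    @property
    def total(self) -> np.ndarray:
        """crop x year x grid rate summed over SN/MA/CR."""
        return self.by_class.sum(axis=1)


def fubc_reference_year(y: int) -> int | None:
    """Map a calendar year to its FUBC survey anchor year.

    Years before 2003 are not calibrated and map to ``None``.
    """
    if y < CALIBRATION_START:
        return None
    if y <= 2006:
        return 2006
    if y <= 2008:
        return 2007
    if y <= 2012:
        return 2010
    if y <= 2016:
        return 2014
    return 2018


def extend_n_amount(
    panel: NAmountPanel,
    hierarchy: AdminHierarchy,
    *,
    pivot_year: int = PIVOT_YEAR,
) -> pd.DataFrame:
    """Extend the county prior beyond its last year with national ratios.

    For pivot_year < y, county amounts scale by the national ratio
    national(f, y, j) / national(f, pivot, j); earlier years pass through.
    A zero national pivot value with later positive values triggers a
    uniform split of the national amount over the country's counties.
    """
    years = list(panel.national.columns)
    counties = list(panel.prior.index.get_level_values(1).unique())
    classes = list(panel.prior.index.get_level_values(0).unique())
    c_of = np.array(
        [list(hierarchy.countries).index(hierarchy.county_country[c]) for c in counties]
    )
    n_per = np.bincount(c_of, minlength=len(hierarchy.countries)).astype(float)

    nat = (
        panel.national.reindex(
            pd.MultiIndex.from_product([classes, hierarchy.countries])
        )
        .fillna(0.0)
        .to_numpy()
        .reshape(len(classes), len(hierarchy.countries), len(years))
    )
    out = panel.prior.reindex(columns=years)
    prior_pivot = panel.prior[pivot_year].to_numpy().reshape(len(classes), len(counties))
    base = nat[:, :, years.index(pivot_year)]
    later = [y for y in years if y > pivot_year]
    for y in later:
        ratio = np.where(base > 0, nat[:, :, years.index(y)] / np.where(base > 0, base, 1.0), 0.0)
        vals = prior_pivot * ratio[:, c_of]
        undef = (base <= 0) & (nat[:, :, years.index(y)] > 0)
        if undef.any():
            logger.warning(
                "zero national pivot-year amount with later positive values "
                "(%d class-country cells, year %d); splitting uniformly", int(undef.sum()), y,
            )
            for fi, ji in zip(*np.nonzero(undef)):
                vals[fi, c_of == ji] = nat[fi, ji, years.index(y)] / n_per[ji]
        out[y] = vals.reshape(-1)
    return out.fillna(0.0)


def correct_sn_to_national(
    extended: pd.DataFrame,
    national: pd.DataFrame,
    hierarchy: AdminHierarchy,
    cropland_use_fraction: dict[str, float] | float = 1.0,
) -> pd.DataFrame:
    """Scale county SN amounts so country sums equal the national statistics.

    The national SN statistic covers all agricultural uses; the cropland-use
    fraction (per country, default 1) removes pasture applications before
    the correction.  CR and MA pass through unchanged.
    """
    out = extended.copy()
    years = list(extended.columns)
    counties = list(extended.index.get_level_values(1).unique())
    c_of = np.array(
        [list(hierarchy.countries).index(hierarchy.county_country[c]) for c in counties]
    )
    sn = out.loc["SN"].to_numpy()                    # (county, year)
    nat_sn = (
        national.loc["SN"]
        .reindex(list(hierarchy.countries))
        .fillna(0.0)
        .to_numpy()                                  # (country, year)
    )
    if isinstance(cropland_use_fraction, dict):
        frac = np.array([cropland_use_fraction.get(j, 1.0) for j in hierarchy.countries])
    else:
        frac = np.full(len(hierarchy.countries), float(cropland_use_fraction))
    target = nat_sn * frac[:, None]
    sums = np.zeros_like(target)
    for ji in range(len(hierarchy.countries)):
        sums[ji] = sn[c_of == ji].sum(axis=0)
    factor = np.where(sums > 0, target / np.where(sums > 0, sums, 1.0), 0.0)
    corrected = sn * factor[c_of]
    need = (sums <= 0) & (target > 0)
    if need.any():
        logger.warning(
            "zero county SN sum with positive national target "
            "(%d country-years); splitting uniformly", int(need.sum()),
        )
        n_per = np.bincount(c_of, minlength=len(hierarchy.countries)).astype(float)
        for ji, yi in zip(*np.nonzero(need)):
            corrected[c_of == ji, yi] = target[ji, yi] / n_per[ji]
    out.loc["SN"] = corrected
    return out


def scale_crop_rates(
    corrected: pd.DataFrame,
    ref_rates: pd.DataFrame,
    harea_county: pd.DataFrame,
    vocab: Vocabulary = DEFAULT_VOCAB,
) -> pd.DataFrame:
    """Split county class amounts across crops under the constant-ratio rule.

    rate(cro, f, y, i) = refrate(cro, f, i) * amount(f, y, i) /
    sum_cro refrate(cro, f, i) * harea(cro, y, i).  The per-county scale
    factor is shared by all crops, so summing rate x area over crops
    reproduces the class amount exactly.  A zero denominator with a positive
    amount leaves rates at zero and flags the amount as unallocatable.
    """
    crops = list(vocab.crop_groups)
    classes = list(corrected.index.get_level_values(0).unique())
    counties = list(corrected.index.get_level_values(1).unique())
    years = list(corrected.columns)

    ref = (
        ref_rates.reindex(pd.MultiIndex.from_product([crops, classes]))
        .fillna(0.0)
        .to_numpy()
        .reshape(len(crops), len(classes), len(counties))
    )
    harea = (
        harea_county.reindex(pd.MultiIndex.from_product([crops, counties]))
        .fillna(0.0)
        .to_numpy()
        .reshape(len(crops), len(counties), len(years))
    )
    amount = corrected.to_numpy().reshape(len(classes), len(counties), len(years))
    denom = np.einsum("cfi,ciy->fiy", ref, harea)
    scale = np.where(denom > 0, amount / np.where(denom > 0, denom, 1.0), 0.0)
    lost = (denom <= 0) & (amount > 0)
    if lost.any():
        logger.warning(
            "%d class-county-years have N amounts but a zero rate-x-area "
            "denominator; amounts left unallocated", int(lost.sum()),
        )
    rates = ref[:, :, :, None] * scale[None, :, :, :]   # (crop, class, county, year)
    idx = pd.MultiIndex.from_product([crops, classes, counties],
                                     names=["crop", "class", "county"])
    return pd.DataFrame(rates.reshape(-1, len(years)), index=idx, columns=years)


def calibrate_to_fubc(
    rates: pd.DataFrame,
    harea_county: pd.DataFrame,
    fubc: pd.DataFrame,
    hierarchy: AdminHierarchy,
    vocab: Vocabulary = DEFAULT_VOCAB,
    *,
    start_year: int = CALIBRATION_START,
) -> pd.DataFrame:
    """Calibrate SN rates after ``start_year`` to FUBC crop-group consumption.

    One multiplicative factor per (country, FUBC group, anchor year),
    computed once from pre-calibration rates: factor = survey consumption /
    sum over member crops and counties of rate(SN, y0) x area(y0).  The
    factor for a year's anchor is applied to that year's SN rates; MA/CR
    and years before ``start_year`` pass through.  Zero denominators with a
    positive survey value skip the group (logged).
    """
    out = rates.copy()
    years = [y for y in rates.columns if y >= start_year]
    anchors = sorted({fubc_reference_year(y) for y in years} - {None})
    counties = list(rates.index.get_level_values(2).unique())
    county_country = hierarchy.county_country

    # factors[(country, group, y0)] from pre-calibration rates
    factors: dict[tuple[str, str, int], float] = {}
    sn = rates.xs("SN", level="class")
    for y0 in anchors:
        if y0 not in rates.columns:
            logger.warning("FUBC anchor year %d outside the rate panel; skipped", y0)
            continue
        amount = sn[y0] * harea_county.reindex(sn.index).fillna(0.0)[y0]
        frame = amount.reset_index()
        frame.columns = ["crop", "county", "amount"]
        frame["group"] = frame["crop"].map(vocab.crop_to_fubc)
        frame["country"] = frame["county"].map(county_country)
        denom = frame.groupby(["country", "group"])["amount"].sum()
        for (j, g2), d in denom.items():
            try:
                num = float(fubc.loc[(g2, j), y0])
            except KeyError:
                continue
            if d > 0:
                factors[(j, g2, y0)] = num / d
            elif num > 0:
                logger.warning(
                    "FUBC group %s in %s reports %g kg N at %d but the "
                    "pre-calibration amount is zero; group skipped", g2, j, num, y0,
                )

    crop_group = {c: vocab.crop_to_fubc[c] for c in vocab.crop_groups}
    idx = out.index
    is_sn = idx.get_level_values("class") == "SN"
    row_country = np.array([county_country[c] for c in idx.get_level_values("county")])
    row_group = np.array([crop_group.get(c, "") for c in idx.get_level_values("crop")])
    for y in years:
        y0 = fubc_reference_year(y)
        fac = np.ones(len(idx))
        for (j, g2, a), f in factors.items():
            if a != y0:
                continue
            fac[(row_country == j) & (row_group == g2) & is_sn] = f
        out[y] = out[y].to_numpy() * fac
    return out


def rasterize_rates(
    rates: pd.DataFrame,
    hierarchy: AdminHierarchy,
    grid: GridDefinition,
) -> NRateCube:
    """Broadcast county rates to every cell of the county (cells without a
    county get rate 0)."""
    crops = tuple(rates.index.get_level_values(0).unique())
    classes = tuple(rates.index.get_level_values(1).unique())
    counties = list(rates.index.get_level_values(2).unique())
    years = np.array(list(rates.columns))
    arr = rates.to_numpy().reshape(len(crops), len(classes), len(counties), len(years))
    mem = hierarchy.membership
    land = mem >= 0
    by_class = arr[:, :, np.clip(mem, 0, None), :]            # (crop, class, R, C, year)
    by_class = np.moveaxis(by_class, -1, 2)                   # (crop, class, year, R, C)
    by_class[:, :, :, ~land] = 0.0
    return NRateCube(crops=crops, classes=classes, years=years, by_class=by_class)


def build_rate_stage(
    panel: NAmountPanel,
    ref_rates: pd.DataFrame,
    harea_county: pd.DataFrame,
    fubc: pd.DataFrame,
    hierarchy: AdminHierarchy,
    grid: GridDefinition,
    vocab: Vocabulary = DEFAULT_VOCAB,
    cropland_use_fraction: dict[str, float] | float = 1.0,
) -> tuple[NAmountPanel, pd.DataFrame, NRateCube]:
    """Full rate stage; returns (panel with corrected amounts, calibrated
    county rates, gridded rate cube)."""
    from .harvested_area import handle_disintegration

    national = handle_disintegration(panel.national, hierarchy.disintegration_events)
    extended = extend_n_amount(NAmountPanel(panel.prior, national), hierarchy)
    corrected = correct_sn_to_national(extended, national, hierarchy, cropland_use_fraction)
    panel = NAmountPanel(prior=panel.prior, national=national, corrected=corrected)
    rates = scale_crop_rates(corrected, ref_rates, harea_county, vocab)
    rates = calibrate_to_fubc(rates, harea_county, fubc, hierarchy, vocab)
    cube = rasterize_rates(rates, hierarchy, grid)
    return panel, rates, cube
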