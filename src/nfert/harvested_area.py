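"""Crop-specific harvested-area reconstruction.

A year-2000 county reference map is carried through time with national
harvested-area ratios (counties are assumed to track their country's annual
changes), re-attributed across political disintegrations, disaggregated to
the grid in proportion to cropland (the rice layer for rice, the upland
layer for everything else), and finally rescaled so national sums match the
country statistics exactly.
"""

from __future__ import annotations

import logging
from dataclasses import dataclass

import numpy as np
import pandas as pd

from .grid import AdminHierarchy, DisintegrationEvent, GridDefinition
from .vocab import Vocabulary, DEFAULT_VOCAB

logger = logging.getLogger(__name__)

REFERENCE_YEAR = 2000


@dataclass
class CroplandCube:
    """Rice and upland cropland area (ha) per grid cell and year.

    Before 2000 the layers are constant within each decade; after the last
    mapped year the final slice is reused.
    """

    years: np.ndarray          # (n_years,)
    rice: np.ndarray           # (n_years, n_rows, n_cols)
    upland: np.ndarray         # (n_years, n_rows, n_cols)

    def layer(self, crop: str) -> np.ndarray:
        return self.rice if crop == "Rice" else self.upland

    def total(self) -> np.ndarray:
        return self.rice + self.upland


@dataclass
class HareaCube:
    """Harvested area (ha per cell): crop x year x grid."""

    crops: tuple[str, ...]
    years: np.ndarray
    values: np.ndarray         # (n_crops, n_years, n_rows, n_cols)

    def crop_index(self, crop: str) -> int:
        return self.crops.index(crop)

    def sel(self, crop: str) -> np.ndarray:
        return self.values[self.crop_index(crop)]

    def total(self) -> np.ndarray:
        return self.values.sum(axis=0)


def county_sums(cube: HareaCube, hierarchy: AdminHierarchy) -> pd.DataFrame:
    """Sum a gridded cube back to the county level: (crop, county) x year."""
    mem = hierarchy.membership
    land = mem >= 0
    n_i = hierarchy.n_counties
    rows = []
    for ci in range(len(cube.crops)):
        per_year = np.stack([
            np.bincount(mem[land], weights=cube.values[ci, yi][land], minlength=n_i)
            for yi in range(len(cube.years))
        ], axis=1)                                   # (county, year)
        rows.append(per_year)
    values = np.concatenate(rows, axis=0)
    idx = pd.MultiIndex.from_product(
        [cube.crops, hierarchy.counties], names=["crop", "county"]
    )
    return pd.DataFrame(values, index=idx, columns=list(cube.years))


def handle_disintegration(
    national: pd.DataFrame,
    events: tuple[DisintegrationEvent, ...],
) -> pd.DataFrame:
    """Re-attribute parent-era national statistics to successor countries.

    ``national`` has a (..., country) MultiIndex (country last) or a plain
    country index, with year columns.  For each event, values in years
    before the split are distributed to successors in proportion to each
    successor's value in the first post-split year; if all successors report
    zero that year, the split is equal (with a warning).  Parent rows are
    dropped; remaining NaNs become zero.
    """
    out = national.copy()
    multi = isinstance(out.index, pd.MultiIndex)
    for ev in events:
        country_level = out.index.nlevels - 1
        countries_present = out.index.get_level_values(country_level)
        if ev.parent not in set(countries_present):
            continue
        pre_years = [y for y in out.columns if y < ev.year]
        if ev.year not in out.columns or not pre_years:
            out = out[countries_present != ev.parent]
            continue
        parent = out.xs(ev.parent, level=country_level)
        first = {}
        for s in ev.successors:
            try:
                first[s] = out.xs(s, level=country_level)[ev.year]
            except KeyError:
                first[s] = pd.Series(0.0, index=parent.index)
        first_df = pd.DataFrame(first).reindex(parent.index).fillna(0.0)
        totals = first_df.sum(axis=1)
        shares = first_df.div(totals.where(totals > 0), axis=0)
        n_zero = int((totals <= 0).sum())
        if n_zero:
            logger.warning(
                "disintegration of %s in %d: %d series with all-zero successors "
                "in the first post-split year; splitting equally", ev.parent,
                ev.year, n_zero,
            )
            shares.loc[totals <= 0] = 1.0 / len(ev.successors)
        for s in ev.successors:
            for lead in parent.index:
                if multi:
                    lead_t = lead if isinstance(lead, tuple) else (lead,)
                    row = (*lead_t, s)
                else:
                    row = s
                if row not in out.index:
                    out.loc[row] = np.nan
                out.loc[row, pre_years] = (
                    parent.loc[lead, pre_years].to_numpy() * shares.loc[lead, s]
                )
        keep = out.index.get_level_values(country_level) != ev.parent
        out = out[keep]
    return out.fillna(0.0).sort_index()


def extend_harvested_area(
    ref: pd.DataFrame,
    national: pd.DataFrame,
    hierarchy: AdminHierarchy,
    *,
    ref_year: int = REFERENCE_YEAR,
) -> pd.DataFrame:
    """Extend the reference-year county map through time with national ratios.

    ``ref``: crop x county table (ha) for ``ref_year``.
    ``national``: (crop, country) x year table (ha), already rectangular
    (disintegrations handled).

    Each county inherits its country's ratio to the reference year.  When a
    country's reference-year value is zero but later years are positive, the
    reference share is undefined and the national amount is spread uniformly
    over the country's counties (logged).
    """
    years = list(national.columns)
    counties = list(ref.columns)
    crops = list(ref.index)
    c_of = np.array(
        [list(hierarchy.countries).index(hierarchy.county_country[c]) for c in counties]
    )
    n_counties_per = np.bincount(c_of, minlength=len(hierarchy.countries)).astype(float)

    nat = (
        national.reindex(
            pd.MultiIndex.from_product([crops, hierarchy.countries],
                                       names=national.index.names)
        )
        .fillna(0.0)
        .to_numpy()
        .reshape(len(crops), len(hierarchy.countries), len(years))
    )
    base = nat[:, :, years.index(ref_year)]                  # (crop, country)
    with np.errstate(divide="ignore", invalid="ignore"):
        ratio = np.where(base[:, :, None] > 0, nat / base[:, :, None], 0.0)

    refv = ref.to_numpy()                                    # (crop, county)
    values = refv[:, None, :] * np.transpose(ratio, (0, 2, 1))[:, :, c_of]
    # (crop, year, county)

    undefined = (base <= 0) & (nat > 0).any(axis=2)          # (crop, country)
    if undefined.any():
        logger.warning(
            "zero reference-year national harvested area with later positive "
            "values for %d crop-country series; spreading uniformly over counties",
            int(undefined.sum()),
        )
        for ci, ji in zip(*np.nonzero(undefined)):
            cols = np.nonzero(c_of == ji)[0]
            values[ci, :, cols] = (nat[ci, ji, :] / n_counties_per[ji])[None, :]

    out = pd.DataFrame(
        np.transpose(values, (0, 2, 1)).reshape(len(crops) * len(counties), len(years)),
        index=pd.MultiIndex.from_product([crops, counties], names=["crop", "county"]),
        columns=years,
    )
    return out


def disaggregate_to_grid(
    county_table: pd.DataFrame,
    cropland: CroplandCube,
    hierarchy: AdminHierarchy,
    grid: GridDefinition,
    vocab: Vocabulary = DEFAULT_VOCAB,
) -> HareaCube:
    """Spread county harvested areas over grid cells proportional to cropland.

    Rice follows the rice cropland layer, all other crops the upland layer.
    A county with harvested area but zero matching cropland falls back to a
    uniform spread over its land cells (logged).
    """
    crops = list(county_table.index.get_level_values(0).unique())
    years = list(county_table.columns)
    mem = hierarchy.membership
    land = mem >= 0
    n_counties = hierarchy.n_counties
    cell_counts = hierarchy.county_cell_counts().astype(float)

    cube = np.zeros((len(crops), len(years), *grid.shape))
    vals = county_table.to_numpy().reshape(len(crops), n_counties, len(years))
    fallback_hits = 0
    for yi, _y in enumerate(years):
        shares = {}
        for name, layer in (("rice", cropland.rice[yi]), ("upland", cropland.upland[yi])):
            csum = np.bincount(mem[land], weights=layer[land], minlength=n_counties)
            with np.errstate(divide="ignore", invalid="ignore"):
                per_cell = np.where(
                    csum[np.clip(mem, 0, None)] > 0,
                    layer / np.where(csum[np.clip(mem, 0, None)] > 0,
                                     csum[np.clip(mem, 0, None)], 1.0),
                    1.0 / np.maximum(cell_counts, 1.0)[np.clip(mem, 0, None)],
                )
            per_cell[~land] = 0.0
            shares[name] = (per_cell, csum)
        for ci, crop in enumerate(crops):
            share, csum = shares["rice" if crop == "Rice" else "upland"]
            fallback_hits += int(((csum <= 0) & (vals[ci, :, yi] > 0)).sum())
            cube[ci, yi] = vals[ci, np.clip(mem, 0, None), yi] * share
            cube[ci, yi][~land] = 0.0
    if fallback_hits:
        logger.warning(
            "%d county-crop-years had harvested area but zero matching cropland; "
            "spread uniformly over county land cells", fallback_hits,
        )
    return HareaCube(crops=tuple(crops), years=np.array(years), values=cube)


def match_national_totals(
    cube: HareaCube,
    national: pd.DataFrame,
    hierarchy: AdminHierarchy,
    cropland: CroplandCube | None = None,
) -> HareaCube:
    """Rescale grid cells so national sums equal the country statistics.

    A single multiplicative factor per (crop, country, year).  Countries with
    a zero gridded sum but a nonzero target receive a uniform spread over
    their cells with positive cropland (or all land cells without a cropland
    cube).
    """
    country_r = hierarchy.country_raster()
    land = country_r >= 0
    n_j = len(hierarchy.countries)
    years = list(cube.years)
    nat = (
        national.reindex(
            pd.MultiIndex.from_product([cube.crops, hierarchy.countries],
                                       names=national.index.names)
        )
        .fillna(0.0)
        .to_numpy()
        .reshape(len(cube.crops), n_j, len(years))
    )
    out = cube.values.copy()
    for ci in range(len(cube.crops)):
        for yi in range(len(years)):
            plane = out[ci, yi]
            sums = np.bincount(country_r[land], weights=plane[land], minlength=n_j)
            factor = np.ones(n_j)
            pos = sums > 0
            factor[pos] = nat[ci, pos, yi] / sums[pos]
            plane[land] *= factor[country_r[land]]
            need = (~pos) & (nat[ci, :, yi] > 0)
            for ji in np.nonzero(need)[0]:
                cells = country_r == ji
                if cropland is not None:
                    w = cropland.total()[yi] * cells
                    if w.sum() <= 0:
                        w = cells.astype(float)
                else:
                    w = cells.astype(float)
                plane += nat[ci, ji, yi] * w / w.sum()
    return HareaCube(crops=cube.crops, years=cube.years, values=out)


def build_harea_cube(
    ref: pd.DataFrame,
    national: pd.DataFrame,
    cropland: CroplandCube,
    hierarchy: AdminHierarchy,
    grid: GridDefinition,
    vocab: Vocabulary = DEFAULT_VOCAB,
    *,
    ref_year: int = REFERENCE_YEAR,
) -> tuple[pd.DataFrame, HareaCube]:
    """Full harvested-area stage: returns (county table, matched grid cube)."""
    nat = handle_disintegration(national, hierarchy.disintegration_events)
    county = extend_harvested_area(ref, nat, hierarchy, ref_year=ref_year)
    cube = disaggregate_to_grid(county, cropland, hierarchy, grid, vocab)
    cube = match_national_totals(cube, nat, hierarchy, cropland)
    return county, cube
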