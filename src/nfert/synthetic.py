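"""Synthetic-world generator: a small self-consistent planet with known truth.

Every input the reconstruction consumes — a year-2000 county reference map
of harvested area, national statistics panels, county-level prior N amounts,
a year-2000 crop-specific rate map, crop-group consumption surveys,
fertilizer-type consumption with realistic missingness, covariates, and
no-till driver rasters — is generated from one seeded ground truth, so each
pipeline stage can be tested for exact recovery (noise off) or for
mass-conservation under perturbation (noise on).

The generative model mirrors the reconstruction's own assumptions: county
harvested areas and class rates follow country-uniform multiplicative
growth curves anchored at the year 2000 (the constant-ratio premise), one
political disintegration is always present, cropland is decadal-constant
before 2000 and annual after, and the fertilizer-type consumption panel has
the early-period block gap plus scattered random missingness.
"""

from __future__ import annotations

import logging
from dataclasses import dataclass, field, asdict

import numpy as np
import pandas as pd

from .fertilizer_types import TypeConsumptionPanel
from .grid import AdminHierarchy, ConfigError, DisintegrationEvent, GridDefinition
from .harvested_area import CroplandCube, HareaCube
from .n_application import FUBC_ANCHOR_YEARS
from .placement import (
    LogitParams, NoTillDrivers, NoTillSurface, allocate_potential_notill,
    crop_notill_fraction, downscale_notill, notill_probability, _scaled_logistic,
)
from .vocab import Vocabulary, DEFAULT_VOCAB, CLASSES

logger = logging.getLogger(__name__)

#: Year-2000 total N application rates per crop group (kg N / ha), the level
#: around which county rate maps are drawn.
BASE_RATES: dict[str, float] = {
    "Barley": 60.0, "Cassava": 30.0, "Cotton": 90.0, "Fruits": 110.0,
    "Groundnut": 25.0, "Maize": 95.0, "Millet": 30.0, "Oilpalm": 70.0,
    "Potato": 100.0, "Rapeseed": 80.0, "Rye": 55.0, "Rice": 110.0,
    "Sorghum": 45.0, "Soybean": 20.0, "Sugarbeet": 100.0, "Sugarcane": 120.0,
    "Sunflower": 40.0, "Sweetpotato": 50.0, "Vegetables": 130.0, "Wheat": 90.0,
    "Other crops": 40.0,
}

#: Year-2000 national-scale harvested areas per crop group (ha per county).
BASE_AREAS: dict[str, float] = {
    "Barley": 30_000, "Cassava": 12_000, "Cotton": 18_000, "Fruits": 20_000,
    "Groundnut": 10_000, "Maize": 55_000, "Millet": 12_000, "Oilpalm": 8_000,
    "Potato": 15_000, "Rapeseed": 16_000, "Rye": 8_000, "Rice": 50_000,
    "Sorghum": 14_000, "Soybean": 35_000, "Sugarbeet": 9_000, "Sugarcane": 14_000,
    "Sunflower": 12_000, "Sweetpotato": 7_000, "Vegetables": 22_000,
    "Wheat": 60_000, "Other crops": 40_000,
}


@dataclass
class WorldConfig:
    """Configuration of the synthetic world.

    Defaults are the study conditions the pipeline is exercised under:
    1961-2020, a handful of countries with contiguous rectangular counties
    on a desk-scale grid, one disintegration, the 1962-1972 type-consumption
    gap plus 6% random missingness, and mild multiplicative log-normal
    noise on reported statistics (``noise_sd=0`` gives the exact regime).
    """

    seed: int = 0
    years: tuple[int, int] = (1961, 2020)
    n_countries: int = 4
    counties_per_country: int = 3
    grid_shape: tuple[int, int] = (24, 48)
    n_regions: int = 2
    disintegration: bool = True
    split_year: int = 1991
    noise_sd: float = 0.05
    missing_block: tuple[int, int] | None = (1962, 1972)
    missing_frac: float = 0.06
    base_rates: dict[str, float] = field(default_factory=lambda: dict(BASE_RATES))
    base_areas: dict[str, float] = field(default_factory=lambda: dict(BASE_AREAS))
    class_fracs: dict[str, float] = field(
        default_factory=lambda: {"SN": 0.60, "MA": 0.25, "CR": 0.15}
    )
    crop_presence: float = 0.92
    cropland_use_fraction: float = 1.0
    notill_amplitude: float = 0.25
    notill_scale: float = 0.5
    logit_slopes: dict[str, float] = field(
        default_factory=lambda: {
            "erosion": 1.0, "aridity": 1.0, "crop_mix": 1.0, "field_size": 1.0,
        }
    )
    large_field_threshold: float = 8.0
    ref_year: int = 2000

    def validate(self) -> None:
        y0, y1 = self.years
        if y1 <= y0:
            raise ConfigError(f"invalid year range {self.years}")
        if self.n_countries < 1 or self.counties_per_country < 1:
            raise ConfigError("need at least one country and one county per country")
        anchors = [a for a in FUBC_ANCHOR_YEARS if y0 <= a <= y1]
        if len(anchors) < 2:
            raise ConfigError(
                f"year range {self.years} spans {len(anchors)} FUBC anchors; need >= 2"
            )
        if not (y0 <= self.ref_year <= y1):
            raise ConfigError("reference year outside the year range")
        if not 0.0 <= self.missing_frac <= 1.0:
            raise ConfigError("missing_frac must be in [0, 1]")
        if self.noise_sd < 0:
            raise ConfigError("noise_sd must be >= 0")
        fr = self.class_fracs
        if any(v < 0 for v in fr.values()):
            raise ConfigError("class fractions must be >= 0")

    @property
    def year_list(self) -> list[int]:
        return list(range(self.years[0], self.years[1] + 1))


@dataclass
class GroundTruth:
    """The quantities every panel was generated from."""

    harea_county: pd.DataFrame            # (crop, county) x year, ha
    harea_grid: HareaCube
    rate_county: pd.DataFrame             # (crop, class, county) x year, kg N/ha
    namount_county: pd.DataFrame          # (class, county) x year, kg N
    type_mix: pd.DataFrame                # (sn_type, region) x year fractions
    type_consumption_complete: TypeConsumptionPanel
    national_notill: pd.DataFrame         # country x year area, ha
    notill: NoTillSurface


@dataclass
class SyntheticWorld:
    """The bundle of all pipeline inputs plus ground truth."""

    config: WorldConfig
    vocabulary: Vocabulary
    grid: GridDefinition
    hierarchy: AdminHierarchy
    reference_harea_map: pd.DataFrame       # crop x county, year-2000 ha
    country_harea_series: pd.DataFrame      # (crop, country) x year ha
    cropland_cube: CroplandCube
    prior_namount_panel: pd.DataFrame       # (class, county) x year kg N, <= 2014
    fao_namount_series: pd.DataFrame        # (class, country) x year kg N
    reference_rate_map: pd.DataFrame        # (crop, class) x county kg N/ha
    fubc_anchor_table: pd.DataFrame         # (group, country) x anchor years kg N
    fubc_historic_table: pd.DataFrame       # (group, country) x validation years
    type_consumption_panel: TypeConsumptionPanel
    covariate_panel: pd.DataFrame           # (variable, country) x year
    notill_drivers: NoTillDrivers
    notill_params: LogitParams
    notill_curve: tuple[float, float, float]
    cropland_use_fraction: float
    ground_truth: GroundTruth


def _logistic(y: np.ndarray, y0: float, tau: float) -> np.ndarray:
    return 1.0 / (1.0 + np.exp(-(np.asarray(y, dtype=float) - y0) / tau))


def _build_hierarchy(config: WorldConfig) -> tuple[GridDefinition, AdminHierarchy]:
    R, C = config.grid_shape
    n_j, cpc = config.n_countries, config.counties_per_country
    rows_per = R // n_j
    cols_per = C // cpc
    if rows_per < 1 or cols_per < 1:
        raise ConfigError(
            f"grid {config.grid_shape} too small for {n_j} countries x {cpc} counties"
        )
    grid = GridDefinition(n_rows=R, n_cols=C, resolution=180.0 / R)
    countries = tuple(f"C{k:02d}" for k in range(n_j))
    counties, county_country = [], {}
    membership = np.full((R, C), -1, dtype=int)
    for k, j in enumerate(countries):
        r0, r1 = k * rows_per, (k + 1) * rows_per
        for c in range(cpc):
            c0 = c * cols_per
            c1 = C if c == cpc - 1 else (c + 1) * cols_per
            name = f"{j}-{c:02d}"
            membership[r0:r1, c0:c1] = len(counties)
            counties.append(name)
            county_country[name] = j
    regions = {j: f"R{k % config.n_regions}" for k, j in enumerate(countries)}
    events: tuple[DisintegrationEvent, ...] = ()
    if config.disintegration and n_j >= 2:
        y0, y1 = config.years
        if y0 < config.split_year <= y1:
            events = (DisintegrationEvent(parent="FRM", year=config.split_year,
                                          successors=(countries[0], countries[1])),)
    hierarchy = AdminHierarchy(
        countries=countries, counties=tuple(counties),
        county_country=county_country, membership=membership,
        regions=regions, disintegration_events=events,
    )
    return grid, hierarchy


def _growth_curves(rng, n_series: int, n_countries: int, years: np.ndarray,
                   ref_year: int, *, floor: float, spans: tuple[float, float],
                   midpoint: tuple[float, float], tau: tuple[float, float],
                   ) -> np.ndarray:
    """Country-uniform multiplicative growth, 1 at the reference year.

    Returns (n_series, n_countries, n_years).  The same country-level
    logistic timing is shared by all series; per-series amplitudes vary.
    """
    y0 = rng.uniform(*midpoint, size=n_countries)
    t = rng.uniform(*tau, size=n_countries)
    amp = rng.uniform(*spans, size=(n_series, n_countries))
    out = np.empty((n_series, n_countries, len(years)))
    for j in range(n_countries):
        Lj = _logistic(years, y0[j], t[j])
        h = floor + amp[:, j][:, None] * Lj[None, :]
        href = floor + amp[:, j][:, None] * _logistic(np.array([ref_year]), y0[j], t[j])
        out[:, j, :] = h / href
    return out


def _patch_presplit(curves: np.ndarray, parent_curve: np.ndarray,
                    succ_idx: tuple[int, int], years: np.ndarray,
                    split_year: int) -> None:
    """Make successor growth before the split follow the parent's timing.

    After the patch, both successors' series change by the same factor in
    every pre-split year, which is what re-attribution by first post-split
    shares assumes.  ``curves`` is modified in place."""
    pre = years < split_year
    if not pre.any():
        return
    si = int(np.searchsorted(years, split_year))
    base = parent_curve[:, si]
    shape = parent_curve / base[:, None]          # (n_series, n_years), 1 at split
    for k in succ_idx:
        curves[:, k, pre] = curves[:, k, si][:, None] * shape[:, pre]


def _noise(rng, sd: float, size) -> np.ndarray:
    return np.exp(rng.normal(0.0, 1.0, size=size) * sd)


def generate_world(config: WorldConfig,
                   vocab: Vocabulary = DEFAULT_VOCAB) -> SyntheticWorld:
    """Generate a :class:`SyntheticWorld`; identical config => identical world."""
    config.validate()
    rng = np.random.default_rng(config.seed)
    grid, hierarchy = _build_hierarchy(config)
    years = np.array(config.year_list)
    n_y = len(years)
    crops = list(vocab.crop_groups)
    n_cro = len(crops)
    countries = list(hierarchy.countries)
    counties = list(hierarchy.counties)
    n_j, n_i = len(countries), len(counties)
    c_of = hierarchy.country_of_county_index()
    ref_year = config.ref_year
    events = hierarchy.disintegration_events
    split = events[0] if events else None
    succ_idx = (0, 1) if split else None

    # ---- harvested area truth ------------------------------------------
    county_factor = rng.lognormal(0.0, 0.4, size=n_i)
    present = rng.random((n_cro, n_i)) < config.crop_presence
    base_area = np.array([config.base_areas[c] for c in crops])
    harea_ref = base_area[:, None] * county_factor[None, :] * present
    # national growth (country-uniform per crop)
    r_growth = _growth_curves(
        rng, n_cro, n_j, years, ref_year, floor=0.25, spans=(0.5, 1.5),
        midpoint=(1975.0, 1995.0), tau=(6.0, 14.0),
    )
    if split:
        # one crop-independent parent-era shape: successor statistics then
        # scale uniformly before the split, which is what re-attribution by
        # first post-split shares assumes
        parent = _growth_curves(
            rng, 1, 1, years, ref_year, floor=0.25, spans=(0.5, 1.5),
            midpoint=(1975.0, 1995.0), tau=(6.0, 14.0),
        )[0, 0, :]
        _patch_presplit(r_growth, np.tile(parent, (n_cro, 1)), succ_idx,
                        years, split.year)
    # after the prior product's last year the reconstruction assumes county
    # amounts track national changes; a crop-independent national tail makes
    # that hold exactly
    pivot = 2014
    if pivot in years:
        pi = int(np.searchsorted(years, pivot))
        tail = _growth_curves(
            rng, 1, n_j, years, pivot, floor=0.25, spans=(0.5, 1.5),
            midpoint=(1975.0, 1995.0), tau=(6.0, 14.0),
        )[0]                                          # (n_j, n_y), 1 at pivot
        post = years > pivot
        r_growth[:, :, post] = (r_growth[:, :, pi][:, :, None]
                                * tail[None, :, post])

    harea_county_truth = harea_ref[:, :, None] * r_growth[:, c_of, :]
    # (crop, county, year)

    # ---- cropland cube and gridded truth -------------------------------
    R, C = grid.shape
    mem = hierarchy.membership
    land = mem >= 0
    rice_base = harea_ref[crops.index("Rice")] / 1.2               # per county
    upland_base = np.maximum(harea_ref.sum(axis=0) / 1.2 - rice_base, 0.0)
    w_rice = np.where(land, rng.gamma(2.0, 1.0, size=(R, C)) + 0.05, 0.0)
    w_upland = np.where(land, rng.gamma(2.0, 1.0, size=(R, C)) + 0.2, 0.0)

    def _county_share(w):
        csum = np.bincount(mem[land], weights=w[land], minlength=n_i)
        share = np.zeros_like(w)
        share[land] = w[land] / csum[mem[land]]
        return share

    share_rice = _county_share(w_rice)
    share_upland = _county_share(w_upland)

    ts = np.empty(n_y)
    for yi, y in enumerate(years):
        if y < 2000:
            yy = max(config.years[0], (y // 10) * 10)
        elif y <= 2017:
            yy = y
        else:
            yy = 2017
        ts[yi] = 1.0 + 0.004 * (yy - 1961)
    rice_cube = np.zeros((n_y, R, C))
    upland_cube = np.zeros((n_y, R, C))
    rice_cells = np.where(land, rice_base[np.clip(mem, 0, None)] * share_rice, 0.0)
    upland_cells = np.where(land, upland_base[np.clip(mem, 0, None)] * share_upland, 0.0)
    for yi in range(n_y):
        rice_cube[yi] = rice_cells * ts[yi]
        upland_cube[yi] = upland_cells * ts[yi]
    cropland = CroplandCube(years=years, rice=rice_cube, upland=upland_cube)

    harea_grid = np.zeros((n_cro, n_y, R, C))
    for ci, crop in enumerate(crops):
        share = share_rice if crop == "Rice" else share_upland
        vals = harea_county_truth[ci][np.clip(mem, 0, None), :]    # (R, C, year)
        harea_grid[ci] = np.moveaxis(vals * share[:, :, None], -1, 0)
        harea_grid[ci][:, ~land] = 0.0
    harea_cube_truth = HareaCube(crops=tuple(crops), years=years, values=harea_grid)

    # ---- reported national harvested-area series ------------------------
    nat_truth = np.zeros((n_cro, n_j, n_y))
    for ji in range(n_j):
        nat_truth[:, ji, :] = harea_county_truth[:, c_of == ji, :].sum(axis=1)
    nat_noise = nat_truth * _noise(rng, config.noise_sd, nat_truth.shape)
    series_countries = countries + ([split.parent] if split else [])
    idx = pd.MultiIndex.from_product([crops, series_countries],
                                     names=["crop", "country"])
    nat_df = pd.DataFrame(np.nan, index=idx, columns=list(years))
    for ci, crop in enumerate(crops):
        for ji, j in enumerate(countries):
            vals = nat_noise[ci, ji].copy()
            if split and ji in succ_idx:
                vals[years < split.year] = np.nan
            nat_df.loc[(crop, j)] = vals
        if split:
            parent_vals = nat_noise[ci, succ_idx[0]] + nat_noise[ci, succ_idx[1]]
            parent_vals = parent_vals.astype(float)
            parent_vals[years >= split.year] = np.nan
            nat_df.loc[(crop, split.parent)] = parent_vals

    # ---- rates and amounts truth ----------------------------------------
    class_frac = np.array([config.class_fracs[f] for f in CLASSES])
    base_rate = np.array([config.base_rates[c] for c in crops])
    rate_ref = (base_rate[:, None, None] * class_frac[None, :, None]
                * rng.lognormal(0.0, 0.2, size=(n_cro, 3, n_i)))
    rate_ref *= present[:, None, :]
    class_floor = {"SN": 0.15, "MA": 0.8, "CR": 0.6}
    class_span = {"SN": (0.8, 1.2), "MA": (0.2, 0.4), "CR": (0.3, 0.6)}
    s_growth = np.empty((3, n_j, n_y))
    for fi, f in enumerate(CLASSES):
        s_growth[fi] = _growth_curves(
            rng, 1, n_j, years, ref_year, floor=class_floor[f],
            spans=class_span[f], midpoint=(1978.0, 1992.0), tau=(6.0, 12.0),
        )[0]
    if split:
        for fi, f in enumerate(CLASSES):
            parent = _growth_curves(
                rng, 1, 1, years, ref_year, floor=class_floor[f],
                spans=class_span[f], midpoint=(1978.0, 1992.0), tau=(6.0, 12.0),
            )[0, 0, :]
            _patch_presplit(s_growth[fi][None, :, :], parent[None, :],
                            succ_idx, years, split.year)

    s_county = s_growth[:, c_of, :]                           # (class, county, year)
    rate_truth = rate_ref[:, :, :, None] * s_county[None, :, :, :]
    # (crop, class, county, year)
    namount_truth = np.einsum("cfi,ciy->fiy", rate_ref, harea_county_truth) \
        * s_county
    # (class, county, year)

    # ---- prior panel (county product through 2014) ----------------------
    prior_years = [y for y in years if y <= 2014]
    prior_vals = namount_truth[:, :, : len(prior_years)]
    prior_vals = prior_vals * _noise(rng, config.noise_sd, prior_vals.shape)
    prior_df = pd.DataFrame(
        prior_vals.reshape(3 * n_i, len(prior_years)),
        index=pd.MultiIndex.from_product([list(CLASSES), counties],
                                         names=["class", "county"]),
        columns=prior_years,
    )

    # ---- reported national amount series --------------------------------
    nat_amount = np.zeros((3, n_j, n_y))
    for ji in range(n_j):
        nat_amount[:, ji, :] = namount_truth[:, c_of == ji, :].sum(axis=1)
    nat_amount_noisy = nat_amount * _noise(rng, config.noise_sd, nat_amount.shape)
    nat_amount_noisy[0] /= config.cropland_use_fraction      # SN incl. pasture uses
    amt_idx = pd.MultiIndex.from_product([list(CLASSES), series_countries],
                                         names=["class", "country"])
    fao_df = pd.DataFrame(np.nan, index=amt_idx, columns=list(years))
    for fi, f in enumerate(CLASSES):
        for ji, j in enumerate(countries):
            vals = nat_amount_noisy[fi, ji].copy()
            if split and ji in succ_idx:
                vals[years < split.year] = np.nan
            fao_df.loc[(f, j)] = vals
        if split:
            pv = nat_amount_noisy[fi, succ_idx[0]] + nat_amount_noisy[fi, succ_idx[1]]
            pv = pv.astype(float)
            pv[years >= split.year] = np.nan
            fao_df.loc[(f, split.parent)] = pv

    ref_rate_df = pd.DataFrame(
        rate_ref.reshape(n_cro * 3, n_i),
        index=pd.MultiIndex.from_product([crops, list(CLASSES)],
                                         names=["crop", "class"]),
        columns=counties,
    )

    # ---- FUBC tables -----------------------------------------------------
    groups = list(vocab.fubc_crop_groups)
    group_of = np.array([groups.index(vocab.crop_to_fubc[c]) for c in crops])
    sn_amount_crop = (rate_truth[:, 0, :, :] * harea_county_truth)  # (crop, county, y)
    anchors = [a for a in FUBC_ANCHOR_YEARS if a in set(years.tolist())]
    fubc_idx = pd.MultiIndex.from_product([groups, countries],
                                          names=["group", "country"])
    fubc_anchor = pd.DataFrame(0.0, index=fubc_idx, columns=anchors)
    hist_years = [y for y in range(1978, 2002, 3) if y in set(years.tolist())]
    fubc_hist = pd.DataFrame(0.0, index=fubc_idx, columns=hist_years)
    for gi, g in enumerate(groups):
        sel = sn_amount_crop[group_of == gi].sum(axis=0)          # (county, year)
        for ji, j in enumerate(countries):
            tot = sel[c_of == ji].sum(axis=0)
            for a in anchors:
                fubc_anchor.loc[(g, j), a] = tot[list(years).index(a)]
            for y in hist_years:
                fubc_hist.loc[(g, j), y] = tot[list(years).index(y)]
    fubc_anchor *= _noise(rng, config.noise_sd, fubc_anchor.shape)

    # ---- fertilizer-type consumption ------------------------------------
    sn_types = list(vocab.sn_types)
    region_names = sorted(set(hierarchy.regions.values()))
    alpha = np.array([1.5, 2.0, 1.5, 1.5, 1.0, 1.0, 8.0, 2.0, 1.0, 3.0, 1.0])
    q = np.zeros((len(sn_types), len(region_names), n_y))
    for mi in range(len(region_names)):
        start = rng.dirichlet(alpha)
        end = rng.dirichlet(alpha)
        w = (years - years[0]) / (years[-1] - years[0])
        q[:, mi, :] = start[:, None] * (1 - w)[None, :] + end[:, None] * w[None, :]
    sn_region = np.zeros((len(region_names), n_y))
    for ji, j in enumerate(countries):
        mi = region_names.index(hierarchy.regions[j])
        sn_region[mi] += nat_amount[0, ji]
    fer_vals = q * sn_region[None, :, :]
    fer_vals = fer_vals * _noise(rng, config.noise_sd, fer_vals.shape)
    fer_idx = pd.MultiIndex.from_product([sn_types, region_names],
                                         names=["type", "unit"])
    fer_df = pd.DataFrame(fer_vals.reshape(-1, n_y), index=fer_idx,
                          columns=list(years))
    total_df = pd.DataFrame(fer_vals.sum(axis=0), index=region_names,
                            columns=list(years))
    complete_panel = TypeConsumptionPanel(values=fer_df, total_sn=total_df)
    panel = inject_missingness(complete_panel, config,
                               rng=np.random.default_rng(rng.integers(2**31)))

    type_mix_df = pd.DataFrame(
        q.reshape(-1, n_y),
        index=pd.MultiIndex.from_product([sn_types, region_names],
                                         names=["type", "region"]),
        columns=list(years),
    )

    # ---- covariates ------------------------------------------------------
    pop0 = rng.lognormal(np.log(5e6), 0.5, size=n_j)
    pop = pop0[:, None] * np.exp(0.012 * (years - years[0]))[None, :]
    gdp0 = rng.lognormal(np.log(2e10), 0.8, size=n_j)
    gdp = gdp0[:, None] * (0.4 + s_growth[0])                     # tracks SN growth
    cropland_country = np.zeros((n_j, n_y))
    for ji in range(n_j):
        sel = c_of == ji
        cropland_country[ji] = (rice_base[sel].sum() + upland_base[sel].sum()) * ts
    cov_idx = pd.MultiIndex.from_product(
        [["gdp", "population", "cropland"], countries],
        names=["variable", "country"],
    )
    cov_df = pd.DataFrame(
        np.concatenate([gdp, pop, cropland_country], axis=0),
        index=cov_idx, columns=list(years),
    )

    # ---- no-till drivers and truth --------------------------------------
    rowf = np.abs(np.sin(2 * np.pi * np.arange(R) / max(R, 1)))
    erosion = np.clip(2.0 + 3.0 * rowf[:, None] + rng.normal(0, 0.5, (R, C)), 0.0, None)
    aridity = np.clip(0.3 + 1.4 * (np.arange(C) / max(C - 1, 1))[None, :]
                      + rng.normal(0, 0.05, (R, C)), 0.05, None)
    field_size = rng.lognormal(np.log(6.0), 0.6, size=(R, C))
    rainfed = rng.uniform(0.5, 1.0, size=(R, C))
    income = {j: ("high" if k % 2 == 0 else "low") for k, j in enumerate(countries)}
    rural_share = np.clip(0.75 - 0.004 * (years - years[0]), 0.15, None)
    rural = pd.DataFrame(pop * rural_share[None, :], index=countries,
                         columns=list(years))
    cropland_df = pd.DataFrame(cropland_country, index=countries, columns=list(years))

    x_cap = cropland_country / np.maximum(pop * rural_share[None, :], 1.0)
    x_mid = float(np.log(np.median(x_cap)))
    curve = (config.notill_amplitude, x_mid, config.notill_scale)
    frac_true = np.clip(_scaled_logistic(x_cap, *curve), 0.0, 1.0)
    notill_area_true = pd.DataFrame(frac_true * cropland_country,
                                    index=countries, columns=list(years))

    census_rows = {}
    census_specs = []
    if n_j >= 4:
        census_specs = [(countries[-2], range(1989, 2009)), (countries[-1], range(2000, 2017))]
    elif n_j >= 2:
        census_specs = [(countries[-1], range(1989, 2017))]
    for j, span in census_specs:
        ji = countries.index(j)
        sel = c_of == ji
        cl_share = (rice_base[sel] + upland_base[sel])
        cl_share = cl_share / cl_share.sum()
        for ii, county in enumerate(np.array(counties)[sel]):
            row = {}
            for y in span:
                if y in set(years.tolist()):
                    row[y] = notill_area_true.loc[j, y] * cl_share[ii]
            census_rows[(j, county)] = row
    census_df = pd.DataFrame.from_dict(census_rows, orient="index")
    census_df.index = pd.MultiIndex.from_tuples(census_df.index,
                                                names=["country", "province"])

    suit_idx = [crops.index(c) for c in vocab.notill_crops]
    total_h = harea_grid.sum(axis=0)
    with np.errstate(invalid="ignore", divide="ignore"):
        crop_mix = np.where(total_h > 0,
                            harea_grid[suit_idx].sum(axis=0)
                            / np.where(total_h > 0, total_h, 1.0), 0.0)
    drivers = NoTillDrivers(
        field_size=field_size, erosion=erosion, aridity=aridity,
        income_class=income, rural_population=rural, census_notill=census_df,
        rainfed_fraction=rainfed, crop_mix=crop_mix,
        large_field_threshold=config.large_field_threshold,
    )
    ref_idx = list(years).index(ref_year)
    xmids = {
        "erosion": float(np.median(erosion[land])),
        "aridity": float(np.median(aridity[land])),
        "field_size": float(np.median(field_size[land])),
        "crop_mix": float(np.median(crop_mix[ref_idx][land])),
    }
    logit_params = LogitParams(k=dict(config.logit_slopes), xmid=xmids)

    potential = allocate_potential_notill(harea_cube_truth, drivers, hierarchy, vocab)
    prob = notill_probability(drivers, logit_params)
    surface = downscale_notill(notill_area_true, potential, prob, hierarchy,
                               cropland_total=cropland.total())
    surface = crop_notill_fraction(surface, harea_cube_truth)

    # ---- assemble --------------------------------------------------------
    harea_county_df = pd.DataFrame(
        harea_county_truth.reshape(n_cro * n_i, n_y),
        index=pd.MultiIndex.from_product([crops, counties],
                                         names=["crop", "county"]),
        columns=list(years),
    )
    rate_county_df = pd.DataFrame(
        rate_truth.reshape(n_cro * 3 * n_i, n_y),
        index=pd.MultiIndex.from_product([crops, list(CLASSES), counties],
                                         names=["crop", "class", "county"]),
        columns=list(years),
    )
    namount_df = pd.DataFrame(
        namount_truth.reshape(3 * n_i, n_y),
        index=pd.MultiIndex.from_product([list(CLASSES), counties],
                                         names=["class", "county"]),
        columns=list(years),
    )
    truth = GroundTruth(
        harea_county=harea_county_df, harea_grid=harea_cube_truth,
        rate_county=rate_county_df, namount_county=namount_df,
        type_mix=type_mix_df, type_consumption_complete=complete_panel,
        national_notill=notill_area_true, notill=surface,
    )
    ref_map = pd.DataFrame(harea_ref, index=crops, columns=counties)
    return SyntheticWorld(
        config=config, vocabulary=vocab, grid=grid, hierarchy=hierarchy,
        reference_harea_map=ref_map, country_harea_series=nat_df,
        cropland_cube=cropland, prior_namount_panel=prior_df,
        fao_namount_series=fao_df, reference_rate_map=ref_rate_df,
        fubc_anchor_table=fubc_anchor, fubc_historic_table=fubc_hist,
        type_consumption_panel=panel, covariate_panel=cov_df,
        notill_drivers=drivers, notill_params=logit_params,
        notill_curve=curve, cropland_use_fraction=config.cropland_use_fraction,
        ground_truth=truth,
    )


def inject_missingness(
    panel: TypeConsumptionPanel,
    config: WorldConfig,
    rng: np.random.Generator | None = None,
) -> TypeConsumptionPanel:
    """Blank the configured year block for every reporting unit plus a
    random fraction of the remaining cells; the mask of blanked cells is
    kept for imputation scoring.  With no block and rate 0 the panel is
    returned unchanged (empty mask)."""
    rng = rng if rng is not None else np.random.default_rng(config.seed + 1)
    values = panel.values.copy()
    mask = pd.DataFrame(False, index=values.index, columns=values.columns)
    if config.missing_block is not None:
        b0, b1 = config.missing_block
        block_cols = [y for y in values.columns if b0 <= y <= b1]
        if block_cols:
            mask.loc[:, block_cols] = True
    if config.missing_frac > 0:
        eligible = ~mask.to_numpy()
        hits = (rng.random(mask.shape) < config.missing_frac) & eligible
        mask |= pd.DataFrame(hits, index=mask.index, columns=mask.columns)
    values = values.mask(mask)
    return TypeConsumptionPanel(values=values, total_sn=panel.total_sn.copy(),
                                missing_mask=mask)
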