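"""End-to-end orchestration of the reconstruction stages.

Fixed stage order: harvested area -> class amounts and crop rates ->
fertilizer-type shares -> placement -> conservation audits.  Every stage
consumes the previous stage's output; correction factors applied along the
way are logged.
"""

from __future__ import annotations

import logging
from dataclasses import dataclass, field

import numpy as np
import pandas as pd

from .fertilizer_types import (
    TypeShareCube, compute_type_shares, impute_missing_consumption,
)
from .grid import ConfigError
from .harvested_area import (
    HareaCube, county_sums, disaggregate_to_grid, extend_harvested_area,
    handle_disintegration, match_national_totals,
)
from .n_application import (
    NAmountPanel, NRateCube, calibrate_to_fubc, correct_sn_to_national,
    extend_n_amount, rasterize_rates, scale_crop_rates,
)
from .placement import (
    DEFAULT_INJECTED, BASE_TOPDRESSING_RATIO, LogitParams, NoTillSurface,
    PlacementCube, allocate_potential_notill, crop_notill_fraction,
    downscale_notill, notill_probability, placement_shares,
    predict_national_notill,
)
from .validation import ValidationReport, conservation_report

logger = logging.getLogger(__name__)


@dataclass
class RunParams:
    """Tunable parameters of a pipeline run."""

    injected: frozenset = DEFAULT_INJECTED
    base_topdressing_ratio: float = BASE_TOPDRESSING_RATIO
    logit_params: LogitParams | None = None      # default: world.notill_params
    notill_curve: tuple[float, float, float] | None = None  # default: fit census
    m_imputations: int = 5
    seed: int = 0


@dataclass
class PipelineResult:
    """All intermediate and final products of one reconstruction run."""

    harea_county: pd.DataFrame
    harea_cube: HareaCube
    harea_national: pd.DataFrame
    namount_panel: NAmountPanel
    county_rates: pd.DataFrame
    rate_cube: NRateCube
    type_shares: TypeShareCube
    notill: NoTillSurface
    placement: PlacementCube
    report: ValidationReport


def run_pipeline(world, params: RunParams | None = None) -> PipelineResult:
    """Run the full reconstruction on a (synthetic or adapted) world."""
    params = params or RunParams()
    hierarchy = world.hierarchy
    grid = world.grid
    vocab = world.vocabulary

    logit = params.logit_params or getattr(world, "notill_params", None)
    if logit is None:
        raise ConfigError(
            "missing logit-parameter block: supply RunParams.logit_params "
            "(k and xmid per predictor) or a world with notill_params"
        )

    # -- stage 1: harvested area -----------------------------------------
    logger.info("stage 1/5: harvested area")
    nat_h = handle_disintegration(world.country_harea_series,
                                  hierarchy.disintegration_events)
    county_h = extend_harvested_area(world.reference_harea_map, nat_h, hierarchy)
    cube = disaggregate_to_grid(county_h, world.cropland_cube, hierarchy, grid, vocab)
    cube = match_national_totals(cube, nat_h, hierarchy, world.cropland_cube)
    county_h = county_sums(cube, hierarchy)

    # -- stage 2: class amounts and crop rates ----------------------------
    logger.info("stage 2/5: N amounts and crop-specific rates")
    nat_a = handle_disintegration(world.fao_namount_series,
                                  hierarchy.disintegration_events)
    extended = extend_n_amount(NAmountPanel(world.prior_namount_panel, nat_a),
                               hierarchy)
    corrected = correct_sn_to_national(extended, nat_a, hierarchy,
                                       world.cropland_use_fraction)
    frac = world.cropland_use_fraction
    nat_audit = nat_a.copy()
    if isinstance(frac, dict):
        for j, fr in frac.items():
            nat_audit.loc[("SN", j)] *= fr
    else:
        nat_audit.loc["SN"] = (nat_audit.loc["SN"] * frac).to_numpy()
    panel = NAmountPanel(prior=world.prior_namount_panel, national=nat_audit,
                         corrected=corrected)
    rates = scale_crop_rates(corrected, world.reference_rate_map, county_h, vocab)
    rates = calibrate_to_fubc(rates, county_h, world.fubc_anchor_table,
                              hierarchy, vocab)
    rate_cube = rasterize_rates(rates, hierarchy, grid)

    # -- stage 3: fertilizer-type shares ----------------------------------
    logger.info("stage 3/5: fertilizer-type shares")
    imputed = impute_missing_consumption(
        world.type_consumption_panel, world.covariate_panel, hierarchy,
        m_imputations=params.m_imputations, seed=params.seed,
    )
    shares = compute_type_shares(imputed, panel, hierarchy, grid, vocab)

    # -- stage 4: placement ------------------------------------------------
    logger.info("stage 4/5: no-till surface and placement")
    drivers = world.notill_drivers
    total_h = cube.total()
    suit_idx = [cube.crops.index(c) for c in vocab.notill_crops if c in cube.crops]
    with np.errstate(invalid="ignore", divide="ignore"):
        crop_mix = np.where(total_h > 0,
                            cube.values[suit_idx].sum(axis=0)
                            / np.where(total_h > 0, total_h, 1.0), 0.0)
    drivers.crop_mix = crop_mix
    cropland_country = pd.DataFrame(
        {y: np.zeros(len(hierarchy.countries)) for y in cube.years},
        index=list(hierarchy.countries),
    )
    country_r = hierarchy.country_raster()
    land = country_r >= 0
    cl_total = world.cropland_cube.total()
    for yi, y in enumerate(cube.years):
        cropland_country[y] = np.bincount(
            country_r[land], weights=cl_total[yi][land],
            minlength=len(hierarchy.countries),
        )
    targets = predict_national_notill(
        drivers.rural_population, cropland_country, drivers.census_notill,
        hierarchy, curve_params=params.notill_curve,
    )
    potential = allocate_potential_notill(cube, drivers, hierarchy, vocab)
    prob = notill_probability(drivers, logit)
    surface = downscale_notill(targets, potential, prob, hierarchy,
                               cropland_total=cl_total)
    surface = crop_notill_fraction(surface, cube)
    placement = placement_shares(surface, vocab, injected=params.injected,
                                 base_ratio=params.base_topdressing_ratio)

    # -- stage 5: audits ----------------------------------------------------
    logger.info("stage 5/5: conservation audits")
    report = conservation_report(
        harea_cube=cube, harea_national=nat_h, namount_panel=panel,
        rates=rates, harea_county=county_h, fubc=world.fubc_anchor_table,
        type_shares=shares, placement=placement, hierarchy=hierarchy,
        vocab=vocab,
    )
    if not report.passed:
        failing = report.conservation[
            report.conservation["max_rel_err"] > report.conservation["tol"]
        ].index.tolist()
        raise RuntimeError(f"stage contract violated: {failing}\n{report}")
    return PipelineResult(
        harea_county=county_h, harea_cube=cube, harea_national=nat_h,
        namount_panel=panel, county_rates=rates, rate_cube=rate_cube,
        type_shares=shares, notill=surface, placement=placement, report=report,
    )
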