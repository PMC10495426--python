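"""Monte Carlo uncertainty of crop-specific rates.

The constant-ratio assumption — all crops in a county share one temporal
scaling of the application rate — is the dominant approximation of the
reconstruction.  Its uncertainty is quantified by perturbing each
year-to-year change ratio of a crop-region rate trajectory with mean-1
normal noise whose standard deviation is the coefficient of variation (CV)
of that crop group's fertilizer use across the five survey anchor years,
rebuilding trajectories outward from the year-2000 anchor, and taking the
2.5th/97.5th percentiles across iterations.
"""

from __future__ import annotations

import logging
from dataclasses import dataclass

import numpy as np
import pandas as pd

from .n_application import FUBC_ANCHOR_YEARS

logger = logging.getLogger(__name__)

ANCHOR_YEAR = 2000
DEFAULT_N_ITER = 1000


@dataclass
class UncertaintyEnvelope:
    """Point estimate plus Monte Carlo summary per trajectory and year."""

    point: pd.DataFrame      # trajectories x years
    mean: pd.DataFrame
    sd: pd.DataFrame
    lower: pd.DataFrame      # 2.5th percentile
    upper: pd.DataFrame      # 97.5th percentile
    n_iterations: int


def estimate_cv_from_fubc(
    fubc: pd.DataFrame,
    region_map: dict[str, str],
    *,
    anchor_years: tuple[int, ...] = FUBC_ANCHOR_YEARS,
) -> pd.DataFrame:
    """Mean, sample SD (n-1), and CV of crop-group fertilizer use per region.

    ``fubc``: (group, country) x anchor-year consumption amounts; countries
    are pooled onto regions via ``region_map``.  Groups with zero mean have
    an undefined CV and are flagged (CV = NaN) and excluded by consumers.
    """
    frame = fubc.loc[:, list(anchor_years)].copy()
    frame["region"] = [region_map.get(j, j) for j in frame.index.get_level_values(1)]
    pooled = frame.groupby([frame.index.get_level_values(0), "region"]).sum()
    pooled.index.names = ["group", "region"]
    mean = pooled.mean(axis=1)
    sd = pooled.std(axis=1, ddof=1)
    with np.errstate(invalid="ignore", divide="ignore"):
        cv = sd / mean
    undefined = mean <= 0
    if undefined.any():
        logger.warning("%d group-regions with zero mean consumption; CV undefined",
                       int(undefined.sum()))
        cv[undefined] = np.nan
    return pd.DataFrame({"mean": mean, "sd": sd, "cv": cv})


def _perturbation_factors(
    n_years: int, anchor_idx: int, cv: float, n_iter: int,
    rng: np.random.Generator,
) -> np.ndarray:
    """Cumulative multiplicative factors (n_iter, n_years), 1 at the anchor.

    Each year-to-year ratio is multiplied by an independent N(1, cv) draw
    truncated at zero; factors accumulate outward from the anchor in both
    directions.
    """
    eps = np.maximum(rng.normal(1.0, cv, size=(n_iter, n_years)), 0.0)
    factors = np.ones((n_iter, n_years))
    for t in range(anchor_idx + 1, n_years):
        factors[:, t] = factors[:, t - 1] * eps[:, t]
    for t in range(anchor_idx - 1, -1, -1):
        factors[:, t] = factors[:, t + 1] * eps[:, t]
    return factors


def monte_carlo_rates(
    rates: pd.DataFrame,
    cv: pd.Series | pd.DataFrame,
    *,
    n_iter: int = DEFAULT_N_ITER,
    seed: int = 0,
    anchor_year: int = ANCHOR_YEAR,
) -> UncertaintyEnvelope:
    """Monte Carlo envelope for rate trajectories.

    ``rates``: trajectories x years (one row per crop-region series).
    ``cv``: one CV per row (aligned by index); rows with a missing CV keep
    their point estimate as a degenerate envelope (logged).
    """
    if n_iter < 2:
        raise ValueError("n_iter must be at least 2")
    rng = np.random.default_rng(seed)
    years = list(rates.columns)
    anchor_idx = years.index(anchor_year) if anchor_year in years else 0
    if isinstance(cv, pd.DataFrame):
        cv = cv["cv"]
    cvs = cv.reindex(rates.index)

    mean = rates.copy()
    sd = rates.copy() * 0.0
    lower = rates.copy()
    upper = rates.copy()
    n_missing = int(cvs.isna().sum())
    if n_missing:
        logger.warning("%d trajectories without a CV; envelope equals the point estimate",
                       n_missing)
    for row in rates.index:
        c = cvs.loc[row]
        x = rates.loc[row].to_numpy()
        if not np.isfinite(c):
            continue
        factors = _perturbation_factors(len(years), anchor_idx, float(c), n_iter, rng)
        sims = x[None, :] * factors
        mean.loc[row] = sims.mean(axis=0)
        sd.loc[row] = sims.std(axis=0, ddof=1)
        lower.loc[row] = np.percentile(sims, 2.5, axis=0)
        upper.loc[row] = np.percentile(sims, 97.5, axis=0)
    return UncertaintyEnvelope(point=rates.copy(), mean=mean, sd=sd,
                               lower=lower, upper=upper, n_iterations=n_iter)
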