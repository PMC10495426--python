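"""Fertilizer-type consumption imputation and 13-way type shares.

The type-consumption panel (11 synthetic fertilizer types x reporting unit x
year, kg N) has structural gaps — notably an early-period block missing for
every reporting unit — that are filled with a multiple-imputation scheme for
time-series cross-section data: a bootstrap-EM multivariate-normal model on
log-transformed consumption with national covariates (GDP, population,
cropland area) and polynomial time terms, averaging m imputation draws.
Shares then follow the amount identity: CR and MA shares are their amount
over the total; each synthetic type's share is its survey consumption
proportion times the synthetic share of the total.
"""

from __future__ import annotations

import logging
from dataclasses import dataclass, field

import numpy as np
import pandas as pd

from .grid import AdminHierarchy, GridDefinition
from .n_application import NAmountPanel
from .vocab import Vocabulary, DEFAULT_VOCAB

logger = logging.getLogger(__name__)


@dataclass
class TypeConsumptionPanel:
    """Synthetic-fertilizer consumption by type, reporting unit, and year.

    ``values`` is a (sn_type, unit) x year table in kg N with NaN for missing
    cells; ``total_sn`` (unit x year) may be observed even when components
    are missing; ``missing_mask`` marks cells that were blanked.
    """

    values: pd.DataFrame
    total_sn: pd.DataFrame
    missing_mask: pd.DataFrame | None = None

    @property
    def units(self) -> list[str]:
        return list(self.values.index.get_level_values(1).unique())

    def copy(self) -> "TypeConsumptionPanel":
        return TypeConsumptionPanel(
            self.values.copy(), self.total_sn.copy(),
            None if self.missing_mask is None else self.missing_mask.copy(),
        )


@dataclass
class TypeShareCube:
    """Fractions of total N amount by the 13 fertilizer types."""

    types: tuple[str, ...]
    years: np.ndarray
    county: pd.DataFrame          # (type, county) x year fractions
    gridded: np.ndarray           # (13, n_years, R, C)


# ---------------------------------------------------------------------------
# EM for a multivariate normal with missing values
# ---------------------------------------------------------------------------

def _em_mvn(X: np.ndarray, *, max_iter: int = 100, tol: float = 1e-6,
            ridge: float = 1e-6) -> tuple[np.ndarray, np.ndarray]:
    """Fit mean and covariance of a MVN from rows with missing entries.

    Classic EM: the E-step replaces missing entries with their conditional
    expectations (accumulating the conditional covariance into the second
    moment), the M-step re-estimates the mean and covariance.  A small ridge
    keeps the covariance invertible for collinear columns.
    """
    n, p = X.shape
    obs = ~np.isnan(X)
    col_mean = np.nanmean(X, axis=0)
    Xf = np.where(obs, X, col_mean)
    mu = Xf.mean(axis=0)
    sigma = np.cov(Xf, rowvar=False) + ridge * np.eye(p)

    patterns: dict[bytes, np.ndarray] = {}
    for r in range(n):
        patterns.setdefault(obs[r].tobytes(), []).append(r)  # type: ignore[arg-type]
    patterns = {k: np.array(v) for k, v in patterns.items()}

    for _ in range(max_iter):
        Ex = np.where(obs, X, 0.0)
        Exx_corr = np.zeros((p, p))
        for key, rows in patterns.items():
            o = np.frombuffer(key, dtype=bool)
            m = ~o
            if not m.any():
                continue
            S_oo = sigma[np.ix_(o, o)]
            S_mo = sigma[np.ix_(m, o)]
            S_mm = sigma[np.ix_(m, m)]
            solve = np.linalg.solve(S_oo, (X[np.ix_(rows, o)] - mu[o]).T)
            cond_mean = mu[m][None, :] + (S_mo @ solve).T
            cond_cov = S_mm - S_mo @ np.linalg.solve(S_oo, S_mo.T)
            Ex[np.ix_(rows, m)] = cond_mean
            Exx_corr[np.ix_(m, m)] += len(rows) * cond_cov
        mu_new = Ex.mean(axis=0)
        centered = Ex - mu_new
        sigma_new = (centered.T @ centered + Exx_corr) / n + ridge * np.eye(p)
        shift = np.max(np.abs(mu_new - mu)) + np.max(np.abs(sigma_new - sigma))
        scale = 1.0 + np.max(np.abs(mu)) + np.max(np.abs(sigma))
        mu, sigma = mu_new, sigma_new
        if shift / scale < tol:
            break
    return mu, sigma


def _conditional_draw(X: np.ndarray, mu: np.ndarray, sigma: np.ndarray,
                      rng: np.random.Generator) -> np.ndarray:
    """One imputation draw: missing entries sampled from their conditional
    normal given the observed entries of the row."""
    out = X.copy()
    obs = ~np.isnan(X)
    patterns: dict[bytes, list[int]] = {}
    for r in range(X.shape[0]):
        patterns.setdefault(obs[r].tobytes(), []).append(r)
    for key, rows in patterns.items():
        o = np.frombuffer(key, dtype=bool)
        m = ~o
        if not m.any():
            continue
        rows_a = np.array(rows)
        S_oo = sigma[np.ix_(o, o)]
        S_mo = sigma[np.ix_(m, o)]
        cond_cov = sigma[np.ix_(m, m)] - S_mo @ np.linalg.solve(S_oo, S_mo.T)
        cond_cov = (cond_cov + cond_cov.T) / 2 + 1e-9 * np.eye(m.sum())
        L = np.linalg.cholesky(cond_cov)
        solve = np.linalg.solve(S_oo, (X[np.ix_(rows_a, o)] - mu[o]).T)
        cond_mean = mu[m][None, :] + (S_mo @ solve).T
        z = rng.standard_normal((len(rows_a), int(m.sum())))
        out[np.ix_(rows_a, m)] = cond_mean + z @ L.T
    return out


def impute_missing_consumption(
    panel: TypeConsumptionPanel,
    covariates: pd.DataFrame,
    hierarchy: AdminHierarchy | None = None,
    *,
    m_imputations: int = 5,
    seed: int = 0,
    min_obs: int = 3,
    time_degree: int = 3,
) -> TypeConsumptionPanel:
    """Fill missing consumption cells; observed cells pass through untouched.

    ``covariates`` is a (variable, country) x year table with variables
    gdp, population, cropland; countries are aggregated onto the panel's
    reporting units when a hierarchy with a region map is given.  Reporting
    units with fewer than ``min_obs`` observed years for some type fall back
    to within-unit linear interpolation/extrapolation for that type.
    """
    rng = np.random.default_rng(seed)
    values = panel.values
    if not values.isna().any().any():
        return panel.copy()
    types = list(values.index.get_level_values(0).unique())
    units = panel.units
    years = np.array(list(values.columns), dtype=float)

    # unit-level covariates: sum member countries (fall back to unit name)
    cov_vars = list(covariates.index.get_level_values(0).unique())
    cov_unit = {}
    for u in units:
        if hierarchy is not None and hierarchy.regions:
            members = [j for j in hierarchy.countries
                       if hierarchy.regions.get(j, j) == u]
        else:
            members = [u]
        rows = covariates.reindex(
            pd.MultiIndex.from_product([cov_vars, members])
        ).fillna(0.0)
        cov_unit[u] = rows.groupby(level=0).sum().reindex(cov_vars)

    t = (years - years.mean()) / max(years.std(), 1.0)
    blocks = []
    for u in units:
        cons = np.log1p(
            values.reindex(pd.MultiIndex.from_product([types, [u]]))
            .to_numpy().reshape(len(types), len(years)).T
        )
        covs = np.log1p(np.maximum(cov_unit[u].to_numpy().T, 0.0))
        poly = np.column_stack([t**d for d in range(1, time_degree + 1)])
        blocks.append(np.column_stack([cons, covs, poly]))
    X = np.concatenate(blocks, axis=0)          # (units*years, p)

    draws = np.zeros((m_imputations, X.shape[0], len(types)))
    n_rows = X.shape[0]
    for d in range(m_imputations):
        boot = rng.integers(0, n_rows, size=n_rows)
        mu, sigma = _em_mvn(X[boot])
        filled = _conditional_draw(X, mu, sigma, rng)
        draws[d] = filled[:, : len(types)]
    mean_draw = draws.mean(axis=0)

    out = values.copy()
    for ui, u in enumerate(units):
        block = mean_draw[ui * len(years): (ui + 1) * len(years)]
        for ti, f in enumerate(types):
            series = out.loc[(f, u)]
            miss = series.isna()
            if not miss.any():
                continue
            n_obs = int((~miss).sum())
            if n_obs < min_obs:
                logger.warning(
                    "unit %s type %s has only %d observed years; falling back "
                    "to linear interpolation", u, f, n_obs,
                )
                filled = series.interpolate(limit_direction="both")
                out.loc[(f, u), miss[miss].index] = filled[miss].fillna(0.0)
            else:
                imput = np.maximum(np.expm1(block[:, ti]), 0.0)
                out.loc[(f, u), miss[miss].index] = imput[miss.to_numpy()]
    mask = values.isna()
    return TypeConsumptionPanel(out, panel.total_sn.copy(), mask)


def compute_type_shares(
    panel: TypeConsumptionPanel,
    amounts: NAmountPanel,
    hierarchy: AdminHierarchy,
    grid: GridDefinition,
    vocab: Vocabulary = DEFAULT_VOCAB,
    *,
    total_mismatch_tol: float = 0.01,
) -> TypeShareCube:
    """13-way fertilizer-type shares of the total N amount, per county and
    gridded.

    CR and MA shares come from the county amount panel directly; synthetic
    types multiply the unit-level consumption proportion by the county SN
    share.  Component proportions are normalized to the component sum (the
    reported total is only trusted when it agrees within
    ``total_mismatch_tol``); a unit-year with zero component consumption but
    positive SN amount routes the SN mass to urea as the default carrier.
    """
    if amounts.corrected is None:
        raise ValueError("amounts panel lacks the corrected county amounts")
    corrected = amounts.corrected
    years = list(corrected.columns)
    counties = list(corrected.index.get_level_values(1).unique())
    sn_types = list(vocab.sn_types)

    cls = corrected.to_numpy().reshape(3, len(counties), len(years))
    classes = list(corrected.index.get_level_values(0).unique())
    sn = cls[classes.index("SN")]
    ma = cls[classes.index("MA")]
    cr = cls[classes.index("CR")]
    total = sn + ma + cr

    units = panel.units
    vals = panel.values.to_numpy().reshape(len(sn_types), len(units), len(years))
    comp_sum = vals.sum(axis=0)                              # (unit, year)
    reported = panel.total_sn.reindex(units).to_numpy()
    with np.errstate(invalid="ignore", divide="ignore"):
        disagree = np.abs(comp_sum - reported) > total_mismatch_tol * np.maximum(reported, 1e-300)
    if np.nansum(disagree & (reported > 0)) > 0:
        logger.info(
            "%d unit-years where component consumption disagrees with the "
            "reported total by >%g%%; normalizing to the component sum",
            int(np.nansum(disagree & (reported > 0))), 100 * total_mismatch_tol,
        )
    with np.errstate(invalid="ignore", divide="ignore"):
        q = np.where(comp_sum > 0, vals / np.where(comp_sum > 0, comp_sum, 1.0), 0.0)
    # zero component consumption: urea carries the SN mass
    urea = sn_types.index("Urea")
    zero_cols = comp_sum <= 0
    if zero_cols.any():
        logger.warning(
            "%d unit-years with zero component consumption; assigning the "
            "synthetic share to urea", int(zero_cols.sum()),
        )
        q[urea][zero_cols] = 1.0

    unit_of_county = np.array([
        units.index(hierarchy.regions.get(hierarchy.county_country[c],
                                          hierarchy.county_country[c]))
        for c in counties
    ])
    with np.errstate(invalid="ignore", divide="ignore"):
        inv_total = np.where(total > 0, 1.0 / np.where(total > 0, total, 1.0), 0.0)
    shares = np.zeros((len(vocab.fertilizer_types), len(counties), len(years)))
    for fi, f in enumerate(vocab.fertilizer_types):
        if f == "CR":
            shares[fi] = cr * inv_total
        elif f == "MA":
            shares[fi] = ma * inv_total
        else:
            shares[fi] = q[sn_types.index(f)][unit_of_county] * sn * inv_total

    idx = pd.MultiIndex.from_product([vocab.fertilizer_types, counties],
                                     names=["type", "county"])
    county_df = pd.DataFrame(shares.reshape(-1, len(years)), index=idx, columns=years)

    mem = hierarchy.membership
    land = mem >= 0
    gridded = shares[:, np.clip(mem, 0, None), :]            # (type, R, C, year)
    gridded = np.moveaxis(gridded, -1, 1)
    gridded[:, :, ~land] = 0.0
    return TypeShareCube(
        types=tuple(vocab.fertilizer_types), years=np.array(years),
        county=county_df, gridded=gridded,
    )
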