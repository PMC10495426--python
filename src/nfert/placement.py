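"""Deep/surface placement fractions driven by a gridded no-till surface.

National no-till fractions are predicted from cropland area per rural
capita (a labour-availability proxy) with a monotone scaled-logistic
regression, overridden by sub-national census statistics where available.
The national area is downscaled to grid cells that are eligible for no-till
(rain-fed area of 11 suitable annual crops; low-income countries only where
large fields dominate), ranked by a four-predictor logit probability
(erosion, aridity, crop mix, field size) and selected greedily until the
national target is met.  Cell no-till area is split across crops by
harvested-area share.  Placement then follows fixed rules per fertilizer
type: injected fertilizers go fully deep; other synthetic fertilizers are
incorporated at the 0.7 base-topdressing ratio times the no-till fraction;
manure and residues are incorporated only where tillage remains.
"""

from __future__ import annotations

import logging
from dataclasses import dataclass, field

import numpy as np
import pandas as pd
from scipy.optimize import curve_fit

from .grid import AdminHierarchy, ConfigError
from .harvested_area import HareaCube
from .vocab import Vocabulary, DEFAULT_VOCAB

logger = logging.getLogger(__name__)

BASE_TOPDRESSING_RATIO = 0.7
#: Fertilizers commonly injected and therefore always placed deep.  The
#: classification by application mechanism puts anhydrous ammonia and
#: nitrogen solutions here; ``{"AA", "AN"}`` restores the alternative
#: grouping in which ammonium nitrate joins anhydrous ammonia.
DEFAULT_INJECTED: frozenset = frozenset({"AA", "NS"})

PREDICTORS = ("erosion", "aridity", "crop_mix", "field_size")


@dataclass(frozen=True)
class LogitParams:
    """Slope and midpoint per predictor of the no-till probability logit."""

    k: dict[str, float]
    xmid: dict[str, float]

    def __post_init__(self) -> None:
        for name in PREDICTORS:
            if name not in self.k or name not in self.xmid:
                raise ConfigError(
                    f"logit parameters must provide k and xmid for {name!r}; "
                    f"got k={sorted(self.k)}, xmid={sorted(self.xmid)}"
                )

    @classmethod
    def from_dict(cls, d: dict) -> "LogitParams":
        if not d:
            raise ConfigError(
                "missing logit-parameter block: provide k and xmid for "
                f"predictors {PREDICTORS}"
            )
        return cls(k=dict(d["k"]), xmid=dict(d["xmid"]))


@dataclass
class NoTillDrivers:
    """Static rasters and national series driving the no-till surface."""

    field_size: np.ndarray                 # (R, C), field-size proxy
    erosion: np.ndarray                    # (R, C)
    aridity: np.ndarray                    # (R, C) precipitation / PET
    income_class: dict[str, str]           # country -> "high" | "low"
    rural_population: pd.DataFrame         # country x year
    census_notill: pd.DataFrame | None = None   # (country, province) x year area
    rainfed_fraction: np.ndarray | None = None  # (R, C)
    crop_mix: np.ndarray | None = None     # (n_years, R, C), filled by pipeline
    large_field_threshold: float = 0.0


@dataclass
class NoTillSurface:
    """Cell and crop no-till fractions plus the allocated areas."""

    years: np.ndarray
    cell_area: np.ndarray                  # (n_years, R, C) allocated area
    cell_fraction: np.ndarray              # (n_years, R, C) of cropland
    crop_fraction: np.ndarray | None = None  # (n_crops, n_years, R, C)
    crops: tuple[str, ...] | None = None


@dataclass
class PlacementCube:
    """Deep/surface fractions per crop x fertilizer, lazily expanded.

    surface + deep = 1 exactly for every crop-fertilizer pair.
    """

    crops: tuple[str, ...]
    fertilizer_types: tuple[str, ...]
    years: np.ndarray
    notill_crop: np.ndarray                # (n_crops, n_years, R, C)
    injected: frozenset = DEFAULT_INJECTED
    base_ratio: float = BASE_TOPDRESSING_RATIO

    def deep(self, crop: str, ftype: str) -> np.ndarray:
        nt = self.notill_crop[self.crops.index(crop)]
        if ftype in self.injected:
            return np.ones_like(nt)
        if ftype in ("CR", "MA"):
            return 1.0 - nt
        return self.base_ratio * nt

    def surface(self, crop: str, ftype: str) -> np.ndarray:
        return 1.0 - self.deep(crop, ftype)


def _scaled_logistic(x: np.ndarray, amp: float, x0: float, s: float) -> np.ndarray:
    return amp / (1.0 + np.exp(-(np.log(np.maximum(x, 1e-12)) - x0) / s))


def predict_national_notill(
    rural_population: pd.DataFrame,
    cropland_area: pd.DataFrame,
    census_notill: pd.DataFrame | None,
    hierarchy: AdminHierarchy,
    *,
    curve_params: tuple[float, float, float] | None = None,
) -> pd.DataFrame:
    """Country x year no-till area (ha).

    The no-till fraction is a monotone non-decreasing scaled logistic in
    log(cropland per rural capita), clipped to [0, 1], times the cropland
    area.  If ``curve_params`` (amplitude, log-midpoint, scale) is not
    given, the curve is fitted to the census countries' national fractions.
    Census country-years use the census areas directly.
    """
    countries = list(hierarchy.countries)
    years = list(cropland_area.columns)
    crop = cropland_area.reindex(countries).fillna(0.0)
    rural = rural_population.reindex(countries).reindex(columns=years)

    zero_rural = (rural.to_numpy() <= 0) | rural.isna().to_numpy()
    x = crop.to_numpy() / np.where(zero_rural, 1.0, rural.to_numpy())

    census_nat = None
    if census_notill is not None and len(census_notill):
        # min_count keeps uncovered census years as NaN instead of zero
        census_nat = census_notill.groupby(level=0).sum(min_count=1)

    if curve_params is None:
        if census_nat is None:
            raise ConfigError(
                "no census no-till statistics and no regression parameters; "
                "provide curve_params=(amplitude, log_midpoint, scale)"
            )
        xs, fs = [], []
        for j in census_nat.index:
            ji = countries.index(j)
            for y in census_nat.columns:
                v = census_nat.loc[j, y]
                if y in years and crop.loc[j, y] > 0 and np.isfinite(v):
                    xs.append(x[ji, years.index(y)])
                    fs.append(v / crop.loc[j, y])
        xs_a, fs_a = np.array(xs), np.clip(np.array(fs), 0.0, 1.0)
        try:
            popt, _ = curve_fit(
                _scaled_logistic, xs_a, fs_a,
                p0=(max(fs_a.max(), 0.1), float(np.log(np.maximum(xs_a, 1e-12)).mean()), 1.0),
                bounds=([1e-6, -20.0, 1e-3], [1.0, 20.0, 20.0]),
                maxfev=10_000,
            )
            curve_params = tuple(popt)
        except RuntimeError:
            curve_params = (float(np.clip(fs_a.mean(), 1e-6, 1.0)), 0.0, 1.0)
            logger.warning(
                "no-till regression fit failed; using flat fraction %.3f",
                curve_params[0],
            )

    amp, x0, s = curve_params
    frac = np.clip(_scaled_logistic(x, amp, x0, s), 0.0, 1.0)
    if zero_rural.any():
        logger.warning(
            "%d country-years with zero rural population; no-till fraction "
            "set to the model's upper asymptote", int(zero_rural.sum()),
        )
        frac[zero_rural] = np.clip(amp, 0.0, 1.0)
    area = pd.DataFrame(frac * crop.to_numpy(), index=countries, columns=years)

    if census_nat is not None:
        for j in census_nat.index:
            for y in census_nat.columns:
                v = census_nat.loc[j, y]
                if y in area.columns and np.isfinite(v):
                    area.loc[j, y] = v
    return area


def allocate_potential_notill(
    harea: HareaCube,
    drivers: NoTillDrivers,
    hierarchy: AdminHierarchy,
    vocab: Vocabulary = DEFAULT_VOCAB,
) -> np.ndarray:
    """Potential no-till area per year and cell.

    Rain-fed harvested area of the 11 suitable crops; zeroed in low-income
    countries where large fields do not dominate (high-income countries keep
    all field sizes).
    """
    suit_idx = [harea.crops.index(c) for c in vocab.notill_crops if c in harea.crops]
    potential = harea.values[suit_idx].sum(axis=0)           # (n_years, R, C)
    if drivers.rainfed_fraction is not None:
        potential = potential * drivers.rainfed_fraction[None, :, :]
    country_r = hierarchy.country_raster()
    low_income = np.zeros(country_r.shape, dtype=bool)
    for ji, j in enumerate(hierarchy.countries):
        if drivers.income_class.get(j, "high") == "low":
            low_income |= country_r == ji
    small_fields = drivers.field_size < drivers.large_field_threshold
    potential = potential.copy()
    potential[:, low_income & small_fields] = 0.0
    return potential


def notill_probability(
    drivers: NoTillDrivers,
    params: LogitParams,
) -> np.ndarray:
    """Four-predictor logit probability of no-till occurrence per cell.

    p = 1 / (1 + exp(-sum_n k_n (x_n - xmid_n))).  Cells with a missing
    driver value get probability 0 (logged).
    """
    layers = {
        "erosion": drivers.erosion,
        "aridity": drivers.aridity,
        "field_size": drivers.field_size,
        "crop_mix": drivers.crop_mix,
    }
    if layers["crop_mix"] is None:
        raise ConfigError("drivers.crop_mix not set; compute it from the harvested-area cube")
    mix = layers["crop_mix"]
    per_year = mix.ndim == 3
    shape = mix.shape if per_year else (1, *mix.shape)
    z = np.zeros(shape)
    invalid = np.zeros(shape, dtype=bool)
    for name in PREDICTORS:
        v = layers[name]
        if v.ndim == 2 and per_year:
            v = v[None, :, :]
        elif v.ndim == 2:
            v = v[None, :, :]
        bad = ~np.isfinite(v)
        invalid |= bad
        z = z + params.k[name] * (np.where(bad, 0.0, v) - params.xmid[name])
    prob = 1.0 / (1.0 + np.exp(-z))
    if invalid.any():
        logger.warning("%d cells with missing no-till drivers; probability 0",
                       int(invalid.any(axis=0).sum()))
        prob[invalid] = 0.0
    return prob if per_year else prob[0]


def downscale_notill(
    targets: pd.DataFrame,
    potential: np.ndarray,
    probability: np.ndarray,
    hierarchy: AdminHierarchy,
    cropland_total: np.ndarray | None = None,
) -> NoTillSurface:
    """Greedy ranked allocation of national no-till areas to cells.

    Within each country-year, cells are ranked by descending probability
    (ties broken by cell index); each selected cell contributes
    potential x probability; the last cell is partially selected so the
    allocated sum hits the target exactly.  Targets above the total
    available contribution select everything (shortfall logged).
    """
    years = list(targets.columns)
    n_years = len(years)
    R, C = hierarchy.membership.shape
    if potential.ndim == 2:
        potential = np.broadcast_to(potential, (n_years, R, C))
    if probability.ndim == 2:
        probability = np.broadcast_to(probability, (n_years, R, C))
    country_r = hierarchy.country_raster().ravel()
    cell_area = np.zeros((n_years, R, C))
    shortfalls = 0
    for ji, j in enumerate(hierarchy.countries):
        cells = np.nonzero(country_r == ji)[0]
        if not len(cells):
            continue
        for yi, y in enumerate(years):
            target = float(targets.loc[j, y]) if j in targets.index else 0.0
            if target <= 0:
                continue
            pot = potential[yi].ravel()[cells]
            prob = probability[yi].ravel()[cells]
            contrib = pot * prob
            order = np.lexsort((cells, -prob))
            sorted_contrib = contrib[order]
            cum = np.cumsum(sorted_contrib)
            total = cum[-1] if len(cum) else 0.0
            alloc = np.zeros(len(cells))
            if total <= target:
                alloc = sorted_contrib
                if total < target:
                    shortfalls += 1
            else:
                k = int(np.searchsorted(cum, target, side="left"))
                alloc[:k] = sorted_contrib[:k]
                prev = cum[k - 1] if k > 0 else 0.0
                alloc[k] = target - prev
            flat = np.zeros(len(cells))
            flat[order] = alloc
            cell_area[yi].flat[cells] = flat
    if shortfalls:
        logger.warning(
            "%d country-years where the no-till target exceeds the total "
            "potential contribution; allocation capped", shortfalls,
        )
    if cropland_total is not None:
        with np.errstate(invalid="ignore", divide="ignore"):
            frac = np.where(cropland_total > 0,
                            cell_area / np.where(cropland_total > 0, cropland_total, 1.0),
                            0.0)
        frac = np.clip(frac, 0.0, 1.0)
    else:
        frac = np.zeros_like(cell_area)
    return NoTillSurface(years=np.array(years), cell_area=cell_area, cell_fraction=frac)


def crop_notill_fraction(surface: NoTillSurface, harea: HareaCube) -> NoTillSurface:
    """Split cell no-till area across crops by harvested-area share and
    express it as a fraction of each crop's harvested area (clipped to 1)."""
    total = harea.total()
    with np.errstate(invalid="ignore", divide="ignore"):
        per_area = np.where(total > 0,
                            surface.cell_area / np.where(total > 0, total, 1.0), 0.0)
    crop_frac = np.clip(per_area[None, :, :, :] * np.ones((len(harea.crops), 1, 1, 1)),
                        0.0, 1.0)
    crop_frac[harea.values <= 0] = 0.0
    return NoTillSurface(
        years=surface.years, cell_area=surface.cell_area,
        cell_fraction=surface.cell_fraction,
        crop_fraction=crop_frac, crops=harea.crops,
    )


def placement_shares(
    notill: NoTillSurface,
    vocab: Vocabulary = DEFAULT_VOCAB,
    *,
    injected: frozenset = DEFAULT_INJECTED,
    base_ratio: float = BASE_TOPDRESSING_RATIO,
) -> PlacementCube:
    """Deep/surface fractions per crop and fertilizer from the no-till
    surface (see module docstring for the three placement rules)."""
    if notill.crop_fraction is None or notill.crops is None:
        raise ValueError("no-till surface lacks crop fractions; run crop_notill_fraction")
    unknown = injected - set(vocab.sn_types)
    if unknown:
        raise ConfigError(f"injected set contains non-synthetic types: {sorted(unknown)}")
    return PlacementCube(
        crops=notill.crops, fertilizer_types=tuple(vocab.fertilizer_types),
        years=notill.years, notill_crop=notill.crop_fraction,
        injected=frozenset(injected), base_ratio=base_ratio,
    )
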