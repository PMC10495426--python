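"""Spatial scaffold: the regular lon/lat grid and the administrative hierarchy.

Grid cells (index ``g``) nest in counties/districts (``i``), which nest in
countries (``j``); countries belong to fertilizer-survey reporting regions
(``m``).  All cubes in the pipeline share one :class:`GridDefinition` and one
:class:`AdminHierarchy`.
"""

from __future__ import annotations

from dataclasses import dataclass, field

import numpy as np

EARTH_RADIUS_M = 6_371_000.0


class ConfigError(ValueError):
    """Raised when a configuration or input contract is violated."""


@dataclass(frozen=True)
class GridDefinition:
    """A regular geographic grid in WGS84, row-major from the north-west corner.

    Parameters
    ----------
    n_rows, n_cols
        Cell counts.  The production grid is 2160 x 4320 at 5 arc-min;
        tests use desk-scale grids driven through the same code path.
    resolution
        Cell size in degrees (both axes).
    origin
        (lon, lat) of the grid's upper-left (north-west) corner.
    """

    n_rows: int
    n_cols: int
    resolution: float
    origin: tuple[float, float] = (-180.0, 90.0)
    crs_label: str = "WGS84"

    def __post_init__(self) -> None:
        if self.resolution <= 0:
            raise ConfigError("grid resolution must be positive")
        if self.n_rows <= 0 or self.n_cols <= 0:
            raise ConfigError("grid shape must be positive")

    @property
    def shape(self) -> tuple[int, int]:
        return (self.n_rows, self.n_cols)

    def cell_latitudes(self) -> np.ndarray:
        """Cell-centre latitudes per row (degrees), north to south."""
        lat0 = self.origin[1]
        return lat0 - (np.arange(self.n_rows) + 0.5) * self.resolution

    def cell_longitudes(self) -> np.ndarray:
        lon0 = self.origin[0]
        return lon0 + (np.arange(self.n_cols) + 0.5) * self.resolution

    def cell_areas_ha(self) -> np.ndarray:
        """Spherical-approximation cell areas (ha), shape (n_rows, n_cols).

        Latitude bands shrink towards the poles; areas are strictly positive
        for any grid that stays inside [-90, 90].
        """
        res_rad = np.deg2rad(self.resolution)
        lat_top = np.deg2rad(self.origin[1] - np.arange(self.n_rows) * self.resolution)
        lat_bot = lat_top - res_rad
        band = EARTH_RADIUS_M**2 * res_rad * (np.sin(lat_top) - np.sin(lat_bot))
        areas_m2 = np.repeat(band[:, None], self.n_cols, axis=1)
        return areas_m2 / 1e4


@dataclass(frozen=True)
class DisintegrationEvent:
    """A country splitting into successor countries in a given year.

    ``year`` is the first year in which the successors report their own
    national statistics; earlier years are attributed to ``parent``.
    """

    parent: str
    year: int
    successors: tuple[str, ...]

    def __post_init__(self) -> None:
        if len(self.successors) < 1:
            raise ConfigError("disintegration event needs at least one successor")


@dataclass
class AdminHierarchy:
    """County -> country membership plus the grid-cell -> county raster.

    Attributes
    ----------
    countries
        Ordered country identifiers (post-disintegration world).
    counties
        Ordered county identifiers.
    county_country
        county -> country map; every county has exactly one country.
    membership
        Integer raster (n_rows, n_cols); value is the index of the county in
        ``counties`` or -1 for cells outside any county (ocean).
    regions
        country -> fertilizer-survey reporting region (index ``m``).
    disintegration_events
        Historical splits whose parent-era statistics need re-attribution.
    """

    countries: tuple[str, ...]
    counties: tuple[str, ...]
    county_country: dict[str, str]
    membership: np.ndarray
    regions: dict[str, str] = field(default_factory=dict)
    disintegration_events: tuple[DisintegrationEvent, ...] = ()

    def __post_init__(self) -> None:
        missing = set(self.counties) - set(self.county_country)
        if missing:
            raise ConfigError(f"counties without a country: {sorted(missing)}")
        bad = set(self.county_country.values()) - set(self.countries)
        if bad:
            raise ConfigError(f"unknown countries in county map: {sorted(bad)}")
        if self.membership.max() >= len(self.counties):
            raise ConfigError("membership raster references unknown county index")
        for ev in self.disintegration_events:
            unknown = set(ev.successors) - set(self.countries)
            if unknown:
                raise ConfigError(f"unknown successor countries: {sorted(unknown)}")

    # -- lookups -----------------------------------------------------------

    @property
    def n_counties(self) -> int:
        return len(self.counties)

    def county_index(self, county: str) -> int:
        return self.counties.index(county)

    def counties_of(self, country: str) -> tuple[str, ...]:
        return tuple(c for c in self.counties if self.county_country[c] == country)

    def country_of_county_index(self) -> np.ndarray:
        """Index array mapping county index -> country index."""
        cidx = {j: k for k, j in enumerate(self.countries)}
        return np.array([cidx[self.county_country[c]] for c in self.counties])

    def country_raster(self) -> np.ndarray:
        """(n_rows, n_cols) int raster of country index, -1 outside."""
        c_of_i = self.country_of_county_index()
        out = np.full(self.membership.shape, -1, dtype=int)
        land = self.membership >= 0
        out[land] = c_of_i[self.membership[land]]
        return out

    def land_mask(self) -> np.ndarray:
        return self.membership >= 0

    def county_cell_counts(self) -> np.ndarray:
        land = self.membership >= 0
        return np.bincount(self.membership[land], minlength=self.n_counties)

    def region_of_country(self, country: str) -> str:
        return self.regions.get(country, country)
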