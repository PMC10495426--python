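"""Hand-sized worlds and tables for operation-level tests."""

from __future__ import annotations

import numpy as np
import pandas as pd

from nfert.grid import AdminHierarchy, GridDefinition
from nfert.harvested_area import CroplandCube


def toy_hierarchy(
    n_countries: int = 1,
    counties_per_country: int = 2,
    rows_per: int = 2,
    cols_per: int = 2,
    events=(),
    ocean_rows: int = 0,
) -> tuple[GridDefinition, AdminHierarchy]:
    """Rectangular-block countries/counties on a small grid."""
    R = rows_per * n_countries + ocean_rows
    C = cols_per * counties_per_country
    grid = GridDefinition(n_rows=R, n_cols=C, resolution=180.0 / R)
    countries = tuple(f"C{k:02d}" for k in range(n_countries))
    counties, county_country = [], {}
    membership = np.full((R, C), -1, dtype=int)
    for k, j in enumerate(countries):
        for c in range(counties_per_country):
            name = f"{j}-{c:02d}"
            membership[k * rows_per:(k + 1) * rows_per,
                       c * cols_per:(c + 1) * cols_per] = len(counties)
            counties.append(name)
            county_country[name] = j
    hierarchy = AdminHierarchy(
        countries=countries, counties=tuple(counties),
        county_country=county_country, membership=membership,
        regions={j: "R0" for j in countries},
        disintegration_events=tuple(events),
    )
    return grid, hierarchy


def toy_cropland(grid: GridDefinition, years, rice=None, upland=None) -> CroplandCube:
    """Constant-in-time cropland cube from 2D layers (default: uniform 1 ha)."""
    n_y = len(years)
    rice = np.ones(grid.shape) if rice is None else np.asarray(rice, dtype=float)
    upland = np.ones(grid.shape) if upland is None else np.asarray(upland, dtype=float)
    return CroplandCube(
        years=np.asarray(list(years)),
        rice=np.repeat(rice[None], n_y, axis=0),
        upland=np.repeat(upland[None], n_y, axis=0),
    )


def panel(index_tuples, columns, values, names=None) -> pd.DataFrame:
    idx = pd.MultiIndex.from_tuples(index_tuples, names=names)
    return pd.DataFrame(np.asarray(values, dtype=float), index=idx, columns=list(columns))
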