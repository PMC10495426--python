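"""Readers and writers for the published dataset layout and world bundles.

The published product is one HDF5 file per crop group,
``N_rate_{Crop name}_1961-2020.h5``, holding 26 records named
``{Fertilizer type}_{Placement}`` (13 types x surface/deep) of shape
years x grid in kg N per hectare of harvested area, plus one
``Harvested_area_1961-2020.h5`` with 21 crop records in hectares per grid
cell.  A synthetic world serializes to one HDF5 file of arrays plus CSV
tables for the statistics panels.
"""

from __future__ import annotations

import logging
from dataclasses import dataclass, asdict
from pathlib import Path

import h5py
import numpy as np
import pandas as pd
import yaml

from .fertilizer_types import TypeConsumptionPanel, TypeShareCube
from .grid import AdminHierarchy, ConfigError, DisintegrationEvent, GridDefinition
from .harvested_area import CroplandCube, HareaCube
from .n_application import NRateCube
from .placement import LogitParams, NoTillDrivers, NoTillSurface, PlacementCube
from .vocab import Vocabulary, DEFAULT_VOCAB

logger = logging.getLogger(__name__)

EN_DASH = "–"


@dataclass
class OutputBundle:
    """Paths and metadata of a written dataset."""

    directory: Path
    rate_files: dict[str, Path]
    area_file: Path
    years: tuple[int, int]

    @property
    def n_rate_files(self) -> int:
        return len(self.rate_files)


def _span(years: np.ndarray, en_dash: bool) -> str:
    dash = EN_DASH if en_dash else "-"
    return f"{int(years[0])}{dash}{int(years[-1])}"


def write_outputs(
    rate_cube: NRateCube,
    type_shares: TypeShareCube,
    placement: PlacementCube,
    harea_cube: HareaCube,
    grid: GridDefinition,
    outdir: str | Path,
    *,
    en_dash: bool = False,
    gzip_level: int = 4,
) -> OutputBundle:
    """Write the per-crop rate files and the harvested-area file.

    Each record is total rate x fertilizer-type share x placement share, so
    record x harvested area re-aggregates to the N amount.  Dimension
    mismatches abort before any file is written.
    """
    years = rate_cube.years
    shape = rate_cube.by_class.shape[-2:]
    for name, arr_years, arr_shape in (
        ("type shares", type_shares.years, type_shares.gridded.shape[-2:]),
        ("placement", placement.years, placement.notill_crop.shape[-2:]),
        ("harvested area", harea_cube.years, harea_cube.values.shape[-2:]),
    ):
        if len(arr_years) != len(years) or arr_shape != shape:
            raise ConfigError(
                f"dimension mismatch: {name} is {len(arr_years)} years x "
                f"{arr_shape}, rates are {len(years)} years x {shape}"
            )
    if shape != grid.shape:
        raise ConfigError(f"cube shape {shape} does not match grid {grid.shape}")

    outdir = Path(outdir)
    outdir.mkdir(parents=True, exist_ok=True)
    span = _span(years, en_dash)
    attrs = {
        "crs": grid.crs_label,
        "resolution_deg": grid.resolution,
        "origin_lon": grid.origin[0],
        "origin_lat": grid.origin[1],
        "year_start": int(years[0]),
        "year_end": int(years[-1]),
    }

    total = rate_cube.total                                   # (crop, year, R, C)
    rate_files: dict[str, Path] = {}
    for ci, crop in enumerate(rate_cube.crops):
        path = outdir / f"N_rate_{crop}_{span}.h5"
        with h5py.File(path, "w") as h5:
            for k, v in attrs.items():
                h5.attrs[k] = v
            h5.attrs["units"] = "kg N per hectare of harvested area"
            for fi, f in enumerate(placement.fertilizer_types):
                share = type_shares.gridded[fi]               # (year, R, C)
                for pname in ("Surface", "Deep"):
                    frac = (placement.surface(crop, f) if pname == "Surface"
                            else placement.deep(crop, f))
                    rec = total[ci] * share * frac
                    h5.create_dataset(f"{f}_{pname}", data=rec,
                                      compression="gzip",
                                      compression_opts=gzip_level,
                                      track_times=False)
        rate_files[crop] = path

    area_file = outdir / f"Harvested_area_{span}.h5"
    with h5py.File(area_file, "w") as h5:
        for k, v in attrs.items():
            h5.attrs[k] = v
        h5.attrs["units"] = "hectare per grid cell"
        for ci, crop in enumerate(harea_cube.crops):
            h5.create_dataset(crop, data=harea_cube.values[ci],
                              compression="gzip", compression_opts=gzip_level,
                              track_times=False)
    logger.info("wrote %d rate files and %s", len(rate_files), area_file.name)
    return OutputBundle(directory=outdir, rate_files=rate_files,
                        area_file=area_file, years=(int(years[0]), int(years[-1])))


def read_record(path: str | Path, record: str) -> np.ndarray:
    with h5py.File(path, "r") as h5:
        return h5[record][()]


def list_records(path: str | Path) -> list[str]:
    with h5py.File(path, "r") as h5:
        return list(h5.keys())


# ---------------------------------------------------------------------------
# World serialization: one HDF5 of arrays + CSV tables + a YAML config
# ---------------------------------------------------------------------------

_CSV_TABLES = {
    # name -> number of index levels
    "reference_harea_map": 1,
    "country_harea_series": 2,
    "prior_namount_panel": 2,
    "fao_namount_series": 2,
    "reference_rate_map": 2,
    "fubc_anchor_table": 2,
    "fubc_historic_table": 2,
    "type_values": 2,
    "type_total_sn": 1,
    "type_missing_mask": 2,
    "covariate_panel": 2,
    "rural_population": 1,
    "census_notill": 2,
    "truth_harea_county": 2,
    "truth_rate_county": 3,
    "truth_namount_county": 2,
    "truth_type_mix": 2,
    "truth_national_notill": 1,
    "truth_type_values": 2,
    "truth_type_total_sn": 1,
}


def _write_csv(df: pd.DataFrame, path: Path) -> None:
    df.to_csv(path)


def _read_csv(path: Path, n_levels: int) -> pd.DataFrame:
    df = pd.read_csv(path, index_col=list(range(n_levels)))
    cols = []
    for c in df.columns:
        try:
            cols.append(int(c))
        except (TypeError, ValueError):
            cols.append(c)
    df.columns = cols
    return df


def save_world(world, directory: str | Path) -> Path:
    """Serialize a synthetic world to ``directory`` (HDF5 + CSV + YAML)."""
    from .synthetic import SyntheticWorld  # noqa: F401 (type only)

    d = Path(directory)
    d.mkdir(parents=True, exist_ok=True)
    cfg = asdict(world.config)
    manifest = {
        "config": _yamlify(cfg),
        "countries": list(world.hierarchy.countries),
        "counties": list(world.hierarchy.counties),
        "county_country": dict(world.hierarchy.county_country),
        "regions": dict(world.hierarchy.regions),
        "events": [
            {"parent": e.parent, "year": e.year, "successors": list(e.successors)}
            for e in world.hierarchy.disintegration_events
        ],
        "income_class": dict(world.notill_drivers.income_class),
        "logit_k": dict(world.notill_params.k),
        "logit_xmid": dict(world.notill_params.xmid),
        "notill_curve": list(world.notill_curve),
        "cropland_use_fraction": world.cropland_use_fraction,
        "large_field_threshold": world.notill_drivers.large_field_threshold,
        "grid": {
            "n_rows": world.grid.n_rows, "n_cols": world.grid.n_cols,
            "resolution": world.grid.resolution,
            "origin": list(world.grid.origin),
        },
    }
    (d / "world.yaml").write_text(yaml.safe_dump(manifest, sort_keys=False))

    with h5py.File(d / "world.h5", "w") as h5:
        h5.create_dataset("membership", data=world.hierarchy.membership)
        h5.create_dataset("years", data=world.cropland_cube.years)
        h5.create_dataset("cropland/rice", data=world.cropland_cube.rice)
        h5.create_dataset("cropland/upland", data=world.cropland_cube.upland)
        for name in ("field_size", "erosion", "aridity", "rainfed_fraction"):
            h5.create_dataset(f"drivers/{name}",
                              data=getattr(world.notill_drivers, name))
        h5.create_dataset("truth/harea_grid", data=world.ground_truth.harea_grid.values)
        nt = world.ground_truth.notill
        h5.create_dataset("truth/notill_cell_area", data=nt.cell_area)
        h5.create_dataset("truth/notill_cell_fraction", data=nt.cell_fraction)
        if nt.crop_fraction is not None:
            h5.create_dataset("truth/notill_crop_fraction", data=nt.crop_fraction)

    tables = {
        "reference_harea_map": world.reference_harea_map,
        "country_harea_series": world.country_harea_series,
        "prior_namount_panel": world.prior_namount_panel,
        "fao_namount_series": world.fao_namount_series,
        "reference_rate_map": world.reference_rate_map,
        "fubc_anchor_table": world.fubc_anchor_table,
        "fubc_historic_table": world.fubc_historic_table,
        "type_values": world.type_consumption_panel.values,
        "type_total_sn": world.type_consumption_panel.total_sn,
        "type_missing_mask": world.type_consumption_panel.missing_mask,
        "covariate_panel": world.covariate_panel,
        "rural_population": world.notill_drivers.rural_population,
        "census_notill": world.notill_drivers.census_notill,
        "truth_harea_county": world.ground_truth.harea_county,
        "truth_rate_county": world.ground_truth.rate_county,
        "truth_namount_county": world.ground_truth.namount_county,
        "truth_type_mix": world.ground_truth.type_mix,
        "truth_national_notill": world.ground_truth.national_notill,
        "truth_type_values": world.ground_truth.type_consumption_complete.values,
        "truth_type_total_sn": world.ground_truth.type_consumption_complete.total_sn,
    }
    for name, df in tables.items():
        if df is not None:
            _write_csv(df, d / f"{name}.csv")
    return d


def _yamlify(obj):
    if isinstance(obj, dict):
        return {k: _yamlify(v) for k, v in obj.items()}
    if isinstance(obj, (tuple, list)):
        return [_yamlify(v) for v in obj]
    if isinstance(obj, (np.integer,)):
        return int(obj)
    if isinstance(obj, (np.floating,)):
        return float(obj)
    return obj


def load_world(directory: str | Path):
    """Load a serialized synthetic world back into memory."""
    from .synthetic import GroundTruth, SyntheticWorld, WorldConfig

    d = Path(directory)
    manifest = yaml.safe_load((d / "world.yaml").read_text())
    cfg_d = manifest["config"]
    for key in ("years", "grid_shape", "missing_block"):
        if cfg_d.get(key) is not None:
            cfg_d[key] = tuple(cfg_d[key])
    config = WorldConfig(**cfg_d)
    g = manifest["grid"]
    grid = GridDefinition(n_rows=g["n_rows"], n_cols=g["n_cols"],
                          resolution=g["resolution"], origin=tuple(g["origin"]))

    with h5py.File(d / "world.h5", "r") as h5:
        membership = h5["membership"][()]
        years = h5["years"][()]
        rice = h5["cropland/rice"][()]
        upland = h5["cropland/upland"][()]
        drivers_arrays = {name: h5[f"drivers/{name}"][()]
                          for name in ("field_size", "erosion", "aridity",
                                       "rainfed_fraction")}
        truth_grid = h5["truth/harea_grid"][()]
        nt_area = h5["truth/notill_cell_area"][()]
        nt_frac = h5["truth/notill_cell_fraction"][()]
        nt_crop = (h5["truth/notill_crop_fraction"][()]
                   if "truth/notill_crop_fraction" in h5 else None)

    hierarchy = AdminHierarchy(
        countries=tuple(manifest["countries"]),
        counties=tuple(manifest["counties"]),
        county_country=dict(manifest["county_country"]),
        membership=membership,
        regions=dict(manifest["regions"]),
        disintegration_events=tuple(
            DisintegrationEvent(parent=e["parent"], year=e["year"],
                                successors=tuple(e["successors"]))
            for e in manifest["events"]
        ),
    )
    t = {name: _read_csv(d / f"{name}.csv", n)
         for name, n in _CSV_TABLES.items() if (d / f"{name}.csv").exists()}

    vocab = DEFAULT_VOCAB
    panel = TypeConsumptionPanel(
        values=t["type_values"], total_sn=t["type_total_sn"],
        missing_mask=t.get("type_missing_mask").astype(bool)
        if "type_missing_mask" in t else None,
    )
    complete = TypeConsumptionPanel(values=t["truth_type_values"],
                                    total_sn=t["truth_type_total_sn"])
    drivers = NoTillDrivers(
        field_size=drivers_arrays["field_size"],
        erosion=drivers_arrays["erosion"],
        aridity=drivers_arrays["aridity"],
        rainfed_fraction=drivers_arrays["rainfed_fraction"],
        income_class=dict(manifest["income_class"]),
        rural_population=t["rural_population"],
        census_notill=t.get("census_notill"),
        large_field_threshold=manifest["large_field_threshold"],
    )
    truth_cube = HareaCube(crops=tuple(vocab.crop_groups), years=years,
                           values=truth_grid)
    notill = NoTillSurface(years=years, cell_area=nt_area, cell_fraction=nt_frac,
                           crop_fraction=nt_crop,
                           crops=tuple(vocab.crop_groups) if nt_crop is not None else None)
    truth = GroundTruth(
        harea_county=t["truth_harea_county"],
        harea_grid=truth_cube,
        rate_county=t["truth_rate_county"],
        namount_county=t["truth_namount_county"],
        type_mix=t["truth_type_mix"],
        type_consumption_complete=complete,
        national_notill=t["truth_national_notill"],
        notill=notill,
    )
    return SyntheticWorld(
        config=config, vocabulary=vocab, grid=grid, hierarchy=hierarchy,
        reference_harea_map=t["reference_harea_map"],
        country_harea_series=t["country_harea_series"],
        cropland_cube=CroplandCube(years=years, rice=rice, upland=upland),
        prior_namount_panel=t["prior_namount_panel"],
        fao_namount_series=t["fao_namount_series"],
        reference_rate_map=t["reference_rate_map"],
        fubc_anchor_table=t["fubc_anchor_table"],
        fubc_historic_table=t["fubc_historic_table"],
        type_consumption_panel=panel,
        covariate_panel=t["covariate_panel"],
        notill_drivers=drivers,
        notill_params=LogitParams(k=dict(manifest["logit_k"]),
                                  xmid=dict(manifest["logit_xmid"])),
        notill_curve=tuple(manifest["notill_curve"]),
        cropland_use_fraction=manifest["cropland_use_fraction"],
        ground_truth=truth,
    )
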