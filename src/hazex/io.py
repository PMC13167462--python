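"""File I/O: CF-style netCDF for gridded artifacts, CSV for entity tables.

Gridded fields travel as xarray Datasets written with the scipy netCDF3
backend; booleans are stored as int8 with a ``dtype='bool'`` attribute
and restored on read.  Entity tables (range overlaps, exposure records)
are plain CSV.
"""

from __future__ import annotations

import hashlib
import json
import platform
from pathlib import Path

import numpy as np
import pandas as pd
import xarray as xr

from .events import EventMatrix, ThresholdSet
from .exposure import FrequencyField
from .grid import Grid
from .synthetic import SimulationRun, VARIABLES

_ENGINE = "scipy"

_UNITS = {
    "tasmax": ("degC", "daily maximum near-surface air temperature"),
    "soil_moisture": ("1", "monthly root-zone soil moisture fraction"),
    "outflow": ("m3 s-1", "daily river outflow"),
    "burned_area": ("1", "annual burned area fraction of cell"),
    "discharge": ("mm day-1", "annual mean discharge"),
    "flooded_fraction": ("1", "annual flooded fraction of cell"),
}

_TIME_DIMS = {"daily": ("year", "dayofyear"), "monthly": ("year", "month"), "annual": ("year",)}


class GriddedIOError(IOError):
    pass


def _encode_bool(ds: xr.Dataset) -> xr.Dataset:
    for name, da in ds.data_vars.items():
        if da.dtype == bool:
            ds[name] = da.astype("i1")
            ds[name].attrs["dtype"] = "bool"
    return ds


def _decode_bool(ds: xr.Dataset) -> xr.Dataset:
    for name, da in ds.data_vars.items():
        if da.attrs.get("dtype") == "bool":
            ds[name] = da.astype(bool)
            ds[name].attrs.pop("dtype", None)
    return ds


def write_gridded(path: str | Path, ds: xr.Dataset) -> None:
    """Write a Dataset as netCDF3 (classic), preserving bool variables."""
    ds = _encode_bool(ds.copy())
    ds.to_netcdf(path, engine=_ENGINE)


def read_gridded(
    path: str | Path, required: tuple[str, ...] = (), grid: Grid | None = None
) -> xr.Dataset:
    """Read a gridded netCDF file, checking required variables and grid shape."""
    path = Path(path)
    try:
        ds = xr.open_dataset(path, engine=_ENGINE).load()
    except Exception as exc:  # noqa: BLE001 - rewrap with path context
        raise GriddedIOError(f"cannot read gridded file {path}: {exc}") from exc
    for var in required:
        if var not in ds:
            raise GriddedIOError(f"{path}: required variable {var!r} missing")
    if grid is not None and {"lat", "lon"} <= set(ds.sizes):
        if (ds.sizes["lat"], ds.sizes["lon"]) != grid.shape:
            raise GriddedIOError(
                f"{path}: grid shape {(ds.sizes['lat'], ds.sizes['lon'])} "
                f"does not match configured grid {grid.shape}"
            )
    return _decode_bool(ds)


def grid_coords(grid: Grid) -> dict:
    return {"lat": ("lat", grid.lat_centers), "lon": ("lon", grid.lon_centers)}


def run_to_dataset(run: SimulationRun, grid: Grid) -> xr.Dataset:
    """SimulationRun -> CF-style Dataset (dims year/dayofyear|month/lat/lon)."""
    data = {}
    for name, arr in run.fields.items():
        dims = _TIME_DIMS[VARIABLES[name]] + ("lat", "lon")
        units, long_name = _UNITS[name]
        data[name] = xr.DataArray(
            arr, dims=dims, attrs={"units": units, "long_name": long_name}
        )
    ds = xr.Dataset(data, coords={**grid_coords(grid), "year": ("year", run.years)})
    ds.attrs.update(
        run_kind=run.run_kind,
        scenario_tag=run.scenario_tag,
        climate_model_id=run.climate_model_id,
        impact_model_id=run.impact_model_id,
        calendar="365_day",
    )
    return ds


def dataset_to_run(ds: xr.Dataset) -> SimulationRun:
    fields = {name: ds[name].values for name in ds.data_vars if name in VARIABLES}
    return SimulationRun(
        run_kind=ds.attrs.get("run_kind", "scenario"),
        scenario_tag=ds.attrs.get("scenario_tag", ""),
        climate_model_id=ds.attrs.get("climate_model_id", ""),
        impact_model_id=ds.attrs.get("impact_model_id", ""),
        years=ds["year"].values,
        fields=fields,
    )


def frequency_to_dataset(field: FrequencyField, grid: Grid) -> xr.Dataset:
    ds = xr.Dataset(
        {
            "counts": xr.DataArray(field.counts, dims=("lat", "lon")),
            "valid": xr.DataArray(field.valid, dims=("lat", "lon")),
        },
        coords=grid_coords(grid),
    )
    ds.attrs.update(
        event_type=field.event_type,
        window_center=field.window_center,
        window_width=field.width,
        combination_id=field.combination_id,
        scenario_tag=field.scenario_tag,
    )
    return ds


def dataset_to_frequency(ds: xr.Dataset) -> FrequencyField:
    return FrequencyField(
        event_type=ds.attrs["event_type"],
        window_center=int(ds.attrs["window_center"]),
        counts=ds["counts"].values,
        width=int(ds.attrs["window_width"]),
        valid=ds["valid"].values.astype(bool),
        combination_id=ds.attrs.get("combination_id", ""),
        scenario_tag=ds.attrs.get("scenario_tag", ""),
    )


def events_to_dataset(ev: EventMatrix, grid: Grid) -> xr.Dataset:
    data = {}
    for name, flags in ev.flags.items():
        data[f"{name}_flag"] = xr.DataArray(flags, dims=("year", "lat", "lon"))
        data[f"{name}_valid"] = xr.DataArray(ev.valid[name], dims=("lat", "lon"))
    ds = xr.Dataset(data, coords={**grid_coords(grid), "year": ("year", ev.years)})
    ds.attrs.update(combination_id=ev.combination_id, scenario_tag=ev.scenario_tag)
    return ds


def dataset_to_events(ds: xr.Dataset) -> EventMatrix:
    flags, valid = {}, {}
    for name in ds.data_vars:
        if name.endswith("_flag"):
            flags[name[:-5]] = ds[name].values.astype(bool)
        elif name.endswith("_valid"):
            valid[name[:-6]] = ds[name].values.astype(bool)
    return EventMatrix(
        years=ds["year"].values, flags=flags, valid=valid,
        combination_id=ds.attrs.get("combination_id", ""),
        scenario_tag=ds.attrs.get("scenario_tag", ""),
    )


def thresholds_to_dataset(thr: ThresholdSet, grid: Grid) -> xr.Dataset:
    ds = xr.Dataset(
        {
            "hw_doy_p90": xr.DataArray(thr.hw_doy_p90, dims=("dayofyear", "lat", "lon")),
            "hw_q25": xr.DataArray(thr.hw_q25, dims=("lat", "lon")),
            "hw_q75": xr.DataArray(thr.hw_q75, dims=("lat", "lon")),
            "hwmid_extreme_level": xr.DataArray(thr.hwmid_extreme_level, dims=("lat", "lon")),
            "drought_monthly_level": xr.DataArray(thr.drought_monthly_level, dims=("lat", "lon")),
            "gev_params": xr.DataArray(thr.gev_params, dims=("gev_param", "lat", "lon")),
            "flood_return_level": xr.DataArray(thr.flood_return_level, dims=("lat", "lon")),
            "wildfire_level": xr.DataArray(thr.wildfire_level, dims=("lat", "lon")),
            "dryness_mask": xr.DataArray(thr.dryness_mask, dims=("lat", "lon")),
            "gev_usable": xr.DataArray(thr.gev_usable, dims=("lat", "lon")),
        },
        coords=grid_coords(grid),
    )
    ds.attrs.update(percentile=thr.q, flood_return_period=thr.flood_return_period)
    return ds


def dataset_to_thresholds(ds: xr.Dataset) -> ThresholdSet:
    from .events import ThresholdSet as TS

    return TS(
        q=float(ds.attrs["percentile"]),
        hw_doy_p90=ds["hw_doy_p90"].values,
        hw_q25=ds["hw_q25"].values,
        hw_q75=ds["hw_q75"].values,
        hwmid_extreme_level=ds["hwmid_extreme_level"].values,
        drought_monthly_level=ds["drought_monthly_level"].values,
        gev_params=ds["gev_params"].values,
        flood_return_level=ds["flood_return_level"].values,
        flood_return_period=float(ds.attrs["flood_return_period"]),
        wildfire_level=ds["wildfire_level"].values,
        dryness_mask=ds["dryness_mask"].values.astype(bool),
        gev_usable=ds["gev_usable"].values.astype(bool),
    )


def write_provenance(path: str | Path, config_text: str, seed: int) -> dict:
    """Machine-readable provenance record: config hash, seed, versions."""
    import scipy

    rec = {
        "config_sha256": hashlib.sha256(config_text.encode()).hexdigest(),
        "seed": int(seed),
        "python": platform.python_version(),
        "numpy": np.__version__,
        "scipy": scipy.__version__,
        "pandas": pd.__version__,
        "xarray": xr.__version__,
    }
    Path(path).write_text(json.dumps(rec, indent=2))
    return rec
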