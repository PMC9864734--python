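"""Readers and writers for the pipeline's on-disk artifacts.

Gridded stacks travel as NetCDF (classic format via xarray's scipy backend,
CF-style ``time``/``lat``/``lon`` dimensions); station series, event lists,
zone tables and validation reports as CSV.
"""

from __future__ import annotations

import numpy as np
import pandas as pd
import xarray as xr

__all__ = [
    "write_netcdf",
    "read_netcdf",
    "write_station_csv",
    "read_station_csv",
    "write_events_csv",
    "read_events_csv",
]


def write_netcdf(ds: xr.Dataset, path) -> None:
    ds.to_netcdf(path, engine="scipy")


def read_netcdf(path) -> xr.Dataset:
    return xr.open_dataset(path, engine="scipy").load()


def write_station_csv(df: pd.DataFrame, path) -> None:
    out = df.copy()
    out["date"] = pd.to_datetime(out["date"]).dt.strftime("%Y-%m-%d")
    out.to_csv(path, index=False)


def read_station_csv(path) -> pd.DataFrame:
    df = pd.read_csv(path, parse_dates=["date"])
    return df


def write_events_csv(events, path) -> None:
    from .events import events_table
    events_table(events).to_csv(path, index=False)


def read_events_csv(path) -> pd.DataFrame:
    return pd.read_csv(path)


def indicators_to_dataset(ind: dict, lat=None, lon=None) -> xr.Dataset:
    """Annual indicator dict (from ``annual_indicators``) as a Dataset."""
    coords = {"year": ind["years"]}
    dims = ("year",)
    shape = ind["hwf"].shape
    if len(shape) == 3:
        dims = ("year", "lat", "lon")
        coords["lat"] = np.asarray(lat) if lat is not None else np.arange(shape[1])
        coords["lon"] = np.asarray(lon) if lon is not None else np.arange(shape[2])
    return xr.Dataset({k: (dims, ind[k]) for k in ("hwf", "hwmhi", "hwmd")},
                      coords=coords)
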