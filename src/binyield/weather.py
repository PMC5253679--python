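"""Gridded daily weather container (Tmin/Tmax/precip per cell-day)."""

from __future__ import annotations

import numpy as np
import pandas as pd
import xarray as xr

__all__ = ["DailyWeatherGrid"]

_VARS = ("tmin", "tmax", "precip")


class DailyWeatherGrid:
    """Daily Tmin/Tmax/precipitation on a set of grid cells.

    Thin wrapper around an :class:`xarray.Dataset` with dimensions
    ``(time, cell)``, data variables ``tmin``, ``tmax``, ``precip`` (degC,
    degC, mm/day) and per-cell coordinates ``lat``/``lon`` in degrees.
    Dates must be contiguous (one record per cell-day) and ``tmax >= tmin``
    everywhere; both are validated on construction.
    """

    def __init__(self, data: xr.Dataset):
        for v in _VARS:
            if v not in data:
                raise ValueError(f"weather dataset missing variable {v!r}")
        for c in ("lat", "lon"):
            if c not in data.coords:
                raise ValueError(f"weather dataset missing coordinate {c!r}")
        times = pd.DatetimeIndex(data.indexes["time"])
        if len(times) > 1:
            deltas = np.diff(times.values).astype("timedelta64[D]").astype(int)
            if not np.all(deltas == 1):
                raise ValueError("weather dates are not contiguous daily records")
        if np.any(data["tmax"].values < data["tmin"].values):
            raise ValueError("tmax < tmin in weather data")
        self.data = data

    # -- basic accessors ---------------------------------------------------
    @property
    def cells(self) -> np.ndarray:
        return np.asarray(self.data.indexes["cell"])

    @property
    def times(self) -> pd.DatetimeIndex:
        return pd.DatetimeIndex(self.data.indexes["time"])

    @property
    def lat(self) -> pd.Series:
        return pd.Series(self.data["lat"].values, index=self.cells, name="lat")

    @property
    def lon(self) -> pd.Series:
        return pd.Series(self.data["lon"].values, index=self.cells, name="lon")

    def window(self, start, end) -> xr.Dataset:
        """Subset [start, end] inclusive; raises if any day is missing."""
        start = pd.Timestamp(start)
        end = pd.Timestamp(end)
        times = self.times
        if start < times[0] or end > times[-1]:
            raise ValueError(
                f"requested window {start.date()}..{end.date()} not covered by "
                f"weather record {times[0].date()}..{times[-1].date()}"
            )
        return self.data.sel(time=slice(start, end))

    # -- round-trippable formats -------------------------------------------
    def to_dataframe(self) -> pd.DataFrame:
        """Long format: one row per cell-day with lat/lon repeated."""
        df = self.data.to_dataframe().reset_index()
        return df[["cell", "time", "lat", "lon", "tmin", "tmax", "precip"]].rename(
            columns={"time": "date"}
        )

    @classmethod
    def from_dataframe(cls, df: pd.DataFrame) -> "DailyWeatherGrid":
        required = {"cell", "date", "lat", "lon", "tmin", "tmax", "precip"}
        missing = required - set(df.columns)
        if missing:
            raise ValueError(f"weather table missing columns: {sorted(missing)}")
        df = df.copy()
        df["date"] = pd.to_datetime(df["date"])
        if df.duplicated(["cell", "date"]).any():
            raise ValueError("duplicate cell-day records in weather table")
        wide = df.set_index(["date", "cell"])
        ds = xr.Dataset(
            {v: wide[v].unstack("cell") for v in _VARS},
        ).rename({"date": "time"})
        if ds["tmin"].isnull().any():
            raise ValueError("weather table is not a complete cell x day grid")
        meta = df.drop_duplicates("cell").set_index("cell").sort_index()
        ds = ds.assign_coords(
            lat=("cell", meta["lat"].to_numpy()), lon=("cell", meta["lon"].to_numpy())
        )
        return cls(ds)

    def to_netcdf(self, path) -> None:
        ds = self.data.copy()
        # scipy backend writes NetCDF3: no datetime64 support for coords
        ds.to_netcdf(path, engine="scipy")

    @classmethod
    def from_netcdf(cls, path) -> "DailyWeatherGrid":
        with xr.open_dataset(path, engine="scipy") as ds:
            return cls(ds.load())

    def to_csv(self, path) -> None:
        self.to_dataframe().to_csv(path, index=False, date_format="%Y-%m-%d")

    @classmethod
    def from_csv(cls, path) -> "DailyWeatherGrid":
        return cls.from_dataframe(pd.read_csv(path))

    def __repr__(self) -> str:
        t = self.times
        return (
            f"<DailyWeatherGrid {len(self.cells)} cells, "
            f"{t[0].date()}..{t[-1].date()}>"
        )
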