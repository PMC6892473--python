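"""Gridded daily concentration fields and fire attribution by run differencing.

The attribution primitive is the "brute-force zero-out" difference of two
paired model runs: one with all emission sources and one with fire sources
removed. Per cell-day, ``fire = all_sources - no_fire``. Negative
differences can occur (nonlinear chemistry/transport makes the runs not
strictly nested) and are retained by default; an optional flag clips them
to zero and logs how many were clipped.
"""

from __future__ import annotations

import logging
from dataclasses import dataclass
from pathlib import Path
from typing import Literal

import numpy as np
import pandas as pd
import xarray as xr

from .grid import GridDefinition

logger = logging.getLogger(__name__)

__all__ = [
    "DailyField",
    "fire_difference",
    "daily_from_hourly",
    "read_field_netcdf",
    "write_field_netcdf",
    "read_field_csv",
    "write_field_csv",
]

SourceLabel = Literal["all_sources", "no_fire", "fire"]
_SOURCE_LABELS = ("all_sources", "no_fire", "fire")


@dataclass
class DailyField:
    """Daily-mean concentration on a regular grid.

    values are μg/m³, shaped (n_days, n_rows, n_cols) and finite;
    ``all_sources`` and ``no_fire`` fields must be non-negative, while a
    ``fire`` difference field may contain negatives (see module docstring).
    """

    grid: GridDefinition
    dates: pd.DatetimeIndex
    values: np.ndarray
    source_label: SourceLabel

    def __post_init__(self) -> None:
        self.values = np.asarray(self.values, dtype=np.float64)
        self.dates = pd.DatetimeIndex(self.dates)
        expected = (len(self.dates), self.grid.n_rows, self.grid.n_cols)
        if self.values.shape != expected:
            raise ValueError(
                f"values shape {self.values.shape} != (n_days, n_rows, n_cols) "
                f"{expected}"
            )
        if self.source_label not in _SOURCE_LABELS:
            raise ValueError(f"source_label must be one of {_SOURCE_LABELS}")
        if not np.all(np.isfinite(self.values)):
            raise ValueError("field values must be finite")
        if self.source_label != "fire" and (self.values < 0).any():
            raise ValueError(f"{self.source_label} field must be non-negative")
        if not self.dates.is_monotonic_increasing or self.dates.has_duplicates:
            raise ValueError("dates must be strictly increasing")

    @property
    def n_days(self) -> int:
        return len(self.dates)

    def cell_series(self, col: int, row: int) -> pd.Series:
        """One cell's daily series (index: dates)."""
        return pd.Series(self.values[:, row, col], index=self.dates)

    def to_xarray(self) -> xr.Dataset:
        da = xr.DataArray(
            self.values,
            dims=("time", "row", "col"),
            coords={"time": self.dates},
            name="pm25",
            attrs={"units": "ug/m3", "source_label": self.source_label},
        )
        ds = da.to_dataset()
        ds.attrs.update(self.grid.to_dict())
        return ds

    @classmethod
    def from_xarray(cls, ds: xr.Dataset) -> "DailyField":
        grid = GridDefinition.from_dict(ds.attrs)
        da = ds["pm25"]
        return cls(
            grid=grid,
            dates=pd.DatetimeIndex(da["time"].values),
            values=da.transpose("time", "row", "col").values,
            source_label=da.attrs["source_label"],
        )


def _check_paired(a: DailyField, b: DailyField) -> None:
    if a.grid != b.grid:
        raise ValueError("paired fields must share an identical grid")
    if not a.dates.equals(b.dates):
        raise ValueError("paired fields must cover identical dates")


def fire_difference(
    all_field: DailyField,
    nofire_field: DailyField,
    clip_negative: bool = False,
) -> DailyField:
    """Fire-attributable concentration: ``all_sources - no_fire`` per cell-day.

    With ``clip_negative`` the (logged) negative differences are set to 0;
    otherwise ``fire + no_fire`` reconstructs ``all_sources`` exactly.
    """
    if all_field.source_label != "all_sources" or nofire_field.source_label != "no_fire":
        raise ValueError(
            "fire_difference expects (all_sources, no_fire) fields, got "
            f"({all_field.source_label}, {nofire_field.source_label})"
        )
    _check_paired(all_field, nofire_field)
    diff = all_field.values - nofire_field.values
    if clip_negative:
        n_neg = int((diff < 0).sum())
        if n_neg:
            logger.info("clipped %d negative fire cell-day differences to 0", n_neg)
        diff = np.maximum(diff, 0.0)
    return DailyField(all_field.grid, all_field.dates, diff, "fire")


def daily_from_hourly(
    hourly: np.ndarray,
    start_utc: pd.Timestamp | str,
    utc_offset_hours: int,
    grid: GridDefinition,
    source_label: SourceLabel = "all_sources",
) -> DailyField:
    """Average hourly model output into local-calendar daily means.

    ``hourly`` is (n_hours, n_rows, n_cols) with the first slice valid at
    ``start_utc``; a day runs midnight-to-midnight in local time, i.e. after
    shifting timestamps by ``utc_offset_hours`` (−8 for Pacific Standard
    Time). Incomplete first/last local days are dropped and logged.
    """
    if utc_offset_hours != int(utc_offset_hours) or not (-12 <= utc_offset_hours <= 14):
        raise ValueError(
            f"utc_offset_hours must be an integer in [-12, 14], got {utc_offset_hours}"
        )
    hourly = np.asarray(hourly, dtype=np.float64)
    if hourly.ndim != 3 or hourly.shape[1:] != (grid.n_rows, grid.n_cols):
        raise ValueError("hourly must be shaped (n_hours, n_rows, n_cols)")
    start_local = pd.Timestamp(start_utc) + pd.Timedelta(hours=int(utc_offset_hours))
    times_local = start_local + pd.to_timedelta(np.arange(hourly.shape[0]), unit="h")

    # index of the first local midnight; complete days are 24-hour blocks from there
    first_midnight = int((-(start_local.hour + start_local.minute / 60)) % 24)
    n_complete = (hourly.shape[0] - first_midnight) // 24
    n_dropped = hourly.shape[0] - first_midnight - n_complete * 24 + first_midnight
    if n_complete < 1:
        raise ValueError("fewer than one complete local day of hourly values")
    if n_dropped:
        logger.info("dropped %d hour(s) in partial first/last local days", n_dropped)

    block = hourly[first_midnight : first_midnight + n_complete * 24]
    daily = block.reshape(n_complete, 24, grid.n_rows, grid.n_cols).mean(axis=1)
    dates = pd.DatetimeIndex(
        [times_local[first_midnight + 24 * d].normalize() for d in range(n_complete)]
    )
    return DailyField(grid, dates, daily, source_label)


# ---------------------------------------------------------------------------
# I/O: NetCDF (time,row,col)/pm25 and long CSV date,row,col,value


def write_field_netcdf(field: DailyField, path: str | Path) -> None:
    field.to_xarray().to_netcdf(path, engine="scipy")


def read_field_netcdf(path: str | Path) -> DailyField:
    with xr.open_dataset(path, engine="scipy") as ds:
        return DailyField.from_xarray(ds.load())


def write_field_csv(field: DailyField, path: str | Path) -> None:
    """Long-format CSV: date,row,col,value with a grid/source header comment."""
    n_days, n_rows, n_cols = field.values.shape
    dates = np.repeat(field.dates.strftime("%Y-%m-%d"), n_rows * n_cols)
    rows = np.tile(np.repeat(np.arange(n_rows), n_cols), n_days)
    cols = np.tile(np.arange(n_cols), n_days * n_rows)
    df = pd.DataFrame(
        {"date": dates, "row": rows, "col": cols, "value": field.values.ravel()}
    )
    with open(path, "w") as fh:
        meta = {**field.grid.to_dict(), "source_label": field.source_label}
        fh.write("# " + " ".join(f"{k}={v}" for k, v in meta.items()) + "\n")
        df.to_csv(fh, index=False, float_format="%.17g")


def read_field_csv(path: str | Path) -> DailyField:
    with open(path) as fh:
        header = fh.readline()
        if not header.startswith("# "):
            raise ValueError(f"{path}: missing grid metadata header line")
        meta = dict(kv.split("=", 1) for kv in header[2:].split())
        df = pd.read_csv(fh, float_precision="round_trip")
    grid = GridDefinition(
        origin_x=float(meta["origin_x"]),
        origin_y=float(meta["origin_y"]),
        cell_size=float(meta["cell_size"]),
        n_cols=int(meta["n_cols"]),
        n_rows=int(meta["n_rows"]),
        crs_label=meta["crs_label"],
    )
    dates = pd.DatetimeIndex(sorted(df["date"].unique()))
    values = np.full((len(dates), grid.n_rows, grid.n_cols), np.nan)
    di = dates.get_indexer(pd.DatetimeIndex(df["date"]))
    values[di, df["row"].to_numpy(), df["col"].to_numpy()] = df["value"].to_numpy()
    if np.isnan(values).any():
        raise ValueError(f"{path}: incomplete field (missing cell-days)")
    return DailyField(grid, dates, values, meta["source_label"])
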