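"""Model-monitor evaluation of PM2.5 carbon, stratified by fire impact.

Monitor observations (organic + elemental carbon, μg/m³) are matched to
the grid cell containing the monitor. Monitor-days are split into a
"wildfire_impacted" stratum where the model predicts fire carbon strictly
above a threshold (0.34 μg/m³ in the replication configuration) and a
"little_or_no" stratum otherwise; per stratum and year the summary reports
N, mean observed, mean predicted, and bias = predicted − observed.
"""

from __future__ import annotations

import logging
from pathlib import Path

import numpy as np
import pandas as pd

from .grid import GridDefinition

logger = logging.getLogger(__name__)

__all__ = [
    "WILDFIRE_IMPACTED",
    "LITTLE_OR_NO",
    "CARBON_THRESHOLD",
    "match_monitors_to_cells",
    "stratify_by_fire_impact",
    "stratum_summary",
    "read_monitor_csv",
    "write_monitor_csv",
]

WILDFIRE_IMPACTED = "wildfire_impacted"
LITTLE_OR_NO = "little_or_no"
CARBON_THRESHOLD = 0.34  # μg/m³ predicted fire carbon

MONITOR_COLUMNS = ["monitor_id", "x", "y", "date", "obs_carbon"]


def match_monitors_to_cells(
    records: pd.DataFrame, grid: GridDefinition
) -> pd.DataFrame:
    """Attach (col, row) of the containing grid cell to each monitor record.

    Cells are half-open rectangles [left, right) × [bottom, top), so every
    interior point maps to exactly one cell; records outside the grid
    extent (including points on the exact right/top edge) are dropped with
    a warning in the log.
    """
    x = records["x"].to_numpy(dtype=float)
    y = records["y"].to_numpy(dtype=float)
    col = np.floor((x - grid.origin_x) / grid.cell_size).astype(int)
    row = np.floor((y - grid.origin_y) / grid.cell_size).astype(int)
    inside = (col >= 0) & (col < grid.n_cols) & (row >= 0) & (row < grid.n_rows)
    n_dropped = int((~inside).sum())
    if n_dropped:
        logger.warning("dropped %d monitor record(s) outside the grid extent",
                       n_dropped)
    out = records.loc[inside].copy()
    out["col"] = col[inside]
    out["row"] = row[inside]
    return out


def stratify_by_fire_impact(
    predicted_fire_carbon, threshold: float = CARBON_THRESHOLD
):
    """Stratum label per monitor-day: strictly above threshold →
    wildfire_impacted, at or below → little_or_no."""
    pred = np.asarray(predicted_fire_carbon, dtype=float)
    if not np.all(np.isfinite(pred)):
        raise ValueError("predicted fire carbon must be finite")
    labels = np.where(pred > threshold, WILDFIRE_IMPACTED, LITTLE_OR_NO)
    return str(labels) if labels.ndim == 0 else labels


def stratum_summary(pairs: pd.DataFrame) -> pd.DataFrame:
    """Observed/predicted means and bias per (stratum, year).

    ``pairs`` needs columns obs_carbon, pred_carbon, stratum, and either
    year or date. Bias (``difference``) is predicted − observed at full
    precision; empty stratum-years simply do not appear. Rounding to one
    decimal is presentation only.
    """
    df = pairs.copy()
    if "year" not in df.columns:
        df["year"] = pd.DatetimeIndex(df["date"]).year
    grouped = df.groupby(["stratum", "year"], sort=True)
    out = grouped.agg(
        n=("obs_carbon", "size"),
        mean_observed=("obs_carbon", "mean"),
        mean_predicted=("pred_carbon", "mean"),
    ).reset_index()
    out["difference"] = out["mean_predicted"] - out["mean_observed"]
    return out


def read_monitor_csv(path: str | Path) -> pd.DataFrame:
    """Monitor records: monitor_id,x,y,date,obs_carbon[,pred_carbon,...]."""
    df = pd.read_csv(path, comment="#", parse_dates=["date"])
    missing = set(MONITOR_COLUMNS) - set(df.columns)
    if missing:
        raise ValueError(f"{path}: missing monitor columns {sorted(missing)}")
    if df.duplicated(["monitor_id", "date"]).any():
        raise ValueError(f"{path}: duplicate (monitor_id, date) records")
    if (df["obs_carbon"] < 0).any():
        raise ValueError(f"{path}: negative observed carbon")
    return df


def write_monitor_csv(records: pd.DataFrame, path: str | Path) -> None:
    out = records.copy()
    out["date"] = pd.DatetimeIndex(out["date"]).strftime("%Y-%m-%d")
    out.to_csv(path, index=False, float_format="%.17g")
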