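"""Unit-level exposure metrics: aggregation, summaries, classes, smokewaves.

Daily unit means are unweighted arithmetic means over the grid cells
assigned to the unit by the centroid rule. Annual/period summaries reduce
those daily series. Exposure classes bin annual-mean fire-PM2.5 into four
classes at the quartile breaks of the pooled unit-year values (intervals
are lower-open/upper-closed, so a value equal to a break falls in the lower
class). A *smokewave* is a maximal run of consecutive days on which the
daily fire-PM2.5 strictly exceeds a threshold — by default the 35 μg/m³
24-h NAAQS level — for at least ``min_consecutive_days`` days (default 3,
i.e. "more than two consecutive days").
"""

from __future__ import annotations

import warnings
from dataclasses import dataclass
from typing import Iterable

import numpy as np
import pandas as pd

from .fields import DailyField
from .grid import CellAssignment

__all__ = [
    "ExposureClassBreaks",
    "SmokewaveParams",
    "SmokewaveEpisode",
    "unit_daily_mean",
    "annual_summary",
    "period_summary",
    "percent_attributable",
    "quartile_breaks",
    "classify_exposure",
    "detect_smokewaves",
    "smokewave_counts_cells",
    "smokewave_counts_units",
]

#: quartile breaks (and observed max) of pooled county-year annual-mean
#: fire-PM2.5 from the California 2007-2013 assessment, μg/m³
CALIFORNIA_BREAKS = (0.34, 0.56, 0.86, 20.3)

NAAQS_24H_PM25 = 35.0  # μg/m³, 24-h National Ambient Air Quality Standard


@dataclass(frozen=True)
class ExposureClassBreaks:
    """Three cut points (and observed max) defining four exposure classes."""

    q1: float
    q2: float
    q3: float
    max_value: float

    def __post_init__(self) -> None:
        if not (0 <= self.q1 <= self.q2 <= self.q3 <= self.max_value):
            raise ValueError(
                f"breaks must satisfy 0 <= q1 <= q2 <= q3 <= max, got {self}"
            )


@dataclass(frozen=True)
class SmokewaveParams:
    threshold: float = NAAQS_24H_PM25
    min_consecutive_days: int = 3

    def __post_init__(self) -> None:
        if self.threshold <= 0:
            raise ValueError("threshold must be > 0")
        if self.min_consecutive_days < 1:
            raise ValueError("min_consecutive_days must be >= 1")


@dataclass(frozen=True)
class SmokewaveEpisode:
    """Maximal exceedance run; length = (end - start) + 1 days."""

    scope: str
    start: pd.Timestamp
    end: pd.Timestamp
    length: int
    peak: float


def unit_daily_mean(field: DailyField, assignment: CellAssignment) -> pd.DataFrame:
    """Per-unit daily means (rows: dates; columns: unit_ids).

    Unweighted mean over a unit's member cells for each day; empty units
    (no cell centroid inside) yield all-NaN columns.
    """
    flat = field.values.reshape(field.n_days, -1)
    out = pd.DataFrame(index=field.dates, columns=list(assignment.unit_ids),
                       dtype=float)
    members: dict[str, list[int]] = {u: [] for u in assignment.unit_ids}
    for (col, row), uid in assignment.mapping.items():
        if not (0 <= col < field.grid.n_cols and 0 <= row < field.grid.n_rows):
            raise ValueError("assignment does not match the field's grid")
        members.setdefault(uid, []).append(row * field.grid.n_cols + col)
    for uid, idx in members.items():
        if idx:
            out[uid] = flat[:, idx].mean(axis=1)
    return out


def _summary(values: np.ndarray, ddof: int) -> tuple[float, float, int]:
    return float(values.mean()), float(values.std(ddof=ddof)), int(values.size)


def annual_summary(
    series: pd.DataFrame, ddof: int = 0, min_coverage: float = 0.0
) -> pd.DataFrame:
    """Per unit-year mean, std and day count of a unit daily-mean table.

    std divides by n (population convention, ``ddof=0``) by default.
    Unit-years whose available-day fraction is below ``min_coverage`` (of
    the days present in the table for that year) are dropped; empty units
    never appear.
    """
    rows = []
    for year, chunk in series.groupby(series.index.year):
        for uid in series.columns:
            vals = chunk[uid].dropna().to_numpy()
            if vals.size == 0 or vals.size < min_coverage * len(chunk):
                continue
            mean, std, n = _summary(vals, ddof)
            rows.append({"unit_id": uid, "year": int(year), "mean": mean,
                         "std": std, "n_days": n})
    return pd.DataFrame(rows, columns=["unit_id", "year", "mean", "std", "n_days"])


def period_summary(
    series: pd.DataFrame,
    years: tuple[int, int] | None = None,
    ddof: int = 0,
) -> pd.DataFrame:
    """Per-unit mean/std over all days in an inclusive year range (or all days)."""
    if years is not None:
        mask = (series.index.year >= years[0]) & (series.index.year <= years[1])
        series = series.loc[mask]
    rows = []
    for uid in series.columns:
        vals = series[uid].dropna().to_numpy()
        if vals.size == 0:
            continue
        mean, std, n = _summary(vals, ddof)
        rows.append({"unit_id": uid, "mean": mean, "std": std, "n_days": n})
    return pd.DataFrame(rows, columns=["unit_id", "mean", "std", "n_days"])


def percent_attributable(fire_mean, all_mean):
    """Percent of all-source PM2.5 attributable to fire: 100·fire/all.

    Returns full precision (round only for presentation); NaN with a
    warning where ``all_mean <= 0``.
    """
    fire = np.asarray(fire_mean, dtype=float)
    total = np.asarray(all_mean, dtype=float)
    with np.errstate(divide="ignore", invalid="ignore"):
        pct = np.where(total > 0, 100.0 * fire / total, np.nan)
    if np.any(~(total > 0)):
        warnings.warn("percent_attributable undefined where all_mean <= 0",
                      stacklevel=2)
    return float(pct) if pct.ndim == 0 else pct


def quartile_breaks(values: Iterable[float]) -> ExposureClassBreaks:
    """Quartile breaks of pooled unit-year annual means.

    Percentiles use linear interpolation between order statistics; the
    method choice is recorded in run metadata by the pipeline.
    """
    vals = np.asarray(list(values), dtype=float)
    vals = vals[np.isfinite(vals)]
    if vals.size < 4:
        raise ValueError(f"need >= 4 finite values for quartile breaks, got {vals.size}")
    q1, q2, q3 = np.percentile(vals, [25, 50, 75], method="linear")
    return ExposureClassBreaks(float(q1), float(q2), float(q3), float(vals.max()))


def classify_exposure(annual_mean, breaks: ExposureClassBreaks):
    """Exposure class 1-4 for an annual mean (scalar or array).

    Intervals are lower-open/upper-closed: class 1 = [0, q1],
    class 2 = (q1, q2], class 3 = (q2, q3], class 4 = (q3, ∞). Negative
    inputs (possible when the fire difference is not clipped) classify as
    class 1 with a warning.
    """
    v = np.asarray(annual_mean, dtype=float)
    if not np.all(np.isfinite(v)):
        raise ValueError("annual mean must be finite")
    if np.any(v < 0):
        warnings.warn("negative annual mean(s) assigned to class 1", stacklevel=2)
    cls = np.searchsorted([breaks.q1, breaks.q2, breaks.q3], v, side="left") + 1
    return int(cls) if cls.ndim == 0 else cls


def detect_smokewaves(
    series: pd.Series, params: SmokewaveParams = SmokewaveParams(), scope: str = ""
) -> list[SmokewaveEpisode]:
    """All maximal runs of consecutive exceedance days in one daily series.

    Exceedance is strict (value > threshold); runs must span at least
    ``min_consecutive_days`` *consecutive calendar days* — a date gap in the
    series splits a run. NaN days count as non-exceedance.
    """
    idx = pd.DatetimeIndex(series.index)
    if not idx.is_monotonic_increasing or idx.has_duplicates:
        raise ValueError("series dates must be strictly increasing and unique")
    values = series.to_numpy(dtype=float)
    exceed = values > params.threshold  # NaN compares False

    episodes: list[SmokewaveEpisode] = []

    def close(start: int, end: int) -> None:
        length = end - start + 1  # run days are consecutive by construction
        if length >= params.min_consecutive_days:
            episodes.append(
                SmokewaveEpisode(
                    scope=scope,
                    start=idx[start],
                    end=idx[end],
                    length=length,
                    peak=float(values[start : end + 1].max()),
                )
            )

    run_start: int | None = None
    for i in range(len(values)):
        if exceed[i]:
            if run_start is None:
                run_start = i
            elif (idx[i] - idx[i - 1]).days != 1:
                close(run_start, i - 1)  # a date gap splits runs
                run_start = i
        elif run_start is not None:
            close(run_start, i - 1)
            run_start = None
    if run_start is not None:
        close(run_start, len(values) - 1)
    return episodes


def _count_by_year(
    episodes: list[SmokewaveEpisode], years: Iterable[int]
) -> dict[int, int]:
    # an episode is counted once, in the year containing its start date
    counts = {int(y): 0 for y in years}
    for ep in episodes:
        counts[ep.start.year] = counts.get(ep.start.year, 0) + 1
    return counts


def smokewave_counts_cells(
    fire_field: DailyField, params: SmokewaveParams = SmokewaveParams()
) -> pd.DataFrame:
    """Per grid cell, smokewave episodes per year plus a period total.

    Rows indexed by (col, row); columns are years and ``total``.
    """
    years = sorted(set(fire_field.dates.year))
    rows = {}
    for row in range(fire_field.grid.n_rows):
        for col in range(fire_field.grid.n_cols):
            eps = detect_smokewaves(
                fire_field.cell_series(col, row), params, scope=f"cell_{col}_{row}"
            )
            rows[(col, row)] = _count_by_year(eps, years)
    out = pd.DataFrame.from_dict(rows, orient="index").fillna(0).astype(int)
    out.index = pd.MultiIndex.from_tuples(out.index, names=["col", "row"])
    out = out.reindex(sorted(out.columns), axis=1)
    out["total"] = out.sum(axis=1)
    return out


def smokewave_counts_units(
    unit_series: pd.DataFrame, params: SmokewaveParams = SmokewaveParams()
) -> pd.DataFrame:
    """Per administrative unit, smokewave episodes per year plus a period total."""
    years = sorted(set(pd.DatetimeIndex(unit_series.index).year))
    rows = {}
    for uid in unit_series.columns:
        s = unit_series[uid].dropna()
        eps = detect_smokewaves(s, params, scope=uid) if len(s) else []
        rows[uid] = _count_by_year(eps, years)
    out = pd.DataFrame.from_dict(rows, orient="index").fillna(0).astype(int)
    out.index.name = "unit_id"
    out = out.reindex(sorted(out.columns), axis=1)
    out["total"] = out.sum(axis=1)
    return out
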