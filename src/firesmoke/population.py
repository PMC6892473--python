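"""Population-at-risk tabulation by exposure class.

Each administrative unit's demographic and health-event counts are
attributed wholly to the unit's exposure class (a county-level design; no
within-unit apportionment). The at-risk table has one row per class plus
``missing`` (units without model data) and ``total``; for every column the
class rows plus missing sum to the total.
"""

from __future__ import annotations

import warnings
from typing import Mapping

import numpy as np
import pandas as pd

__all__ = [
    "CLASS_ROWS",
    "tabulate_at_risk",
    "at_risk_from_class_sums",
    "fraction_above",
    "smokewave_population",
    "allocate_pooled_counts",
]

CLASS_ROWS = ("class_1", "class_2", "class_3", "class_4")
_ALL_ROWS = CLASS_ROWS + ("missing", "total")


def tabulate_at_risk(
    unit_classes: Mapping[str, int], population: pd.DataFrame
) -> pd.DataFrame:
    """Sum population columns by exposure class.

    ``unit_classes`` maps unit_id -> class in {1,2,3,4}; units present in
    ``population`` but absent from the mapping (no model data) land in the
    ``missing`` row. The ``total`` row is the column total of the input, so
    class rows + missing = total by construction.
    """
    if population.index.has_duplicates:
        raise ValueError("duplicate unit_id in population table")
    bad = {u: c for u, c in unit_classes.items() if c not in (1, 2, 3, 4)}
    if bad:
        raise ValueError(f"exposure classes must be in 1..4: {bad}")

    out = pd.DataFrame(
        0.0, index=pd.Index(_ALL_ROWS, name="row"), columns=population.columns
    )
    for uid, row in population.iterrows():
        cls = unit_classes.get(uid)
        label = f"class_{cls}" if cls is not None else "missing"
        out.loc[label] += row.astype(float)
    out.loc["total"] = population.sum(axis=0).astype(float)
    return out


def at_risk_from_class_sums(
    class_sums: pd.DataFrame, total: pd.Series | None = None
) -> pd.DataFrame:
    """Build an at-risk table from pre-aggregated per-class sums.

    ``class_sums`` is indexed by class_1..class_4 and optionally missing;
    ``total`` overrides the total row (published tables sometimes carry a
    total with its own rounding), otherwise the column sums are used.
    """
    out = pd.DataFrame(
        0.0, index=pd.Index(_ALL_ROWS, name="row"), columns=class_sums.columns
    )
    for label in class_sums.index:
        if label not in _ALL_ROWS[:-1]:
            raise ValueError(f"unexpected row label {label!r}")
        out.loc[label] = class_sums.loc[label].astype(float)
    out.loc["total"] = (
        total.astype(float) if total is not None
        else out.loc[list(_ALL_ROWS[:-1])].sum(axis=0)
    )
    return out


def fraction_above(at_risk: pd.DataFrame, min_class: int = 2) -> pd.DataFrame:
    """Per column: sum over classes >= min_class, the total, and the percent.

    Percent is 100 · (sum of class rows >= min_class) / total, at full
    precision (present with one decimal for population columns, integer for
    event counts). With the replication breaks, ``min_class=2`` corresponds
    to units above 0.34 μg/m³ annual-mean fire-PM2.5.
    """
    if not 1 <= min_class <= 4:
        raise ValueError("min_class must be in 1..4")
    rows = [f"class_{c}" for c in range(min_class, 5)]
    above = at_risk.loc[rows].sum(axis=0)
    total = at_risk.loc["total"]
    if (total == 0).any():
        warnings.warn("fraction_above undefined for zero-total column(s)",
                      stacklevel=2)
    with np.errstate(divide="ignore", invalid="ignore"):
        pct = np.where(total > 0, 100.0 * above / total, np.nan)
    return pd.DataFrame({"sum_above": above, "total": total, "percent": pct})


def smokewave_population(
    episode_totals: pd.Series,
    population: pd.Series,
    min_total_episodes: int = 1,
) -> tuple[float, float]:
    """(population, percent of grand total) living in units whose period
    smokewave total meets ``min_total_episodes``.

    Over a 7-year run, thresholds 7 and 14 correspond to "at least one" and
    "at least two" smokewaves per year on average.
    """
    common = episode_totals.index.intersection(population.index)
    qualifying = common[episode_totals.loc[common] >= min_total_episodes]
    pop = float(population.loc[qualifying].sum())
    grand = float(population.sum())
    return pop, 100.0 * pop / grand if grand > 0 else float("nan")


def allocate_pooled_counts(
    population: pd.DataFrame,
    pooled_total: float,
    target_units: list[str],
    column: str,
    weight_column: str = "total_population_millions",
) -> pd.DataFrame:
    """Proportionally allocate a pooled count to small units by population.

    Health registries sometimes pool counts (e.g. births) for units below a
    disclosure size into one "unidentified" total; this splits that total
    across ``target_units`` proportionally to ``weight_column`` and adds it
    to ``column``. Returns a new table.
    """
    out = population.copy()
    weights = out.loc[target_units, weight_column].astype(float)
    if weights.sum() <= 0:
        raise ValueError("allocation weights must sum to a positive value")
    out.loc[target_units, column] = (
        out.loc[target_units, column] + pooled_total * weights / weights.sum()
    )
    return out
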