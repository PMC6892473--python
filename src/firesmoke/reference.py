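"""Published summary tables from the California 2007–2013 assessment.

The original study post-processed 12-km CMAQ national-run output (paired
all-sources / no-fire simulations) for California, 2007–2013. Its printed
summary tables are shipped here as small CSVs so the derived arithmetic —
percent attributable to fire, at-risk shares by exposure class, and the
stratified monitor-evaluation biases — can be recomputed with this
package's functions. The full gridded runs are not redistributable at desk
scale; use :mod:`firesmoke.scenario` for end-to-end pipeline runs.
"""

from __future__ import annotations

from importlib import resources

import pandas as pd

from .exposure import CALIFORNIA_BREAKS, ExposureClassBreaks

__all__ = [
    "statewide_annual_means",
    "county_period_means",
    "population_at_risk_table",
    "carbon_evaluation_means",
    "california_breaks",
]


def _read(name: str, **kwargs) -> pd.DataFrame:
    with resources.files("firesmoke.data").joinpath(name).open() as fh:
        return pd.read_csv(fh, comment="#", **kwargs)


def statewide_annual_means() -> pd.DataFrame:
    """Statewide mean daily PM2.5 by year (all-sources and fire-only, μg/m³);
    the ``period`` row is the 2007–2013 average."""
    return _read("ca_statewide_annual_pm25.csv").set_index("year")


def county_period_means() -> pd.DataFrame:
    """County-level 2007–2013 mean daily PM2.5 (μg/m³); the county with no
    cell centroid inside its boundary carries NaN."""
    return _read("ca_county_pm25.csv").set_index("county")


def population_at_risk_table() -> pd.DataFrame:
    """Population/health counts by annual-mean fire-PM2.5 exposure class
    (population columns in millions, event columns as counts)."""
    return _read("ca_population_at_risk.csv").set_index("row")


def carbon_evaluation_means() -> pd.DataFrame:
    """Annual mean observed/predicted PM2.5 carbon by fire-impact stratum
    at rural monitor locations (n = matched monitor-day pairs)."""
    return _read("ca_carbon_evaluation.csv")


def california_breaks() -> ExposureClassBreaks:
    """The study's quartile breaks of pooled county-year annual fire-PM2.5
    means: 0.34 / 0.56 / 0.86 μg/m³, observed max 20.3."""
    return ExposureClassBreaks(*CALIFORNIA_BREAKS)
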