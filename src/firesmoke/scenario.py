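"""Synthetic scenario generator: paired gridded runs with known fire truth.

Real inputs to this pipeline are paired chemical-transport-model runs
(all-sources and no-fire), administrative polygons, population tables and
monitor records. This module fabricates all of them with controllable
statistical structure and an explicit injected fire field, so the full
pipeline can be validated against stored truth at desk scale:

* background (no-fire) PM2.5: a positive, spatiotemporally smooth field —
  a seasonal sinusoid around a mean level, modulated by mean-one lognormal
  noise whose log follows a lag-1 autoregression in time and is Gaussian-
  smoothed in space;
* fire plumes: isotropic Gaussian blobs with linear advection and a
  trapezoidal rise-plateau-decay temporal profile — many near-zero days
  punctuated by sharp multi-day peaks, as in real fire seasons. This is a
  stand-in shape, not a dispersion model;
* units: a rectangular tiling of the grid, optionally plus one unit
  smaller than a cell that contains no cell centroid (so it has no model
  data, like a very small county);
* monitors: observations = carbon_fraction × true total PM2.5 ×
  per-year bias factor × mean-one lognormal noise, on a daily, 1-in-3 or
  1-in-6 sampling schedule.

All randomness derives from one master seed via independent spawned
streams per generator, so e.g. adding monitors never perturbs the fields.
"""

from __future__ import annotations

import warnings
from dataclasses import dataclass, field as dc_field
from typing import Mapping, Sequence

import numpy as np
import pandas as pd
from scipy.ndimage import gaussian_filter
from shapely.geometry import box

from .fields import DailyField
from .grid import AdminUnit, GridDefinition, build_grid

__all__ = [
    "BackgroundModel",
    "FireEvent",
    "MonitorSpec",
    "ScenarioConfig",
    "SyntheticScenario",
    "default_fire_events",
    "simulate_background",
    "simulate_fire",
    "compose_fields",
    "generate_units",
    "generate_population",
    "generate_monitors",
    "generate_scenario",
]

# Generated concentrations are quantized to multiples of 2^-20 μg/m³
# (≈ 1e-6). Sums and differences of such values below ~2^30 are exact in
# IEEE double arithmetic, so composing all = background + fire and then
# differencing recovers the stored fire truth bit-for-bit.
_QUANTUM = 2.0**-20


def _quantize(values: np.ndarray) -> np.ndarray:
    return np.round(values / _QUANTUM) * _QUANTUM


POPULATION_COLUMNS = [
    "asthma_ed_visits",
    "births",
    "heart_attack_hosp",
    "poverty_millions",
    "under_18_millions",
    "over_65_millions",
    "total_population_millions",
]


@dataclass(frozen=True)
class BackgroundModel:
    """No-fire background PM2.5 model (all concentrations μg/m³)."""

    mean_level: float = 3.7
    seasonal_amplitude: float = 1.2
    ar1: float = 0.5  # lag-1 autocorrelation of the log-noise process
    noise_sigma: float = 0.3  # lognormal scale; 0 gives a deterministic field
    spatial_sigma_cells: float = 2.0  # Gaussian smoothing of innovations

    def __post_init__(self) -> None:
        if self.noise_sigma < 0 or self.spatial_sigma_cells < 0:
            raise ValueError("variance parameters must be >= 0")
        if not -1 < self.ar1 < 1:
            raise ValueError("ar1 must be in (-1, 1)")
        if self.mean_level - self.seasonal_amplitude <= 0:
            raise ValueError("seasonal trough must stay positive")


@dataclass(frozen=True)
class FireEvent:
    """One advected Gaussian plume.

    Concentration added on day t of the event at cell (c, r):
    ``peak * profile(t) * exp(-d^2 / (2 sigma^2))`` where d is the distance
    in cell units from the advected center ``origin + advect * t`` and
    profile is a trapezoid with the given rise/plateau/decay fractions.
    """

    origin_col: float
    origin_row: float
    start: str  # ISO date
    duration: int
    peak: float
    sigma_cells: float
    advect_col: float = 0.0  # cells/day
    advect_row: float = 0.0
    profile: tuple[float, float, float] = (0.25, 0.5, 0.25)

    def __post_init__(self) -> None:
        if self.duration < 1:
            raise ValueError("duration must be >= 1 day")
        if self.peak <= 0 or self.sigma_cells <= 0:
            raise ValueError("peak and sigma_cells must be > 0")
        if abs(sum(self.profile) - 1.0) > 1e-9 or any(f < 0 for f in self.profile):
            raise ValueError("profile fractions must be >= 0 and sum to 1")

    def profile_value(self, day: int) -> float:
        """Trapezoidal temporal weight in [0, 1] for event day ``day``."""
        rise, _, decay = self.profile
        u = (day + 0.5) / self.duration
        if u < rise:
            return u / rise
        if u > 1.0 - decay:
            return (1.0 - u) / decay
        return 1.0


@dataclass(frozen=True)
class MonitorSpec:
    n_monitors: int = 10
    cadence_days: int = 3  # daily, 1-in-3 or 1-in-6 sampling
    carbon_fraction: float = 0.5  # of total PM2.5 mass
    noise_sigma: float = 0.1  # mean-one lognormal multiplicative noise
    bias_factor: float = 1.0  # default observed/predicted ratio
    bias_by_year: Mapping[int, float] = dc_field(default_factory=dict)

    def __post_init__(self) -> None:
        if self.cadence_days not in (1, 3, 6):
            raise ValueError("cadence_days must be 1, 3 or 6")
        if not 0 < self.carbon_fraction <= 1:
            raise ValueError("carbon_fraction must be in (0, 1]")
        if self.noise_sigma < 0:
            raise ValueError("noise_sigma must be >= 0")


def default_fire_events(
    grid: GridDefinition, years: Sequence[int]
) -> list[FireEvent]:
    """A sparse fire season per year, sized for the default 20×20 grid.

    Two large events (peak 200 μg/m³, σ = 3 cells, 10 days) and one
    moderate event (peak 120, σ = 2, 6 days) per year, placed so the
    injected fire mass is roughly a quarter of the total period mean over
    the default background.
    """
    events = []
    for i, year in enumerate(years):
        jitter = i % 3
        events += [
            FireEvent(0.30 * grid.n_cols + jitter, 0.65 * grid.n_rows,
                      f"{year}-07-10", 10, 200.0, 3.0, 0.4, -0.2),
            FireEvent(0.65 * grid.n_cols, 0.30 * grid.n_rows + jitter,
                      f"{year}-08-{20 + jitter:02d}", 10, 200.0, 3.0, -0.3, 0.3),
            FireEvent(0.45 * grid.n_cols, 0.45 * grid.n_rows,
                      f"{year}-06-05", 6, 120.0, 2.0, 0.5, 0.0),
        ]
    return events


@dataclass
class ScenarioConfig:
    grid: GridDefinition = dc_field(
        default_factory=lambda: build_grid(0.0, 0.0, 12_000.0, 20, 20)
    )
    start_date: str = "2007-01-01"
    end_date: str = "2008-12-31"
    background: BackgroundModel = dc_field(default_factory=BackgroundModel)
    fire_events: list[FireEvent] | None = None  # None -> default_fire_events
    unit_layout: tuple[int, int] = (2, 4)  # (block rows, block cols)
    include_tiny_unit: bool = True
    population_scale: float = 1.0
    monitors: MonitorSpec = dc_field(default_factory=MonitorSpec)
    seed: int = 0

    @property
    def dates(self) -> pd.DatetimeIndex:
        return pd.date_range(self.start_date, self.end_date, freq="D")

    @property
    def years(self) -> list[int]:
        return sorted(set(self.dates.year))

    def events(self) -> list[FireEvent]:
        if self.fire_events is None:
            return default_fire_events(self.grid, self.years)
        return list(self.fire_events)

    def _streams(self) -> dict[str, np.random.Generator]:
        names = ("background", "fire", "units", "population", "monitors")
        children = np.random.SeedSequence(self.seed).spawn(len(names))
        return {n: np.random.default_rng(s) for n, s in zip(names, children)}

    def stream(self, name: str) -> np.random.Generator:
        return self._streams()[name]


def _smoothed_unit_variance(rng, shape, sigma):
    """White standard-normal field, Gaussian-smoothed and re-standardized
    to unit marginal variance per cell (exact, including edge effects)."""
    eps = rng.standard_normal(shape)
    if sigma <= 0 or shape == (1, 1):
        return eps
    smoothed = gaussian_filter(eps, sigma, mode="nearest")
    # per-cell variance of the smoothed field: filter each basis vector once
    # and cache per shape/sigma
    scale = _smoothing_scale(shape, sigma)
    return smoothed / scale


_SCALE_CACHE: dict[tuple[tuple[int, int], float], np.ndarray] = {}


def _smoothing_scale(shape: tuple[int, int], sigma: float) -> np.ndarray:
    key = (shape, float(sigma))
    if key not in _SCALE_CACHE:
        # Var[(G eps)(x)] = sum_j w(x,j)^2 with w(x,j) = (G e_j)(x); summing
        # the squared response of every basis vector gives each cell's exact
        # variance including edge effects (n_cells filter calls, cached).
        var = np.zeros(shape)
        basis = np.zeros(shape)
        for r in range(shape[0]):
            for c in range(shape[1]):
                basis[r, c] = 1.0
                var += gaussian_filter(basis, sigma, mode="nearest") ** 2
                basis[r, c] = 0.0
        _SCALE_CACHE[key] = np.sqrt(var)
    return _SCALE_CACHE[key]


def simulate_background(config: ScenarioConfig) -> DailyField:
    """Strictly positive no-fire background field, reproducible per seed.

    day-of-year seasonality (winter maximum) times mean-one lognormal
    noise; the log-noise is AR(1) in time with the configured lag-1
    autocorrelation and spatially smoothed innovations.
    """
    bg = config.background
    dates = config.dates
    rng = config.stream("background")
    shape = (config.grid.n_rows, config.grid.n_cols)

    doy = dates.dayofyear.to_numpy()
    base = bg.mean_level + bg.seasonal_amplitude * np.cos(
        2 * np.pi * (doy - 15) / 365.25
    )

    if bg.noise_sigma == 0:
        values = np.repeat(base[:, None, None], shape[0], axis=1)
        values = np.repeat(values, shape[1], axis=2)
    else:
        rho = bg.ar1
        z = np.empty((len(dates), *shape))
        z[0] = _smoothed_unit_variance(rng, shape, bg.spatial_sigma_cells)
        innov_scale = np.sqrt(1 - rho**2)
        for t in range(1, len(dates)):
            eps = _smoothed_unit_variance(rng, shape, bg.spatial_sigma_cells)
            z[t] = rho * z[t - 1] + innov_scale * eps
        # exp(sigma z - sigma^2/2) has mean one for z ~ N(0, 1)
        values = base[:, None, None] * np.exp(
            bg.noise_sigma * z - bg.noise_sigma**2 / 2
        )
    return DailyField(config.grid, dates, _quantize(values), "no_fire")


def simulate_fire(config: ScenarioConfig) -> DailyField:
    """Deterministic injected fire-truth field (sum of event plumes)."""
    grid = config.grid
    dates = config.dates
    values = np.zeros((len(dates), grid.n_rows, grid.n_cols))
    cols, rows = np.meshgrid(np.arange(grid.n_cols), np.arange(grid.n_rows))

    n_clipped = 0
    for ev in config.events():
        start_idx = (pd.Timestamp(ev.start) - dates[0]).days
        for day in range(ev.duration):
            t = start_idx + day
            if not 0 <= t < len(dates):
                n_clipped += 1
                continue
            cc = ev.origin_col + ev.advect_col * day
            cr = ev.origin_row + ev.advect_row * day
            d2 = (cols - cc) ** 2 + (rows - cr) ** 2
            values[t] += (
                ev.peak
                * ev.profile_value(day)
                * np.exp(-d2 / (2 * ev.sigma_cells**2))
            )
    if n_clipped:
        warnings.warn(
            f"{n_clipped} fire-event day(s) fell outside the date range and "
            "were clipped",
            stacklevel=2,
        )
    return DailyField(grid, dates, _quantize(values), "fire")


def compose_fields(
    background: DailyField, fire_truth: DailyField
) -> tuple[DailyField, DailyField, DailyField]:
    """(all_sources, no_fire, fire_truth) with all = background + fire,
    so run differencing recovers the stored truth bit-for-bit."""
    if background.grid != fire_truth.grid or not background.dates.equals(
        fire_truth.dates
    ):
        raise ValueError("background and fire truth must share grid and dates")
    all_field = DailyField(
        background.grid,
        background.dates,
        background.values + fire_truth.values,
        "all_sources",
    )
    return all_field, background, fire_truth


def generate_units(config: ScenarioConfig) -> list[AdminUnit]:
    """Rectangular tiling of the grid extent into block units, optionally
    plus one sub-cell unit placed to avoid every cell centroid."""
    grid = config.grid
    xmin, ymin, xmax, ymax = grid.extent
    n_br, n_bc = config.unit_layout
    dx = (xmax - xmin) / n_bc
    dy = (ymax - ymin) / n_br
    units = []
    for br in range(n_br):
        for bc in range(n_bc):
            units.append(
                AdminUnit(
                    unit_id=f"unit_{br}{bc}",
                    name=f"Block {br}-{bc}",
                    geometry=box(
                        xmin + bc * dx, ymin + br * dy,
                        xmin + (bc + 1) * dx, ymin + (br + 1) * dy,
                    ),
                )
            )
    if config.include_tiny_unit:
        # a square spanning 5-20% of cell (0,0): well clear of the centroid
        s = grid.cell_size
        units.append(
            AdminUnit(
                unit_id="unit_tiny",
                name="Tiny (sub-cell) unit",
                geometry=box(xmin + 0.05 * s, ymin + 0.05 * s,
                             xmin + 0.20 * s, ymin + 0.20 * s),
            )
        )
    return units


def generate_population(config: ScenarioConfig) -> pd.DataFrame:
    """Per-unit demographic and health-event table (synthetic draws).

    Population columns are millions of persons; event columns are counts
    over the scenario period. Magnitudes follow rough real-world rates
    (≈24% under 18, ≈14% 65+, ≈35% under twice the poverty line, and
    event rates per resident-year) scaled by ``population_scale``.
    """
    rng = config.stream("population")
    units = generate_units(config)
    n_years = len(config.years)
    rows = {}
    for u in units:
        total = config.population_scale * rng.lognormal(mean=0.0, sigma=0.6)
        if u.unit_id == "unit_tiny":
            total *= 0.02
        persons = total * 1e6
        rows[u.unit_id] = {
            "asthma_ed_visits": float(
                np.round(persons * 50e-6 * n_years * rng.uniform(0.8, 1.2))
            ),
            "births": float(
                np.round(persons * 12e-3 * n_years * rng.uniform(0.9, 1.1))
            ),
            "heart_attack_hosp": float(
                np.round(persons * 25e-6 * n_years * rng.uniform(0.8, 1.2))
            ),
            "poverty_millions": total * 0.35 * rng.uniform(0.8, 1.2),
            "under_18_millions": total * 0.24 * rng.uniform(0.9, 1.1),
            "over_65_millions": total * 0.14 * rng.uniform(0.9, 1.1),
            "total_population_millions": total,
        }
    df = pd.DataFrame.from_dict(rows, orient="index", dtype=float)
    df.index.name = "unit_id"
    return df[POPULATION_COLUMNS]


def generate_monitors(
    config: ScenarioConfig,
    background: DailyField,
    fire_truth: DailyField,
) -> pd.DataFrame:
    """Synthetic monitor records with stored predictions.

    Columns: monitor_id, x, y, date, obs_carbon, pred_carbon,
    pred_fire_carbon. Observations are
    carbon_fraction × (background + fire) × bias_factor(year) × noise with
    mean-one lognormal noise; predictions are the noise- and bias-free
    model values at the monitor's cell, so the observed/predicted contrast
    isolates the configured bias.
    """
    spec = config.monitors
    rng = config.stream("monitors")
    grid = config.grid
    xmin, ymin, xmax, ymax = grid.extent
    xs = rng.uniform(xmin, xmax, spec.n_monitors)
    ys = rng.uniform(ymin, ymax, spec.n_monitors)
    dates = config.dates

    records = []
    for m in range(spec.n_monitors):
        cell = grid.cell_containing(xs[m], ys[m])
        assert cell is not None  # uniform draws are inside the half-open extent
        col, row = cell
        offset = m % spec.cadence_days  # stagger 1-in-3 / 1-in-6 schedules
        for t in range(offset, len(dates), spec.cadence_days):
            truth_total = background.values[t, row, col] + fire_truth.values[t, row, col]
            pred_carbon = spec.carbon_fraction * truth_total
            bias = spec.bias_by_year.get(dates[t].year, spec.bias_factor)
            noise = (
                np.exp(spec.noise_sigma * rng.standard_normal()
                       - spec.noise_sigma**2 / 2)
                if spec.noise_sigma > 0
                else 1.0
            )
            records.append(
                {
                    "monitor_id": f"mon_{m:03d}",
                    "x": xs[m],
                    "y": ys[m],
                    "date": dates[t],
                    "obs_carbon": pred_carbon * bias * noise,
                    "pred_carbon": pred_carbon,
                    "pred_fire_carbon": spec.carbon_fraction
                    * fire_truth.values[t, row, col],
                }
            )
    return pd.DataFrame.from_records(records)


@dataclass
class SyntheticScenario:
    """Everything the pipeline needs, plus the stored fire truth."""

    config: ScenarioConfig
    all_sources: DailyField
    no_fire: DailyField
    fire_truth: DailyField
    units: list[AdminUnit]
    population: pd.DataFrame
    monitors: pd.DataFrame


def generate_scenario(config: ScenarioConfig | None = None) -> SyntheticScenario:
    """Generate a complete, fully deterministic scenario from one seed."""
    config = config or ScenarioConfig()
    background = simulate_background(config)
    fire = simulate_fire(config)
    all_field, no_fire, fire_truth = compose_fields(background, fire)
    return SyntheticScenario(
        config=config,
        all_sources=all_field,
        no_fire=no_fire,
        fire_truth=fire_truth,
        units=generate_units(config),
        population=generate_population(config),
        monitors=generate_monitors(config, background, fire),
    )
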