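"""Synthetic scenario generator: determinism, statistical structure, truth."""

import numpy as np
import pandas as pd
import pytest

import firesmoke as fs
from firesmoke.scenario import (
    compose_fields,
    default_fire_events,
    generate_population,
    generate_units,
    simulate_background,
    simulate_fire,
)


def single_cell_config(**bg_kwargs):
    defaults = dict(mean_level=4.0, seasonal_amplitude=0.0, ar1=0.5,
                    noise_sigma=0.3, spatial_sigma_cells=0.0)
    defaults.update(bg_kwargs)
    return fs.ScenarioConfig(
        grid=fs.build_grid(0, 0, 12_000, 1, 1),
        start_date="2000-01-01",
        end_date="2027-05-18",  # 10,000 days
        background=fs.BackgroundModel(**defaults),
        fire_events=[],
    )


class TestBackground:
    def test_zero_noise_zero_amplitude_is_constant(self):
        cfg = single_cell_config(noise_sigma=0.0)
        field = simulate_background(cfg)
        assert np.allclose(field.values, 4.0)

    def test_deterministic_under_seed(self):
        cfg = fs.ScenarioConfig(seed=42, end_date="2007-03-01")
        a = simulate_background(cfg)
        b = simulate_background(cfg)
        assert np.array_equal(a.values, b.values)
        other = fs.ScenarioConfig(seed=43, end_date="2007-03-01")
        assert not np.array_equal(a.values, simulate_background(other).values)

    def test_strictly_positive(self):
        field = simulate_background(fs.ScenarioConfig(end_date="2007-06-30"))
        assert (field.values > 0).all()

    def test_lag1_autocorrelation_recovered(self):
        # 10,000-day single-cell run: the sample lag-1 autocorrelation of
        # the field should sit within ±0.05 of the configured 0.5 (the
        # lognormal transform attenuates it slightly below 0.5)
        field = simulate_background(single_cell_config())
        x = field.values[:, 0, 0]
        r = np.corrcoef(x[:-1], x[1:])[0, 1]
        assert abs(r - 0.5) < 0.05

    def test_seasonal_cycle_visible(self):
        cfg = fs.ScenarioConfig(
            grid=fs.build_grid(0, 0, 12_000, 1, 1),
            start_date="2007-01-01", end_date="2007-12-31",
            background=fs.BackgroundModel(noise_sigma=0.0),
            fire_events=[],
        )
        x = simulate_background(cfg).values[:, 0, 0]
        assert x[:30].mean() > x[170:200].mean()  # winter above summer


class TestFirePlumes:
    def test_no_events_gives_zero_field(self):
        cfg = fs.ScenarioConfig(fire_events=[], end_date="2007-02-01")
        assert not simulate_fire(cfg).values.any()

    def test_point_source_limit_hits_only_origin_cell(self):
        ev = fs.FireEvent(origin_col=5, origin_row=7, start="2007-01-10",
                          duration=4, peak=100.0, sigma_cells=1e-3,
                          profile=(0.0, 1.0, 0.0))
        cfg = fs.ScenarioConfig(fire_events=[ev], end_date="2007-02-01")
        field = simulate_fire(cfg)
        day = field.values[9]
        assert day[7, 5] == pytest.approx(100.0)
        day[7, 5] = 0.0
        assert not day.any()

    def test_off_center_cell_matches_closed_form(self):
        ev = fs.FireEvent(origin_col=5.0, origin_row=7.0, start="2007-01-10",
                          duration=5, peak=80.0, sigma_cells=2.0,
                          advect_col=0.5, advect_row=-0.25)
        cfg = fs.ScenarioConfig(fire_events=[ev], end_date="2007-02-01")
        field = simulate_fire(cfg)
        day = 2  # third event day, 2007-01-12, index 11
        cc, cr = 5.0 + 0.5 * day, 7.0 - 0.25 * day
        col, row = 8, 6
        d2 = (col - cc) ** 2 + (row - cr) ** 2
        expected = 80.0 * ev.profile_value(day) * np.exp(-d2 / (2 * 2.0**2))
        assert field.values[11, row, col] == pytest.approx(expected, abs=2e-6)

    def test_trapezoid_profile_rises_plateaus_decays(self):
        ev = fs.FireEvent(1, 1, "2007-01-01", 8, 10.0, 1.0,
                          profile=(0.25, 0.5, 0.25))
        w = [ev.profile_value(d) for d in range(8)]
        assert w[0] < w[1] < w[2] == w[3] == 1.0
        assert w[6] > w[7]

    def test_events_outside_range_clipped_with_warning(self):
        ev = fs.FireEvent(3, 3, "2006-12-30", 5, 50.0, 1.0)
        cfg = fs.ScenarioConfig(fire_events=[ev], end_date="2007-02-01")
        with pytest.warns(UserWarning, match="clipped"):
            field = simulate_fire(cfg)
        assert field.values[:3].any()  # tail of the event landed in range


class TestComposition:
    def test_zero_fire_means_all_equals_nofire(self):
        cfg = fs.ScenarioConfig(fire_events=[], end_date="2007-03-01")
        bg = simulate_background(cfg)
        fire = simulate_fire(cfg)
        all_field, no_fire, _ = compose_fields(bg, fire)
        assert np.array_equal(all_field.values, no_fire.values)

    def test_difference_recovers_stored_truth_bit_for_bit(self, default_scenario):
        recovered = fs.fire_difference(
            default_scenario.all_sources, default_scenario.no_fire
        )
        assert np.array_equal(recovered.values, default_scenario.fire_truth.values)

    def test_fire_share_matches_tuned_quarter(self, default_scenario):
        truth_share = 100.0 * (
            default_scenario.fire_truth.values.mean()
            / default_scenario.all_sources.values.mean()
        )
        assert truth_share == pytest.approx(25.0, abs=2.0)
        recovered_share = fs.percent_attributable(
            fs.fire_difference(
                default_scenario.all_sources, default_scenario.no_fire
            ).values.mean(),
            default_scenario.all_sources.values.mean(),
        )
        assert recovered_share == pytest.approx(truth_share, abs=1e-9)


class TestUnitsAndPopulation:
    def test_2x2_tiling_of_4x4_grid_gives_four_cells_each(self):
        cfg = fs.ScenarioConfig(grid=fs.build_grid(0, 0, 10, 4, 4),
                                unit_layout=(2, 2), include_tiny_unit=False)
        units = generate_units(cfg)
        asg = fs.assign_cells_to_units(cfg.grid, units)
        assert all(n == 4 for n in asg.cell_counts().values())
        assert not asg.unassigned

    def test_tiny_unit_contains_no_centroid(self, default_scenario):
        asg = fs.assign_cells_to_units(
            default_scenario.config.grid, default_scenario.units
        )
        assert "unit_tiny" in asg.empty_units

    def test_population_nonnegative_and_deterministic(self):
        cfg = fs.ScenarioConfig(seed=3)
        a = generate_population(cfg)
        b = generate_population(cfg)
        pd.testing.assert_frame_equal(a, b)
        assert (a >= 0).all().all()
        assert "unit_tiny" in a.index


class TestMonitors:
    def test_unbiased_noiseless_monitors_give_zero_bias(self):
        cfg = fs.ScenarioConfig(
            end_date="2007-06-30",
            monitors=fs.MonitorSpec(n_monitors=8, cadence_days=1,
                                    noise_sigma=0.0, bias_factor=1.0),
        )
        scen = fs.generate_scenario(cfg)
        matched = fs.match_monitors_to_cells(scen.monitors, cfg.grid)
        matched["stratum"] = fs.stratify_by_fire_impact(matched["pred_fire_carbon"])
        out = fs.stratum_summary(matched)
        assert np.allclose(out["difference"], 0.0)

    def test_cadence_thins_sampling(self):
        days = (pd.Timestamp("2007-03-31") - pd.Timestamp("2007-01-01")).days + 1
        for cadence in (1, 3, 6):
            cfg = fs.ScenarioConfig(
                end_date="2007-03-31",
                monitors=fs.MonitorSpec(n_monitors=4, cadence_days=cadence),
            )
            scen = fs.generate_scenario(cfg)
            per_mon = scen.monitors.groupby("monitor_id").size()
            assert (abs(per_mon - days / cadence) <= 1).all()

    def test_bias_factor_recovered_from_stratified_summary(self):
        # observations = 0.7 x predictions x mean-one noise, so the mean
        # bias (predicted - observed) should approach 0.3 x mean prediction
        cfg = fs.ScenarioConfig(
            start_date="2007-01-01", end_date="2007-12-31",
            monitors=fs.MonitorSpec(n_monitors=50, cadence_days=1,
                                    noise_sigma=0.1, bias_factor=0.7),
            seed=12,
        )
        scen = fs.generate_scenario(cfg)
        matched = fs.match_monitors_to_cells(scen.monitors, cfg.grid)
        pred_mean = matched["pred_carbon"].mean()
        diff = (matched["pred_carbon"] - matched["obs_carbon"]).mean()
        assert diff == pytest.approx(0.3 * pred_mean, rel=0.05)

    def test_adding_monitors_does_not_perturb_fields(self):
        few = fs.ScenarioConfig(seed=7, end_date="2007-03-01",
                                monitors=fs.MonitorSpec(n_monitors=2))
        many = fs.ScenarioConfig(seed=7, end_date="2007-03-01",
                                 monitors=fs.MonitorSpec(n_monitors=30))
        a, b = fs.generate_scenario(few), fs.generate_scenario(many)
        assert np.array_equal(a.no_fire.values, b.no_fire.values)
        pd.testing.assert_frame_equal(a.population, b.population)


class TestReplicationScenarioShape:
    def test_seven_year_series_has_fig4_like_sparsity(self):
        # 12-km cells, 7 years, sparse large events: most unit-days are
        # near zero with isolated multi-day peaks above the 35 μg/m³ level
        cfg = fs.ScenarioConfig(start_date="2007-01-01", end_date="2013-12-31",
                                seed=1)
        scen = fs.generate_scenario(cfg)
        asg = fs.assign_cells_to_units(cfg.grid, scen.units)
        series = fs.unit_daily_mean(scen.fire_truth, asg).drop(
            columns="unit_tiny"
        )
        vals = series.to_numpy()
        assert (vals < 1.0).mean() >= 0.80
        assert (vals > 35.0).any()
        counts = fs.smokewave_counts_units(series)
        assert counts["total"].sum() >= 7  # multi-day peaks, not single spikes

    def test_default_events_scale_with_years(self):
        grid = fs.build_grid(0, 0, 12_000, 20, 20)
        assert len(default_fire_events(grid, [2007])) == 3
        assert len(default_fire_events(grid, range(2007, 2014))) == 21
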