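"""Startup integration, steady-state metrics, recycle mixing, sweeps.

Heavier column-scale properties (grid convergence, carbon balance,
velocity sweeps at the study resolution) live in test_acceptance.py;
the runs here use small grids and short horizons.
"""

import dataclasses
import math

import numpy as np
import pytest

from syncol import (
    RecycleSpec,
    RunConfig,
    SimulationResult,
    SimulationSettings,
    apply_gas_recycle,
    build_column_model,
    fresh_feed_conversions,
    run_parameter_sweep,
    simulate_startup,
    simulate_with_recycle,
    steady_state_metrics,
)
from syncol.transport import ColumnState


def small_settings(config, n=12, tf=200.0, **kw):
    return dataclasses.replace(config.to_settings(), n_nodes=n, final_time=tf, **kw)


def run_config(network, config, settings=None, initial_biomass=None):
    settings = settings or config.to_settings()
    model = build_column_model(
        network,
        config.to_uptake_kinetics(),
        config.to_geometry(),
        config.to_gas_params(),
        config.feed_tuple(),
        settings,
        initial_biomass=(
            config.initial.biomass if initial_biomass is None else initial_biomass
        ),
    )
    return model, simulate_startup(model, settings)


def synthetic_result(exit_gas_co, exit_gas_h2, ethanol, acetate, feed=None):
    n = 5
    fields = np.zeros((9, n))
    fields[4, -1] = ethanol
    fields[5, -1] = acetate
    fields[6, -1] = exit_gas_co
    fields[7, -1] = exit_gas_h2
    inlet = feed or {"co": 80.64, "h2": 53.76, "co2": 0.0}
    return SimulationResult(
        times=np.array([0.0]),
        states=fields[None],
        final_state=ColumnState(fields),
        steady=True,
        steady_residual=0.0,
        z=np.linspace(0, 25, n),
        inlet_gas=inlet,
        fresh_feed=dict(inlet),
        settings=SimulationSettings(),
    )


class TestStartup:
    def test_no_cells_leaves_initial_state_nearly_stationary(self, toy_network, config_nominal):
        """X0 = 0: biomass and products stay exactly zero; gas and
        dissolved fields deviate only through the clean-liquid inlet
        dilution (bounded a priori by a closed-form estimate at ~3%)."""
        settings = small_settings(config_nominal, n=16, tf=300.0)
        model, res = run_config(toy_network, config_nominal, settings, initial_biomass=0.0)
        init = model.initial_state().fields
        final = res.final_state.fields
        assert np.all(final[0] == 0.0)
        assert np.all(final[4] == 0.0) and np.all(final[5] == 0.0)
        for i in (1, 2, 3, 6, 7, 8):
            scale = max(np.abs(init[i]).max(), 1e-12)
            assert np.abs(final[i] - init[i]).max() / scale < 0.05

    def test_startup_reaches_steady_state_with_growth(self, toy_network, config_nominal):
        settings = small_settings(config_nominal, n=12, tf=800.0)
        _, res = run_config(toy_network, config_nominal, settings)
        assert res.steady
        assert res.final_state["X"][-1] > 0.0
        m = steady_state_metrics(res)
        assert 0.0 < m.co_conversion < 1.0
        assert 0.0 < m.h2_conversion < 1.0

    def test_determinism_identical_runs_identical_metrics(self, toy_network, config_nominal):
        settings = small_settings(config_nominal, n=10, tf=60.0)
        _, r1 = run_config(toy_network, config_nominal, settings)
        _, r2 = run_config(toy_network, config_nominal, settings)
        np.testing.assert_array_equal(r1.final_state.fields, r2.final_state.fields)

    def test_tolerance_halving_leaves_exit_metrics_unchanged(self, toy_network, config_nominal):
        settings = small_settings(config_nominal, n=10, tf=600.0)
        tighter = dataclasses.replace(settings, rtol=settings.rtol / 2, atol=settings.atol / 2)
        _, coarse = run_config(toy_network, config_nominal, settings)
        _, fine = run_config(toy_network, config_nominal, tighter)
        mc, mf = steady_state_metrics(coarse), steady_state_metrics(fine)
        for name in ("biomass", "ethanol", "acetate", "co_conversion", "h2_conversion"):
            a, b = getattr(mc, name), getattr(mf, name)
            assert abs(a - b) / max(abs(b), 1e-12) < 1e-3, name


class TestMetrics:
    def test_conversion_limits(self):
        feed = {"co": 80.64, "h2": 53.76, "co2": 0.0}
        full = steady_state_metrics(synthetic_result(0.0, 0.0, 1.0, 1.0, feed))
        none = steady_state_metrics(synthetic_result(80.64, 53.76, 1.0, 1.0, feed))
        assert full.co_conversion == 1.0 and full.h2_conversion == 1.0
        assert none.co_conversion == 0.0 and none.h2_conversion == 0.0

    def test_ratio_sentinel_serializes_as_null_with_flag(self):
        m = steady_state_metrics(synthetic_result(10.0, 10.0, 5.0, 0.0))
        assert math.isinf(m.ethanol_acetate_ratio)
        d = m.to_dict()
        assert d["ethanol_acetate_ratio"] is None
        assert d["ethanol_acetate_ratio_infinite"] is True

    def test_finite_ratio_is_mass_basis(self):
        m = steady_state_metrics(synthetic_result(10.0, 10.0, 30.0, 3.0))
        assert m.ethanol_acetate_ratio == pytest.approx(10.0)


class TestRecycle:
    def test_zero_alpha_returns_fresh_feed(self):
        fresh = {"co": 80.0, "h2": 54.0, "co2": 0.0}
        exit_gas = {"co": 40.0, "h2": 20.0, "co2": 10.0}
        assert apply_gas_recycle(fresh, exit_gas, 0.0) == fresh

    def test_exit_matching_feed_composition_is_fixed_point(self):
        fresh = {"co": 80.0, "h2": 54.0, "co2": 0.0}
        exit_gas = {k: 0.5 * v for k, v in fresh.items()}  # same composition
        for alpha in (0.2, 0.5, 0.9):
            mixed = apply_gas_recycle(fresh, exit_gas, alpha)
            for role in fresh:
                assert mixed[role] == pytest.approx(fresh[role], rel=1e-12)

    def test_total_inlet_concentration_is_preserved(self):
        fresh = {"co": 80.0, "h2": 54.0, "co2": 0.0}
        exit_gas = {"co": 10.0, "h2": 45.0, "co2": 12.0}
        mixed = apply_gas_recycle(fresh, exit_gas, 0.6)
        assert sum(mixed.values()) == pytest.approx(sum(fresh.values()), rel=1e-12)

    def test_invalid_alpha_rejected(self):
        fresh = {"co": 80.0, "h2": 54.0, "co2": 0.0}
        with pytest.raises(ValueError):
            apply_gas_recycle(fresh, fresh, 1.0)
        with pytest.raises(ValueError):
            RecycleSpec(alpha=1.2)

    def test_recycle_improves_fresh_feed_conversions(self, toy_network, config_nominal):
        """Recycling unconsumed gas must not decrease the conversions
        accounted against the fresh feed (it feeds back unconverted
        substrate for another pass)."""
        settings = small_settings(config_nominal, n=10, tf=400.0)
        cfg = config_nominal
        base_model, base = run_config(toy_network, cfg, settings)
        base_conv = fresh_feed_conversions(base, alpha=0.0)
        rec, passes = simulate_with_recycle(
            toy_network, cfg.to_uptake_kinetics(), cfg.to_geometry(),
            cfg.to_gas_params(), cfg.feed_tuple(), settings,
            RecycleSpec(alpha=0.5),
        )
        assert passes <= 50
        conv = fresh_feed_conversions(rec, alpha=0.5)
        assert conv["co"] >= base_conv["co"] - 1e-6
        assert conv["h2"] >= base_conv["h2"] - 1e-6


class TestSweep:
    def test_single_value_sweep_equals_single_simulation(self, toy_network, config_nominal):
        cfg = config_nominal.with_override("simulation.n_nodes", 10)
        cfg = cfg.with_override("simulation.final_time", 60.0)
        table = run_parameter_sweep(toy_network, cfg, "geometry.u_gas", [75.0])
        assert len(table) == 1 and not table["failed"].iloc[0]
        _, res = run_config(toy_network, cfg)
        m = steady_state_metrics(res)
        assert table["biomass_gL"].iloc[0] == pytest.approx(m.biomass, rel=1e-12)

    def test_failed_run_is_recorded_not_raised(self, toy_network, config_nominal):
        cfg = config_nominal.with_override("simulation.n_nodes", 10)
        cfg = cfg.with_override("simulation.final_time", 20.0)
        table = run_parameter_sweep(
            toy_network, cfg, "geometry.u_gas", [75.0, float("nan")]
        )
        assert list(table["failed"]) == [False, True]

    def test_washout_at_high_liquid_velocity(self, toy_network, config_nominal):
        """Beyond a critical liquid velocity the dilution rate exceeds the
        maximum growth rate and the column washes out."""
        cfg = config_nominal.with_override("simulation.n_nodes", 12)
        cfg = cfg.with_override("simulation.final_time", 200.0)
        table = run_parameter_sweep(
            toy_network, cfg, "geometry.u_liquid", [0.25, 25.0]
        )
        assert table["biomass_gL"].iloc[0] > 1.0
        assert table["biomass_gL"].iloc[1] < 1e-3
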