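"""Integrator and co-simulation loop tests."""

import numpy as np
import pytest

from symbiobot import CircuitParams, NoiseParams, SimConfig, Topology, run_simulation
from symbiobot.circuits import N_SPECIES, rhs
from symbiobot.engine import IntegrationError, integrate_step, stall_fraction


class TestIntegrateStep:
    def test_linear_decay_reaches_closed_form(self):
        y = np.array([1.0])
        for _ in range(100):
            y = integrate_step(y, lambda s: -s, 0.01)
        assert abs(y[0] - np.exp(-1.0)) < 1e-9

    def test_zero_rhs_is_identity(self):
        y = np.array([1.0, 2.0, 3.0])
        out = integrate_step(y, lambda s: np.zeros_like(s), 0.5)
        np.testing.assert_array_equal(out, y)

    def test_nonfinite_state_raises_with_diagnostic(self):
        with pytest.raises(IntegrationError, match="non-finite"):
            integrate_step(np.array([1.0]), lambda s: s * np.inf, 0.1)

    def test_invalid_dt(self):
        with pytest.raises(ValueError):
            integrate_step(np.array([1.0]), lambda s: -s, 0.0)

    def test_toggle_state_stable_under_dt_halving(self):
        p = CircuitParams()

        def run(dt, t_end=10.0):
            y = np.zeros(N_SPECIES)
            y[9] = 50.0
            for _ in range(int(round(t_end / dt))):
                y = integrate_step(y, lambda s: rhs(np.maximum(s, 0.0), p), dt)
            return y

        a, b = run(0.01), run(0.005)
        rel = np.max(np.abs(a - b) / np.maximum(np.abs(b), 1e-12))
        assert rel < 1e-8

    def test_agrees_with_rk4_oracle_on_toggle(self):
        """Fixed-step Dormand-Prince vs a classical RK4 oracle, t in [0, 50]."""
        p = CircuitParams()
        f = lambda s: rhs(np.maximum(s, 0.0), p)

        def rk4(y, dt):
            k1 = f(y)
            k2 = f(y + dt / 2 * k1)
            k3 = f(y + dt / 2 * k2)
            k4 = f(y + dt * k3)
            return y + dt / 6 * (k1 + 2 * k2 + 2 * k3 + k4)

        ya = np.zeros(N_SPECIES)
        ya[9] = 50.0
        yb = ya.copy()
        for _ in range(5000):
            ya = integrate_step(ya, f, 0.01)
            yb = rk4(yb, 0.01)
        assert np.max(np.abs(ya - yb) / np.maximum(np.abs(yb), 1e-9)) < 1e-6


class TestStallFraction:
    @pytest.mark.parametrize(
        "efm, expected",
        [([0, 0, 1, 1], 50.0), ([0, 0, 0], 100.0), ([1, 0, 1, 0, 1], 40.0)],
    )
    def test_values(self, efm, expected):
        assert stall_fraction(np.array(efm)) == pytest.approx(expected)

    def test_docked_steps_excluded_from_numerator(self):
        efm = np.array([0, 0, 1, 1])
        docked = np.array([True, False, False, False])
        assert stall_fraction(efm, docked) == pytest.approx(25.0)

    def test_empty_trace_is_an_error(self):
        with pytest.raises(ValueError):
            stall_fraction(np.array([]))


class TestRunSimulation:
    def test_immediate_time_cap(self):
        res = run_simulation(SimConfig(t_max=0.01))
        assert res.metrics["total_steps"] == 1
        assert res.metrics["completed"] is False
        assert res.metrics["lactose_acquired"] + res.metrics["arabinose_acquired"] == 0

    def test_bitwise_reproducibility(self):
        a = run_simulation(SimConfig(t_max=40.0, seed=5))
        b = run_simulation(SimConfig(t_max=40.0, seed=5))
        np.testing.assert_array_equal(a.trace.species, b.trace.species)
        np.testing.assert_array_equal(a.trace.x, b.trace.x)
        np.testing.assert_array_equal(a.trace.efm, b.trace.efm)
        assert a.events == b.events

    def test_stochastic_seeded_reproducibility(self):
        cfg = SimConfig(t_max=30.0, seed=9, noise=NoiseParams(sigma_tx=0.2, enabled=True))
        a, b = run_simulation(cfg), run_simulation(cfg)
        np.testing.assert_array_equal(a.trace.species, b.trace.species)

    def test_trace_clock_and_nonnegativity(self, balanced_result):
        tr = balanced_result.trace
        dt = balanced_result.config.dt
        np.testing.assert_allclose(np.diff(tr.t), dt, rtol=1e-9)
        assert np.all(tr.species >= 0.0)
        assert np.all(np.abs(tr.x) <= 10.0) and np.all(np.abs(tr.y) <= 10.0)

    def test_speed_quantization(self, balanced_result, lux_result):
        for res in (balanced_result, lux_result):
            v = res.config.robot.v_base
            levels = np.unique(np.round(res.trace.speed / v, 12))
            assert set(levels).issubset({0.0, 1.0, 2.0})

    def test_dock_events_consistent_with_trace(self, balanced_result):
        """A dock at time t implies the robot was within r_dock of that
        depot at t and the depot had been spawned while active."""
        res = balanced_result
        r_dock = res.config.robot.r_dock
        spawns = {e["depot_id"]: e for e in res.events if e["kind"] == "spawn"}
        for ev in res.events:
            if ev["kind"] != "dock":
                continue
            i = np.searchsorted(res.trace.t, ev["t"])
            sp = spawns[ev["depot_id"]]
            d = np.hypot(res.trace.x[i] - sp["x"], res.trace.y[i] - sp["y"])
            assert d <= r_dock + 1e-9
            assert sp["t"] < ev["t"]

    def test_plain_toggle_never_fires_ahl(self, balanced_result):
        assert all(e["kind"] != "ahl_pulse" for e in balanced_result.events)

    def test_lux_run_fires_one_pulse_per_approach(self, lux_result):
        pulses = [e for e in lux_result.events if e["kind"] == "ahl_pulse"]
        docks = [e for e in lux_result.events if e["kind"] == "dock"]
        assert len(pulses) == len(docks)
        # pulses and docks interleave: every dock is preceded by its pulse
        for p, d in zip(pulses, docks):
            assert p["t"] < d["t"]

    def test_depot_bookkeeping_over_balanced_run(self, balanced_result):
        events = balanced_result.events
        spawned = [e for e in events if e["kind"] == "spawn"]
        docked = [e for e in events if e["kind"] == "dock"]
        assert len(spawned) == 4 and len(docked) == 4
        by_type = {"lactose": 0, "arabinose": 0}
        for e in spawned:
            by_type[e["inducer"]] += 1
        assert by_type == {"lactose": 2, "arabinose": 2}

    def test_random_spawn_mode_preserves_bistable_foraging(self):
        from symbiobot.environment import ArenaParams

        cfg = SimConfig(arena=ArenaParams(spawn_mode="random"), seed=21)
        res = run_simulation(cfg)
        assert res.metrics["completed"]
        docks = [e["inducer"] for e in res.events if e["kind"] == "dock"]
        assert all(a != b for a, b in zip(docks, docks[1:]))
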