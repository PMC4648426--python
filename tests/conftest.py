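"""Shared fixtures: reference runs are expensive, so they are computed
once per session and reused across test modules."""

import pytest

from symbiobot import CircuitParams, SimConfig, Topology, run_simulation
from symbiobot.sweeps import default_walk_values, walk_rbscI


@pytest.fixture(scope="session")
def balanced_result():
    """Reference balanced-toggle run (deterministic, ~1 s)."""
    return run_simulation(SimConfig())


@pytest.fixture(scope="session")
def lux_result():
    """Reference host-feedback (TOGGLE_LUX) run."""
    cfg = SimConfig(circuit=CircuitParams(topology=Topology.TOGGLE_LUX))
    return run_simulation(cfg)


@pytest.fixture(scope="session")
def biased_result():
    """Biased toggle: LacI RBS 2.4x the TetR RBS."""
    cfg = SimConfig(circuit=CircuitParams(rbs_lacI=0.72, rbs_tetR=0.3))
    return run_simulation(cfg)


@pytest.fixture(scope="session")
def walk_result():
    """Reference rbs_cI walk (~26 runs; the slow fixture, ~2 min)."""
    return walk_rbscI(default_walk_values(), SimConfig())
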