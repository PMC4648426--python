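"""Unit and property tests for the gene-circuit kinetics."""

import numpy as np
import pytest
from hypothesis import given, settings, strategies as st
from scipy.optimize import fsolve

from symbiobot.circuits import (
    CircuitParams,
    CircuitState,
    I_ARA,
    I_GFP,
    I_LAC,
    I_LACI,
    I_M_LACI,
    I_M_TETR,
    I_MCHERRY,
    I_TETR,
    N_SPECIES,
    NoiseParams,
    SPECIES,
    Topology,
    active_repressor,
    apply_noise,
    derivatives,
    hill_activation,
    hill_repression,
    rhs,
)


@pytest.mark.parametrize(
    "R, K, n, expected",
    [
        (0.0, 1.0, 2.0, 1.0),          # no repressor, full activity
        (7.3, 7.3, 3.0, 0.5),          # half-maximal at K
        (3.0, 1.0, 2.0, 0.1),          # 1/(1+9)
    ],
)
def test_hill_repression_values(R, K, n, expected):
    assert hill_repression(R, K, n) == pytest.approx(expected, rel=1e-12)


@pytest.mark.parametrize(
    "A, K, n, expected",
    [
        (0.0, 10.0, 2.0, 0.0),
        (10.0, 10.0, 2.0, 0.5),
        (30.0, 10.0, 2.0, 0.9),        # 9/(1+9)
    ],
)
def test_hill_activation_values(A, K, n, expected):
    assert hill_activation(A, K, n) == pytest.approx(expected, rel=1e-12)


@pytest.mark.parametrize(
    "R, I, K_I, eta, expected",
    [
        (10.0, 0.0, 10.0, 2.0, 10.0),           # no inducer
        (10.0, 4.2, 4.2, 2.0, 5.0),             # half at K_I
        (10.0, 1000.0, 10.0, 2.0, 10.0 / (1 + 100.0**2)),
    ],
)
def test_active_repressor_values(R, I, K_I, eta, expected):
    assert active_repressor(R, I, K_I, eta) == pytest.approx(expected, rel=1e-12)


@pytest.mark.parametrize("bad", [dict(K=0.0), dict(K=-1.0), dict(n=0.5)])
def test_hill_parameter_errors(bad):
    kw = dict(K=1.0, n=2.0) | bad
    with pytest.raises(ValueError):
        hill_repression(1.0, kw["K"], kw["n"])
    with pytest.raises(ValueError):
        hill_activation(1.0, kw["K"], kw["n"])


@given(st.floats(0, 1e4), st.floats(1e-3, 1e3), st.floats(1, 8))
@settings(max_examples=200, derandomize=True)
def test_hill_bounds(R, K, n):
    r = hill_repression(R, K, n)
    a = hill_activation(R, K, n)
    # mathematically r in (0,1] and a in [0,1); large (R/K)^n saturates
    # to the closed bounds in floating point
    assert 0.0 <= r <= 1.0
    assert 0.0 <= a <= 1.0
    # repression + activation of the same ligand partition activity
    assert r + a == pytest.approx(1.0, abs=1e-12)


@given(
    st.floats(0, 100), st.floats(0.1, 100), st.floats(1e-2, 1e3),
    st.floats(1e-2, 1e3), st.floats(1, 6),
)
@settings(max_examples=200, derandomize=True)
def test_active_repressor_monotone_in_inducer(R, I, dI, K_I, eta):
    lo = active_repressor(R, I, K_I, eta)
    hi = active_repressor(R, I + dI, K_I, eta)
    assert hi <= lo <= R


def test_rbs_out_of_range_rejected():
    with pytest.raises(ValueError, match="rbs_lacI"):
        CircuitParams(rbs_lacI=1.5)


def test_derivatives_zero_state_fully_derepressed():
    """At zero state, both toggle promoters run at alpha_tx; nothing else moves."""
    p = CircuitParams(topology=Topology.TOGGLE)
    d = derivatives(CircuitState(), p)
    assert d.m_lacI == pytest.approx(p.alpha_tx)
    assert d.m_tetR == pytest.approx(p.alpha_tx)
    for name in SPECIES:
        if name not in ("m_lacI", "m_tetR"):
            assert getattr(d, name) == 0.0


def _mirror(y):
    """Swap the two toggle sides: LacI<->TetR, GFP<->mCherry, lac<->ara."""
    out = y.copy()
    out[[I_M_LACI, I_M_TETR]] = y[[I_M_TETR, I_M_LACI]]
    out[[I_LACI, I_TETR]] = y[[I_TETR, I_LACI]]
    out[[I_GFP, I_MCHERRY]] = y[[I_MCHERRY, I_GFP]]
    out[[I_LAC, I_ARA]] = y[[I_ARA, I_LAC]]
    return out


def test_balanced_toggle_mirror_symmetry():
    p = CircuitParams(topology=Topology.TOGGLE)  # balanced by default
    rng = np.random.default_rng(0)
    for _ in range(20):
        y = rng.uniform(0, 30, N_SPECIES)
        y[2] = y[5] = y[10] = 0.0  # lux species unused in TOGGLE
        np.testing.assert_allclose(rhs(_mirror(y), p), _mirror(rhs(y, p)), rtol=1e-12)


def test_toggle_fixed_point_residual():
    """An independently root-solved steady state zeroes the RHS to < 1e-8."""
    p = CircuitParams(topology=Topology.TOGGLE)
    # seed the solver near the mCherry-dominant branch
    y0 = np.zeros(N_SPECIES)
    y0[I_M_LACI] = 10.0
    y0[I_LACI] = 16.0
    y0[I_MCHERRY] = 16.0
    star = fsolve(lambda y: rhs(np.abs(y), p), y0, full_output=False)
    assert np.linalg.norm(rhs(np.abs(star), p)) < 1e-8
    # and it is a genuinely LacI-dominant state
    assert np.abs(star)[I_LACI] > 10 * np.abs(star)[I_TETR]


def test_rbs_monotonicity_of_steady_state():
    """Raising rbs_lacI weakly raises steady LacI/mCherry, lowers TetR/GFP."""
    from symbiobot.engine import integrate_step

    def steady(rbs_lacI):
        p = CircuitParams(rbs_lacI=rbs_lacI)
        y = np.zeros(N_SPECIES)
        y[I_ARA] = 50.0  # push toward the LacI branch
        for _ in range(4000):
            y = np.maximum(integrate_step(y, lambda s: rhs(np.maximum(s, 0.0), p), 0.05), 0.0)
        return y

    lo, hi = steady(0.4), steady(0.8)
    assert hi[I_LACI] >= lo[I_LACI]
    assert hi[I_MCHERRY] >= lo[I_MCHERRY] - 1e-9
    assert hi[I_TETR] <= lo[I_TETR] + 1e-9
    assert hi[I_GFP] <= lo[I_GFP] + 1e-9


def test_apply_noise_zero_sigma_equals_drift():
    p = CircuitParams()
    y = np.full(N_SPECIES, 3.0)
    rng = np.random.default_rng(1)
    inc = apply_noise(y, p, NoiseParams(enabled=True), 0.01, rng)
    np.testing.assert_array_equal(inc, rhs(y, p) * 0.01)


def test_apply_noise_seeded_reproducibility():
    p = CircuitParams()
    noise = NoiseParams(sigma_tx=0.2, sigma_tl=0.1, enabled=True)
    y = np.full(N_SPECIES, 5.0)
    a = [apply_noise(y, p, noise, 0.01, np.random.default_rng(42)) for _ in range(1)]
    b = [apply_noise(y, p, noise, 0.01, np.random.default_rng(42)) for _ in range(1)]
    np.testing.assert_array_equal(a[0], b[0])


def test_apply_noise_never_drives_state_negative():
    p = CircuitParams()
    noise = NoiseParams(sigma_tx=2.0, sigma_tl=2.0, enabled=True)
    rng = np.random.default_rng(7)
    y = np.full(N_SPECIES, 0.05)
    for _ in range(500):
        y = y + apply_noise(y, p, noise, 0.01, rng)
        assert np.all(y >= 0.0)


def test_constitutive_gene_stationary_mean():
    """Langevin mRNA of a constitutive gene averages to alpha/delta_m.

    The lac-reporter operon at saturating lactose is an (effectively)
    constitutive gene; the linear SDE's stationary mean is the
    deterministic fixed point, checked against 50 seeded replicates.
    """
    p = CircuitParams(topology=Topology.LAC_REPORTER, delta_ind=1e-9)
    noise = NoiseParams(sigma_tx=0.3, enabled=True)
    lac = 1e6  # saturating: activation ~ 1
    expected = p.alpha_tx * hill_activation(lac, p.K_lac, p.eta_ind) / p.delta_m
    dt, burn, keep = 0.02, 2000, 4000
    means = []
    for seed in range(50):
        rng = np.random.default_rng(seed)
        y = np.zeros(N_SPECIES)
        y[I_LAC] = lac
        samples = []
        for i in range(burn + keep):
            y = y + apply_noise(y, p, noise, dt, rng)
            if i >= burn:
                samples.append(y[I_M_TETR])
        means.append(np.mean(samples))
    grand = np.mean(means)
    se = np.std(means, ddof=1) / np.sqrt(len(means))
    assert abs(grand - expected) < 3 * se + 1e-9
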