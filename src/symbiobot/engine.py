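"""Fixed-step integration and the hybrid co-simulation loop.

The circuit ODEs are advanced with a fixed-step, fifth-order
Dormand-Prince (RK45 pair, fifth-order solution) update; discrete
events -- inducer dosing windows, AHL pulses, dock/deplete/respawn --
are applied only at step boundaries so the right-hand side stays
smooth within a step.  In stochastic mode the integrator is replaced
by the order-1 Euler-Maruyama scheme of :func:`~symbiobot.circuits.apply_noise`.

One master seed drives the run; child streams for depot placement and
expression noise are derived from it deterministically, so a run is
bitwise reproducible given its config.
"""

from __future__ import annotations

import math
from dataclasses import dataclass, field
from typing import Callable, Optional

import numpy as np

from . import circuits, environment, robot as robot_mod, transduction
from .circuits import (
    CircuitParams,
    CircuitState,
    I_AHL,
    I_ARA,
    I_GFP,
    I_MCHERRY,
    N_SPECIES,
    NoiseParams,
    SPECIES,
)
from .environment import Arena, ArenaParams, Inducer, dose_rates, init_arena, respawn
from .robot import RobotParams, RobotState, ahl_trigger, check_dock, select_target, step_motion, update_arming
from .transduction import EFMConfig, EFMState, efm_signal

__all__ = [
    "IntegrationError",
    "SimConfig",
    "SimTrace",
    "SimResult",
    "integrate_step",
    "run_simulation",
    "stall_fraction",
]


class IntegrationError(RuntimeError):
    """Raised when the circuit state leaves the finite domain."""


# Dormand-Prince 5(4) tableau; only the fifth-order solution weights
# are used (b7 = 0, so six stage evaluations suffice at fixed step).
_DP_A = (
    (1 / 5,),
    (3 / 40, 9 / 40),
    (44 / 45, -56 / 15, 32 / 9),
    (19372 / 6561, -25360 / 2187, 64448 / 6561, -212 / 729),
    (9017 / 3168, -355 / 33, 46732 / 5247, 49 / 176, -5103 / 18656),
)
_DP_B = (35 / 384, 0.0, 500 / 1113, 125 / 192, -2187 / 6784, 11 / 84)


def integrate_step(y: np.ndarray, f: Callable[[np.ndarray], np.ndarray], dt: float) -> np.ndarray:
    """One fixed-step fifth-order Dormand-Prince update of ``y' = f(y)``.

    ``f`` must be autonomous over the step (events are frozen at the
    step boundary by the caller).  Raises :class:`IntegrationError` on
    a non-finite result.
    """
    if dt <= 0:
        raise ValueError(f"dt must be > 0, got {dt}")
    k1 = f(y)
    k2 = f(y + dt * (_DP_A[0][0] * k1))
    k3 = f(y + dt * (_DP_A[1][0] * k1 + _DP_A[1][1] * k2))
    k4 = f(y + dt * (_DP_A[2][0] * k1 + _DP_A[2][1] * k2 + _DP_A[2][2] * k3))
    k5 = f(y + dt * (_DP_A[3][0] * k1 + _DP_A[3][1] * k2 + _DP_A[3][2] * k3 + _DP_A[3][3] * k4))
    k6 = f(
        y
        + dt
        * (
            _DP_A[4][0] * k1
            + _DP_A[4][1] * k2
            + _DP_A[4][2] * k3
            + _DP_A[4][3] * k4
            + _DP_A[4][4] * k5
        )
    )
    out = y + dt * (
        _DP_B[0] * k1 + _DP_B[2] * k3 + _DP_B[3] * k4 + _DP_B[4] * k5 + _DP_B[5] * k6
    )
    if not np.all(np.isfinite(out)):
        bad = [SPECIES[i] for i in np.nonzero(~np.isfinite(out))[0]]
        raise IntegrationError(f"non-finite state after step: {bad}")
    return out


@dataclass
class SimConfig:
    """Complete configuration of one simulation run."""

    circuit: CircuitParams = field(default_factory=CircuitParams)
    noise: NoiseParams = field(default_factory=NoiseParams)
    efm: EFMConfig = field(default_factory=EFMConfig)
    robot: RobotParams = field(default_factory=RobotParams)
    arena: ArenaParams = field(default_factory=ArenaParams)
    dt: float = 0.01        # min
    t_max: float = 500.0    # min
    seed: int = 0
    ara_init: float = 50.0  # t=0 arabinose injection, a.u.

    def __post_init__(self) -> None:
        if self.dt <= 0:
            raise ValueError(f"dt must be > 0, got {self.dt}")
        if self.t_max <= 0:
            raise ValueError(f"t_max must be > 0, got {self.t_max}")
        if self.ara_init < 0:
            raise ValueError("ara_init must be >= 0")


@dataclass
class SimTrace:
    """Per-step time series of a run (arrays share one length)."""

    t: np.ndarray
    x: np.ndarray
    y: np.ndarray
    efm: np.ndarray
    speed: np.ndarray
    docked: np.ndarray
    species: np.ndarray  # (n_steps, N_SPECIES)

    def __len__(self) -> int:
        return len(self.t)


@dataclass
class SimResult:
    """Trace, ordered event log, and summary metrics of one run."""

    config: SimConfig
    trace: SimTrace
    events: list[dict]
    metrics: dict


def stall_fraction(efm_values: np.ndarray, docked: Optional[np.ndarray] = None) -> float:
    """Percentage of steps spent in stall (EFM = 0 while undocked).

    Docked (dosing) steps are excluded from the numerator but kept in
    the denominator: stalling is a behavioral readout of the EFM,
    whereas docking is a commanded stop.
    """
    efm_values = np.asarray(efm_values)
    if efm_values.size == 0:
        raise ValueError("empty trace")
    stalled = efm_values == 0
    if docked is not None:
        stalled = stalled & ~np.asarray(docked, dtype=bool)
    return 100.0 * float(np.count_nonzero(stalled)) / efm_values.size


def run_simulation(cfg: SimConfig) -> SimResult:
    """Run the coupled circuit/robot/arena simulation to completion.

    Per step: (1) freeze dosing sources, (2) advance the circuit, (3)
    read the EFM, (4) select a target and move (unless docked), (5)
    check AHL proximity and docking, (6) on dock start dosing, deplete
    and respawn per budget.  The run ends when the depot budget has
    been acquired or ``t_max`` is reached.
    """
    seed_seq = np.random.SeedSequence(cfg.seed)
    arena_seed, noise_seed = seed_seq.spawn(2)
    arena = init_arena(cfg.arena, seed=arena_seed)
    noise_rng = np.random.default_rng(noise_seed)

    p = cfg.circuit
    y = np.zeros(N_SPECIES)
    y[I_ARA] = cfg.ara_init  # the t=0 simulated arabinose injection
    robot = RobotState()
    efm = EFMState()

    events: list[dict] = []
    for d in arena.depots:
        events.append(
            {"t": 0.0, "kind": "spawn", "depot_id": d.id, "inducer": d.inducer.value, "x": d.x, "y": d.y}
        )

    n_max = int(math.ceil(cfg.t_max / cfg.dt)) + 1
    tr_t = np.empty(n_max)
    tr_x = np.empty(n_max)
    tr_y = np.empty(n_max)
    tr_efm = np.empty(n_max, dtype=np.int8)
    tr_speed = np.empty(n_max)
    tr_docked = np.empty(n_max, dtype=bool)
    tr_species = np.empty((n_max, N_SPECIES))

    acquired = {Inducer.LACTOSE: 0, Inducer.ARABINOSE: 0}
    dose_inducer: Optional[Inducer] = None
    t_dock = -math.inf
    stochastic = cfg.noise.enabled and (cfg.noise.sigma_tx > 0 or cfg.noise.sigma_tl > 0)

    t = 0.0
    n = 0
    while t < cfg.t_max - 1e-12:
        # (1) dosing source terms, frozen over the step
        q_lac, q_ara = dose_rates(dose_inducer, t, t_dock, cfg.arena)

        # (2) circuit update
        if stochastic:
            y = y + circuits.apply_noise(y, p, cfg.noise, cfg.dt, noise_rng, q_lac, q_ara)
            np.maximum(y, 0.0, out=y)
        else:
            y = integrate_step(y, lambda s: circuits.rhs(np.maximum(s, 0.0), p, q_lac, q_ara), cfg.dt)
            np.maximum(y, 0.0, out=y)
        t += cfg.dt

        # (3) EFM readout
        efm = efm_signal(y[I_GFP], y[I_MCHERRY], cfg.efm, efm.last_sign)

        docked = robot.docked(t)
        speed = 0.0
        if not docked:
            if robot.docked_until is not None:
                robot.docked_until = None  # dosing finished; undock
            # (4) target selection and motion
            target = select_target(efm, arena.depots, (robot.x, robot.y))
            robot.target_id = target.id if target is not None else None
            speed = step_motion(robot, target, efm, cfg.robot, cfg.dt, cfg.arena.half_width)

            # (5) host feedback: one-shot AHL pulse near any depot
            if p.topology.has_lux and ahl_trigger(robot, arena.depots, cfg.robot.r_prox):
                y[I_AHL] += cfg.robot.A_pulse
                events.append(
                    {"t": t, "kind": "ahl_pulse", "depot_id": None, "inducer": None, "x": robot.x, "y": robot.y}
                )
            update_arming(robot, arena.depots, cfg.robot)

            # (6) docking: deplete, dose, respawn, AHL washout
            if target is not None and check_dock(robot, target, cfg.robot.r_dock):
                target.active = False
                acquired[target.inducer] += 1
                robot.docked_until = t + cfg.arena.T_dose
                dose_inducer = target.inducer
                t_dock = t
                # the dosing flush also washes residual AHL out of the
                # chemostat, disengaging any ongoing strike state
                y[I_AHL] = 0.0
                robot.ahl_armed = True
                events.append(
                    {"t": t, "kind": "dock", "depot_id": target.id, "inducer": target.inducer.value, "x": robot.x, "y": robot.y}
                )
                events.append(
                    {"t": t, "kind": "deplete", "depot_id": target.id, "inducer": target.inducer.value, "x": target.x, "y": target.y}
                )
                new = respawn(arena, target)
                if new is not None:
                    events.append(
                        {"t": t, "kind": "spawn", "depot_id": new.id, "inducer": new.inducer.value, "x": new.x, "y": new.y}
                    )
                docked = True

        tr_t[n] = t
        tr_x[n] = robot.x
        tr_y[n] = robot.y
        tr_efm[n] = efm.value
        tr_speed[n] = speed
        tr_docked[n] = docked
        tr_species[n] = y
        n += 1

        if acquired[Inducer.LACTOSE] + acquired[Inducer.ARABINOSE] >= cfg.arena.depot_budget:
            break

    trace = SimTrace(
        t=tr_t[:n],
        x=tr_x[:n],
        y=tr_y[:n],
        efm=tr_efm[:n],
        speed=tr_speed[:n],
        docked=tr_docked[:n],
        species=tr_species[:n],
    )
    total = acquired[Inducer.LACTOSE] + acquired[Inducer.ARABINOSE]
    metrics = {
        "lactose_acquired": acquired[Inducer.LACTOSE],
        "arabinose_acquired": acquired[Inducer.ARABINOSE],
        "stall_fraction": stall_fraction(trace.efm, trace.docked) if n else 0.0,
        "total_steps": n,
        "completed": total >= cfg.arena.depot_budget,
    }
    return SimResult(config=cfg, trace=trace, events=events, metrics=metrics)
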