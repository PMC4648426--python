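"""Motion subroutines of the robotic host.

The host is a point agent whose behavior is entirely slaved to the EFM
signal: the sign picks which inducer depot it seeks, the magnitude
multiplies the base speed (0, 1x or 2x), docking within ``r_dock``
consumes a depot, and -- in the host-feedback topologies -- crossing
within ``r_prox`` of any active depot fires a single AHL pulse into
the onboard microbiome (the "subroutine 6" feedback channel).  The
pulse is one-shot per approach: it re-arms only after the next dock or
after the robot retreats beyond ``r_prox + r_hyst``.
"""

from __future__ import annotations

import math
from dataclasses import dataclass
from typing import Optional

from .environment import Depot, Inducer
from .transduction import EFMState

__all__ = ["RobotParams", "RobotState", "select_target", "step_motion", "check_dock", "ahl_trigger", "update_arming"]


@dataclass
class RobotParams:
    """Motion and feedback constants of the host platform."""

    v_base: float = 0.5    # m/min
    r_dock: float = 0.2    # m
    r_prox: float = 1.5    # m, AHL-injection proximity
    r_hyst: float = 0.5    # m, re-arming hysteresis
    A_pulse: float = 50.0  # a.u. AHL per injection

    def __post_init__(self) -> None:
        for name in ("v_base", "r_dock", "r_prox", "r_hyst", "A_pulse"):
            if getattr(self, name) <= 0:
                raise ValueError(f"RobotParams.{name} must be > 0")
        if self.r_prox <= self.r_dock:
            raise ValueError("r_prox must exceed r_dock")


@dataclass
class RobotState:
    """Pose and discrete mode of the host."""

    x: float = 0.0
    y: float = 0.0
    target_id: Optional[int] = None
    docked_until: Optional[float] = None
    ahl_armed: bool = True

    def docked(self, t: float) -> bool:
        return self.docked_until is not None and t < self.docked_until


def select_target(
    efm: EFMState,
    depots: list[Depot],
    position: tuple[float, float],
) -> Optional[Depot]:
    """Pick the depot the current EFM sign commands the host to seek.

    Positive EFM (GFP-dominant) seeks the nearest active arabinose
    depot, negative (mCherry-dominant) the nearest active lactose
    depot, zero none.  Distance ties break toward the lowest depot id.
    """
    if efm.value == 0:
        return None
    sought = Inducer.ARABINOSE if efm.value > 0 else Inducer.LACTOSE
    candidates = [d for d in depots if d.active and d.inducer == sought]
    if not candidates:
        return None
    x, y = position
    return min(candidates, key=lambda d: (d.distance_to(x, y), d.id))


def step_motion(
    robot: RobotState,
    target: Optional[Depot],
    efm: EFMState,
    params: RobotParams,
    dt: float,
    half_width: float = 10.0,
) -> float:
    """Advance the robot one step toward its target; returns the speed.

    Displacement is ``|EFM| * v_base * dt`` along the straight line to
    the target, clamped so the robot never overshoots the target point
    and never leaves the arena.  With no target or EFM = 0 the robot
    holds position.
    """
    if dt <= 0:
        raise ValueError(f"dt must be > 0, got {dt}")
    if target is None or efm.value == 0:
        return 0.0
    speed = abs(efm.value) * params.v_base
    dx, dy = target.x - robot.x, target.y - robot.y
    dist = math.hypot(dx, dy)
    step = speed * dt
    if dist <= step or dist == 0.0:
        robot.x, robot.y = target.x, target.y
    else:
        robot.x += dx / dist * step
        robot.y += dy / dist * step
    robot.x = min(max(robot.x, -half_width), half_width)
    robot.y = min(max(robot.y, -half_width), half_width)
    return speed


def check_dock(robot: RobotState, depot: Depot, r_dock: float) -> bool:
    """True iff the robot is within docking range (closed boundary)."""
    return depot.active and depot.distance_to(robot.x, robot.y) <= r_dock


def ahl_trigger(robot: RobotState, depots: list[Depot], r_prox: float) -> bool:
    """One-shot AHL-injection decision (subroutine 6).

    Fires (and disarms) the first time an armed robot is within
    ``r_prox`` of any active depot.  The caller adds ``A_pulse`` a.u.
    to the microbiome's AHL pool on a True return.
    """
    if not robot.ahl_armed:
        return False
    if any(d.active and d.distance_to(robot.x, robot.y) <= r_prox for d in depots):
        robot.ahl_armed = False
        return True
    return False


def update_arming(robot: RobotState, depots: list[Depot], params: RobotParams) -> None:
    """Re-arm the AHL injector once the robot has left the depot zone.

    Re-arming happens when the distance to every active depot exceeds
    ``r_prox + r_hyst`` (docking re-arms separately, in the engine).
    """
    if robot.ahl_armed:
        return
    if all(
        d.distance_to(robot.x, robot.y) > params.r_prox + params.r_hyst
        for d in depots
        if d.active
    ):
        robot.ahl_armed = True
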