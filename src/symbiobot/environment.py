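"""The 2-D foraging arena and carbon-depot lifecycle.

The arena is the square [-half_width, +half_width]^2 (20 m x 20 m by
default) with the robot starting at its center.  Carbon depots are
point sources of one inducer (lactose or arabinose).  In
``vertex_cycle`` mode depots sit on the vertices of a 10 m x 10 m
square centered on the origin and respawn one vertex onward around the
cycle; in ``random`` mode positions are drawn uniformly with a minimum
separation.  Docking transfers the depot's inducer into the microbiome
as a constant-rate, time-limited dose and consumes the depot.  A
per-run budget caps the total number of depots ever spawned.
"""

from __future__ import annotations

import math
from dataclasses import dataclass, field
from enum import Enum
from typing import Optional

import numpy as np

__all__ = [
    "Inducer",
    "Depot",
    "ArenaParams",
    "Arena",
    "init_arena",
    "respawn",
    "dose_rates",
]


class Inducer(str, Enum):
    LACTOSE = "lactose"
    ARABINOSE = "arabinose"


class SpawnMode(str, Enum):
    VERTEX_CYCLE = "vertex_cycle"
    RANDOM = "random"


#: Vertices of the 10 m x 10 m depot square, in respawn-cycle order
#: V1 -> V2 -> V3 -> V4 -> V1.
VERTICES = ((5.0, 5.0), (-5.0, 5.0), (-5.0, -5.0), (5.0, -5.0))


@dataclass
class Depot:
    """A stationary point source of one inducer."""

    id: int
    inducer: Inducer
    x: float
    y: float
    active: bool = True

    def distance_to(self, x: float, y: float) -> float:
        return math.hypot(self.x - x, self.y - y)


@dataclass
class ArenaParams:
    """Geometry, spawn policy and dosing constants of the arena."""

    half_width: float = 10.0
    spawn_mode: SpawnMode = SpawnMode.VERTEX_CYCLE
    min_separation: float = 2.0   # random mode only
    q_dose: float = 25.0          # a.u./min delivered while docked
    T_dose: float = 2.0           # min of dosing per dock (bolus 50 a.u.)
    depot_budget: int = 4         # total depots spawned per run

    def __post_init__(self) -> None:
        if isinstance(self.spawn_mode, str) and not isinstance(self.spawn_mode, SpawnMode):
            self.spawn_mode = SpawnMode(self.spawn_mode)
        if self.half_width <= 0:
            raise ValueError("half_width must be > 0")
        if self.q_dose <= 0 or self.T_dose <= 0:
            raise ValueError("dosing constants must be > 0")
        if self.depot_budget < 2:
            raise ValueError("depot_budget must be >= 2 (two initial depots)")


@dataclass
class Arena:
    """Mutable depot set plus spawn bookkeeping for one run."""

    params: ArenaParams
    depots: list[Depot] = field(default_factory=list)
    spawned: int = 0
    rng: Optional[np.random.Generator] = None
    _next_id: int = 0

    def active_depots(self) -> list[Depot]:
        return [d for d in self.depots if d.active]

    def active_of(self, inducer: Inducer) -> list[Depot]:
        return [d for d in self.depots if d.active and d.inducer == inducer]

    def _add(self, inducer: Inducer, x: float, y: float) -> Depot:
        depot = Depot(id=self._next_id, inducer=inducer, x=x, y=y, active=True)
        self._next_id += 1
        self.depots.append(depot)
        self.spawned += 1
        return depot


def _draw_position(arena: Arena) -> tuple[float, float]:
    """Uniform position with rejection against the separation rule."""
    hw = arena.params.half_width
    sep = arena.params.min_separation
    occupied = [(d.x, d.y) for d in arena.active_depots()]
    for _ in range(10_000):
        x, y = arena.rng.uniform(-hw, hw, size=2)
        if all(math.hypot(x - ox, y - oy) >= sep for ox, oy in occupied):
            return float(x), float(y)
    raise RuntimeError("could not place depot with required separation")


def init_arena(params: ArenaParams, seed: Optional[int] = None) -> Arena:
    """Create the arena with one active depot of each inducer.

    Fixed-vertex mode places lactose at V1=(5,5) and arabinose at
    V3=(-5,-5) (the diagonal); random mode draws both positions from
    the seeded stream with the minimum separation enforced.
    """
    arena = Arena(params=params, rng=np.random.default_rng(seed))
    if params.spawn_mode is SpawnMode.VERTEX_CYCLE:
        arena._add(Inducer.LACTOSE, *VERTICES[0])
        arena._add(Inducer.ARABINOSE, *VERTICES[2])
    else:
        arena._add(Inducer.LACTOSE, *_draw_position(arena))
        arena._add(Inducer.ARABINOSE, *_draw_position(arena))
    return arena


def respawn(arena: Arena, depleted: Depot) -> Optional[Depot]:
    """Spawn a replacement depot of the same inducer, budget permitting.

    In vertex mode the replacement appears at the next free vertex
    around the cycle; in random mode at a fresh uniform position.
    Returns the new depot, or ``None`` when the spawn budget is
    exhausted (the run then ends once remaining depots are consumed).
    """
    if depleted.active:
        raise ValueError("can only respawn for a depleted (inactive) depot")
    if arena.spawned >= arena.params.depot_budget:
        return None
    if arena.params.spawn_mode is SpawnMode.VERTEX_CYCLE:
        start = VERTICES.index((depleted.x, depleted.y))
        occupied = {(d.x, d.y) for d in arena.active_depots()}
        for k in range(1, len(VERTICES) + 1):
            vertex = VERTICES[(start + k) % len(VERTICES)]
            if vertex not in occupied:
                return arena._add(depleted.inducer, *vertex)
        raise RuntimeError("no free vertex available")
    return arena._add(depleted.inducer, *_draw_position(arena))


def dose_rates(
    inducer: Optional[Inducer],
    t: float,
    t_dock: float,
    params: ArenaParams,
) -> tuple[float, float]:
    """(q_lac, q_ara) source terms at time ``t`` for a dock at ``t_dock``.

    The depot's inducer enters the microbiome at ``q_dose`` a.u./min
    for ``T_dose`` minutes, a total bolus of ``q_dose * T_dose`` a.u.
    """
    if inducer is None or not (t_dock <= t < t_dock + params.T_dose):
        return 0.0, 0.0
    if inducer == Inducer.LACTOSE:
        return params.q_dose, 0.0
    return 0.0, params.q_dose
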