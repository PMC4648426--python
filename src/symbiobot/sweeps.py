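"""Parameter sweeps and behavioral-regime classification.

Two drivers: a 2-D sweep over the toggle RBS strengths (which biases
the switch and shifts the host between depot-alternation, preference
and stalling behavior) and a 1-D walk over the cI RBS strength in the
auto-repressing feedback topology, which moves the host through four
qualitatively distinct regimes: stalk-pause-strike predation, the
interrupted strike, permanent stall, and plain bistable toggling.

The classifier operationalizes those regimes from the run record: a
capped run with zero acquisitions is a permanent stall; a run whose
EFM never reaches magnitude 2 is plain toggling; otherwise each depot
approach's run-length-collapsed |EFM| sequence is matched against the
stalk(1)-pause(0)-strike(2) and strike-interrupted (...2-0-1) motifs
and the majority label wins.
"""

from __future__ import annotations

import dataclasses
from dataclasses import dataclass, replace
from enum import Enum
from typing import Optional, Sequence

import numpy as np
import pandas as pd

from .circuits import Topology
from .engine import SimConfig, SimResult, run_simulation

__all__ = [
    "Regime",
    "SweepResult",
    "classify_regime",
    "collapse_runs",
    "sweep_rbs",
    "walk_rbscI",
    "default_walk_values",
]


class Regime(str, Enum):
    BISTABLE_TOGGLE = "BISTABLE_TOGGLE"
    STALK_PAUSE_STRIKE = "STALK_PAUSE_STRIKE"
    STRIKE_INTERRUPTED = "STRIKE_INTERRUPTED"
    PERMANENT_STALL = "PERMANENT_STALL"


@dataclass
class SweepResult:
    """Per-cell metrics table of a parameter sweep."""

    table: pd.DataFrame
    axes: dict

    @property
    def regimes(self) -> list[Optional[Regime]]:
        return [None if pd.isna(r) else Regime(r) for r in self.table["regime"]]


def collapse_runs(values: Sequence[int]) -> list[int]:
    """Run-length collapse: [1,1,0,0,2,2,2] -> [1,0,2]."""
    out: list[int] = []
    for v in values:
        if not out or out[-1] != v:
            out.append(int(v))
    return out


def _approach_segments(result: SimResult) -> list[np.ndarray]:
    """|EFM| per undocked stretch that ends in a dock."""
    docked = result.trace.docked
    efm = np.abs(result.trace.efm)
    segments: list[np.ndarray] = []
    start = 0
    for i in range(len(docked)):
        if docked[i] and (i == 0 or not docked[i - 1]):
            # step i is the docking step itself (motion then dock);
            # include it in the approach
            segments.append(efm[start : i + 1])
        if docked[i] and (i + 1 == len(docked) or not docked[i + 1]):
            start = i + 1
    return [s for s in segments if s.size]


def _label_approach(seq: list[int]) -> Optional[Regime]:
    if 2 not in seq:
        return None
    if len(seq) >= 3 and seq[-3:] == [1, 0, 2]:
        return Regime.STALK_PAUSE_STRIKE
    if len(seq) >= 3 and seq[-3:] == [2, 0, 1]:
        return Regime.STRIKE_INTERRUPTED
    # degenerate motifs: fall back on how the approach ended
    return Regime.STALK_PAUSE_STRIKE if seq[-1] == 2 else Regime.STRIKE_INTERRUPTED


def classify_regime(result: SimResult) -> Regime:
    """Assign one behavioral regime label to a completed or capped run."""
    if len(result.trace) == 0:
        raise ValueError("cannot classify an empty trace")
    m = result.metrics
    if m["lactose_acquired"] + m["arabinose_acquired"] == 0:
        return Regime.PERMANENT_STALL
    if not np.any(np.abs(result.trace.efm) == 2):
        return Regime.BISTABLE_TOGGLE
    labels = [
        lab
        for seg in _approach_segments(result)
        if (lab := _label_approach(collapse_runs(seg))) is not None
    ]
    if not labels:
        return Regime.STRIKE_INTERRUPTED
    n_sps = labels.count(Regime.STALK_PAUSE_STRIKE)
    n_int = labels.count(Regime.STRIKE_INTERRUPTED)
    if n_sps > n_int:
        return Regime.STALK_PAUSE_STRIKE
    return Regime.STRIKE_INTERRUPTED  # majority or tie


_METRIC_COLS = ("lactose_acquired", "arabinose_acquired", "stall_fraction", "total_steps", "completed")


def _run_cell(cfg: SimConfig) -> tuple[dict, Optional[str]]:
    try:
        result = run_simulation(cfg)
        row = {k: result.metrics[k] for k in _METRIC_COLS}
        row["regime"] = classify_regime(result).value
        return row, None
    except Exception as exc:  # per-cell failures must not kill the sweep
        row = {k: np.nan for k in _METRIC_COLS}
        row["regime"] = np.nan
        return row, f"{type(exc).__name__}: {exc}"


def sweep_rbs(
    rbs_lacI_values: Sequence[float],
    rbs_tetR_values: Sequence[float],
    base_cfg: Optional[SimConfig] = None,
) -> SweepResult:
    """Full-factorial sweep of the toggle RBS strengths.

    One complete simulation per grid cell, TOGGLE topology, all other
    parameters from ``base_cfg``.
    """
    base_cfg = base_cfg if base_cfg is not None else SimConfig()
    rows = []
    for rl in rbs_lacI_values:
        for rt in rbs_tetR_values:
            cfg = replace(
                base_cfg,
                circuit=base_cfg.circuit.replace(topology=Topology.TOGGLE, rbs_lacI=rl, rbs_tetR=rt),
            )
            row, err = _run_cell(cfg)
            rows.append({"rbs_lacI": rl, "rbs_tetR": rt, **row, "error": err})
    return SweepResult(
        table=pd.DataFrame(rows),
        axes={"rbs_lacI": list(rbs_lacI_values), "rbs_tetR": list(rbs_tetR_values)},
    )


def default_walk_values(n_log: int = 24, lo: float = 1e-3, hi: float = 0.9) -> np.ndarray:
    """Reference rbs_cI walk: {0} + log-spaced interior + {1}."""
    return np.concatenate([[0.0], np.geomspace(lo, hi, n_log), [1.0]])


def walk_rbscI(
    values: Sequence[float],
    base_cfg: Optional[SimConfig] = None,
) -> SweepResult:
    """1-D walk over the cI RBS strength (auto-repressing feedback).

    One run per value in the TOGGLE_LUX_CI topology; each run is
    classified into a behavioral regime.
    """
    base_cfg = base_cfg if base_cfg is not None else SimConfig()
    rows = []
    for v in values:
        cfg = replace(
            base_cfg,
            circuit=base_cfg.circuit.replace(topology=Topology.TOGGLE_LUX_CI, rbs_cI=v),
        )
        row, err = _run_cell(cfg)
        rows.append({"rbs_cI": v, **row, "error": err})
    return SweepResult(table=pd.DataFrame(rows), axes={"rbs_cI": list(values)})
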