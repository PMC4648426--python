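"""Serialization of simulation outputs.

Every run writes a self-describing output directory: the per-step
trajectory as CSV (full float precision, lossless round-trip), the
discrete event log as JSONL, summary metrics as JSON (with a config
digest), and the fully-resolved config as TOML.
"""

from __future__ import annotations

import json
from pathlib import Path

import numpy as np
import pandas as pd

from .circuits import SPECIES
from .config import config_hash, dump_config_toml
from .engine import SimResult

__all__ = ["trajectory_frame", "write_outputs", "read_trajectory"]

TRAJECTORY_COLUMNS = ("t", "x", "y", "efm", "speed", *SPECIES)


def trajectory_frame(result: SimResult) -> pd.DataFrame:
    """Per-step trajectory as a DataFrame (one row per time step)."""
    tr = result.trace
    data = {"t": tr.t, "x": tr.x, "y": tr.y, "efm": tr.efm.astype(int), "speed": tr.speed}
    for i, name in enumerate(SPECIES):
        data[name] = tr.species[:, i]
    return pd.DataFrame(data, columns=list(TRAJECTORY_COLUMNS))


def write_outputs(result: SimResult, outdir: str | Path) -> dict[str, Path]:
    """Write trajectory CSV, events JSONL, metrics JSON and config TOML.

    Filenames are fixed; returns a name -> path mapping.
    """
    outdir = Path(outdir)
    outdir.mkdir(parents=True, exist_ok=True)
    paths = {
        "trajectory": outdir / "trajectory.csv",
        "events": outdir / "events.jsonl",
        "metrics": outdir / "metrics.json",
        "config": outdir / "config.toml",
    }

    # %.17g guarantees binary64 round-trip through text
    trajectory_frame(result).to_csv(paths["trajectory"], index=False, float_format="%.17g")

    with open(paths["events"], "w") as fh:
        for ev in result.events:
            fh.write(json.dumps(ev) + "\n")

    metrics = dict(result.metrics)
    metrics["wall_config_hash"] = config_hash(result.config)
    with open(paths["metrics"], "w") as fh:
        json.dump(metrics, fh, indent=2)
        fh.write("\n")

    paths["config"].write_text(dump_config_toml(result.config))
    return paths


def read_trajectory(path: str | Path) -> pd.DataFrame:
    """Read back a trajectory CSV written by :func:`write_outputs`."""
    df = pd.read_csv(path, float_precision="round_trip")
    missing = set(TRAJECTORY_COLUMNS) - set(df.columns)
    if missing:
        raise ValueError(f"trajectory file {path} is missing columns {sorted(missing)}")
    # constant columns parse as int; restore the schema dtypes
    return df.astype({c: (int if c == "efm" else float) for c in TRAJECTORY_COLUMNS})
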