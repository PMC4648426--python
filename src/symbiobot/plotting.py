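"""Figure rendering for runs and sweeps (cosmetic; smoke-tested only)."""

from __future__ import annotations

from pathlib import Path
from typing import Optional

import matplotlib

matplotlib.use("Agg")
import matplotlib.pyplot as plt
import numpy as np

from .circuits import SPECIES
from .engine import SimResult
from .sweeps import SweepResult

__all__ = ["plot_arena", "plot_timeseries", "plot_heatmaps", "save_run_figures"]

_DEPOT_STYLE = {"lactose": dict(marker="^", color="tab:cyan"), "arabinose": dict(marker="s", color="tab:orange")}


def plot_arena(result: SimResult, ax: Optional[plt.Axes] = None) -> plt.Axes:
    """Robot path in the arena with depot and dock markers."""
    if ax is None:
        _, ax = plt.subplots(figsize=(5, 5))
    hw = result.config.arena.half_width
    tr = result.trace
    ax.plot(tr.x, tr.y, lw=0.8, color="0.3", label="path")
    for ev in result.events:
        if ev["kind"] == "spawn":
            ax.scatter([ev["x"]], [ev["y"]], s=60, **_DEPOT_STYLE[ev["inducer"]])
        elif ev["kind"] == "dock":
            ax.scatter([ev["x"]], [ev["y"]], s=120, facecolors="none", edgecolors="tab:red")
    ax.set(xlim=(-hw, hw), ylim=(-hw, hw), xlabel="x (m)", ylabel="y (m)", aspect="equal")
    return ax


def plot_timeseries(result: SimResult) -> plt.Figure:
    """Reporters, inducers/AHL, and EFM trace stacked over time."""
    tr = result.trace
    fig, axes = plt.subplots(3, 1, sharex=True, figsize=(8, 6))
    sp = {name: tr.species[:, i] for i, name in enumerate(SPECIES)}
    axes[0].plot(tr.t, sp["GFP"], color="tab:green", label="GFP")
    axes[0].plot(tr.t, sp["mCherry"], color="tab:red", label="mCherry")
    axes[0].set_ylabel("reporter (a.u.)")
    axes[0].legend(loc="upper right", fontsize=8)
    axes[1].plot(tr.t, sp["lac_int"], color="tab:cyan", label="lactose")
    axes[1].plot(tr.t, sp["ara_int"], color="tab:orange", label="arabinose")
    axes[1].plot(tr.t, sp["AHL"], color="gold", label="AHL")
    axes[1].set_ylabel("inducer (a.u.)")
    axes[1].legend(loc="upper right", fontsize=8)
    axes[2].step(tr.t, tr.efm, where="post", color="0.2")
    axes[2].set(ylabel="EFM", xlabel="t (min)", yticks=[-2, -1, 0, 1, 2])
    fig.tight_layout()
    return fig


def plot_heatmaps(sweep: SweepResult) -> plt.Figure:
    """Metric surfaces of an RBS grid sweep."""
    tab = sweep.table
    xs = sorted(tab["rbs_tetR"].unique())
    ys = sorted(tab["rbs_lacI"].unique())
    metrics = ["lactose_acquired", "arabinose_acquired", "stall_fraction", "total_steps"]
    fig, axes = plt.subplots(2, 2, figsize=(9, 8))
    for ax, metric in zip(axes.ravel(), metrics):
        grid = np.full((len(ys), len(xs)), np.nan)
        for _, row in tab.iterrows():
            grid[ys.index(row["rbs_lacI"]), xs.index(row["rbs_tetR"])] = row[metric]
        im = ax.imshow(grid, origin="lower", aspect="auto",
                       extent=(min(xs), max(xs), min(ys), max(ys)))
        ax.set(title=metric, xlabel="rbs_tetR", ylabel="rbs_lacI")
        fig.colorbar(im, ax=ax)
    fig.tight_layout()
    return fig


def save_run_figures(result: SimResult, outdir: str | Path) -> list[Path]:
    """Render and save the standard per-run figures."""
    outdir = Path(outdir)
    outdir.mkdir(parents=True, exist_ok=True)
    paths = []
    fig, ax = plt.subplots(figsize=(5, 5))
    plot_arena(result, ax)
    p = outdir / "arena.png"
    fig.savefig(p, dpi=120)
    plt.close(fig)
    paths.append(p)
    fig = plot_timeseries(result)
    p = outdir / "timeseries.png"
    fig.savefig(p, dpi=120)
    plt.close(fig)
    paths.append(p)
    return paths
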