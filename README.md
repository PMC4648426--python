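# symbiobot

A hybrid continuous/discrete simulator of a **robotic host driven by an
engineered, living microbiome**.  Synthetic gene circuits — variants of
the LacI/TetR genetic toggle switch — run as ODEs (optionally
chemical-Langevin SDEs) in a well-mixed, chemostat-like bacterial
compartment carried on board a point robot.  The circuit's fluorescent
readout (GFP vs mCherry) is discretized by a model of the onboard
epifluorescence-microscope electronics into an integer **EFM signal**
in {−2, −1, 0, +1, +2}, which is the robot's only control input: the
sign selects which inducer depot it seeks (GFP → arabinose, mCherry →
lactose), the magnitude multiplies its base speed, and 0 is a stall.
Docking at a depot doses that inducer back into the culture and flips
the toggle; in the feedback topologies the robot additionally injects
the quorum-sensing autoinducer AHL when it nears a depot, activating an
orthogonal P<sub>lux-λ</sub> operon and closing a host → microbiome
information loop.

The package is for researchers studying host–microbiome interaction
models, synthetic-biology circuit behavior embedded in closed
sensorimotor loops, and hybrid dynamical systems: it reproduces, from a
single TOML configuration, the emergent behavioral regimes of such a
system — balanced foraging alternation, biased nutrient preference,
stalk-pause-strike "predation", and permanent stall — and maps them
over circuit parameter space.

## Model

For the toggle (two-stage expression, arbitrary units, minutes):

```
dm_tetR/dt = α · 1/(1 + (LacI*/K)^n) − δ_m · m_tetR      LacI* = LacI/(1+(lac/K_lac)^η)
dm_lacI/dt = α · 1/(1 + (TetR*/K)^n) − δ_m · m_lacI      TetR* = TetR/(1+(ara/K_ara)^η)
dP/dt      = k_tl · rbs_P · m_operon − δ_p · P           P ∈ {LacI, TetR, GFP, mCherry}
```

GFP is co-translated from the *tetR* transcript and mCherry from the
*lacI* transcript (polycistronic operons), so the dominant side of the
toggle is visible as a color.  The feedback operon transcribes at
`lux_gain · α · (AHL/K_ahl)^n/(1+(AHL/K_ahl)^n)`, drives both reporters
(and, in the auto-repressing variant, the λ repressor cI, which
multiplies the operon's activity by `1/(1+(cI/K_cI)^n_cI)`).
Stochastic runs perturb every transcription flux by
`(1 + σ_tx·ξ/√dt)` and every translation flux by `(1 + σ_tl·ξ′/√dt)`
(Euler–Maruyama); deterministic runs use a fixed-step fifth-order
Dormand–Prince update.  Dosing, AHL pulses and dock/respawn events are
applied at step boundaries.

## Worked example

```
$ symbiobot simulate --outdir out/balanced --no-plot
{"lactose_acquired": 2, "arabinose_acquired": 2, "stall_fraction": 12.045889101338432, "total_steps": 11506, "completed": true}
outputs in out/balanced
```

The balanced toggle (equal RBS strengths) makes the host alternate:
the initial arabinose injection silences TetR, so mCherry dominates
and the robot seeks lactose; each captured depot doses the opposite
inducer and flips the switch.  The run completes all four depots
(2 lactose + 2 arabinose, docks at t ≈ 15.8, 51.5, 78.8, 115.1 min,
strictly alternating), spending ≈ 12 % of steps with EFM = 0 (the
brief "pauses" while the toggle transits its flip).  The output
directory holds the per-step trajectory (`trajectory.csv`), the
dock/spawn/deplete/AHL event log (`events.jsonl`), summary metrics
(`metrics.json`) and the fully-resolved configuration (`config.toml`).

Other entry points:

```
symbiobot simulate --topology TOGGLE_LUX        # stalk-pause-strike predation
symbiobot simulate --set circuit.rbs_lacI=0.72 --set circuit.rbs_tetR=0.3
                                                # biased toggle: lactose preference
symbiobot sweep  --outdir out/sweep             # RBS grid, metric heatmaps
symbiobot walk   --outdir out/walk              # rbs_cI walk + regime labels
```

The same functionality is available as a library
(`symbiobot.run_simulation`, `symbiobot.sweep_rbs`,
`symbiobot.walk_rbscI`); see `examples/reference.toml` for every
parameter and its reference value, and `docs/methods.md` for the model
details and calibration rationale.

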