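# Methods

## Scope and structure

symbiobot couples four submodels in a fixed-step co-simulation loop
(`engine.run_simulation`): gene-circuit kinetics (`circuits`),
reporter-to-EFM transduction (`transduction`), robot motion
subroutines (`robot`), and the arena/depot lifecycle (`environment`).
Each step: dosing sources are frozen, the circuit is advanced over
`dt`, the EFM is read from the new reporter levels, the robot selects
a target and moves (unless docked), AHL proximity and docking are
checked, and dock events deplete/respawn depots.  Discrete events act
only at step boundaries so the ODE right-hand side is smooth within a
step.

## Circuit model and assumptions

The microbiome is a single well-mixed compartment in exponential
phase (a chemostat), so concentrations are deterministic ODE variables
in arbitrary units; there is no cell-to-cell heterogeneity, growth
coupling, or resource competition.  Expression is two-stage (mRNA,
then protein) because the model must distinguish transcriptional from
translational noise and must expose ribosome-binding-site strength as
a translation-rate multiplier in [0, 1].  Repression and activation
are Hill functions; inducers (lactose, arabinose) act by sequestering
their cognate repressor (`R/(1+(I/K_I)^η)`), treating the two inducer
arms symmetrically.  Reporters are co-translated from their operon's
transcript (polycistronic), so a reporter RBS scales output without
feeding back on the switch.

Reference parameters (full list in `examples/reference.toml`):
`alpha_tx = 10 a.u./min`, `K_rep = 1`, `n_rep = 2`, `k_tl = 1/min`,
`delta_m = 1/min`, `delta_p = 0.3/min`, balanced RBS strengths 0.5,
`K_lac = K_ara = 10`, `eta_ind = 2`, `delta_ind = 0.05/min`,
`K_ahl = 10`, `n_ahl = 2`, `delta_ahl = 0.001/min`, `K_cI = 1`,
`n_cI = 2`, `delta_cI = 0.3/min`, `lux_gain = 6`.  These were
calibrated once, jointly with the EFM thresholds and robot constants,
so that the system's time scales nest correctly, and then frozen:

* **Toggle amplitude and flip time.**  The dominant side settles at
  mRNA ≈ α/δ_m = 10 and reporter ≈ k_tl·rbs·m/δ_p ≈ 16.7 a.u.  With
  `delta_p = 0.3` (deg-tagged proteins, ≈ 2.3 min half-life) a 50 a.u.
  inducer bolus flips the switch in ≈ 5–10 min, well inside the
  ≈ 15–30 min travel time between depots, which is what makes the
  foraging alternation clean.  A slower `delta_p` leaves the robot
  heading to the wrong depot for most of a leg.
* **Feedback operon strength.**  The strike state requires *both*
  reporters above the co-expression threshold while the toggle holds
  one side near 16.7; the lux operon therefore needs substantially
  more output than a toggle operon.  `lux_gain = 6` puts the
  AHL-saturated lux reporter contribution at ≈ 96 a.u., cleanly above
  the strike threshold.
* **EFM thresholds** (`theta_on = 2`, `rho_dom = 2`,
  `theta_both = 40`): the detection floor sits far below the 16.7
  a.u. steady reporter; the dominance ratio 2 gives short, symmetric
  pauses during toggle flips; the co-expression threshold 40 lies
  above the transient co-expression reached mid-flip (≈ 12 a.u. peak
  on the weak channel) and below the lux output, so |EFM| = 2 is
  reachable only through host feedback.  This separation is asserted
  by test, over a grid of toggle steady states.
* **AHL lifetime and washout.**  AHL decays slowly
  (`delta_ahl = 0.001/min`) so that a pulse outlives a frozen
  approach — that persistence is what makes the permanent-stall
  regime permanent.  Docking, however, flushes the chemostat with the
  depot dose, and the same flush removes extracellular AHL (modeled
  as AHL := 0 at the dock event).  Without the washout the decaying
  lux output holds the EFM at ±2 with a stale sign through the next
  leg and the host docks the same inducer twice.
* **Robot constants.**  `v_base = 0.5 m/min` makes a center-to-vertex
  leg ≈ 14 min, commensurate with the flip time; `r_prox = 1.5 m`
  gives the lux operon the ≈ 2–3 min it needs to ramp through the
  pause into the strike before the depot is reached; `r_dock = 0.2 m`,
  `r_hyst = 0.5 m`, `A_pulse = 50 a.u.`
* **Dosing** delivers 25 a.u./min for 2 min (a 50 a.u. bolus matching
  the t = 0 arabinose initial condition, which is implemented as
  `ara_int(0) = 50`, not as a timed dose).

## Transduction

All optics and electronics collapse into one pure map
(GFP, mCherry, memory) → {−2…2}, evaluated in order: dark floor,
co-expression strike (sign inherited from the last committed
direction — a one-bit memory, so a strike continues toward the
already-chosen depot), ratio dominance (+1 GFP / −1 mCherry), else
pause.  Ratio-based dominance (not absolute difference) is essential:
AHL-driven equal co-expression must collapse dominance regardless of
the toggle's amplitude, which is what produces the pause of the
stalk-pause-strike pattern.

## Stochastic mode

Noise is chemical-Langevin-style and multiplicative: each
transcription flux is scaled by `1 + σ_tx·ξ/√dt` and each translation
flux by `1 + σ_tl·ξ′/√dt` (independent standard normals per species
per step), integrated with Euler–Maruyama and clipped at zero.  This
represents bursty synthesis in a continuous framework; it is not a
Gillespie simulation and carries no molecule-number scale.  At
σ_tx = 0.1 the integrated reporter fluctuations are a few percent —
far from the factor-2 dominance band except during flips — so the
bistable foraging outcome is highly robust (25/25 replicates), while
the measured stall-fraction change is within Monte-Carlo error of
zero.  Conclusions about noise in real hardware should not be drawn
from the σ-scale of this model.

## Numerics

Deterministic integration is a fixed-step, fifth-order Dormand–Prince
update (the 5th-order weights of the RK45 pair; six stage evaluations
per step) at `dt = 0.01 min`.  There is no adaptive control: events
are aligned to the grid, and accuracy is verified instead by closed
form (e^(−1) to ~1e−14), by an independent classical RK4 oracle on
the toggle (agreement to ~1e−13 relative over 50 min), and by
dt-halving (state at t = 10 stable to ~1e−13 relative).  States are
clipped at zero before each right-hand-side evaluation; in
deterministic runs the clip is inactive in practice.  Runs terminate
at four acquired depots or at `t_max = 500 min` — the cap exists so
that stalled runs (which otherwise never end) are well defined.  One
master seed feeds separate child streams (numpy `SeedSequence`) for
depot placement and expression noise; runs are bitwise reproducible.

## Regime classification

`sweeps.classify_regime` operationalizes the behavioral regimes from
the run record: zero acquisitions by the cap → permanent stall; no
|EFM| = 2 anywhere → bistable toggling; otherwise each depot
approach's run-length-collapsed |EFM| sequence is matched on its
suffix — `…1,0,2,dock` → stalk-pause-strike, `…2,0,1,dock` →
interrupted strike — with the majority label deciding mixed runs and
ties going to the interrupted label.

Under the reference dynamics the rbs_cI walk produces three of the
four regimes, in the order stalk-pause-strike (rbs_cI ≲ 0.015) →
permanent stall (≈ 0.016–0.065) → bistable toggling (≳ 0.08).  The
interrupted-strike regime is a known limitation of this model class:
within one approach it requires the lux output to first exceed the
strike threshold (weak cI repression) and then fall below the
dominance-collapse level (strong cI repression).  The cI
auto-repression loop here is a two-variable smooth system with
strictly negative trace, so its output settles monotonically to a
steady level that decreases monotonically with rbs_cI; consequently
the "resume and dock" band can only sit above the stall band, and in
that band the transient peak never reaches the strike threshold.
Producing an interrupted band *below* the stall band would require an
oscillatory or discrete element (e.g., a delayed or multi-stage cI
pathway) that is deliberately out of scope.  The classifier itself
recognizes all four labels and is exercised on constructed traces.

## What the simulations do and do not show

All inputs are generated by the simulator itself; there is no external
data.  The depots, dosing and optics are idealized (point depots, no
inducer diffusion or gradients, no detector noise, no fluorophore
maturation), the robot is a point with perfect heading and quantized
speed, and all units are arbitrary.  Passing tests therefore
demonstrate the *qualitative* claims — bistable behavioral memory and
its parameter dependence, feedback-induced predation patterns, regime
bifurcations under RBS variation — not calibrated predictions for any
physical robot or strain.
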