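"""Gene-circuit kinetics of the engineered microbiome.

The microbiome is modeled as a single well-mixed chemostat compartment
(exponential-phase culture) carrying one of four synthetic circuit
topologies built around the LacI/TetR mutual-repression toggle switch:

* ``LAC_REPORTER`` -- a single lactose-inducible operon expressing GFP;
  the minimal proof-of-signal circuit.
* ``TOGGLE`` -- the balanced/biased toggle: LacI represses the *tetR*
  operon and TetR represses the *lacI* operon.  GFP is co-translated
  from the *tetR* transcript, mCherry from the *lacI* transcript, so
  the dominant repressor side is read out as a fluorescent color.
  Lactose sequesters LacI, arabinose sequesters TetR, so a transient
  inducer bolus flips the stored state.
* ``TOGGLE_LUX`` -- adds an orthogonal, AHL-activated P_lux-lambda
  operon expressing GFP and mCherry polycistronically, the channel by
  which the robotic host feeds information back into the microbiome.
* ``TOGGLE_LUX_CI`` -- the P_lux-lambda operon additionally expresses
  the lambda repressor cI, which represses its own promoter, making
  the feedback operon auto-repressing and tunable via the cI ribosome
  binding site strength.

Gene expression is two-stage (mRNA then protein) so that transcription
and translation can carry distinct stochastic noise and so that RBS
strengths act where they do biologically: on translation.  All
concentrations are arbitrary units (a.u.), time is minutes.
"""

from __future__ import annotations

import math
from dataclasses import dataclass, field, fields, replace
from enum import Enum

import numpy as np

__all__ = [
    "Topology",
    "SPECIES",
    "CircuitState",
    "CircuitParams",
    "NoiseParams",
    "hill_repression",
    "hill_activation",
    "active_repressor",
    "derivatives",
    "rhs",
    "rhs_terms",
    "apply_noise",
]


class Topology(str, Enum):
    """Selectable circuit topology of the engineered microbiome."""

    LAC_REPORTER = "LAC_REPORTER"
    TOGGLE = "TOGGLE"
    TOGGLE_LUX = "TOGGLE_LUX"
    TOGGLE_LUX_CI = "TOGGLE_LUX_CI"

    @property
    def has_lux(self) -> bool:
        return self in (Topology.TOGGLE_LUX, Topology.TOGGLE_LUX_CI)

    @property
    def has_cI(self) -> bool:
        return self is Topology.TOGGLE_LUX_CI


#: Ordered species names; index into the state vector.
SPECIES = (
    "m_lacI", "m_tetR", "m_cI",
    "LacI", "TetR", "cI",
    "GFP", "mCherry",
    "lac_int", "ara_int", "AHL",
)

I_M_LACI, I_M_TETR, I_M_CI = 0, 1, 2
I_LACI, I_TETR, I_CI = 3, 4, 5
I_GFP, I_MCHERRY = 6, 7
I_LAC, I_ARA, I_AHL = 8, 9, 10

N_SPECIES = len(SPECIES)


@dataclass
class CircuitState:
    """Molecular state of the microbiome (all concentrations in a.u.).

    ``m_*`` are transcripts; ``LacI``/``TetR``/``cI`` repressor
    proteins; ``GFP``/``mCherry`` fluorescent reporters; ``lac_int`` /
    ``ara_int`` internal inducer pools; ``AHL`` the quorum-sensing
    autoinducer injected by the host.
    """

    m_lacI: float = 0.0
    m_tetR: float = 0.0
    m_cI: float = 0.0
    LacI: float = 0.0
    TetR: float = 0.0
    cI: float = 0.0
    GFP: float = 0.0
    mCherry: float = 0.0
    lac_int: float = 0.0
    ara_int: float = 0.0
    AHL: float = 0.0

    def to_array(self) -> np.ndarray:
        return np.array([getattr(self, name) for name in SPECIES], dtype=float)

    @classmethod
    def from_array(cls, y: np.ndarray) -> "CircuitState":
        if len(y) != N_SPECIES:
            raise ValueError(f"state vector must have {N_SPECIES} entries, got {len(y)}")
        return cls(**{name: float(y[i]) for i, name in enumerate(SPECIES)})

    def validate(self) -> None:
        for name in SPECIES:
            v = getattr(self, name)
            if not math.isfinite(v) or v < 0:
                raise ValueError(f"CircuitState.{name} must be finite and >= 0, got {v}")


@dataclass
class CircuitParams:
    """Kinetic constants of the engineered circuits.

    The defaults are the package's reference parameter set: a single
    calibration, stored here and in the default config, under which the
    toggle is robustly bistable, an inducer bolus of 50 a.u. flips it
    within a few protein lifetimes, and the AHL-driven lux operon
    out-expresses the toggle reporters (``lux_gain``) so host feedback
    can override the stored color.  Units: rates 1/min, synthesis
    a.u./min, half-constants a.u., Hill coefficients dimensionless,
    RBS strengths relative in [0, 1].
    """

    topology: Topology = Topology.TOGGLE
    alpha_tx: float = 10.0     # max transcription rate
    K_rep: float = 1.0         # repression half-constant
    n_rep: float = 2.0
    k_tl: float = 1.0          # translation rate per unit RBS
    rbs_lacI: float = 0.5
    rbs_tetR: float = 0.5
    rbs_gfp: float = 0.5
    rbs_mcherry: float = 0.5
    rbs_cI: float = 0.5
    delta_m: float = 1.0       # mRNA decay
    delta_p: float = 0.3       # protein decay (deg-tagged, fast readout)
    K_lac: float = 10.0
    K_ara: float = 10.0
    eta_ind: float = 2.0
    delta_ind: float = 0.05
    K_ahl: float = 10.0
    n_ahl: float = 2.0
    delta_ahl: float = 0.001   # AHL is long-lived between dock washouts
    K_cI: float = 1.0
    n_cI: float = 2.0
    delta_cI: float = 0.3      # cI protein decay (separate knob from the reporters)
    lux_gain: float = 6.0      # P_lux-lambda strength relative to alpha_tx

    def __post_init__(self) -> None:
        if isinstance(self.topology, str) and not isinstance(self.topology, Topology):
            self.topology = Topology(self.topology)
        self.validate()

    def validate(self) -> None:
        positive = (
            "alpha_tx", "K_rep", "k_tl", "delta_m", "delta_p",
            "K_lac", "K_ara", "delta_ind", "K_ahl", "delta_ahl",
            "K_cI", "delta_cI", "lux_gain",
        )
        for name in positive:
            v = getattr(self, name)
            if not (v > 0) or not math.isfinite(v):
                raise ValueError(f"CircuitParams.{name} must be > 0, got {v}")
        for name in ("n_rep", "eta_ind", "n_ahl", "n_cI"):
            v = getattr(self, name)
            if not (v >= 1):
                raise ValueError(f"CircuitParams.{name} must be >= 1, got {v}")
        for name in ("rbs_lacI", "rbs_tetR", "rbs_gfp", "rbs_mcherry", "rbs_cI"):
            v = getattr(self, name)
            if not (0.0 <= v <= 1.0):
                raise ValueError(f"CircuitParams.{name} must lie in [0, 1], got {v}")

    def replace(self, **kw) -> "CircuitParams":
        return replace(self, **kw)


@dataclass
class NoiseParams:
    """Multiplicative chemical-Langevin noise on gene expression.

    ``sigma_tx`` scales white noise on every transcription (mRNA
    synthesis) term, ``sigma_tl`` on every translation (protein
    synthesis) term; decay and transport terms stay deterministic.
    """

    sigma_tx: float = 0.0
    sigma_tl: float = 0.0
    enabled: bool = False

    def __post_init__(self) -> None:
        if self.sigma_tx < 0 or self.sigma_tl < 0:
            raise ValueError("noise magnitudes must be >= 0")


def _check_hill(K: float, n: float) -> None:
    if not (K > 0):
        raise ValueError(f"Hill half-constant must be > 0, got {K}")
    if not (n >= 1):
        raise ValueError(f"Hill coefficient must be >= 1, got {n}")


def hill_repression(R_active: float, K: float, n: float) -> float:
    """Fractional promoter activity under repression: ``1/(1+(R/K)^n)``."""
    _check_hill(K, n)
    if R_active < 0:
        raise ValueError(f"repressor concentration must be >= 0, got {R_active}")
    return 1.0 / (1.0 + (R_active / K) ** n)


def hill_activation(A: float, K: float, n: float) -> float:
    """Fractional promoter activity under activation: ``(A/K)^n/(1+(A/K)^n)``."""
    _check_hill(K, n)
    if A < 0:
        raise ValueError(f"activator concentration must be >= 0, got {A}")
    x = (A / K) ** n
    return x / (1.0 + x)


def active_repressor(R_total: float, I: float, K_I: float, eta: float) -> float:
    """Repressor remaining active after inducer sequestration.

    ``R_total / (1 + (I/K_I)^eta)``: the inducer binds its cognate
    repressor and removes it from the operator-competent pool.
    """
    if K_I <= 0:
        raise ValueError(f"inducer half-constant must be > 0, got {K_I}")
    if R_total < 0 or I < 0:
        raise ValueError("concentrations must be >= 0")
    return R_total / (1.0 + (I / K_I) ** eta)


def rhs_terms(
    y: np.ndarray,
    p: CircuitParams,
    q_lac: float = 0.0,
    q_ara: float = 0.0,
) -> tuple[np.ndarray, np.ndarray, np.ndarray]:
    """Decomposed right-hand side: (transcription, translation, other).

    The full derivative is the elementwise sum of the three vectors.
    The decomposition exists so that the stochastic integrator can
    perturb transcription and translation fluxes independently.
    ``q_lac``/``q_ara`` are external dosing source terms (a.u./min)
    delivered while the robot is docked at a depot.
    """
    tx = np.zeros(N_SPECIES)
    tl = np.zeros(N_SPECIES)
    other = np.zeros(N_SPECIES)
    topo = p.topology

    if topo is Topology.LAC_REPORTER:
        # One-operon lactose -> GFP circuit; the single P_lac transcript
        # occupies the m_tetR slot (there is no TetR protein here).
        tx[I_M_TETR] = p.alpha_tx * hill_activation(y[I_LAC], p.K_lac, p.eta_ind)
        tl[I_GFP] = p.k_tl * p.rbs_gfp * y[I_M_TETR]
        other[I_M_TETR] = -p.delta_m * y[I_M_TETR]
        other[I_GFP] = -p.delta_p * y[I_GFP]
    else:
        lacI_act = active_repressor(y[I_LACI], y[I_LAC], p.K_lac, p.eta_ind)
        tetR_act = active_repressor(y[I_TETR], y[I_ARA], p.K_ara, p.eta_ind)
        tx[I_M_TETR] = p.alpha_tx * hill_repression(lacI_act, p.K_rep, p.n_rep)
        tx[I_M_LACI] = p.alpha_tx * hill_repression(tetR_act, p.K_rep, p.n_rep)
        tl[I_LACI] = p.k_tl * p.rbs_lacI * y[I_M_LACI]
        tl[I_TETR] = p.k_tl * p.rbs_tetR * y[I_M_TETR]
        # Reporters are co-translated from their operon's transcript.
        tl[I_GFP] = p.k_tl * p.rbs_gfp * y[I_M_TETR]
        tl[I_MCHERRY] = p.k_tl * p.rbs_mcherry * y[I_M_LACI]
        other[I_M_LACI] = -p.delta_m * y[I_M_LACI]
        other[I_M_TETR] = -p.delta_m * y[I_M_TETR]
        other[I_LACI] = -p.delta_p * y[I_LACI]
        other[I_TETR] = -p.delta_p * y[I_TETR]
        other[I_GFP] = -p.delta_p * y[I_GFP]
        other[I_MCHERRY] = -p.delta_p * y[I_MCHERRY]

        if topo.has_lux:
            act = hill_activation(y[I_AHL], p.K_ahl, p.n_ahl)
            if topo.has_cI:
                act *= hill_repression(y[I_CI], p.K_cI, p.n_cI)
            tx[I_M_CI] = p.lux_gain * p.alpha_tx * act
            other[I_M_CI] = -p.delta_m * y[I_M_CI]
            # The lux transcript is polycistronic for both reporters
            # (and cI in the auto-repressing variant).
            tl[I_GFP] += p.k_tl * p.rbs_gfp * y[I_M_CI]
            tl[I_MCHERRY] += p.k_tl * p.rbs_mcherry * y[I_M_CI]
            if topo.has_cI:
                tl[I_CI] = p.k_tl * p.rbs_cI * y[I_M_CI]
                other[I_CI] = -p.delta_cI * y[I_CI]

    other[I_LAC] = q_lac - p.delta_ind * y[I_LAC]
    other[I_ARA] = q_ara - p.delta_ind * y[I_ARA]
    other[I_AHL] = -p.delta_ahl * y[I_AHL]
    return tx, tl, other


def rhs(y: np.ndarray, p: CircuitParams, q_lac: float = 0.0, q_ara: float = 0.0) -> np.ndarray:
    """Deterministic derivative of the state vector (engine fast path)."""
    tx, tl, other = rhs_terms(y, p, q_lac, q_ara)
    return tx + tl + other


def derivatives(
    state: CircuitState,
    params: CircuitParams,
    t: float = 0.0,
    q_lac: float = 0.0,
    q_ara: float = 0.0,
) -> CircuitState:
    """Time derivative of a :class:`CircuitState` (autonomous in ``t``)."""
    state.validate()
    return CircuitState.from_array(rhs(state.to_array(), params, q_lac, q_ara))


def apply_noise(
    y: np.ndarray,
    params: CircuitParams,
    noise: NoiseParams,
    dt: float,
    rng: np.random.Generator,
    q_lac: float = 0.0,
    q_ara: float = 0.0,
) -> np.ndarray:
    """One Euler-Maruyama increment with multiplicative expression noise.

    Transcription fluxes are scaled by ``1 + sigma_tx * xi / sqrt(dt)``
    and translation fluxes by ``1 + sigma_tl * xi' / sqrt(dt)`` with
    independent standard-normal draws per species per step, so the
    increment is ``drift*dt + sigma*flux*xi*sqrt(dt)``.  The increment
    is clipped so that ``y + increment >= 0``.
    """
    if dt <= 0:
        raise ValueError(f"dt must be > 0, got {dt}")
    tx, tl, other = rhs_terms(y, params, q_lac, q_ara)
    inc = (tx + tl + other) * dt
    if noise.enabled:
        sqdt = math.sqrt(dt)
        if noise.sigma_tx > 0:
            inc += noise.sigma_tx * tx * rng.standard_normal(N_SPECIES) * sqdt
        if noise.sigma_tl > 0:
            inc += noise.sigma_tl * tl * rng.standard_normal(N_SPECIES) * sqdt
    return np.maximum(inc, -y)
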