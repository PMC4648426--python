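"""Reporter-to-EFM signal transduction.

The conceptual hardware chain -- epifluorescent microscope, photo-
detector, thresholding electronics -- is collapsed into one pure
decision map from the instantaneous (GFP, mCherry) pair to a discrete
EFM level in {-2, -1, 0, +1, +2}.  The sign selects which inducer the
host seeks (+ = GFP-dominant = seek arabinose, - = mCherry-dominant =
seek lactose); the magnitude multiplies the base speed; 0 is a stall.

Level 2 ("strike") fires when *both* reporters are strongly expressed,
which the toggle alone cannot sustain: it is the signature of the
AHL-driven lux operon.  Because co-expression carries no direction,
the strike inherits its sign from the last committed direction
(``last_sign``), a one-bit memory in the electronics.
"""

from __future__ import annotations

from dataclasses import dataclass

__all__ = ["EFMConfig", "EFMState", "efm_signal"]


@dataclass
class EFMConfig:
    """Thresholds of the EFM electronics.

    ``theta_on``: detection floor below which both channels read dark.
    ``rho_dom``: fold-ratio one channel must exceed the other by to
    count as dominant.  ``theta_both``: co-expression level on *both*
    channels that triggers the strike state; calibrated above the
    transient co-expression seen while the toggle flips and below the
    steady lux-operon output.
    """

    theta_on: float = 2.0
    rho_dom: float = 2.0
    theta_both: float = 40.0

    def __post_init__(self) -> None:
        if not (self.theta_on > 0):
            raise ValueError(f"theta_on must be > 0, got {self.theta_on}")
        if not (self.rho_dom > 1):
            raise ValueError(f"rho_dom must be > 1, got {self.rho_dom}")
        if not (self.theta_both > self.theta_on):
            raise ValueError("theta_both must exceed theta_on")


@dataclass
class EFMState:
    """Current EFM level and the sign memory of the electronics."""

    value: int = 0
    last_sign: int = 0

    def __post_init__(self) -> None:
        if self.value not in (-2, -1, 0, 1, 2):
            raise ValueError(f"EFM value must be in {{-2..2}}, got {self.value}")
        if self.last_sign not in (-1, 0, 1):
            raise ValueError(f"last_sign must be in {{-1,0,1}}, got {self.last_sign}")


def efm_signal(GFP: float, mCherry: float, cfg: EFMConfig, last_sign: int = 0) -> EFMState:
    """Map instantaneous reporter levels to the discrete EFM signal.

    Rules, evaluated in order:

    1. both channels below ``theta_on``            -> 0 (dark)
    2. both channels above ``theta_both``          -> 2 * last_sign (strike)
    3. GFP > rho_dom * mCherry                     -> +1 (seek arabinose)
    4. mCherry > rho_dom * GFP                     -> -1 (seek lactose)
    5. otherwise (no dominance)                    -> 0 (pause)

    ``last_sign`` is updated to the sign of any nonzero output.
    """
    if GFP < 0 or mCherry < 0:
        raise ValueError("reporter concentrations must be >= 0")
    if last_sign not in (-1, 0, 1):
        raise ValueError(f"last_sign must be in {{-1,0,1}}, got {last_sign}")

    if max(GFP, mCherry) < cfg.theta_on:
        value = 0
    elif min(GFP, mCherry) > cfg.theta_both:
        value = 2 * last_sign
    elif GFP > cfg.rho_dom * mCherry:
        value = 1
    elif mCherry > cfg.rho_dom * GFP:
        value = -1
    else:
        value = 0

    new_sign = (1 if value > 0 else -1) if value != 0 else last_sign
    return EFMState(value=value, last_sign=new_sign)
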