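"""DNA-damage-signal (DDS) logic.

The damage signal is an algebraic function of the instantaneous
Mad2:Cdc20P (mitotic checkpoint complex, MCC) level:

* MCC < 0.36            -> DDS = 0 (checkpoint silent)
* 0.36 < MCC <= 0.6     -> DDS = 200 * (MCC - 0.36) (activation branch)
* MCC > 0.6             -> DDS = 200 * (MCC - 0.6) and the cell-cycle
  arrest condition is met (the simulator then resets Cdc20 to zero).

The signal entering the ATM/ATR synthesis term is Sig = DDS * exp(-1e-8 t),
a near-permanent damage memory with a vanishingly slow decay.  As written
the signal is continuous on [0, 0.6) and drops discontinuously at the
arrest boundary; this is deliberate and kept exactly as specified (see
docs/methods.md).
"""

from __future__ import annotations

import math
from dataclasses import dataclass, replace

__all__ = ["DdsState", "dds_signal", "dds_value"]


@dataclass(frozen=True)
class DdsState:
    """Damage-signal bookkeeping attached to a model state."""

    dds: float = 0.0
    sig: float = 0.0
    arrest_triggered: bool = False
    activation_threshold: float = 0.36
    arrest_threshold: float = 0.6
    gain: float = 200.0
    decay_rate: float = 1e-8  # per hour


def dds_value(mad2cdc20p: float, *, gain: float = 200.0,
              activation_threshold: float = 0.36,
              arrest_threshold: float = 0.6) -> float:
    """Piecewise-linear DDS as a pure function of the MCC level."""
    if mad2cdc20p < activation_threshold:
        return 0.0
    if mad2cdc20p > arrest_threshold:
        return gain * (mad2cdc20p - arrest_threshold)
    return gain * (mad2cdc20p - activation_threshold)


def dds_signal(mad2cdc20p: float, t: float, prior: DdsState = DdsState()) -> DdsState:
    """Evaluate the damage signal for an MCC level at time ``t`` (hours).

    ``arrest_triggered`` latches on once the MCC exceeds the arrest
    threshold; the integrator uses it to fire the Cdc20-reset event.
    """
    if mad2cdc20p < 0:
        raise ValueError(f"Mad2:Cdc20P level must be non-negative, got {mad2cdc20p}")
    if t < 0:
        raise ValueError(f"time must be non-negative, got {t}")
    dds = dds_value(
        mad2cdc20p,
        gain=prior.gain,
        activation_threshold=prior.activation_threshold,
        arrest_threshold=prior.arrest_threshold,
    )
    sig = dds * math.exp(-prior.decay_rate * t)
    arrested = prior.arrest_triggered or (mad2cdc20p > prior.arrest_threshold)
    return replace(prior, dds=dds, sig=sig, arrest_triggered=arrested)
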