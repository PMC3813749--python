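"""Short-term synaptic habituation via a two-state vesicle pool.

Synaptic vesicles are either readily releasable (RR) or not (NRR); the
occupancy probabilities satisfy A_RR + A_NRR = 1 at all times, so a single
state A_RR per habituating connection suffices.  Presynaptic activity
depletes the RR pool at rate n_depress * Q/Q_max, recycling refills it at
rate n_recover:

    dA_RR/dt = n_recover (1 - A_RR) - n_depress (Q/Q_max) A_RR,   Q >= 0
    dA_RR/dt = n_recover (1 - A_RR),                              Q <  0

(rates below the spontaneous level do not deplete).  The synaptic efficacy
W equals A_RR, so W = 1 at rest and every excitatory connection is scaled
by its own dynamic W in the circuit equations.
"""

from __future__ import annotations

import math
from dataclasses import dataclass

__all__ = ["HabituationParams", "VesiclePoolState", "pool_rhs", "efficacy", "recovery_time"]


@dataclass(frozen=True)
class HabituationParams:
    """Depression rate n_depress and recovery (recycling) rate n_recover, 1/s."""

    n_depress: float = 20.0
    n_recover: float = 2.0

    def __post_init__(self) -> None:
        if self.n_depress < 0 or self.n_recover < 0:
            raise ValueError("habituation rates must be non-negative")


@dataclass
class VesiclePoolState:
    """Readily-releasable pool occupancy; A_NRR is derived as 1 - A_RR."""

    A_RR: float = 1.0

    def __post_init__(self) -> None:
        if not 0.0 <= self.A_RR <= 1.0:
            raise ValueError("A_RR must lie in [0, 1]")

    @property
    def A_NRR(self) -> float:
        return 1.0 - self.A_RR


def pool_rhs(A_RR: float, Q_pre: float, p: HabituationParams, Q_max: float) -> float:
    """dA_RR/dt for presynaptic rate deviation ``Q_pre`` (1/s).

    ``Q_max`` normalizes the depression drive so n_depress is the depletion
    rate at maximal presynaptic activity.
    """
    if Q_max <= 0:
        raise ValueError("Q_max must be positive")
    recover = p.n_recover * (1.0 - A_RR)
    if Q_pre < 0:
        return recover
    return recover - p.n_depress * (Q_pre / Q_max) * A_RR


def efficacy(A_RR: float) -> float:
    """Dynamic synaptic efficacy W; proportional to A_RR with W(1) = 1."""
    return A_RR


def recovery_time(p: HabituationParams, target: float) -> float:
    """Time for A_RR to rise from 0 to ``target`` under recovery alone.

    Closed form of the recovery-only branch: t = -ln(1 - target)/n_recover.
    Returns ``inf`` when n_recover is zero.
    """
    if not 0.0 < target < 1.0:
        raise ValueError("target must lie strictly between 0 and 1")
    if p.n_recover == 0:
        return math.inf
    return -math.log1p(-target) / p.n_recover
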