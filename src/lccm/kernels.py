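"""Elementary neural-mass operators.

A neural mass converts an incoming average firing rate into an average
post-synaptic potential (PSP) by convolution with an alpha-shaped impulse
response

    h(t) = (H / tau) * t * exp(-t / tau),   t >= 0,

where ``H`` (volts) tunes the maximum PSP amplitude and ``tau`` (seconds)
lumps conduction, synaptic and dendritic delays.  The convolution is
equivalent to a pair of first-order ODEs (:func:`kernel_rhs`).

The reverse, potential-to-rate, operator is a logistic sigmoid shifted so
that it crosses the origin: with all state variables measured as deviations
from the resting state, zero potential maps to zero rate deviation and the
all-zero state is a fixed point of any circuit built from these operators.
"""

from __future__ import annotations

import math
from dataclasses import dataclass

import numpy as np

__all__ = [
    "SigmoidParams",
    "AlphaKernelParams",
    "SynapseState",
    "sigmoid",
    "sigmoid_max",
    "kernel_rhs",
    "kernel_impulse_response",
]

# exp() argument clip; keeps the sigmoid finite for arbitrarily large |u|
_EXP_CLIP = 700.0


@dataclass(frozen=True)
class SigmoidParams:
    """Parameters of the origin-crossing potential-to-rate sigmoid.

    Attributes
    ----------
    e0 : float
        Half of the maximum firing-rate deviation, 1/s.
    r : float
        Sigmoid slope, 1/V.
    u0 : float
        Membrane potential at which half of the maximum rate is reached, V.
    """

    e0: float = 2.5
    r: float = 560.0
    u0: float = 6e-3

    def __post_init__(self) -> None:
        if not (self.e0 > 0 and self.r > 0 and self.u0 > 0):
            raise ValueError("SigmoidParams require e0 > 0, r > 0, u0 > 0")


@dataclass(frozen=True)
class AlphaKernelParams:
    """Alpha-kernel parameters: synaptic gain H (V) and time constant tau (s)."""

    H: float
    tau: float

    def __post_init__(self) -> None:
        if not (self.H > 0 and self.tau > 0):
            raise ValueError("AlphaKernelParams require H > 0 and tau > 0")


@dataclass
class SynapseState:
    """State of one second-order synaptic transform.

    ``y`` is the PSP contribution (V), ``z`` its time derivative (V/s);
    (0, 0) is the rest state.
    """

    y: float = 0.0
    z: float = 0.0


def sigmoid(u, p: SigmoidParams = SigmoidParams()):
    """Firing-rate deviation S(u) for membrane-potential deviation ``u`` (V).

    S(u) = 2 e0 / (1 + exp(r (u0 - u))) - 2 e0 / (1 + exp(r u0))

    The subtracted constant shifts the classical logistic so S(0) = 0;
    negative values mean firing below the spontaneous rate.  Accepts scalars
    or arrays.
    """
    u = np.asarray(u, dtype=float)
    if not np.all(np.isfinite(u)):
        raise ValueError("sigmoid: non-finite membrane potential")
    arg = np.clip(p.r * (p.u0 - u), -_EXP_CLIP, _EXP_CLIP)
    offset = 2.0 * p.e0 / (1.0 + math.exp(min(p.r * p.u0, _EXP_CLIP)))
    out = 2.0 * p.e0 / (1.0 + np.exp(arg)) - offset
    return out if out.ndim else float(out)


def sigmoid_max(p: SigmoidParams = SigmoidParams()) -> float:
    """Supremum of :func:`sigmoid` (the maximum firing-rate deviation, 1/s)."""
    return 2.0 * p.e0 - 2.0 * p.e0 / (1.0 + math.exp(min(p.r * p.u0, _EXP_CLIP)))


def kernel_rhs(s: SynapseState, q_in: float, p: AlphaKernelParams) -> tuple[float, float]:
    """Time derivatives (dy/dt, dz/dt) of one synaptic transform.

    First-order form of the alpha kernel driven by input rate ``q_in`` (1/s):

        dy/dt = z
        dz/dt = (H/tau) q_in - (2/tau) z - y / tau**2
    """
    dy = s.z
    dz = (p.H / p.tau) * q_in - (2.0 / p.tau) * s.z - s.y / p.tau**2
    return dy, dz


def kernel_impulse_response(t, p: AlphaKernelParams):
    """Closed-form alpha kernel h(t) = (H/tau) t exp(-t/tau), zero for t < 0.

    Serves as the analytic oracle for integration tests of :func:`kernel_rhs`.
    Accepts scalars or arrays.
    """
    t = np.asarray(t, dtype=float)
    out = np.where(t >= 0.0, (p.H / p.tau) * t * np.exp(-np.clip(t, 0.0, None) / p.tau), 0.0)
    return out if out.ndim else float(out)
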