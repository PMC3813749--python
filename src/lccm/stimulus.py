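"""Tone-train paradigms and the continuous afferent drive p(t).

The habituation experiment presents sequences of short identical tones:
ten 15 ms tones per sequence, 485 ms offset-to-onset gap (500 ms
onset-to-onset), sequences separated by 10 s of silence.  Only the onsets
matter to the model; the temporal dispersion of each tone along the sensory
pathway is carried by a gamma-shaped impulse function

    p(t) = sum_k P0 * ((t - t_k)/w)**n * exp(-(t - t_k)/w),   t > t_k,

whose single-pulse peak (at lag n*w, value P0 * n**n * exp(-n)) is scaled by
P0 so that it equals the maximum firing-rate deviation of a neural mass.
With the default sigmoid parameters that gives P0 ~= 0.0064.
"""

from __future__ import annotations

from dataclasses import dataclass, field

import numpy as np

from .kernels import SigmoidParams, sigmoid_max

__all__ = [
    "InputParams",
    "ToneTrain",
    "ParadigmSpec",
    "p0_for",
    "impulse_input",
    "make_tone_train",
    "make_paradigm",
]

# single-pulse contributions below this fraction of the pulse peak are truncated
_PULSE_TRUNC = 1e-12


def p0_for(sig: SigmoidParams = SigmoidParams(), n: int = 7) -> float:
    """Scaling factor making the input-pulse peak equal the sigmoid maximum.

    The unit-scaled pulse (t/w)**n exp(-t/w) peaks at t = n*w with value
    n**n exp(-n); dividing the sigmoid supremum by that peak yields P0.
    """
    return sigmoid_max(sig) / (float(n) ** n * np.exp(-float(n)))


@dataclass(frozen=True)
class InputParams:
    """Afferent-input parameters.

    Attributes
    ----------
    w : float
        Input time constant (s); controls latency and dispersion of the pulse.
    n : int
        Shape exponent (dimensionless); fixed, nearly redundant with w and C1.
    P0 : float
        Pulse scaling factor; by default recomputed from the sigmoid maximum.
    C1 : float
        Extrinsic connection strength scaling the drive into the circuit.
    """

    w: float = 0.005
    n: int = 7
    P0: float = field(default_factory=p0_for)
    C1: float = 50.0

    def __post_init__(self) -> None:
        if not (self.w > 0 and self.n >= 1 and self.P0 > 0 and self.C1 >= 0):
            raise ValueError("InputParams require w > 0, n >= 1, P0 > 0, C1 >= 0")


@dataclass(frozen=True)
class ToneTrain:
    """Stimulus onset times (s) of one tone sequence."""

    onsets: tuple[float, ...]

    def __post_init__(self) -> None:
        if len(self.onsets) == 0:
            raise ValueError("ToneTrain needs at least one onset")
        if np.any(np.diff(self.onsets) <= 0):
            raise ValueError("ToneTrain onsets must be strictly increasing")

    @property
    def count(self) -> int:
        return len(self.onsets)

    @property
    def spacing(self) -> float:
        """Onset-to-onset interval (s); NaN for a single tone."""
        return float(self.onsets[1] - self.onsets[0]) if self.count > 1 else float("nan")


@dataclass(frozen=True)
class ParadigmSpec:
    """Full experimental paradigm: repeated tone sequences with silences."""

    sequences: int = 160
    tones_per_sequence: int = 10
    tone_duration: float = 0.015
    offset_to_onset_gap: float = 0.485
    inter_sequence_silence: float = 10.0

    def __post_init__(self) -> None:
        if min(self.tone_duration, self.offset_to_onset_gap, self.inter_sequence_silence) <= 0:
            raise ValueError("ParadigmSpec durations must be positive")
        if self.sequences < 0 or self.tones_per_sequence < 1:
            raise ValueError("ParadigmSpec counts invalid")

    @property
    def onset_spacing(self) -> float:
        return self.tone_duration + self.offset_to_onset_gap


def make_tone_train(n_tones: int, onset_spacing: float = 0.5, t0: float = 0.0) -> ToneTrain:
    """Equally spaced onsets t0 + k * onset_spacing, k = 0..n_tones-1."""
    if n_tones < 1:
        raise ValueError("n_tones must be >= 1")
    if n_tones > 1 and onset_spacing <= 0:
        raise ValueError("onset_spacing must be positive")
    return ToneTrain(tuple(t0 + k * onset_spacing for k in range(n_tones)))


def make_paradigm(spec: ParadigmSpec, t0: float = 0.0) -> list[ToneTrain]:
    """One :class:`ToneTrain` per sequence.

    Silence is measured from the offset of the last tone of one sequence to
    the onset of the first tone of the next.
    """
    trains: list[ToneTrain] = []
    start = t0
    for _ in range(spec.sequences):
        train = make_tone_train(spec.tones_per_sequence, spec.onset_spacing, start)
        trains.append(train)
        start = train.onsets[-1] + spec.tone_duration + spec.inter_sequence_silence
    return trains


def impulse_input(t, train: ToneTrain, p: InputParams):
    """Afferent firing-rate drive p(t) (1/s) for a tone train.

    Superposition of one gamma-shaped pulse per onset; zero before the first
    onset.  Pulse tails below ``1e-12`` of the single-pulse peak are
    truncated.  Accepts scalar or array ``t``.  Note the extrinsic strength
    C1 is *not* applied here; the circuit applies it at the synapse.
    """
    t = np.asarray(t, dtype=float)
    out = np.zeros_like(t, dtype=float)
    n = float(p.n)
    # lag beyond which the pulse tail is < ~1e-12 of its peak (generous bound)
    max_lag = p.w * (n + 80.0)
    for t_k in train.onsets:
        d = t - t_k
        mask = (d > 0) & (d < max_lag)
        if np.any(mask):
            x = d[mask] / p.w
            out[mask] += p.P0 * x**n * np.exp(-x)
    return out if out.ndim else float(out)
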