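"""Laminar cortical circuit model (LCCM) and Jansen–Rit baseline (JRM).

The LCCM lumps one cortical source into five neural masses: excitatory
interneurons (EIN, layer 4), superficial and deep pyramidal cells (sPC,
layers 2/3; dPC, layers 5/6) and two inhibitory interneuron populations
(sIIN, dIIN).  Thirteen intrinsic connections link them; each connection is
one second-order synaptic transform with its own strength C, time constant
tau and — for the nine intrinsic excitatory connections — a dynamic
efficacy W driven by vesicle-pool habituation.  The extrinsic drive
C1 * p(t) enters the transform that targets the EIN (shared with the
dPC->EIN feedback), which yields exactly 26 core state variables for the
full circuit.  The observed source signal is u_sPC + u_dPC, the summed
pyramidal depolarizations, simulated at 1 kHz and decimated to 125 Hz.

Seven "certain" connections (C2, C3, C4, C5, C7, C9, C10) form the basic
columnar circuit and are always present; six "uncertain" cross-laminar
connections (C6, C8, C11, C12, C13, C14) have zero prior strength and can
be included or excluded to express alternative signal-flow hypotheses
(serial vs parallel layer-4 pathways, cross-layer inhibition).

The JRM baseline is the classical three-population circuit (EIN, PC, IIN)
with three transforms (6 core states), sharing the same kernel and sigmoid
machinery, with optional habituation on its excitatory rate inputs.
"""

from __future__ import annotations

from dataclasses import dataclass, field, replace
from typing import Iterable, Mapping, Sequence

import numpy as np

from ._engine import integrate_jrm, integrate_lccm
from .kernels import SigmoidParams, sigmoid_max
from .plasticity import HabituationParams
from .stimulus import InputParams, ToneTrain

__all__ = [
    "LCCM_POPULATIONS",
    "JRM_POPULATIONS",
    "UNCERTAIN_CONNECTIONS",
    "ConnectionSpec",
    "LCCMParams",
    "JRMParams",
    "LCCModel",
    "JRModel",
    "Trajectory",
    "SourceWaveform",
    "default_connections",
    "build_lccm",
    "build_jrm",
    "simulate",
    "observe",
    "tone_peaks",
]

LCCM_POPULATIONS = ("EIN", "sPC", "dPC", "sIIN", "dIIN")
JRM_POPULATIONS = ("EIN", "PC", "IIN")

TAU_E = 0.010  # excitatory dendritic time constant, s
TAU_I = 0.020  # inhibitory dendritic time constant, s


@dataclass(frozen=True)
class ConnectionSpec:
    """One intrinsic connection: strength C, kernel tau, sign, habituation."""

    name: str
    source: str
    target: str
    sign: str  # "excitatory" | "inhibitory"
    C: float
    tau: float
    habituating: bool
    prior_class: str  # "certain" | "uncertain"

    def __post_init__(self) -> None:
        if self.C < 0:
            raise ValueError(f"{self.name}: C must be non-negative")
        if self.sign not in ("excitatory", "inhibitory"):
            raise ValueError(f"{self.name}: bad sign {self.sign!r}")
        if self.sign == "inhibitory" and not self.source.endswith("IIN"):
            raise ValueError(f"{self.name}: inhibitory connections must originate from an IIN")
        if self.habituating and self.sign == "inhibitory":
            raise ValueError(f"{self.name}: only excitatory connections habituate")

    @property
    def label(self) -> str:
        return f"{self.source}->{self.target}"


# (label, source, target, sign, prior strength, prior_class); habituation on
# all intrinsic excitatory connections, never on inhibitory ones.
_LCCM_TABLE = (
    ("C2", "EIN", "sPC", "excitatory", 108.0, "certain"),
    ("C3", "sPC", "sIIN", "excitatory", 33.75, "certain"),
    ("C4", "sIIN", "sPC", "inhibitory", 33.75, "certain"),
    ("C5", "sPC", "dPC", "excitatory", 135.0, "certain"),
    ("C6", "dPC", "sPC", "excitatory", 0.0, "uncertain"),
    ("C7", "dPC", "EIN", "excitatory", 135.0, "certain"),
    ("C8", "EIN", "dPC", "excitatory", 0.0, "uncertain"),
    ("C9", "dPC", "dIIN", "excitatory", 33.75, "certain"),
    ("C10", "dIIN", "dPC", "inhibitory", 33.75, "certain"),
    ("C11", "sIIN", "dPC", "inhibitory", 0.0, "uncertain"),
    ("C12", "dPC", "sIIN", "excitatory", 0.0, "uncertain"),
    ("C13", "dIIN", "sPC", "inhibitory", 0.0, "uncertain"),
    ("C14", "sPC", "dIIN", "excitatory", 0.0, "uncertain"),
)

UNCERTAIN_CONNECTIONS = frozenset(n for n, *_, pc in _LCCM_TABLE if pc == "uncertain")
CERTAIN_CONNECTIONS = tuple(n for n, *_, pc in _LCCM_TABLE if pc == "certain")

#: transform receiving the extrinsic input C1 * p(t) (shared with dPC->EIN)
INPUT_CONNECTION = "C7"


def default_connections() -> dict[str, ConnectionSpec]:
    """The 13-connection prior table of the laminar circuit."""
    out = {}
    for name, src, tgt, sign, C, pclass in _LCCM_TABLE:
        tau = TAU_E if sign == "excitatory" else TAU_I
        out[name] = ConnectionSpec(
            name=name, source=src, target=tgt, sign=sign, C=C, tau=tau,
            habituating=(sign == "excitatory"), prior_class=pclass,
        )
    return out


@dataclass(frozen=True)
class LCCMParams:
    """Complete parameterization of the laminar circuit."""

    connections: dict[str, ConnectionSpec] = field(default_factory=default_connections)
    He: float = 3.25e-3
    Hi: float = 22e-3
    sigmoid: SigmoidParams = field(default_factory=SigmoidParams)
    input: InputParams = field(default_factory=InputParams)
    habituation: dict[str, HabituationParams] = field(default_factory=dict)

    def __post_init__(self) -> None:
        if self.He <= 0 or self.Hi <= 0:
            raise ValueError("synaptic gains must be positive")

    def hab_params(self, name: str) -> HabituationParams:
        return self.habituation.get(name, HabituationParams())


@dataclass(frozen=True)
class JRMParams:
    """Classical Jansen–Rit parameterization (C = 135 with the usual ratios)."""

    C_pc_ein: float = 135.0    # PC -> EIN (potential scaling of the shared transform)
    C_ein_pc: float = 108.0    # EIN -> PC (0.8 C)
    C_pc_iin: float = 33.75    # PC -> IIN (0.25 C)
    C_iin_pc: float = 33.75    # IIN -> PC (0.25 C)
    tau_pc_out: float = TAU_E
    tau_ein_pc: float = TAU_E
    tau_iin_pc: float = TAU_I
    He: float = 3.25e-3
    Hi: float = 22e-3
    sigmoid: SigmoidParams = field(default_factory=SigmoidParams)
    input: InputParams = field(default_factory=InputParams)
    habituating: bool = False
    habituation: dict[str, HabituationParams] = field(default_factory=dict)

    def hab_params(self, name: str) -> HabituationParams:
        return self.habituation.get(name, HabituationParams())


@dataclass(frozen=True)
class Trajectory:
    """Simulated population potentials (V) and pool occupancies over time."""

    t: np.ndarray            # sample times, s (1 kHz grid)
    u: np.ndarray            # (nt, n_pop) membrane potentials
    pools: np.ndarray        # (nt, n_pool) A_RR occupancies
    populations: tuple[str, ...]
    pool_names: tuple[str, ...]
    dt: float

    def potential(self, population: str) -> np.ndarray:
        return self.u[:, self.populations.index(population)]


@dataclass
class SourceWaveform:
    """Source-level time series: the model's observable and the data format."""

    t: np.ndarray
    y: np.ndarray
    fs: float
    normalized: bool = False

    def __post_init__(self) -> None:
        self.t = np.asarray(self.t, dtype=float)
        self.y = np.asarray(self.y, dtype=float)
        if self.t.shape != self.y.shape:
            raise ValueError("t and y must have equal shapes")


class LCCModel:
    """Assembled laminar circuit: parameter set plus the active connection graph."""

    kind = "LCCM"
    populations = LCCM_POPULATIONS
    observed = ("sPC", "dPC")

    def __init__(self, params: LCCMParams, include_uncertain: frozenset[str]):
        self.params = params
        self.include_uncertain = include_uncertain
        order = [n for n, *_ in _LCCM_TABLE]
        self.active = tuple(
            n for n in order
            if params.connections[n].prior_class == "certain" or n in include_uncertain
        )
        self.pool_connections = tuple(
            n for n in self.active if params.connections[n].habituating
        )

    @property
    def core_dim(self) -> int:
        """Number of first-order core state variables (2 per transform)."""
        return 2 * len(self.active)

    @property
    def n_pools(self) -> int:
        return len(self.pool_connections)

    def connection(self, name: str) -> ConnectionSpec:
        return self.params.connections[name]

    def with_params(self, params: LCCMParams) -> "LCCModel":
        return LCCModel(params, self.include_uncertain)

    def pack(self) -> dict:
        """Flat-array representation consumed by the numba integrator."""
        p = self.params
        pop_idx = {name: i for i, name in enumerate(self.populations)}
        conns = [p.connections[n] for n in self.active]
        src = np.array([pop_idx[c.source] for c in conns], dtype=np.int64)
        tgt = np.array([pop_idx[c.target] for c in conns], dtype=np.int64)
        sign = np.array([1.0 if c.sign == "excitatory" else -1.0 for c in conns])
        C = np.array([c.C for c in conns])
        tau = np.array([c.tau for c in conns])
        H = np.array([p.He if c.sign == "excitatory" else p.Hi for c in conns])
        hab = np.full(len(conns), -1, dtype=np.int64)
        pool_src, n1, n2 = [], [], []
        for j, name in enumerate(self.pool_connections):
            hab[self.active.index(name)] = j
            pool_src.append(pop_idx[p.connections[name].source])
            hp = p.hab_params(name)
            n1.append(hp.n_depress)
            n2.append(hp.n_recover)
        input_idx = self.active.index(INPUT_CONNECTION)
        return dict(
            src=src, tgt=tgt, sign=sign, C=C, tau=tau, H=H, hab=hab,
            pool_src=np.array(pool_src, dtype=np.int64),
            n1=np.array(n1, dtype=float), n2=np.array(n2, dtype=float),
            input_idx=input_idx,
            C1=p.input.C1, P0=p.input.P0, w=p.input.w, nexp=float(p.input.n),
            e0=p.sigmoid.e0, r=p.sigmoid.r, u0=p.sigmoid.u0,
            Qmax=sigmoid_max(p.sigmoid),
        )


class JRModel:
    """Assembled Jansen–Rit baseline circuit."""

    kind = "JRM"
    populations = JRM_POPULATIONS
    observed = ("PC",)
    #: habituating rate inputs: the shared PC output transform and EIN->PC
    pool_connections = ("PC->out", "EIN->PC")

    def __init__(self, params: JRMParams):
        self.params = params

    @property
    def core_dim(self) -> int:
        return 6

    @property
    def n_pools(self) -> int:
        return 2 if self.params.habituating else 0

    def with_params(self, params: JRMParams) -> "JRModel":
        return JRModel(params)

    def pack(self) -> dict:
        p = self.params
        h0 = p.hab_params("PC->out")
        h1 = p.hab_params("EIN->PC")
        return dict(
            C_pe=p.C_pc_ein, C_ep=p.C_ein_pc, C_pi=p.C_pc_iin, C_ip=p.C_iin_pc,
            tau0=p.tau_pc_out, tau1=p.tau_ein_pc, tau2=p.tau_iin_pc,
            He=p.He, Hi=p.Hi,
            hab0=p.habituating, hab1=p.habituating,
            n1=np.array([h0.n_depress, h1.n_depress]),
            n2=np.array([h0.n_recover, h1.n_recover]),
            C1=p.input.C1, P0=p.input.P0, w=p.input.w, nexp=float(p.input.n),
            e0=p.sigmoid.e0, r=p.sigmoid.r, u0=p.sigmoid.u0,
            Qmax=sigmoid_max(p.sigmoid),
        )


def build_lccm(
    include_uncertain: Iterable[str] | None = None,
    params: LCCMParams | None = None,
) -> LCCModel:
    """Assemble the laminar circuit.

    ``include_uncertain`` selects which of the six zero-prior cross-laminar
    connections are present (default: all six, the full 26-state circuit).
    The seven certain connections are always present.
    """
    if include_uncertain is None:
        inc = frozenset(UNCERTAIN_CONNECTIONS)
    else:
        inc = frozenset(include_uncertain)
        unknown = inc - UNCERTAIN_CONNECTIONS
        if unknown:
            raise ValueError(f"not uncertain connections: {sorted(unknown)}")
    return LCCModel(params or LCCMParams(), inc)


def build_jrm(params: JRMParams | None = None) -> JRModel:
    """Assemble the classical three-population Jansen–Rit baseline."""
    return JRModel(params or JRMParams())


def simulate(
    model: LCCModel | JRModel,
    train: ToneTrain | None,
    t_span: tuple[float, float] = (-0.1, 2.5),
    dt: float = 1e-3,
) -> Trajectory:
    """Integrate the circuit from rest over ``t_span`` with fixed-step RK4.

    ``train is None`` simulates without stimulation.  Raises on numerical
    blow-up, naming the first non-finite sample time.
    """
    if dt > 1e-3 + 1e-12:
        raise ValueError("dt must be <= 1 ms for the stiff synaptic kernels")
    t0, t1 = t_span
    nt = int(round((t1 - t0) / dt)) + 1
    onsets = np.array(train.onsets if train is not None else [], dtype=float)
    packed = model.pack()

    if isinstance(model, LCCModel):
        u, A = integrate_lccm(
            packed["src"], packed["tgt"], packed["sign"], packed["C"], packed["tau"],
            packed["H"], packed["hab"], packed["pool_src"], packed["n1"], packed["n2"],
            packed["input_idx"], packed["C1"], packed["P0"], packed["w"], packed["nexp"],
            onsets, packed["e0"], packed["r"], packed["u0"], packed["Qmax"],
            t0, dt, nt, len(model.populations),
        )
        pool_names = tuple(
            model.connection(n).label for n in model.pool_connections
        )
    else:
        u, A = integrate_jrm(
            packed["C_pe"], packed["C_ep"], packed["C_pi"], packed["C_ip"],
            packed["tau0"], packed["tau1"], packed["tau2"], packed["He"], packed["Hi"],
            packed["hab0"], packed["hab1"], packed["n1"], packed["n2"],
            packed["C1"], packed["P0"], packed["w"], packed["nexp"], onsets,
            packed["e0"], packed["r"], packed["u0"], packed["Qmax"],
            t0, dt, nt,
        )
        if not model.params.habituating:
            A = A[:, :0]
        pool_names = model.pool_connections[: A.shape[1]]

    if not np.all(np.isfinite(u)):
        bad = int(np.argmax(~np.all(np.isfinite(u), axis=1)))
        raise FloatingPointError(
            f"simulation blew up at t = {t0 + bad * dt:.4f} s"
        )
    t = t0 + dt * np.arange(nt)
    return Trajectory(t=t, u=u, pools=A, populations=model.populations,
                      pool_names=pool_names, dt=dt)


def observe(
    traj: Trajectory,
    model: LCCModel | JRModel,
    fs_out: float = 125.0,
    normalize: bool = False,
) -> SourceWaveform:
    """Source waveform: summed pyramidal depolarizations, decimated to ``fs_out``.

    The model is integrated at 1 kHz; its output is already band-limited by
    the synaptic kernels, so decimation is a plain stride.  With
    ``normalize`` the amplitude is scaled to max |y| = 1, matching the
    preprocessing of reconstructed dipole waveforms.
    """
    y = np.zeros(traj.u.shape[0])
    for pop in model.observed:
        y = y + traj.potential(pop)
    step_f = 1.0 / (fs_out * traj.dt)
    step = int(round(step_f))
    if abs(step_f - step) > 1e-9 or step < 1:
        raise ValueError(f"fs_out {fs_out} incompatible with simulation step {traj.dt}")
    t = traj.t[::step]
    y = y[::step]
    if normalize:
        peak = np.max(np.abs(y))
        if peak > 0:
            y = y / peak
    return SourceWaveform(t=t, y=np.array(y), fs=fs_out, normalized=normalize)


def tone_peaks(
    wf: SourceWaveform,
    onsets: Sequence[float],
    window: tuple[float, float] = (0.0, 0.4),
) -> np.ndarray:
    """Absolute response peak per tone, measured in ``window`` after each onset."""
    peaks = []
    for t_k in onsets:
        mask = (wf.t >= t_k + window[0]) & (wf.t <= t_k + window[1])
        if not np.any(mask):
            raise ValueError(f"no samples in response window of onset {t_k}")
        peaks.append(np.max(np.abs(wf.y[mask])))
    return np.array(peaks)
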