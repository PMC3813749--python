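"""Re-parameterized Gaussian priors for model inversion.

Every natural parameter φ is positive (or zero-allowed) by construction:

* ``exp`` class: φ = u · exp(θ), u the prior expectation.  Latent variance
  1/2 ("uninformative") lets the parameter roam; 1/16 ("informative") keeps
  it near its expectation.
* ``square`` class: φ = θ², latent variance 1e4.  A shrinkage prior for the
  uncertain connections — the connection is absent (φ = 0) at the prior
  mean and stays absent unless the data pull θ away from zero.
* ``constant`` class: fixed at the expectation, not part of θ.

The default tables mirror the circuit priors: certain connection strengths,
all time constants and all habituation rates are uninformative exp-class;
the input parameters w and C1 are informative; the synaptic gains and
sigmoid parameters are constants; uncertain connection strengths are
square-class.  A free observation gain (exp-class, variance 1/2) absorbs
the unknown source scaling left after max-normalization of the data.
"""

from __future__ import annotations

from dataclasses import dataclass

import numpy as np

from .circuits import JRModel, LCCModel

__all__ = [
    "UNINFORMATIVE_VAR",
    "INFORMATIVE_VAR",
    "SHRINKAGE_VAR",
    "PriorSpec",
    "active_priors",
    "latent_variances",
    "to_natural",
    "default_lccm_priors",
    "default_jrm_priors",
]

UNINFORMATIVE_VAR = 0.5
INFORMATIVE_VAR = 1.0 / 16.0
SHRINKAGE_VAR = 1.0e4


@dataclass(frozen=True)
class PriorSpec:
    """Prior for one natural parameter."""

    name: str
    expectation: float
    reparam: str  # "exp" | "square" | "constant"
    latent_variance: float = 0.0

    def __post_init__(self) -> None:
        if self.reparam not in ("exp", "square", "constant"):
            raise ValueError(f"{self.name}: unknown reparam {self.reparam!r}")
        if self.reparam == "exp" and self.latent_variance not in (
            UNINFORMATIVE_VAR, INFORMATIVE_VAR,
        ):
            raise ValueError(f"{self.name}: exp-class variance must be 1/2 or 1/16")
        if self.reparam == "square" and self.latent_variance != SHRINKAGE_VAR:
            raise ValueError(f"{self.name}: square-class variance must be 1e4")


def active_priors(priors: list[PriorSpec]) -> list[PriorSpec]:
    """Priors that contribute a latent dimension (everything non-constant)."""
    return [p for p in priors if p.reparam != "constant"]


def latent_variances(priors: list[PriorSpec]) -> np.ndarray:
    return np.array([p.latent_variance for p in active_priors(priors)])


def to_natural(theta: np.ndarray, priors: list[PriorSpec]) -> dict[str, float]:
    """Map a latent vector θ to natural-scale parameter values.

    Constants are passed through at their expectation and consume no latent
    dimension.
    """
    theta = np.asarray(theta, dtype=float)
    act = active_priors(priors)
    if theta.shape != (len(act),):
        raise ValueError(f"theta has length {theta.shape}, expected {len(act)}")
    out: dict[str, float] = {}
    it = iter(theta)
    for p in priors:
        if p.reparam == "constant":
            out[p.name] = p.expectation
        elif p.reparam == "exp":
            out[p.name] = p.expectation * float(np.exp(next(it)))
        else:  # square
            out[p.name] = float(next(it)) ** 2
    return out


def default_lccm_priors(model: LCCModel, gain: bool = True) -> list[PriorSpec]:
    """Full prior table for an assembled laminar circuit.

    One strength and one time constant per active connection, a pair of
    habituation rates per habituating connection, the input parameters, the
    fixed gains/sigmoid constants and (optionally) the free observation gain.
    """
    specs: list[PriorSpec] = []
    for name in model.active:
        c = model.connection(name)
        if c.prior_class == "uncertain":
            specs.append(PriorSpec(f"C:{c.label}", 0.0, "square", SHRINKAGE_VAR))
        else:
            specs.append(PriorSpec(f"C:{c.label}", c.C, "exp", UNINFORMATIVE_VAR))
        specs.append(PriorSpec(f"tau:{c.label}", c.tau, "exp", UNINFORMATIVE_VAR))
    for name in model.pool_connections:
        c = model.connection(name)
        hp = model.params.hab_params(name)
        specs.append(PriorSpec(f"nd:{c.label}", hp.n_depress, "exp", UNINFORMATIVE_VAR))
        specs.append(PriorSpec(f"nr:{c.label}", hp.n_recover, "exp", UNINFORMATIVE_VAR))
    specs.append(PriorSpec("w", model.params.input.w, "exp", INFORMATIVE_VAR))
    specs.append(PriorSpec("C1", model.params.input.C1, "exp", INFORMATIVE_VAR))
    specs.append(PriorSpec("He", model.params.He, "constant"))
    specs.append(PriorSpec("Hi", model.params.Hi, "constant"))
    specs.append(PriorSpec("e0", model.params.sigmoid.e0, "constant"))
    specs.append(PriorSpec("r", model.params.sigmoid.r, "constant"))
    specs.append(PriorSpec("u0", model.params.sigmoid.u0, "constant"))
    if gain:
        specs.append(PriorSpec("gain", 1.0, "exp", UNINFORMATIVE_VAR))
    return specs


def default_jrm_priors(model: JRModel, gain: bool = True) -> list[PriorSpec]:
    """Prior table for the Jansen–Rit baseline (all connections certain)."""
    p = model.params
    specs = [
        PriorSpec("C:PC->EIN", p.C_pc_ein, "exp", UNINFORMATIVE_VAR),
        PriorSpec("C:EIN->PC", p.C_ein_pc, "exp", UNINFORMATIVE_VAR),
        PriorSpec("C:PC->IIN", p.C_pc_iin, "exp", UNINFORMATIVE_VAR),
        PriorSpec("C:IIN->PC", p.C_iin_pc, "exp", UNINFORMATIVE_VAR),
        PriorSpec("tau:PC->out", p.tau_pc_out, "exp", UNINFORMATIVE_VAR),
        PriorSpec("tau:EIN->PC", p.tau_ein_pc, "exp", UNINFORMATIVE_VAR),
        PriorSpec("tau:IIN->PC", p.tau_iin_pc, "exp", UNINFORMATIVE_VAR),
    ]
    if p.habituating:
        for name in model.pool_connections:
            hp = p.hab_params(name)
            specs.append(PriorSpec(f"nd:{name}", hp.n_depress, "exp", UNINFORMATIVE_VAR))
            specs.append(PriorSpec(f"nr:{name}", hp.n_recover, "exp", UNINFORMATIVE_VAR))
    specs.append(PriorSpec("w", p.input.w, "exp", INFORMATIVE_VAR))
    specs.append(PriorSpec("C1", p.input.C1, "exp", INFORMATIVE_VAR))
    specs.append(PriorSpec("He", p.He, "constant"))
    specs.append(PriorSpec("Hi", p.Hi, "constant"))
    specs.append(PriorSpec("e0", p.sigmoid.e0, "constant"))
    specs.append(PriorSpec("r", p.sigmoid.r, "constant"))
    specs.append(PriorSpec("u0", p.sigmoid.u0, "constant"))
    if gain:
        specs.append(PriorSpec("gain", 1.0, "exp", UNINFORMATIVE_VAR))
    return specs
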