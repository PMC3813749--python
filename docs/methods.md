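# Methods

## Model

The package implements a neural mass model of one cortical source with
five populations placed in three laminar compartments: excitatory
interneurons (EIN) in layer 4, superficial pyramidal cells (sPC) in
layers 2/3, deep pyramidal cells (dPC) in layers 5/6, and one inhibitory
interneuron population per compartment pair (sIIN for the supragranular
layers including layer 4, dIIN for the infragranular layers).  Each
population is described by two lumped state variables, the average
membrane-potential deviation *u* and the average firing-rate deviation
*Q = S(u)*, both measured relative to the resting state.

**Rate-to-potential operator.**  Every synaptic connection is an
independent second-order linear transform, the alpha kernel
*h(t) = (H/τ) t e^(−t/τ)*, written as the ODE pair dy/dt = z,
dz/dt = (H/τ)q − (2/τ)z − y/τ².  The gain *H* is uniform per sign class
(He = 3.25 mV, Hi = 22 mV); the time constant is connection-specific
with expectations τe = 10 ms, τi = 20 ms.

**Potential-to-rate operator.**  The logistic sigmoid is shifted by its
value at zero, S(u) = 2e0/(1+e^(r(u0−u))) − 2e0/(1+e^(r·u0)), with
e0 = 2.5 s⁻¹, r = 560 V⁻¹, u0 = 6 mV held constant.  The shift makes the
all-zero state an exact fixed point, so rates may be negative (activity
below the spontaneous level).  The supremum S_max ≈ 4.832 s⁻¹ doubles as
the normalizer of the habituation drive and of the input pulse.

**Connectivity.**  Thirteen intrinsic connections are built in.  Seven
"certain" ones form the canonical columnar circuit — EIN→sPC (108),
sPC→dPC (135), dPC→EIN (135), plus intra-laminar pyramidal/interneuron
loops sPC↔sIIN and dPC↔dIIN (33.75 each).  Six "uncertain" cross-laminar
connections (dPC→sPC, EIN→dPC, sIIN→dPC, dPC→sIIN, dIIN→sPC, sPC→dIIN)
have zero prior strength and can be included or excluded from the graph,
expressing alternative hypotheses about laminar signal flow (serial vs
parallel routing of the layer-4 input, cross-layer inhibition).  With all
thirteen present the core system has 26 first-order equations (two per
transform); excluding a connection removes exactly two states, and
setting its strength to zero is numerically identical to excluding it.

**Input.**  Each tone contributes a gamma-shaped rate pulse
P0 (t/w)ⁿ e^(−t/w) with n = 7 fixed and w = 5 ms; P0 is recomputed from
the current sigmoid as S_max/(nⁿe^(−n)) ≈ 0.006434 so that the peak drive
equals the maximum rate deviation (the printed two-significant-figure
value 0.0064 is kept as a regression check).  The drive, scaled by the
extrinsic strength C1 = 50, is injected into the input sum of the
transform targeting the EIN — shared with the dPC→EIN feedback — which is
what yields the 26-state core count.  Tone duration is not modeled;
only onsets matter.

**Habituation.**  Each of the nine intrinsic excitatory connections owns
a vesicle-pool state A_RR ∈ [0,1] (readily releasable fraction; the
not-readily-releasable fraction is 1 − A_RR by conservation, never stored)
obeying dA/dt = n_r(1−A) − n_d·max(Q,0)/Q_max·A with per-connection rates
(expectations n_d = 20 s⁻¹, n_r = 2 s⁻¹).  Negative rate deviations do
not deplete; recovery always acts.  The efficacy W = A_RR multiplies the
static strength C.  The recovery-only closed form gives
t(0→0.99) = −ln(0.01)/n_r ≈ 2.30 s, inside the ~3 s bound expected from
physiology.  Note that for this rate law the recovery time constant is
1/n_r = 500 ms; a 600 ms time constant sometimes quoted for the same
recovery rate is inconsistent with it, and the rate law is what the
implementation honors.  Inhibitory synapses and the extrinsic input are
static.

**Observation.**  The source signal is u_sPC + u_dPC (pyramidal
depolarizations dominate the macroscopic signal).  Simulation runs at
1 kHz with fixed-step RK4 from rest (core states zero, pools at 1) and
the output is decimated by stride to 125 Hz; because the synaptic kernels
band-limit the signal well below the Nyquist rate of 62.5 Hz, no
anti-aliasing filter is needed.  Optional max-abs normalization mirrors
the preprocessing of reconstructed dipole waveforms.  Step-halving
changes the observed waveform by < 1e-6 relative RMS, so 1 ms is in the
asymptotic regime.  Epochs start from rest: each tone sequence follows
≥ 10 s of silence, after which the pools are within e^(−20) of 1.

**Jansen–Rit baseline.**  The classical three-population circuit is
provided with the same kernel/sigmoid machinery and the classical
constants (C = 135 with ratios 1, 0.8, 0.25, 0.25; same gains, time
constants and sigmoid).  It uses the canonical three-transform layout
(6 core states): one shared transform for the pyramidal output driving
EIN and IIN, one excitatory and one inhibitory transform onto the
pyramidal cells.  Optional habituation attaches pools to its two
excitatory rate inputs (the shared pyramidal-output transform and
EIN→PC); because the output transform is shared, its pool habituates both
downstream paths jointly — a structural simplification of this topology.

## Inversion

The generative model for an observed 125 Hz waveform is y = h(θ) + ε,
ε ~ N(0, λI).  Natural parameters are re-parameterized: φ = u·e^θ
(positive, expectation u at θ = 0) with latent variance 1/2
(uninformative: connection strengths, time constants, habituation rates)
or 1/16 (informative: w, C1); uncertain connections use the shrinkage
form φ = θ² with variance 1e4, which keeps them absent unless the data
demand otherwise.  Gains and sigmoid constants are fixed.  A free
observation gain (exp-class, variance 1/2, expectation 1) multiplies the
max-normalized model output and absorbs the arbitrary scale left by
normalizing the data; it is declared plumbing, not physiology.  The full
laminar table has 47 latent parameters, the baseline 14.

The EM scheme alternates a Gauss-Newton update of the conditional mean
(central-difference Jacobian, step 1e-3 in θ; normal equations
ridge-stabilized if singular) with a ReML fixed-point update of λ that
includes the posterior-uncertainty term tr(ΣJᵀJ); λ is floored at 1e-12
so noise-free data cannot degenerate the precision.  Steps that would
decrease the Laplace free energy are halved up to eight times
(Levenberg-style); convergence is declared at max|Δη| < 1e-4 (tests and
experiments use 1e-3 to spare iterations) within 64 iterations, and a
non-improving iterate is returned as the optimum.  The free energy is
the standard Laplace form: Gaussian log-likelihood of the residual minus
the complexity term ½ηᵀC_θ⁻¹η + ½log|C_θ| − ½log|Σ_θ|y|.  Log-evidence
differences are log Bayes factors with the conventional ≥ 3 threshold.
An uncertain connection is declared present when zero lies outside the
one-sided 10% tail of its latent posterior (|η|/sd > 1.2816).

The square re-parameterization has zero gradient at θ = 0, so a search
started exactly at the prior mean can never activate an absent
connection.  The default initialization is the prior mean (zero
iterations return it unchanged); experiments that need to probe
uncertain connections start those latents at θ = 0.1 (φ = 0.01,
negligible on the natural scale), which restores a usable gradient while
leaving genuine shrinkage behavior intact — on data generated without
the connections, the estimates return below 5% of the certain-connection
scale.

## Synthetic data

The generator emulates the study conditions of an auditory habituation
session: epochs from −100 to 2500 ms containing five tones at 500 ms
onset spacing (the full 10-tone, 10 s-silence paradigm is available),
output max-normalized at 125 Hz, plus i.i.d. Gaussian noise with default
sd 0.05 (5% of the peak) — a stand-in, since the signal-to-noise ratio of
real reconstructed dipole waveforms is not pinned down.  It does *not*
emulate sensor noise, head-model or source-localization error, or the
1–20 Hz band-pass applied to real recordings (the model output is already
band-limited), so passing recovery tests demonstrate correctness of the
inference machinery under the model's own assumptions, not robustness to
real-data artifacts.  Datasets are bit-exact reproducible from (seed,
truth, paradigm).

The model-recovery experiment generates from a "representative subject":
the laminar circuit with its two most commonly supported cross-laminar
features active — the parallel EIN→dPC pathway and sIIN→dPC cross-layer
inhibition, both at the small-connection scale 33.75 — because data
generated with all uncertain connections absent come from a serial
sub-circuit that the Jansen–Rit baseline reproduces to ~1.7% RMS, making
model discrimination impossible in principle at 5% noise.  With the
representative truth the laminar model wins by ln B ≈ 25–30 per seed.

## Numerical and design notes

* Fixed-step RK4 at 1 ms everywhere (deterministic, matches the 1 kHz
  acquisition grid); blow-ups raise an error naming the first bad time.
* Sigmoid exponents are clipped at ±700 to stay finite for extreme
  potentials; the clip is far outside the physiological range.
* Pulse tails below ~1e-12 of the peak are truncated when evaluating the
  input drive.
* Response peaks are measured as max |y| in a 0–400 ms window after each
  onset, on the 1 kHz grid when ratios near 1% matter.
* Per-tone peak measurements include a ~3e-5 relative residual from
  overlapping response tails; tests treat that as the zero-suppression
  floor.
* Problem sizes in tests and the acceptance script (5-tone epochs,
  20-point probe scans, 5 model-recovery seeds at 32 iterations) were
  chosen as the smallest runs that exercise each claim meaningfully.

## Known limitations

* Single source only: no inter-area networks, lead fields or sensor
  models.
* Two-pool vesicle kinetics (no reserve/fused split, no facilitation,
  no inhibitory-synapse plasticity).
* Single isotropic noise component in the inversion; no temporal
  precision structure.
* The equivalence of serial and parallel laminar routings at weak
  cross-laminar coupling means connection-presence decisions from
  waveform data alone are only as identifiable as the data make them —
  the shrinkage estimates can legitimately return "absent" for a weakly
  expressed true connection.
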