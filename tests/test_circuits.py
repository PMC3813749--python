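import numpy as np
import pytest
from dataclasses import replace

from lccm.circuits import (
    JRMParams,
    LCCMParams,
    UNCERTAIN_CONNECTIONS,
    build_jrm,
    build_lccm,
    default_connections,
    observe,
    simulate,
    tone_peaks,
)
from lccm.stimulus import make_tone_train


def test_full_circuit_has_26_core_states(lccm_model):
    assert lccm_model.core_dim == 26
    assert lccm_model.n_pools == 9


def test_certain_only_circuit_has_14_core_states():
    assert build_lccm(include_uncertain=()).core_dim == 14


@pytest.mark.parametrize("name", sorted(UNCERTAIN_CONNECTIONS))
def test_removing_one_uncertain_connection_removes_two_states(name):
    m = build_lccm(include_uncertain=UNCERTAIN_CONNECTIONS - {name})
    assert m.core_dim == 24


def test_unknown_connection_rejected():
    with pytest.raises(ValueError):
        build_lccm(include_uncertain={"C2"})  # certain, not uncertain
    with pytest.raises(ValueError):
        build_lccm(include_uncertain={"C99"})


def test_rest_is_fixed_point(lccm_model):
    """Zero input from rest leaves every state at zero and every pool at 1."""
    traj = simulate(lccm_model, None, t_span=(0.0, 1.0))
    assert np.all(traj.u == 0.0)
    assert np.all(traj.pools == 1.0)
    wf = observe(traj, lccm_model)
    assert np.all(wf.y == 0.0)


def test_zero_strength_equals_exclusion(five_tone_train):
    """C_i = 0 is exactly equivalent to removing the connection."""
    excluded = build_lccm(include_uncertain=())
    conns = default_connections()  # uncertain connections already have C = 0
    zeroed = build_lccm(params=LCCMParams(connections=conns))
    wf_a = observe(simulate(excluded, five_tone_train), excluded)
    wf_b = observe(simulate(zeroed, five_tone_train), zeroed)
    np.testing.assert_array_equal(wf_a.y, wf_b.y)


def test_habituation_suppresses_successive_peaks(five_tone_waveform, five_tone_train):
    peaks = tone_peaks(five_tone_waveform, five_tone_train.onsets)
    assert np.all(np.diff(peaks) <= 0)
    drops = -np.diff(peaks)
    assert drops[0] == np.max(drops)


def test_pool_conservation_along_trial(five_tone_traj):
    A = five_tone_traj.pools
    assert np.all(A >= -1e-9) and np.all(A <= 1 + 1e-9)
    assert np.max(np.abs((A + (1.0 - A)) - 1.0)) < 1e-12
    # habituation actually engages: some pool leaves its resting value
    assert np.min(A) < 0.95


def test_step_halving_convergence(lccm_model, five_tone_train):
    """Halving the integration step changes the waveform by <1e-6 rel RMS."""
    w1 = observe(simulate(lccm_model, five_tone_train, dt=1e-3), lccm_model)
    w2 = observe(simulate(lccm_model, five_tone_train, dt=0.5e-3), lccm_model)
    rel = np.sqrt(np.mean((w1.y - w2.y) ** 2) / np.mean(w2.y**2))
    assert rel < 1e-6


def test_observe_sampling_and_normalization(five_tone_traj, lccm_model):
    wf = observe(five_tone_traj, lccm_model)
    assert wf.fs == 125.0
    assert wf.y.size == 326  # -100..2500 ms at 125 Hz
    wf_n = observe(five_tone_traj, lccm_model, normalize=True)
    assert np.max(np.abs(wf_n.y)) == pytest.approx(1.0)
    # observation is the summed pyramidal depolarization
    manual = five_tone_traj.potential("sPC") + five_tone_traj.potential("dPC")
    np.testing.assert_allclose(wf.y, manual[::8])


def test_large_step_rejected(lccm_model, five_tone_train):
    with pytest.raises(ValueError):
        simulate(lccm_model, five_tone_train, dt=5e-3)


def test_disinhibited_low_gain_response_is_positive_dominated(five_tone_train):
    """Without inhibition and habituation, a positive pulse yields a
    positive-dominated PSP response (no spurious ringing at small coupling)."""
    conns = {}
    for name, spec in default_connections().items():
        C = 0.0 if spec.sign == "inhibitory" else 0.3 * spec.C
        conns[name] = replace(spec, C=C, habituating=False)
    m = build_lccm(include_uncertain=(), params=LCCMParams(connections=conns))
    wf = observe(simulate(m, make_tone_train(1, 0.5)), m)
    assert np.min(wf.y) > -0.05 * np.max(wf.y)


def test_jrm_dimensions_and_fixed_point():
    jrm = build_jrm()
    assert jrm.core_dim == 6
    traj = simulate(jrm, None, t_span=(0.0, 1.0))
    assert np.all(traj.u == 0.0)


def test_jrm_habituation_suppresses_peaks(five_tone_train):
    jrm = build_jrm(JRMParams(habituating=True))
    traj = simulate(jrm, five_tone_train)
    wf = observe(traj, jrm, fs_out=1000.0)
    peaks = tone_peaks(wf, five_tone_train.onsets)
    assert peaks[1] < peaks[0]
    assert traj.pools.shape[1] == 2
    assert np.min(traj.pools) < 1.0

    static = build_jrm()
    traj_s = simulate(static, five_tone_train)
    assert traj_s.pools.shape[1] == 0
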