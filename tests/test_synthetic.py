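import numpy as np
import pytest

from lccm.priors import active_priors, default_lccm_priors
from lccm.inversion import EMOptions
from lccm.synthetic import (
    draw_parameters,
    generate_dataset,
    isi_experiment,
    probe_recovery_experiment,
    recovery_experiment,
    representative_truth,
)


@pytest.fixture(scope="module")
def priors(lccm_model):
    return default_lccm_priors(lccm_model)


def test_dataset_is_bit_exact_reproducible(lccm_model, five_tone_train, priors):
    theta = draw_parameters(priors, seed=3, scale=0.2,
                            subset={"nd:EIN->sPC", "nr:EIN->sPC"})
    a = generate_dataset(theta, lccm_model, five_tone_train, seed=9)
    b = generate_dataset(theta, lccm_model, five_tone_train, seed=9)
    np.testing.assert_array_equal(a.waveform.y, b.waveform.y)
    assert a.truth == b.truth
    c = generate_dataset(theta, lccm_model, five_tone_train, seed=10)
    assert not np.array_equal(a.waveform.y, c.waveform.y)


def test_noise_free_dataset_equals_forward_prediction(noise_free_data, lccm_model,
                                                      five_tone_train):
    data, priors_, predict = noise_free_data
    ds = generate_dataset(np.zeros(47), lccm_model, five_tone_train,
                          noise_sd=0.0, seed=0)
    np.testing.assert_array_equal(ds.waveform.y, predict(np.zeros(47)))
    # pre-stimulus segment is identically zero: the circuit starts at rest
    assert np.all(ds.waveform.y[ds.waveform.t < 0] == 0.0)
    assert ds.truth["C:EIN->sPC"] == 108.0


def test_noise_level_is_calibrated(lccm_model, five_tone_train, priors):
    """Empirical residual sd matches the requested noise sd within 10%."""
    theta = np.zeros(47)
    clean = generate_dataset(theta, lccm_model, five_tone_train,
                             noise_sd=0.0, seed=0).waveform.y
    sds = []
    for seed in range(10):
        noisy = generate_dataset(theta, lccm_model, five_tone_train,
                                 noise_sd=0.05, seed=seed).waveform.y
        sds.append(np.std(noisy - clean))
    assert np.mean(sds) == pytest.approx(0.05, rel=0.10)


def test_draw_parameters_deterministic_and_scaled(priors):
    a = draw_parameters(priors, seed=1)
    b = draw_parameters(priors, seed=1)
    np.testing.assert_array_equal(a, b)
    assert np.all(draw_parameters(priors, seed=1, scale=0.0) == 0.0)
    with pytest.raises(ValueError):
        draw_parameters(priors, seed=1, scale=-1.0)


def test_draw_parameters_match_prior_spread(priors):
    """Monte-Carlo: the sample sd of an uninformative exp-class latent is
    within 3% of sqrt(1/2) over 10^4 draws."""
    act = active_priors(priors)
    i = [p.name for p in act].index("C:EIN->sPC")
    draws = np.array([draw_parameters(priors, seed=s)[i] for s in range(10_000)])
    assert np.std(draws) == pytest.approx(np.sqrt(0.5), rel=0.03)


def test_isi_suppression_ordering():
    table = isi_experiment((0.5, 1.0, 1.5))
    s = table.sort_values("isi_s")["suppression"].to_numpy()
    assert s[0] > s[1] > s[2] > 0
    # monotone non-increasing over the grid
    assert np.all(np.diff(s) < 0)


def test_no_depression_means_no_suppression():
    from lccm.circuits import LCCMParams
    from lccm.plasticity import HabituationParams

    params = LCCMParams(habituation={
        name: HabituationParams(n_depress=0.0)
        for name in ("C2", "C3", "C5", "C6", "C7", "C8", "C9", "C12", "C14")
    })
    table = isi_experiment((0.5,), params=params)
    # residual ~3e-5 comes from overlapping response tails, not habituation
    assert table["suppression"].iloc[0] == pytest.approx(0.0, abs=1e-3)


def test_probe_recovery_scan_monotone():
    df, recovered = probe_recovery_experiment(silences=np.array([0.5, 1.0, 2.0, 4.0]))
    ratios = df["probe_to_first"].to_numpy()
    assert np.all(np.diff(ratios) > 0)  # longer silence, fuller recovery
    assert ratios[-1] == pytest.approx(1.0, abs=0.01)


def test_recovery_experiment_reports_calibrated_summaries():
    """A short noise-free recovery run produces the per-parameter report
    with near-zero bias for the strongly driven habituation rates."""
    summary = recovery_experiment(
        n_reps=1, noise_sd=0.0, seeds=[4], scale=0.2,
        subset={"nd:EIN->sPC", "nr:EIN->sPC"},
        opts=EMOptions(max_iter=12, tol=1e-3),
    )
    assert set(summary.columns) == {"bias", "rmse", "coverage90", "n"}
    assert set(summary.index) == {"nd:EIN->sPC", "nr:EIN->sPC"}
    raw = summary.attrs["raw"]
    # the dominant layer-4 -> layers-2/3 connection is well identified:
    # noise-free estimates land within 15% of the truth
    for _, row in raw.iterrows():
        assert row["estimate"] == pytest.approx(row["truth"], rel=0.15)
        assert 0.0 <= summary.loc[row["parameter"], "coverage90"] <= 1.0


def test_representative_truth_adds_cross_laminar_edges():
    params = representative_truth()
    assert params.connections["C8"].C > 0
    assert params.connections["C11"].C > 0
    assert params.connections["C6"].C == 0.0
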