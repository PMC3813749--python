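import numpy as np
import pytest

from lccm.inversion import (
    EMOptions,
    Posterior,
    _fd_jacobian,
    connection_nonzero,
    em_gauss_newton,
    is_strong_evidence,
    laplace_free_energy,
    log_bayes_factor,
)
from lccm.priors import SHRINKAGE_VAR, UNINFORMATIVE_VAR, PriorSpec


def _linear_problem(seed=0, n=60, p=4, lam=0.05):
    rng = np.random.default_rng(seed)
    A = rng.standard_normal((n, p))
    theta = rng.standard_normal(p)
    y = A @ theta + np.sqrt(lam) * rng.standard_normal(n)
    prior_var = rng.uniform(0.5, 2.0, p)
    return A, y, prior_var, lam


def test_linear_model_matches_conjugate_posterior():
    """With a linear forward model and fixed noise the EM posterior must
    equal the analytic conjugate Gaussian posterior."""
    A, y, prior_var, lam = _linear_problem()
    post = em_gauss_newton(y, lambda th: A @ th, prior_var,
                           EMOptions(lam=lam, tol=1e-12))
    Sigma = np.linalg.inv(A.T @ A / lam + np.diag(1.0 / prior_var))
    mu = Sigma @ (A.T @ y / lam)
    np.testing.assert_allclose(post.eta, mu, atol=1e-8)
    np.testing.assert_allclose(post.Sigma, Sigma, atol=1e-8)


def test_zero_iterations_returns_prior_mean():
    A, y, prior_var, lam = _linear_problem()
    post = em_gauss_newton(y, lambda th: A @ th, prior_var, EMOptions(max_iter=0))
    np.testing.assert_array_equal(post.eta, np.zeros(prior_var.size))
    np.testing.assert_array_equal(post.Sigma, np.diag(prior_var))


def test_reml_estimates_noise_variance():
    A, y, prior_var, lam = _linear_problem(seed=3, n=400, lam=0.2)
    post = em_gauss_newton(y, lambda th: A @ th, prior_var, EMOptions(tol=1e-10))
    assert post.lam == pytest.approx(lam, rel=0.3)


def test_posterior_variance_shrinks_with_informative_data():
    A, y, prior_var, lam = _linear_problem()
    post = em_gauss_newton(y, lambda th: A @ th, prior_var, EMOptions(lam=lam))
    assert np.trace(post.Sigma) < np.sum(prior_var)


def test_fd_jacobian_matches_analytic():
    def h(th):
        return np.array([np.sin(th[0]), th[0] * th[1], np.exp(th[1])])

    th0 = np.array([0.3, -0.7])
    J = _fd_jacobian(h, th0, 1e-4)
    J_true = np.array([
        [np.cos(th0[0]), 0.0],
        [th0[1], th0[0]],
        [0.0, np.exp(th0[1])],
    ])
    np.testing.assert_allclose(J, J_true, atol=1e-7)


def test_complexity_penalty_in_free_energy():
    """At identical fit and noise, a model with an extra free parameter held
    away from its prior mean pays exactly eta^2 / (2 var) in evidence."""
    rng = np.random.default_rng(5)
    r = 0.1 * rng.standard_normal(40)
    lam = 0.1
    eta1 = np.array([0.8])
    var1 = np.array([1.0])
    Sig1 = np.array([[0.2]])
    F1 = laplace_free_energy(r, lam, eta1, var1, Sig1)
    # append a parameter with eta = 2, prior var 1, posterior var = prior var
    # (no information gained about it): complexity grows by 2^2 / 2 = 2
    eta2 = np.array([0.8, 2.0])
    var2 = np.array([1.0, 1.0])
    Sig2 = np.diag([0.2, 1.0])
    F2 = laplace_free_energy(r, lam, eta2, var2, Sig2)
    assert F2 < F1
    assert F1 - F2 == pytest.approx(2.0, abs=1e-10)
    # an extra parameter resting at its prior mean costs nothing
    eta3 = np.array([0.8, 0.0])
    F3 = laplace_free_energy(r, lam, eta3, var2, Sig2)
    assert F3 == pytest.approx(F1, abs=1e-10)


def test_free_energy_requires_valid_covariance():
    with pytest.raises(np.linalg.LinAlgError):
        laplace_free_energy(np.zeros(3), 1.0, np.zeros(1), np.ones(1),
                            np.array([[-1.0]]))


def test_bayes_factor_conventions():
    assert log_bayes_factor(10.0, 7.0) == 3.0
    assert log_bayes_factor(7.0, 10.0) == -3.0
    assert is_strong_evidence(3.0)
    assert not is_strong_evidence(2.999)
    assert not is_strong_evidence(0.0)


def _posterior_with(eta, sd, reparam="square"):
    var = SHRINKAGE_VAR if reparam == "square" else UNINFORMATIVE_VAR
    priors = [PriorSpec("C:EIN->dPC", 0.0 if reparam == "square" else 1.0,
                        reparam, var)]
    return Posterior(eta=np.array([eta]), Sigma=np.array([[sd**2]]), F=0.0,
                     lam=1.0, n_iter=1, converged=True, priors=priors)


def test_connection_nonzero_decision_quantile():
    """One-sided 10% tail: |eta|/sd must exceed the 90% normal quantile."""
    assert connection_nonzero(_posterior_with(2.0, 1.0), "EIN->dPC")
    assert not connection_nonzero(_posterior_with(1.0, 1.0), "EIN->dPC")
    assert not connection_nonzero(_posterior_with(0.0, 1.0), "EIN->dPC")
    # threshold sits between 1.28 and 1.29
    assert connection_nonzero(_posterior_with(1.29, 1.0), "EIN->dPC")
    assert not connection_nonzero(_posterior_with(1.28, 1.0), "C:EIN->dPC")


def test_connection_nonzero_rejects_non_shrinkage():
    with pytest.raises(ValueError):
        connection_nonzero(_posterior_with(2.0, 1.0, reparam="exp"), "EIN->dPC")
    with pytest.raises(KeyError):
        connection_nonzero(_posterior_with(2.0, 1.0), "no-such-edge")


def test_forward_map_taylor_consistency(noise_free_data):
    """A small latent perturbation changes the waveform as the
    finite-difference Jacobian predicts (first-order Taylor check)."""
    data, priors, predict = noise_free_data
    theta0 = np.zeros(47)
    J = _fd_jacobian(predict, theta0, 1e-3)
    rng = np.random.default_rng(11)
    d = 1e-3 * rng.standard_normal(47)
    lhs = predict(theta0 + d) - predict(theta0)
    rhs = J @ d
    denom = np.linalg.norm(lhs)
    assert denom > 0
    assert np.linalg.norm(lhs - rhs) / denom < 5e-3
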