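"""GP machinery against dense brute-force linear-algebra oracles."""

import numpy as np
import pytest

from rxngp import gp_core
from rxngp.gp_core import (classify_probability, default_gp_hypers,
                           kernel_matrix, log_joint_predictive, nlml,
                           predictive_posterior)

LOG_2PI = np.log(2 * np.pi)


# ---------------------------------------------------------------------------
# independent dense oracles (explicit inverse / determinant / conditionals)
# ---------------------------------------------------------------------------

def dense_nlml(theta, Z, y, kernel="rbf"):
    n = len(y)
    K = kernel_matrix(theta, Z, Z, kernel=kernel) + np.exp(theta[2]) * np.eye(n)
    Kinv = np.linalg.inv(K)
    sign, logdet = np.linalg.slogdet(K)
    assert sign > 0
    return 0.5 * (y @ Kinv @ y + logdet + n * LOG_2PI)


def dense_conditional(theta, Zs, ys, Zq, kernel="rbf"):
    noise = np.exp(theta[2])
    os_ = np.exp(theta[1])
    Kss = kernel_matrix(theta, Zs, Zs, kernel=kernel) + noise * np.eye(len(ys))
    Kqs = kernel_matrix(theta, Zq, Zs, kernel=kernel)
    Kqq = kernel_matrix(theta, Zq, Zq, kernel=kernel) + noise * np.eye(Zq.shape[0])
    Kinv = np.linalg.inv(Kss)
    mean = Kqs @ Kinv @ ys
    cov = Kqq - Kqs @ Kinv @ Kqs.T
    assert np.allclose(np.diag(kernel_matrix(theta, Zq, Zq, kernel=kernel)), os_)
    return mean, np.diag(cov)


def _random_instance(rng, n, d=3):
    Z = rng.normal(size=(n, d))
    y = rng.choice([-1.0, 1.0], size=n)
    theta = default_gp_hypers(np.exp(rng.normal(0, 0.3)),
                              np.exp(rng.normal(0, 0.3)),
                              np.exp(rng.normal(-2, 0.3)))
    return theta, Z, y


# ---------------------------------------------------------------------------
# kernel
# ---------------------------------------------------------------------------

@pytest.mark.parametrize("kernel", ["rbf", "matern52"])
def test_kernel_diagonal_equals_outputscale_and_decays(kernel, rng):
    theta = default_gp_hypers(0.7, 2.3, 0.1)
    Z = rng.normal(size=(6, 4))
    K = kernel_matrix(theta, Z, Z, kernel=kernel)
    assert np.allclose(np.diag(K), 2.3)
    assert np.allclose(K, K.T, atol=1e-12)
    far = kernel_matrix(theta, np.zeros((1, 4)), np.full((1, 4), 100.0),
                        kernel=kernel)
    assert far[0, 0] < 1e-8
    eigmin = np.linalg.eigvalsh(K).min()
    assert eigmin > -1e-8


def test_rbf_gram_matches_elementwise_formula(rng):
    theta = default_gp_hypers(0.9, 1.4, 0.05)
    ls, os_ = 0.9, 1.4
    Z1, Z2 = rng.normal(size=(4, 3)), rng.normal(size=(4, 3))
    K = kernel_matrix(theta, Z1, Z2)
    for i in range(4):
        for j in range(4):
            d2 = np.sum((Z1[i] - Z2[j]) ** 2)
            assert K[i, j] == pytest.approx(os_ * np.exp(-0.5 * d2 / ls**2),
                                            abs=1e-10)


def test_kernel_rejects_bad_hyperparameters():
    with pytest.raises(ValueError):
        kernel_matrix(np.array([np.nan, 0.0, 0.0]), np.zeros((2, 2)),
                      np.zeros((2, 2)))


# ---------------------------------------------------------------------------
# nlml
# ---------------------------------------------------------------------------

def test_nlml_univariate_closed_form():
    # k(x,x) + noise = 1 and y = 0: nlml = 0.5 ln(2 pi)
    theta = default_gp_hypers(1.0, 0.5, 0.5)
    v = nlml(theta, np.zeros((1, 2)), np.array([0.0]))
    assert v == pytest.approx(0.5 * LOG_2PI, abs=1e-12)
    assert v == pytest.approx(0.9189385, abs=1e-6)


def test_nlml_permutation_invariant(rng):
    theta, Z, y = _random_instance(rng, 6)
    perm = rng.permutation(6)
    assert nlml(theta, Z, y) == pytest.approx(nlml(theta, Z[perm], y[perm]),
                                              abs=1e-10)


@pytest.mark.parametrize("kernel", ["rbf", "matern52"])
def test_nlml_matches_dense_oracle(kernel, rng):
    for _ in range(100):
        theta, Z, y = _random_instance(rng, int(rng.integers(1, 9)))
        v = nlml(theta, Z, y, kernel=kernel)
        assert v == pytest.approx(dense_nlml(theta, Z, y, kernel=kernel),
                                  abs=1e-8)


@pytest.mark.parametrize("kernel", ["rbf", "matern52"])
def test_nlml_gradients_match_finite_differences(kernel, rng):
    theta, Z, y = _random_instance(rng, 6)
    _, gt, gZ = nlml(theta, Z, y, kernel=kernel, with_grads=True)
    eps = 1e-6
    for i in range(3):
        tp, tm = theta.copy(), theta.copy()
        tp[i] += eps
        tm[i] -= eps
        fd = (nlml(tp, Z, y, kernel=kernel) - nlml(tm, Z, y, kernel=kernel)) / (2 * eps)
        assert gt[i] == pytest.approx(fd, rel=1e-4, abs=1e-7)
    for (i, j) in [(0, 0), (2, 1), (5, 2)]:
        Zp, Zm = Z.copy(), Z.copy()
        Zp[i, j] += eps
        Zm[i, j] -= eps
        fd = (nlml(theta, Zp, y, kernel=kernel) - nlml(theta, Zm, y, kernel=kernel)) / (2 * eps)
        assert gZ[i, j] == pytest.approx(fd, rel=1e-4, abs=1e-7)


# ---------------------------------------------------------------------------
# predictive posterior
# ---------------------------------------------------------------------------

def test_empty_support_returns_prior(rng):
    theta = default_gp_hypers(1.0, 1.5, 0.2)
    post = predictive_posterior(theta, None, None, rng.normal(size=(4, 3)))
    assert np.allclose(post.mean, 0.0)
    assert np.allclose(post.variance, 1.5 + 0.2)
    assert np.allclose(post.probability, 0.5)


def test_interpolation_limit_noise_to_zero():
    theta = default_gp_hypers(1.0, 1.0, 1e-9)
    Zs = np.array([[0.0, 0.0], [2.0, 1.0]])
    ys = np.array([1.0, -1.0])
    post = predictive_posterior(theta, Zs, ys, Zs[:1])
    assert post.mean[0] == pytest.approx(1.0, abs=1e-6)
    assert post.variance[0] < 1e-6


def test_posterior_matches_dense_oracle(rng):
    for _ in range(50):
        theta, Zs, ys = _random_instance(rng, 4)
        Zq = rng.normal(size=(3, 3))
        post = predictive_posterior(theta, Zs, ys, Zq)
        mean, var = dense_conditional(theta, Zs, ys, Zq)
        assert np.allclose(post.mean, mean, atol=1e-8)
        assert np.allclose(post.variance, var, atol=1e-8)


# ---------------------------------------------------------------------------
# joint predictive density
# ---------------------------------------------------------------------------

def test_joint_predictive_single_point_is_univariate_density(rng):
    theta, Zs, ys = _random_instance(rng, 5)
    Zq = rng.normal(size=(1, 3))
    yq = np.array([1.0])
    post = predictive_posterior(theta, Zs, ys, Zq)
    expected = (-0.5 * np.log(2 * np.pi * post.variance[0])
                - 0.5 * (yq[0] - post.mean[0]) ** 2 / post.variance[0])
    assert log_joint_predictive(theta, Zs, ys, Zq, yq) == pytest.approx(
        expected, abs=1e-8)


def test_chain_rule_identity(rng):
    for _ in range(100):
        theta, Z, y = _random_instance(rng, int(rng.integers(3, 9)))
        ns = int(rng.integers(1, len(y)))
        lhs = log_joint_predictive(theta, Z[:ns], y[:ns], Z[ns:], y[ns:])
        rhs = -dense_nlml(theta, Z, y) + dense_nlml(theta, Z[:ns], y[:ns])
        assert lhs == pytest.approx(rhs, abs=1e-8)


def test_joint_predictive_empty_support_is_prior_density(rng):
    theta, Z, y = _random_instance(rng, 4)
    assert log_joint_predictive(theta, None, None, Z, y) == pytest.approx(
        -nlml(theta, Z, y), abs=1e-10)


# ---------------------------------------------------------------------------
# classification link
# ---------------------------------------------------------------------------

def test_classify_probability_properties():
    assert classify_probability(0.0, 1.0) == pytest.approx(0.5)
    assert classify_probability(50.0, 1.0) > 0.999
    means = np.linspace(-3, 3, 13)
    p = classify_probability(means, np.full_like(means, 0.7))
    assert np.all(np.diff(p) > 0)
    with pytest.raises(ValueError):
        classify_probability(0.0, -1.0)


def test_relabeling_symmetry(rng):
    """Negating all support labels negates the mean and flips p -> 1-p."""
    theta, Zs, ys = _random_instance(rng, 5)
    Zq = rng.normal(size=(4, 3))
    post = predictive_posterior(theta, Zs, ys, Zq)
    flipped = predictive_posterior(theta, Zs, -ys, Zq)
    assert np.allclose(flipped.mean, -post.mean, atol=1e-10)
    assert np.allclose(flipped.probability, 1.0 - post.probability, atol=1e-10)


def test_fit_gp_hypers_improves_nlml(rng):
    theta, Z, y = _random_instance(rng, 30)
    theta0 = default_gp_hypers()
    theta_hat = gp_core.fit_gp_hypers(Z, y, theta0)
    assert nlml(theta_hat, Z, y) <= nlml(theta0, Z, y) + 1e-9
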