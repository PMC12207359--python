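"""Deep kernel Gaussian-process machinery.

This module is the shared numerical substrate for all deep kernel models
in the package: the base kernel (RBF or Matern-5/2) evaluated on latent
embeddings, the exact Gaussian-process negative log marginal likelihood
(NLML), the predictive posterior, the joint predictive log density of a
query set given a support set, and the squashing link that turns a
Gaussian posterior over a +/-1 regression target into a class probability.

Conventions
-----------
* Binary classification is carried out as GP *label regression* on
  targets in {-1, +1} with a Gaussian likelihood, so the marginal
  likelihood and all conditionals are available in closed form.  Class
  probabilities are obtained by probit-style squashing of the predictive
  Gaussian (see :func:`classify_probability`).
* GP hyperparameters are a 3-vector ``theta_gp`` stored in log-space:
  ``[log lengthscale, log outputscale, log noise_variance]``.  Anything
  constrained positive is therefore unconstrained during optimisation.
* All solves go through a Cholesky factorisation.  When the factorisation
  fails, diagonal jitter ``1e-6 * outputscale`` is added and escalated
  tenfold at most ``MAX_JITTER_TRIES`` times before a conditioning error
  is raised.

Gradients of the NLML with respect to the hyperparameters *and* with
respect to the latent embeddings are computed analytically; the latter is
what lets a NumPy feature extractor be trained by backpropagation through
the GP objective.
"""

from __future__ import annotations

from dataclasses import dataclass

import numpy as np
from scipy.linalg import cho_solve, cholesky, solve_triangular
from scipy.optimize import minimize
from scipy.special import expit

__all__ = [
    "GPPosterior",
    "default_gp_hypers",
    "kernel_matrix",
    "nlml",
    "predictive_posterior",
    "log_joint_predictive",
    "classify_probability",
    "fit_gp_hypers",
]

LOG_2PI = float(np.log(2.0 * np.pi))

#: maximum number of jitter escalations before giving up on a Cholesky
MAX_JITTER_TRIES = 3

_KERNELS = ("rbf", "matern52")


class ConditioningError(np.linalg.LinAlgError):
    """Raised when a covariance matrix stays indefinite after jitter."""


@dataclass(frozen=True)
class GPPosterior:
    """Predictive posterior at a batch of query points.

    Attributes
    ----------
    mean : ndarray, shape (m,)
        Predictive mean of the +/-1 regression target.
    variance : ndarray, shape (m,)
        Predictive variance (latent variance plus observation noise).
    probability : ndarray, shape (m,)
        Class-1 probability obtained by squashing ``mean``/``variance``.
    """

    mean: np.ndarray
    variance: np.ndarray
    probability: np.ndarray


def default_gp_hypers(lengthscale: float = 1.0, outputscale: float = 1.0,
                      noise: float = 0.1) -> np.ndarray:
    """Return log-space hyperparameters ``[log ls, log os, log noise_var]``."""
    return np.log(np.asarray([lengthscale, outputscale, noise], dtype=float))


def _check_hypers(theta_gp: np.ndarray) -> np.ndarray:
    theta_gp = np.asarray(theta_gp, dtype=float).ravel()
    if theta_gp.shape != (3,):
        raise ValueError("theta_gp must be a 3-vector "
                         "[log lengthscale, log outputscale, log noise]")
    if not np.all(np.isfinite(theta_gp)):
        raise ValueError("non-finite GP hyperparameters")
    return theta_gp


def _sq_dists(Z1: np.ndarray, Z2: np.ndarray) -> np.ndarray:
    d2 = (np.sum(Z1 * Z1, axis=1)[:, None]
          + np.sum(Z2 * Z2, axis=1)[None, :]
          - 2.0 * Z1 @ Z2.T)
    return np.maximum(d2, 0.0)


def kernel_matrix(theta_gp: np.ndarray, Z1: np.ndarray, Z2: np.ndarray,
                  kernel: str = "rbf") -> np.ndarray:
    """Noise-free Gram matrix ``k(Z1, Z2)`` of the base kernel.

    ``k(z, z) = outputscale`` for both kernel choices and the kernel
    decays to zero as the latent distance grows.
    """
    theta_gp = _check_hypers(theta_gp)
    Z1 = np.atleast_2d(np.asarray(Z1, dtype=float))
    Z2 = np.atleast_2d(np.asarray(Z2, dtype=float))
    ls, os_ = np.exp(theta_gp[0]), np.exp(theta_gp[1])
    d2 = _sq_dists(Z1, Z2)
    if kernel == "rbf":
        return os_ * np.exp(-0.5 * d2 / ls**2)
    if kernel == "matern52":
        a = np.sqrt(5.0) * np.sqrt(d2) / ls
        return os_ * (1.0 + a + a * a / 3.0) * np.exp(-a)
    raise ValueError(f"unknown kernel {kernel!r}; choose from {_KERNELS}")


def _chol_with_jitter(K: np.ndarray, outputscale: float):
    """Lower Cholesky of ``K`` with escalating diagonal jitter."""
    jitter = 0.0
    for attempt in range(MAX_JITTER_TRIES + 1):
        try:
            L = cholesky(K + jitter * np.eye(K.shape[0]), lower=True)
            return L, jitter
        except np.linalg.LinAlgError:
            jitter = 1e-6 * outputscale * 10.0**attempt
    cond = np.linalg.cond(K)
    raise ConditioningError(
        f"covariance not positive definite after jitter up to {jitter:.2e} "
        f"(condition number ~ {cond:.2e})")


def _nlml_impl(theta_gp, Z, y, kernel, want_grads):
    """NLML value and, optionally, gradients w.r.t. theta_gp and Z."""
    theta_gp = _check_hypers(theta_gp)
    Z = np.atleast_2d(np.asarray(Z, dtype=float))
    y = np.asarray(y, dtype=float).ravel()
    n = Z.shape[0]
    if y.shape[0] != n:
        raise ValueError("y length must match rows of Z")
    if n < 1:
        raise ValueError("need at least one observation")
    if not np.all(np.isfinite(Z)) or not np.all(np.isfinite(y)):
        raise ValueError("non-finite inputs to nlml")

    ls, os_, noise = np.exp(theta_gp)
    Ks = kernel_matrix(theta_gp, Z, Z, kernel=kernel)
    K = Ks + noise * np.eye(n)
    L, _ = _chol_with_jitter(K, os_)
    alpha = cho_solve((L, True), y)
    value = (0.5 * float(y @ alpha)
             + float(np.sum(np.log(np.diag(L))))
             + 0.5 * n * LOG_2PI)
    if not want_grads:
        return value, None, None

    Kinv = cho_solve((L, True), np.eye(n))
    # dNLML/dK for a zero-mean Gaussian
    G = 0.5 * (Kinv - np.outer(alpha, alpha))

    grad_theta = np.empty(3)
    d2 = _sq_dists(Z, Z)
    if kernel == "rbf":
        # dK/dlog ls = Ks * d2 / ls^2 ; dK/dlog os = Ks
        grad_theta[0] = float(np.sum(G * Ks * d2) / ls**2)
        grad_theta[1] = float(np.sum(G * Ks))
        # dL/dz_i via B = G o Ks (symmetric)
        B = G * Ks
        grad_Z = (2.0 / ls**2) * (B @ Z - np.sum(B, axis=1)[:, None] * Z)
    else:  # matern52
        r = np.sqrt(d2)
        a = np.sqrt(5.0) * r / ls
        ea = np.exp(-a)
        # k = os (1 + a + a^2/3) e^{-a}; dk/da = -os (a/3)(1+a) e^{-a}
        dk_da = -os_ * (a / 3.0) * (1.0 + a) * ea
        grad_theta[0] = float(np.sum(G * dk_da * (-a)))       # da/dlog ls = -a
        grad_theta[1] = float(np.sum(G * Ks))
        # da/dz_i = sqrt5/ls * (z_i - z_j)/r  (0 at r = 0 since dk/da ~ a)
        with np.errstate(divide="ignore", invalid="ignore"):
            W = np.where(r > 0, G * dk_da * np.sqrt(5.0) / (ls * r), 0.0)
        grad_Z = 2.0 * (np.sum(W, axis=1)[:, None] * Z - W @ Z)
    grad_theta[2] = float(np.trace(G) * noise)
    return value, grad_theta, grad_Z


def nlml(theta_gp: np.ndarray, Z: np.ndarray, y: np.ndarray,
         kernel: str = "rbf", with_grads: bool = False):
    """Negative log marginal likelihood ``-log N(y | 0, K + noise I)``.

    Parameters
    ----------
    theta_gp : 3-vector of log hyperparameters.
    Z : (n, d) latent embeddings.
    y : (n,) regression targets (+/-1 labels for classification).
    with_grads : if True, also return ``(grad_theta, grad_Z)``.
    """
    value, gt, gz = _nlml_impl(theta_gp, Z, y, kernel, with_grads)
    if with_grads:
        return value, gt, gz
    return value


def predictive_posterior(theta_gp: np.ndarray, Zs: np.ndarray, ys: np.ndarray,
                         Zq: np.ndarray, kernel: str = "rbf") -> GPPosterior:
    """Exact GP conditional at query embeddings given support observations.

    With an empty support the prior is returned: mean 0 and variance
    ``outputscale + noise`` at every query point.  The reported variance
    is the predictive variance of the observed target, i.e. it includes
    the noise term.
    """
    theta_gp = _check_hypers(theta_gp)
    Zq = np.atleast_2d(np.asarray(Zq, dtype=float))
    _, os_, noise = np.exp(theta_gp)
    m = Zq.shape[0]
    if Zs is None or np.size(Zs) == 0:
        mean = np.zeros(m)
        var = np.full(m, os_ + noise)
        return GPPosterior(mean, var, classify_probability(mean, var))
    Zs = np.atleast_2d(np.asarray(Zs, dtype=float))
    ys = np.asarray(ys, dtype=float).ravel()
    n = Zs.shape[0]
    Kss = kernel_matrix(theta_gp, Zs, Zs, kernel=kernel) + noise * np.eye(n)
    L, _ = _chol_with_jitter(Kss, os_)
    Kqs = kernel_matrix(theta_gp, Zq, Zs, kernel=kernel)
    alpha = cho_solve((L, True), ys)
    mean = Kqs @ alpha
    V = solve_triangular(L, Kqs.T, lower=True)
    var = os_ + noise - np.sum(V * V, axis=0)
    var = np.maximum(var, 1e-12)
    return GPPosterior(mean, var, classify_probability(mean, var))


def log_joint_predictive(theta_gp: np.ndarray, Zs, ys, Zq, yq,
                         kernel: str = "rbf", with_grads: bool = False):
    """Log joint predictive density ``log p(y_Q | y_S)``.

    Computed through the chain-rule identity
    ``log p(y_Q | y_S) = log p(y_{S u Q}) - log p(y_S)``, which also makes
    the gradients a difference of two NLML gradients.  With an empty
    support this reduces to the joint prior density of the query labels.

    Returns ``value`` or ``(value, grad_theta, grad_Zs, grad_Zq)``.
    """
    Zq = np.atleast_2d(np.asarray(Zq, dtype=float))
    yq = np.asarray(yq, dtype=float).ravel()
    if Zq.shape[0] == 0:
        raise ValueError("query set must be non-empty")
    empty_support = Zs is None or np.size(Zs) == 0
    if empty_support:
        v, gt, gz = _nlml_impl(theta_gp, Zq, yq, kernel, with_grads)
        if with_grads:
            return -v, -gt, np.zeros((0, Zq.shape[1])), -gz
        return -v
    Zs = np.atleast_2d(np.asarray(Zs, dtype=float))
    ys = np.asarray(ys, dtype=float).ravel()
    n = Zs.shape[0]
    Zsq = np.vstack([Zs, Zq])
    ysq = np.concatenate([ys, yq])
    v_sq, gt_sq, gz_sq = _nlml_impl(theta_gp, Zsq, ysq, kernel, with_grads)
    v_s, gt_s, gz_s = _nlml_impl(theta_gp, Zs, ys, kernel, with_grads)
    value = -(v_sq - v_s)
    if not with_grads:
        return value
    grad_theta = -(gt_sq - gt_s)
    grad_Zs = -(gz_sq[:n] - gz_s)
    grad_Zq = -gz_sq[n:]
    return value, grad_theta, grad_Zs, grad_Zq


def classify_probability(mean, variance):
    """Map a predictive Gaussian over a +/-1 target to a class-1 probability.

    Uses the moderated logistic link ``p = expit(mean / sqrt(1 + var))``:
    monotone in the mean, shrunk toward 1/2 by predictive uncertainty,
    and exactly 1/2 at mean zero.
    """
    mean = np.asarray(mean, dtype=float)
    variance = np.asarray(variance, dtype=float)
    if np.any(variance <= 0):
        raise ValueError("predictive variance must be positive")
    return expit(mean / np.sqrt(1.0 + variance))


def fit_gp_hypers(Z: np.ndarray, y: np.ndarray, theta0: np.ndarray | None = None,
                  kernel: str = "rbf", maxiter: int = 200) -> np.ndarray:
    """Type-II maximum likelihood for the base-kernel hyperparameters.

    Minimises the exact NLML over the three log hyperparameters with
    L-BFGS-B using analytic gradients; the feature map is held fixed
    (``Z`` are the embeddings).  This is the single-task DKL path for an
    identity extractor and the refit step used by model inspection.
    """
    if theta0 is None:
        theta0 = default_gp_hypers()

    def obj(h):
        v, gt, _ = _nlml_impl(h, Z, y, kernel, True)
        return v, gt

    res = minimize(obj, np.asarray(theta0, dtype=float), jac=True,
                   method="L-BFGS-B",
                   bounds=[(-8.0, 8.0)] * 3,
                   options={"maxiter": maxiter})
    return res.x
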