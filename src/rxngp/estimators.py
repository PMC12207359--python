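"""Meta-learning estimators for few-shot reaction-outcome classification.

All models share one design: a neural feature extractor f(x; theta_NN)
feeds a GP base kernel k'(., .; theta_GP), giving the deep kernel
k(x, x') = k'(f(x), f(x')).  Binary labels are regressed as +/-1 targets
under a Gaussian likelihood so every training objective is available in
closed form.  The estimators differ in *which* parameters are shared
across tasks and which are adapted per task:

``DeepKernelGPClassifier`` (DKL)
    Single-task baseline: (theta_NN, theta_GP) fit jointly by minimising
    the GP negative log marginal likelihood (NLML) on one dataset.
``DKTClassifier`` (deep kernel transfer)
    One shared (theta_NN, theta_GP) fit by the expected NLML over
    episodes sampled from the training tasks; at test time the GP is
    conditioned on the support set with no parameter adaptation.
``ADKFClassifier`` (adaptive deep kernel fitting)
    Bilevel: theta_GP is re-fit on each task's support NLML (inner
    loop); theta_NN is meta-learned by the negative log joint predictive
    posterior of the query given the support (outer loop, first-order
    gradients).
``ADKFPriorClassifier``
    Places a Gaussian prior N(phi, sigma^2 I) over theta_NN.  Both
    theta_GP and theta_NN adapt per task by MAP (support NLML plus the
    Gaussian penalty); the meta-parameters — the prior [phi, sigma^2]
    and the theta_GP initialisation — are learned in the outer loop from
    the query predictive loss, so at test time the whole adaptation
    starts from meta-learned values.
``PrototypicalNetworkClassifier``
    Metric baseline: episodic softmax over negative squared distances to
    class prototypes (support-set class means in embedding space).

Estimators follow scikit-learn conventions (``get_params`` /
``set_params``, ``_``-suffixed fitted attributes, ``random_state``).
Because prediction is few-shot, the central inference API is
``adapt(X_support, y_support) -> predictor`` followed by
``predictor.predict_proba(X_query)``.
"""

from __future__ import annotations

import warnings
from dataclasses import dataclass

import numpy as np
from sklearn.base import BaseEstimator
from sklearn.utils.validation import check_array, check_is_fitted, check_X_y

from . import gp_core
from .evaluate import auprc
from .gp_core import (default_gp_hypers, log_joint_predictive, nlml,
                      predictive_posterior)
from .nn import make_extractor
from .tasks import Episode, Task, sample_episode

__all__ = [
    "AdaptState",
    "FewShotGPPredictor",
    "PrototypePredictor",
    "DeepKernelGPClassifier",
    "DKTClassifier",
    "ADKFClassifier",
    "ADKFPriorClassifier",
    "PrototypicalNetworkClassifier",
    "meta_test",
    "train_dkl_single_task",
    "train_dkt",
    "train_adkf",
    "train_adkf_prior",
    "train_protonet",
]

_SEED_MAX = 2**31 - 1


def _to_targets(y):
    """Map {0,1} labels to {-1,+1} regression targets."""
    y = np.asarray(y).ravel()
    if not np.isin(y, (0, 1)).all():
        raise ValueError("labels must be binary 0/1")
    return 2.0 * y - 1.0


@dataclass
class AdaptState:
    """Record of one inner-loop (task-specific) adaptation."""

    inner_steps: int
    initial_inner_loss: float
    final_inner_loss: float
    single_class_support: bool = False


class _Adam:
    """Plain Adam over a flat parameter vector."""

    def __init__(self, n, lr=0.01, beta1=0.9, beta2=0.999, eps=1e-8):
        self.lr, self.b1, self.b2, self.eps = lr, beta1, beta2, eps
        self.m = np.zeros(n)
        self.v = np.zeros(n)
        self.t = 0

    def step(self, x, g):
        self.t += 1
        self.m = self.b1 * self.m + (1 - self.b1) * g
        self.v = self.b2 * self.v + (1 - self.b2) * g * g
        mhat = self.m / (1 - self.b1**self.t)
        vhat = self.v / (1 - self.b2**self.t)
        return x - self.lr * mhat / (np.sqrt(vhat) + self.eps)


def _block_adapt(extractor, w0, h0, Xs, ts, *, adapt_nn, phi=None, sigma2=None,
                 n_steps=50, lr_h=0.1, lr_w=0.05, tol=1e-5, max_backtracks=8,
                 kernel="rbf"):
    """Inner-loop MAP adaptation by block gradient descent with backtracking.

    Each iteration takes one backtracking step on theta_GP and — when
    ``adapt_nn`` — one on theta_NN under the Gaussian penalty
    ||w - phi||^2 / (2 sigma^2).  Steps that do not decrease the
    objective are rejected, so the inner loss is non-increasing; the loop
    stops early once an iteration improves the loss by less than ``tol``.
    With ``adapt_nn=False`` this is exactly the ADKF inner loop (GP
    hyperparameters only).
    """
    h, w = np.array(h0, dtype=float), np.array(w0, dtype=float)

    def penalty(wv):
        if not adapt_nn or sigma2 is None:
            return 0.0
        d = wv - phi
        return float(d @ d) / (2.0 * sigma2)

    def total_loss(hv, wv):
        Z = extractor.forward(wv, Xs)
        return nlml(hv, Z, ts, kernel=kernel) + penalty(wv)

    f = total_loss(h, w)
    f0 = f
    steps_done = 0
    for _ in range(n_steps):
        f_iter_start = f
        # --- theta_GP step ---
        _, gh, _ = gp_core._nlml_impl(h, extractor.forward(w, Xs), ts, kernel, True)
        lr = lr_h
        for _bt in range(max_backtracks):
            h_try = h - lr * gh
            f_try = total_loss(h_try, w)
            if np.isfinite(f_try) and f_try <= f:
                h, f = h_try, f_try
                break
            lr *= 0.5
        # --- theta_NN step (MAP under the Gaussian prior) ---
        if adapt_nn and extractor.n_params:
            Z, cache = extractor.forward_with_cache(w, Xs)
            _, _, gZ = gp_core._nlml_impl(h, Z, ts, kernel, True)
            gw, _ = extractor.backward(cache, gZ)
            if sigma2 is not None:
                gw = gw + (w - phi) / sigma2
            lr = lr_w
            for _bt in range(max_backtracks):
                w_try = w - lr * gw
                f_try = total_loss(h, w_try)
                if np.isfinite(f_try) and f_try <= f:
                    w, f = w_try, f_try
                    break
                lr *= 0.5
        steps_done += 1
        if f_iter_start - f < tol:
            break
    return h, w, AdaptState(steps_done, float(f0), float(f))


class FewShotGPPredictor:
    """A deep kernel GP conditioned on a support set, ready to predict."""

    def __init__(self, extractor, w, theta_gp, Xs, ys, kernel="rbf",
                 adapt_state: AdaptState | None = None):
        self.extractor = extractor
        self.w = np.asarray(w, dtype=float)
        self.theta_gp = np.asarray(theta_gp, dtype=float)
        self.kernel = kernel
        self.adapt_state = adapt_state
        self._Zs = extractor.forward(w, Xs) if np.size(Xs) else np.zeros((0, 1))
        self._ts = _to_targets(ys) if np.size(ys) else np.zeros(0)

    def posterior(self, X):
        Zq = self.extractor.forward(self.w, np.atleast_2d(X))
        return predictive_posterior(self.theta_gp, self._Zs, self._ts, Zq,
                                    kernel=self.kernel)

    def predict_proba(self, X):
        p1 = self.posterior(X).probability
        return np.column_stack([1.0 - p1, p1])

    def predict(self, X):
        return (self.predict_proba(X)[:, 1] >= 0.5).astype(int)


class PrototypePredictor:
    """Nearest-class-prototype classifier in the learned embedding space."""

    def __init__(self, extractor, w, Xs, ys):
        self.extractor = extractor
        self.w = np.asarray(w, dtype=float)
        ys = np.asarray(ys).ravel().astype(int)
        Zs = extractor.forward(w, Xs)
        if not {0, 1} <= set(ys.tolist()):
            raise ValueError("prototype computation needs both classes in support")
        self.prototypes = np.stack([Zs[ys == c].mean(axis=0) for c in (0, 1)])
        self.adapt_state = AdaptState(0, 0.0, 0.0)

    def predict_proba(self, X):
        Z = self.extractor.forward(self.w, np.atleast_2d(X))
        d2 = ((Z[:, None, :] - self.prototypes[None, :, :]) ** 2).sum(axis=2)
        logits = -d2
        logits -= logits.max(axis=1, keepdims=True)
        e = np.exp(logits)
        return e / e.sum(axis=1, keepdims=True)

    def predict(self, X):
        return np.argmax(self.predict_proba(X), axis=1)


class _BaseDeepKernelEstimator(BaseEstimator):
    """Shared hyperparameters and plumbing for the deep kernel models."""

    def __init__(self, hidden_sizes=(256, 128), latent_dim=64,
                 activation="tanh", kernel="rbf", extractor="mlp",
                 learning_rate=0.01, n_iter=200, task_batch_size=5,
                 train_support_size=512, train_query_size=64,
                 inner_steps=50, inner_lr=0.1, inner_lr_nn=0.05,
                 inner_tol=1e-5, lengthscale_init=1.0, outputscale_init=1.0,
                 noise_init=0.1, val_every=50, n_val_episodes=2,
                 stratified=True, random_state=None):
        self.hidden_sizes = hidden_sizes
        self.latent_dim = latent_dim
        self.activation = activation
        self.kernel = kernel
        self.extractor = extractor
        self.learning_rate = learning_rate
        self.n_iter = n_iter
        self.task_batch_size = task_batch_size
        self.train_support_size = train_support_size
        self.train_query_size = train_query_size
        self.inner_steps = inner_steps
        self.inner_lr = inner_lr
        self.inner_lr_nn = inner_lr_nn
        self.inner_tol = inner_tol
        self.lengthscale_init = lengthscale_init
        self.outputscale_init = outputscale_init
        self.noise_init = noise_init
        self.val_every = val_every
        self.n_val_episodes = n_val_episodes
        self.stratified = stratified
        self.random_state = random_state

    # -- shared helpers ----------------------------------------------------
    def _rng(self):
        return np.random.default_rng(self.random_state)

    def _make_extractor(self, n_features):
        return make_extractor(self.extractor, n_features,
                              hidden_sizes=self.hidden_sizes,
                              out_dim=self.latent_dim,
                              activation=self.activation)

    def _theta0(self):
        return default_gp_hypers(self.lengthscale_init, self.outputscale_init,
                                 self.noise_init)

    def _sample_training_episode(self, X, y, task: Task, rng) -> Episode:
        """Support/query episode clipped to the task size."""
        total = len(task)
        s = min(self.train_support_size, max(2, total // 2))
        q = min(self.train_query_size, total - s)
        if q < 1:
            s = total - 1
            q = 1
        for _attempt in range(20):
            seed = int(rng.integers(_SEED_MAX))
            try:
                return sample_episode(task, s, q, seed=seed,
                                      stratified=self.stratified, y=y)
            except ValueError:
                continue
        raise ValueError(f"could not sample a valid episode from {task.task_id}")

    def _validation_score(self, X, y, valid_tasks, val_seeds):
        scores = []
        for task, seed in zip(valid_tasks, val_seeds):
            try:
                ep = self._sample_training_episode(
                    X, y, task, np.random.default_rng(seed))
                pred = self.adapt(X[ep.support], y[ep.support])
                p = pred.predict_proba(X[ep.query])[:, 1]
                if y[ep.query].sum() == 0:
                    continue
                scores.append(auprc(y[ep.query], p))
            except ValueError:
                continue
        return float(np.mean(scores)) if scores else -np.inf

    def _check_fit_inputs(self, X, y, tasks):
        X, y = check_X_y(X, y, dtype=float)
        if not np.isin(y, (0, 1)).all():
            raise ValueError("labels must be binary 0/1")
        if not tasks:
            raise ValueError("need at least one training task")
        for t in tasks:
            if t.indices.max() >= X.shape[0]:
                raise ValueError(f"task {t.task_id} indexes beyond the dataset")
        return X, np.asarray(y).astype(int)

    # -- sklearn niceties ---------------------------------------------------
    def predict_proba(self, X):  # pragma: no cover - convenience guard
        raise AttributeError(
            f"{type(self).__name__} is a few-shot model: call "
            "adapt(X_support, y_support) and predict on the returned object")


# ---------------------------------------------------------------------------
# single-task DKL baseline
# ---------------------------------------------------------------------------

class DeepKernelGPClassifier(_BaseDeepKernelEstimator):
    """Single-task deep kernel learning (DKL) baseline.

    Learns (theta_NN, theta_GP) jointly by gradient-based minimisation of
    the exact GP NLML on one training set, mini-batched when the set is
    larger than ``minibatch_size``.  Prediction conditions the GP on the
    full training data, so the usual ``fit`` / ``predict_proba`` API
    applies.  With ``extractor='identity'`` the model reduces to an exact
    GP whose three hyperparameters are optimised with L-BFGS.
    """

    def __init__(self, minibatch_size=256, hidden_sizes=(256, 128),
                 latent_dim=64, activation="tanh", kernel="rbf",
                 extractor="mlp", learning_rate=0.01, n_iter=200,
                 task_batch_size=5, train_support_size=512,
                 train_query_size=64, inner_steps=50, inner_lr=0.1,
                 inner_lr_nn=0.05, inner_tol=1e-5, lengthscale_init=1.0,
                 outputscale_init=1.0, noise_init=0.1, val_every=50,
                 n_val_episodes=2, stratified=True, random_state=None):
        self.minibatch_size = minibatch_size
        super().__init__(
            hidden_sizes=hidden_sizes, latent_dim=latent_dim,
            activation=activation, kernel=kernel, extractor=extractor,
            learning_rate=learning_rate, n_iter=n_iter,
            task_batch_size=task_batch_size,
            train_support_size=train_support_size,
            train_query_size=train_query_size, inner_steps=inner_steps,
            inner_lr=inner_lr, inner_lr_nn=inner_lr_nn, inner_tol=inner_tol,
            lengthscale_init=lengthscale_init,
            outputscale_init=outputscale_init, noise_init=noise_init,
            val_every=val_every, n_val_episodes=n_val_episodes,
            stratified=stratified, random_state=random_state)

    def fit(self, X, y):
        X, y = check_X_y(X, y, dtype=float)
        if not np.isin(y, (0, 1)).all():
            raise ValueError("labels must be binary 0/1")
        if len(np.unique(y)) < 2:
            raise ValueError("training data must contain both classes")
        t = _to_targets(y)
        rng = self._rng()
        extractor = self._make_extractor(X.shape[1])
        h = self._theta0()
        if extractor.n_params == 0:
            h = gp_core.fit_gp_hypers(X, t, theta0=h, kernel=self.kernel)
            self.history_ = [float(nlml(h, X, t, kernel=self.kernel))]
            w = np.zeros(0)
        else:
            w = extractor.init_params(rng)
            params = np.concatenate([w, h])
            adam = _Adam(params.size, lr=self.learning_rate)
            self.history_ = []
            n = X.shape[0]
            for _ in range(self.n_iter):
                idx = (np.arange(n) if n <= self.minibatch_size
                       else rng.choice(n, size=self.minibatch_size, replace=False))
                w, h = params[:-3], params[-3:]
                Z, cache = extractor.forward_with_cache(w, X[idx])
                v, gt, gZ = nlml(h, Z, t[idx], with_grads=True,
                                 kernel=self.kernel)
                if not np.isfinite(v):
                    raise FloatingPointError("NLML diverged during DKL training")
                dw, _ = extractor.backward(cache, gZ)
                params = adam.step(params, np.concatenate([dw, gt]))
                self.history_.append(float(v))
            w, h = params[:-3], params[-3:]
        self.extractor_ = extractor
        self.theta_nn_ = w
        self.theta_gp_ = h
        self._train_X, self._train_y = X, y
        self.classes_ = np.array([0, 1])
        return self

    def _predictor(self):
        return FewShotGPPredictor(self.extractor_, self.theta_nn_,
                                  self.theta_gp_, self._train_X,
                                  self._train_y, kernel=self.kernel)

    def predict_proba(self, X):
        check_is_fitted(self, "theta_gp_")
        X = check_array(X, dtype=float)
        return self._predictor().predict_proba(X)

    def predict(self, X):
        return (self.predict_proba(X)[:, 1] >= 0.5).astype(int)

    def adapt(self, X_support, y_support):
        """Condition the learned deep kernel GP on a new support set."""
        check_is_fitted(self, "theta_gp_")
        return FewShotGPPredictor(self.extractor_, self.theta_nn_,
                                  self.theta_gp_, X_support, y_support,
                                  kernel=self.kernel)


# ---------------------------------------------------------------------------
# DKT
# ---------------------------------------------------------------------------

def dkt_batch_objective(extractor, w, h, batch, kernel="rbf"):
    """Mean episode NLML over a batch of (X, targets) pairs, with grads.

    This is DKT's per-iteration loss; with a batch of identical copies of
    one dataset it coincides with the single-task DKL objective on that
    dataset.
    """
    total, gh_total = 0.0, np.zeros(3)
    gw_total = np.zeros(extractor.n_params)
    for Xb, tb in batch:
        Z, cache = extractor.forward_with_cache(w, Xb)
        v, gt, gZ = nlml(h, Z, tb, with_grads=True, kernel=kernel)
        dw, _ = extractor.backward(cache, gZ)
        total += v
        gh_total += gt
        gw_total += dw
    k = len(batch)
    return total / k, gw_total / k, gh_total / k


class DKTClassifier(_BaseDeepKernelEstimator):
    """Deep kernel transfer: one shared deep kernel across all tasks.

    Meta-training minimises the expected NLML over episodes sampled from
    batches of ``task_batch_size`` training tasks.  Meta-testing performs
    no parameter adaptation; the GP is simply conditioned on the test
    task's support set.
    """

    def fit(self, X, y, tasks, valid_tasks=None):
        X, y = self._check_fit_inputs(X, y, tasks)
        t = _to_targets(y)
        rng = self._rng()
        extractor = self._make_extractor(X.shape[1])
        w = extractor.init_params(rng)
        h = self._theta0()
        params = np.concatenate([w, h])
        adam = _Adam(params.size, lr=self.learning_rate)
        self.history_ = []
        best = (-np.inf, params.copy())
        val_seeds = [int(rng.integers(_SEED_MAX))
                     for _ in range(len(valid_tasks or []))]
        for it in range(self.n_iter):
            picks = rng.choice(len(tasks), size=self.task_batch_size,
                               replace=len(tasks) < self.task_batch_size)
            batch = []
            for ti in picks:
                ep = self._sample_training_episode(X, y, tasks[ti], rng)
                idx = np.concatenate([ep.support, ep.query])
                batch.append((X[idx], t[idx]))
            w, h = params[:-3], params[-3:]
            v, gw, gh = dkt_batch_objective(extractor, w, h, batch,
                                            kernel=self.kernel)
            if not np.isfinite(v):
                raise FloatingPointError("DKT meta-loss diverged")
            params = adam.step(params, np.concatenate([gw, gh]))
            self.history_.append(float(v))
            if valid_tasks and (it + 1) % self.val_every == 0:
                self.extractor_ = extractor
                self.theta_nn_, self.theta_gp_ = params[:-3], params[-3:]
                score = self._validation_score(X, y, valid_tasks, val_seeds)
                if score > best[0]:
                    best = (score, params.copy())
        if valid_tasks and best[0] > -np.inf:
            params = best[1]
        self.extractor_ = extractor
        self.theta_nn_ = params[:-3]
        self.theta_gp_ = params[-3:]
        self.classes_ = np.array([0, 1])
        return self

    def adapt(self, X_support, y_support):
        """DKT does not adapt parameters: condition the GP and predict."""
        check_is_fitted(self, "theta_gp_")
        return FewShotGPPredictor(self.extractor_, self.theta_nn_,
                                  self.theta_gp_, X_support, y_support,
                                  kernel=self.kernel,
                                  adapt_state=AdaptState(0, 0.0, 0.0))


# ---------------------------------------------------------------------------
# ADKF
# ---------------------------------------------------------------------------

class ADKFClassifier(_BaseDeepKernelEstimator):
    """Adaptive deep kernel fitting with first-order outer gradients.

    Inner loop: theta_GP minimises the support-set NLML (backtracking
    gradient descent from the shared initialisation).  Outer loop:
    theta_NN minimises the mean negative log joint predictive posterior
    of the query labels given the support, with the adapted theta_GP*
    treated as fixed (first-order approximation).
    """

    max_skip_fraction = 0.25

    def fit(self, X, y, tasks, valid_tasks=None):
        X, y = self._check_fit_inputs(X, y, tasks)
        t = _to_targets(y)
        rng = self._rng()
        extractor = self._make_extractor(X.shape[1])
        w = extractor.init_params(rng)
        adam = _Adam(w.size, lr=self.learning_rate)
        self.history_ = []
        best = (-np.inf, w.copy())
        val_seeds = [int(rng.integers(_SEED_MAX))
                     for _ in range(len(valid_tasks or []))]
        n_skipped = n_tasks_seen = 0
        for it in range(self.n_iter):
            picks = rng.choice(len(tasks), size=self.task_batch_size,
                               replace=len(tasks) < self.task_batch_size)
            loss = 0.0
            gw = np.zeros(w.size)
            used = 0
            for ti in picks:
                n_tasks_seen += 1
                ep = self._sample_training_episode(X, y, tasks[ti], rng)
                ns = ep.support.size
                idx = np.concatenate([ep.support, ep.query])
                Zall, cache = extractor.forward_with_cache(w, X[idx])
                h_star, _, _ = _block_adapt(
                    _FrozenEmbedding(Zall[:ns]), np.zeros(0), self._theta0(),
                    Zall[:ns], t[ep.support], adapt_nn=False,
                    n_steps=self.inner_steps, lr_h=self.inner_lr,
                    tol=self.inner_tol, kernel=self.kernel)
                out = log_joint_predictive(h_star, Zall[:ns], t[ep.support],
                                           Zall[ns:], t[ep.query],
                                           with_grads=True, kernel=self.kernel)
                v, _, gZs, gZq = out
                if not np.isfinite(v):
                    n_skipped += 1
                    warnings.warn(f"skipping diverged task {tasks[ti].task_id}")
                    continue
                dw, _ = extractor.backward(cache, np.vstack([-gZs, -gZq]))
                loss += -v
                gw += dw
                used += 1
            if used == 0 or n_skipped > self.max_skip_fraction * max(1, n_tasks_seen):
                raise FloatingPointError("too many diverged ADKF inner loops")
            w = adam.step(w, gw / used)
            self.history_.append(loss / used)
            if valid_tasks and (it + 1) % self.val_every == 0:
                self.extractor_, self.theta_nn_ = extractor, w
                score = self._validation_score(X, y, valid_tasks, val_seeds)
                if score > best[0]:
                    best = (score, w.copy())
        if valid_tasks and best[0] > -np.inf:
            w = best[1]
        self.extractor_ = extractor
        self.theta_nn_ = w
        self.theta_gp_init_ = self._theta0()
        self.classes_ = np.array([0, 1])
        return self

    def adapt(self, X_support, y_support):
        """Re-fit theta_GP on the support NLML; extractor stays fixed."""
        check_is_fitted(self, "theta_nn_")
        ys = np.asarray(y_support).ravel().astype(int)
        single_class = len(np.unique(ys)) < 2
        if single_class:
            warnings.warn("single-class support: GP adapts on constant targets")
        ts = _to_targets(ys)
        Zs = self.extractor_.forward(self.theta_nn_, X_support)
        h_star, _, state = _block_adapt(
            _FrozenEmbedding(Zs), np.zeros(0), self.theta_gp_init_, Zs, ts,
            adapt_nn=False, n_steps=self.inner_steps, lr_h=self.inner_lr,
            tol=self.inner_tol, kernel=self.kernel)
        state.single_class_support = single_class
        return FewShotGPPredictor(self.extractor_, self.theta_nn_, h_star,
                                  X_support, ys, kernel=self.kernel,
                                  adapt_state=state)


class _FrozenEmbedding:
    """Identity 'extractor' over precomputed embeddings (no parameters)."""

    n_params = 0

    def __init__(self, Z):
        self._Z = np.atleast_2d(np.asarray(Z, dtype=float))

    def forward(self, w, X):
        return np.atleast_2d(np.asarray(X, dtype=float))

    def forward_with_cache(self, w, X):
        return self.forward(w, X), None

    def backward(self, cache, dZ):
        return np.zeros(0), dZ


# ---------------------------------------------------------------------------
# ADKF-prior
# ---------------------------------------------------------------------------

class ADKFPriorClassifier(_BaseDeepKernelEstimator):
    """ADKF with a Gaussian prior N(phi, sigma^2 I) over the extractor.

    Inner loop (per task): [theta_GP, theta_NN] minimise the support NLML
    plus the MAP penalty ||theta_NN - phi||^2 / (2 sigma^2), with
    theta_NN initialised at phi and theta_GP at its meta-learned
    initialisation.  Outer loop: the meta-parameters [phi, theta_GP init,
    log sigma^2] minimise the mean query predictive loss; phi and the
    theta_GP initialisation get first-order (FOMAML-style) gradients
    evaluated at the adapted parameters, and log sigma^2 the proximal
    estimate g . (theta_NN* - phi) — the directional effect of allowing
    larger deviations from the prior mean.  Meta-learning the theta_GP
    initialisation is what stabilises very small supports: adaptation
    starts from kernel hyperparameters that already fit the task
    distribution instead of being re-estimated from a handful of points.
    """

    def __init__(self, prior_variance_init=1e-3, sigma2_bounds=(1e-6, 10.0),
                 init_phi=None, hidden_sizes=(256, 128), latent_dim=64,
                 activation="tanh", kernel="rbf", extractor="mlp",
                 learning_rate=0.01, n_iter=200, task_batch_size=5,
                 train_support_size=512, train_query_size=64, inner_steps=50,
                 inner_lr=0.1, inner_lr_nn=0.05, inner_tol=1e-5,
                 lengthscale_init=1.0, outputscale_init=1.0, noise_init=0.1,
                 val_every=50, n_val_episodes=2, stratified=True,
                 random_state=None):
        self.prior_variance_init = prior_variance_init
        self.sigma2_bounds = sigma2_bounds
        self.init_phi = init_phi
        super().__init__(
            hidden_sizes=hidden_sizes, latent_dim=latent_dim,
            activation=activation, kernel=kernel, extractor=extractor,
            learning_rate=learning_rate, n_iter=n_iter,
            task_batch_size=task_batch_size,
            train_support_size=train_support_size,
            train_query_size=train_query_size, inner_steps=inner_steps,
            inner_lr=inner_lr, inner_lr_nn=inner_lr_nn, inner_tol=inner_tol,
            lengthscale_init=lengthscale_init,
            outputscale_init=outputscale_init, noise_init=noise_init,
            val_every=val_every, n_val_episodes=n_val_episodes,
            stratified=stratified, random_state=random_state)

    def fit(self, X, y, tasks, valid_tasks=None):
        X, y = self._check_fit_inputs(X, y, tasks)
        t = _to_targets(y)
        rng = self._rng()
        extractor = self._make_extractor(X.shape[1])
        phi = (np.array(self.init_phi, dtype=float) if self.init_phi is not None
               else extractor.init_params(rng))
        if phi.size != extractor.n_params:
            raise ValueError("init_phi has the wrong number of parameters")
        log_s2 = np.log(self.prior_variance_init)
        # meta parameter vector: [phi (P) | theta_GP init (3) | log sigma^2]
        params = np.concatenate([phi, self._theta0(), [log_s2]])
        adam = _Adam(params.size, lr=self.learning_rate)
        self.history_ = []
        best = (-np.inf, params.copy())
        val_seeds = [int(rng.integers(_SEED_MAX))
                     for _ in range(len(valid_tasks or []))]
        lo, hi = np.log(self.sigma2_bounds[0]), np.log(self.sigma2_bounds[1])
        for it in range(self.n_iter):
            phi, h0 = params[:-4], params[-4:-1]
            sigma2 = float(np.exp(params[-1]))
            picks = rng.choice(len(tasks), size=self.task_batch_size,
                               replace=len(tasks) < self.task_batch_size)
            loss, g_phi, g_h0, g_ls2, used = (0.0, np.zeros(phi.size),
                                              np.zeros(3), 0.0, 0)
            for ti in picks:
                ep = self._sample_training_episode(X, y, tasks[ti], rng)
                h_star, w_star, _ = _block_adapt(
                    extractor, phi, h0, X[ep.support],
                    t[ep.support], adapt_nn=True, phi=phi, sigma2=sigma2,
                    n_steps=self.inner_steps, lr_h=self.inner_lr,
                    lr_w=self.inner_lr_nn, tol=self.inner_tol,
                    kernel=self.kernel)
                Zall, cache = extractor.forward_with_cache(
                    w_star, np.vstack([X[ep.support], X[ep.query]]))
                ns = ep.support.size
                out = log_joint_predictive(h_star, Zall[:ns], t[ep.support],
                                           Zall[ns:], t[ep.query],
                                           with_grads=True, kernel=self.kernel)
                v, gh, gZs, gZq = out
                if not np.isfinite(v):
                    warnings.warn(f"skipping diverged task {tasks[ti].task_id}")
                    continue
                gw, _ = extractor.backward(cache, np.vstack([-gZs, -gZq]))
                loss += -v
                g_phi += gw                       # FOMAML: d w*/d phi ~ I
                g_h0 += h0 - h_star               # consolidation toward the
                #                                   centroid of adapted optima
                g_ls2 += float(gw @ (w_star - phi))  # d w*/d log s2 ~ (w*-phi)
                used += 1
            if used == 0:
                raise FloatingPointError("all ADKF-prior inner loops diverged")
            params = adam.step(params, np.concatenate([g_phi / used,
                                                       g_h0 / used,
                                                       [g_ls2 / used]]))
            params[-1] = np.clip(params[-1], lo, hi)
            self.history_.append(loss / used)
            if valid_tasks and (it + 1) % self.val_every == 0:
                self._install(extractor, params)
                score = self._validation_score(X, y, valid_tasks, val_seeds)
                if score > best[0]:
                    best = (score, params.copy())
        if valid_tasks and best[0] > -np.inf:
            params = best[1]
        self._install(extractor, params)
        self.classes_ = np.array([0, 1])
        return self

    def _install(self, extractor, params):
        self.extractor_ = extractor
        self.phi_ = params[:-4]
        self.theta_gp_init_ = np.array(params[-4:-1], dtype=float)
        self.log_sigma2_ = float(params[-1])
        self.sigma2_ = float(np.exp(self.log_sigma2_))

    def adapt(self, X_support, y_support):
        """MAP-adapt [theta_GP, theta_NN] on the support under the prior."""
        check_is_fitted(self, "phi_")
        ys = np.asarray(y_support).ravel().astype(int)
        single_class = len(np.unique(ys)) < 2
        if single_class:
            warnings.warn("single-class support: GP adapts on constant targets")
        ts = _to_targets(ys)
        h_star, w_star, state = _block_adapt(
            self.extractor_, self.phi_, self.theta_gp_init_,
            np.atleast_2d(X_support), ts, adapt_nn=True, phi=self.phi_,
            sigma2=self.sigma2_, n_steps=self.inner_steps, lr_h=self.inner_lr,
            lr_w=self.inner_lr_nn, tol=self.inner_tol, kernel=self.kernel)
        state.single_class_support = single_class
        return FewShotGPPredictor(self.extractor_, w_star, h_star,
                                  X_support, ys, kernel=self.kernel,
                                  adapt_state=state)


# ---------------------------------------------------------------------------
# prototypical network
# ---------------------------------------------------------------------------

def protonet_episode_loss(extractor, w, Xs, ys, Xq, yq, with_grads=False):
    """Episodic cross-entropy of softmax over -||z_q - prototype||^2."""
    ys = np.asarray(ys).ravel().astype(int)
    yq = np.asarray(yq).ravel().astype(int)
    ns = np.atleast_2d(Xs).shape[0]
    Z, cache = extractor.forward_with_cache(w, np.vstack([np.atleast_2d(Xs),
                                                          np.atleast_2d(Xq)]))
    Zs, Zq = Z[:ns], Z[ns:]
    classes = (0, 1)
    masks = [ys == c for c in classes]
    if not all(m.any() for m in masks):
        raise ValueError("support must contain both classes")
    protos = np.stack([Zs[m].mean(axis=0) for m in masks])
    diff = Zq[:, None, :] - protos[None, :, :]
    logits = -np.sum(diff * diff, axis=2)
    logits_s = logits - logits.max(axis=1, keepdims=True)
    e = np.exp(logits_s)
    p = e / e.sum(axis=1, keepdims=True)
    m = Zq.shape[0]
    loss = -float(np.mean(np.log(p[np.arange(m), yq] + 1e-300)))
    if not with_grads:
        return loss
    Y = np.zeros_like(p)
    Y[np.arange(m), yq] = 1.0
    dlogits = (p - Y) / m
    dZq = np.einsum("qc,qcd->qd", dlogits, -2.0 * diff)
    dprotos = np.einsum("qc,qcd->cd", dlogits, 2.0 * diff)
    dZs = np.zeros_like(Zs)
    for c, mask in zip(classes, masks):
        dZs[mask] = dprotos[c] / mask.sum()
    dw, _ = extractor.backward(cache, np.vstack([dZs, dZq]))
    return loss, dw


class PrototypicalNetworkClassifier(_BaseDeepKernelEstimator):
    """Metric-based meta-learning baseline (prototypical network).

    Episodic training: each episode embeds support and query, computes
    per-class prototypes as support means, and minimises the
    cross-entropy of the softmax over negative squared Euclidean
    distances from query embeddings to the prototypes.
    """

    def fit(self, X, y, tasks, valid_tasks=None):
        X, y = self._check_fit_inputs(X, y, tasks)
        rng = self._rng()
        extractor = self._make_extractor(X.shape[1])
        w = extractor.init_params(rng)
        adam = _Adam(w.size, lr=self.learning_rate)
        self.history_ = []
        best = (-np.inf, w.copy())
        val_seeds = [int(rng.integers(_SEED_MAX))
                     for _ in range(len(valid_tasks or []))]
        for it in range(self.n_iter):
            picks = rng.choice(len(tasks), size=self.task_batch_size,
                               replace=len(tasks) < self.task_batch_size)
            loss, gw = 0.0, np.zeros(w.size)
            for ti in picks:
                ep = self._sample_training_episode(X, y, tasks[ti], rng)
                v, dw = protonet_episode_loss(extractor, w, X[ep.support],
                                              y[ep.support], X[ep.query],
                                              y[ep.query], with_grads=True)
                loss += v
                gw += dw
            w = adam.step(w, gw / len(picks))
            self.history_.append(loss / len(picks))
            if valid_tasks and (it + 1) % self.val_every == 0:
                self.extractor_, self.theta_nn_ = extractor, w
                score = self._validation_score(X, y, valid_tasks, val_seeds)
                if score > best[0]:
                    best = (score, w.copy())
        if valid_tasks and best[0] > -np.inf:
            w = best[1]
        self.extractor_ = extractor
        self.theta_nn_ = w
        self.classes_ = np.array([0, 1])
        return self

    def adapt(self, X_support, y_support):
        """Compute class prototypes from the support embeddings."""
        check_is_fitted(self, "theta_nn_")
        return PrototypePredictor(self.extractor_, self.theta_nn_,
                                  X_support, y_support)


# ---------------------------------------------------------------------------
# meta-test protocol and functional wrappers
# ---------------------------------------------------------------------------

def meta_test(model, X, y, test_task: Task, support_size: int,
              query_size: int, n_repeats: int, seed: int,
              stratified: bool = True) -> np.ndarray:
    """Few-shot evaluation on a test task.

    For each repeat: sample a disjoint support/query episode, adapt the
    model per its own rule (conditioning, GP refit, MAP adaptation, or
    prototype computation), score the query set, and record the AUPRC.
    Episodes whose query draw contains no positives are redrawn (AUPRC is
    undefined there); everything is deterministic given ``seed``.
    """
    rng = np.random.default_rng(seed)
    scores = np.empty(n_repeats)
    for r in range(n_repeats):
        for _attempt in range(50):
            ep = sample_episode(test_task, support_size, query_size,
                                seed=int(rng.integers(_SEED_MAX)),
                                stratified=stratified, y=y)
            if y[ep.query].sum() > 0:
                break
        else:
            raise ValueError("could not draw a query set with positives")
        pred = model.adapt(X[ep.support], y[ep.support])
        scores[r] = auprc(y[ep.query], pred.predict_proba(X[ep.query])[:, 1])
    return scores


def _fit_meta(cls, X, y, train_tasks, valid_tasks, config):
    model = cls(**(config or {}))
    model.fit(X, y, train_tasks, valid_tasks=valid_tasks)
    return model


def train_dkt(X, y, train_tasks, valid_tasks=None, config=None) -> DKTClassifier:
    return _fit_meta(DKTClassifier, X, y, train_tasks, valid_tasks, config)


def train_adkf(X, y, train_tasks, valid_tasks=None, config=None) -> ADKFClassifier:
    return _fit_meta(ADKFClassifier, X, y, train_tasks, valid_tasks, config)


def train_adkf_prior(X, y, train_tasks, valid_tasks=None,
                     config=None) -> ADKFPriorClassifier:
    return _fit_meta(ADKFPriorClassifier, X, y, train_tasks, valid_tasks, config)


def train_protonet(X, y, train_tasks, valid_tasks=None,
                   config=None) -> PrototypicalNetworkClassifier:
    return _fit_meta(PrototypicalNetworkClassifier, X, y, train_tasks,
                     valid_tasks, config)


def train_dkl_single_task(X, y, config=None) -> DeepKernelGPClassifier:
    model = DeepKernelGPClassifier(**(config or {}))
    model.fit(X, y)
    return model
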