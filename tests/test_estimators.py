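"""Meta-learning estimators: reductions, oracles, adaptation contracts."""

import copy

import numpy as np
import pytest

from rxngp.estimators import (ADKFClassifier, ADKFPriorClassifier, _Adam,
                              DeepKernelGPClassifier, DKTClassifier,
                              PrototypicalNetworkClassifier, _block_adapt,
                              _to_targets, dkt_batch_objective, meta_test,
                              protonet_episode_loss)
from rxngp.gp_core import default_gp_hypers, log_joint_predictive, nlml
from rxngp.nn import MLPExtractor
from rxngp.synthetic import SyntheticSpec, generate_tasks

SMALL = dict(hidden_sizes=(16,), latent_dim=4, n_iter=8, task_batch_size=3,
             train_support_size=32, train_query_size=16, inner_steps=8,
             val_every=1000)


@pytest.fixture(scope="module")
def suite():
    spec = SyntheticSpec(n_tasks=4, n_per_task=128, dim=24, latent_dim=6,
                         seed=21)
    X, y, tasks, _ = generate_tasks(spec)
    return X, y, tasks


# ---------------------------------------------------------------------------
# optimizer / inner-loop contracts
# ---------------------------------------------------------------------------

def test_adam_zero_learning_rate_is_identity(rng):
    x = rng.normal(size=5)
    opt = _Adam(5, lr=0.0)
    assert np.array_equal(opt.step(x, rng.normal(size=5)), x)


def test_block_adapt_zero_steps_is_noop(rng):
    ext = MLPExtractor(6, hidden_sizes=(4,), out_dim=2)
    w = ext.init_params(rng)
    Xs = rng.normal(size=(10, 6))
    ts = rng.choice([-1.0, 1.0], 10)
    h0 = default_gp_hypers()
    h, w_out, state = _block_adapt(ext, w, h0, Xs, ts, adapt_nn=True,
                                   phi=w, sigma2=0.1, n_steps=0)
    assert np.array_equal(h, h0)
    assert np.array_equal(w_out, w)
    assert state.inner_steps == 0


def test_block_adapt_loss_never_increases(rng):
    ext = MLPExtractor(6, hidden_sizes=(4,), out_dim=2)
    w = ext.init_params(rng)
    Xs = rng.normal(size=(20, 6))
    ts = rng.choice([-1.0, 1.0], 20)
    _, _, state = _block_adapt(ext, w, default_gp_hypers(), Xs, ts,
                               adapt_nn=True, phi=w, sigma2=0.1, n_steps=20)
    assert state.final_inner_loss <= state.initial_inner_loss


def test_block_adapt_penalty_zero_at_prior_mean(rng):
    """At theta_NN = phi the MAP objective equals the bare support NLML."""
    ext = MLPExtractor(5, hidden_sizes=(3,), out_dim=2)
    w = ext.init_params(rng)
    Xs = rng.normal(size=(8, 5))
    ts = rng.choice([-1.0, 1.0], 8)
    h0 = default_gp_hypers()
    _, _, state = _block_adapt(ext, w, h0, Xs, ts, adapt_nn=True, phi=w,
                               sigma2=1e-3, n_steps=0)
    assert state.initial_inner_loss == pytest.approx(
        nlml(h0, ext.forward(w, Xs), ts), abs=1e-12)


def test_large_sigma2_matches_unpenalized_adaptation(rng):
    """sigma^2 -> infinity removes the prior: same trajectory as no penalty."""
    ext = MLPExtractor(6, hidden_sizes=(4,), out_dim=2)
    w = ext.init_params(rng)
    Xs = rng.normal(size=(16, 6))
    ts = rng.choice([-1.0, 1.0], 16)
    h0 = default_gp_hypers()
    h_a, w_a, _ = _block_adapt(ext, w, h0, Xs, ts, adapt_nn=True, phi=w,
                               sigma2=1e12, n_steps=10)
    h_b, w_b, _ = _block_adapt(ext, w, h0, Xs, ts, adapt_nn=True, phi=w,
                               sigma2=None, n_steps=10)
    assert np.allclose(h_a, h_b, atol=1e-6)
    assert np.allclose(w_a, w_b, atol=1e-6)


# ---------------------------------------------------------------------------
# reduction chain
# ---------------------------------------------------------------------------

def test_dkt_batch_of_identical_tasks_equals_single_task_nlml(rng):
    """DKT's meta objective on replicated copies of one dataset collapses
    to the single-task DKL objective on that dataset."""
    ext = MLPExtractor(8, hidden_sizes=(5,), out_dim=3)
    w = ext.init_params(rng)
    h = default_gp_hypers(0.9, 1.1, 0.15)
    Xb = rng.normal(size=(12, 8))
    tb = rng.choice([-1.0, 1.0], 12)
    batch = [(Xb, tb)] * 5
    v, gw, gh = dkt_batch_objective(ext, w, h, batch)
    single = nlml(h, ext.forward(w, Xb), tb)
    assert v == pytest.approx(single, abs=1e-12)
    _, gw1, gh1 = dkt_batch_objective(ext, w, h, [(Xb, tb)])
    assert np.allclose(gw, gw1, atol=1e-12)
    assert np.allclose(gh, gh1, atol=1e-12)


def test_adkf_prior_sigma_to_zero_reduces_to_adkf_at_phi(suite, rng):
    """With a vanishing prior variance the extractor cannot move, so the
    ADKF-prior adaptation must reproduce ADKF's adapted behaviour with
    theta_NN = phi on the same episode."""
    X, y, tasks = suite
    adkf = ADKFClassifier(random_state=0, **SMALL)
    adkf.fit(X, y, tasks[:3])
    prior = ADKFPriorClassifier(random_state=0, **SMALL)
    prior.extractor_ = adkf.extractor_
    prior.phi_ = adkf.theta_nn_.copy()
    prior.theta_gp_init_ = adkf.theta_gp_init_.copy()
    prior.sigma2_ = 1e-12
    prior.log_sigma2_ = np.log(1e-12)
    prior.classes_ = np.array([0, 1])

    idx = tasks[3].indices
    Xs, ys = X[idx[:16]], y[idx[:16]]
    Xq, yq = X[idx[16:48]], y[idx[16:48]]
    pred_a = adkf.adapt(Xs, ys)
    pred_p = prior.adapt(Xs, ys)
    assert np.allclose(pred_p.w, prior.phi_)           # extractor pinned
    tq = _to_targets(yq)
    ts = _to_targets(ys)
    loss_a = -log_joint_predictive(pred_a.theta_gp,
                                   pred_a.extractor.forward(pred_a.w, Xs), ts,
                                   pred_a.extractor.forward(pred_a.w, Xq), tq)
    loss_p = -log_joint_predictive(pred_p.theta_gp,
                                   pred_p.extractor.forward(pred_p.w, Xs), ts,
                                   pred_p.extractor.forward(pred_p.w, Xq), tq)
    assert loss_p == pytest.approx(loss_a, abs=1e-4)
    assert np.allclose(pred_p.predict_proba(Xq), pred_a.predict_proba(Xq),
                       atol=1e-6)


# ---------------------------------------------------------------------------
# prototypical network
# ---------------------------------------------------------------------------

def brute_force_protonet(Z_support, ys, Z_query):
    probs = np.zeros((len(Z_query), 2))
    protos = [np.mean([z for z, c in zip(Z_support, ys) if c == k], axis=0)
              for k in (0, 1)]
    for i, z in enumerate(Z_query):
        d = np.array([np.sum((z - p) ** 2) for p in protos])
        e = np.exp(-d + d.min())
        probs[i] = e / e.sum()
    return probs


def test_protonet_matches_brute_force_on_random_episodes(rng):
    ext = MLPExtractor(7, hidden_sizes=(6,), out_dim=3)
    model = PrototypicalNetworkClassifier(hidden_sizes=(6,), latent_dim=3)
    model.extractor_ = ext
    model.theta_nn_ = ext.init_params(rng)
    model.classes_ = np.array([0, 1])
    for _ in range(50):
        ns, nq = int(rng.integers(4, 12)), int(rng.integers(2, 8))
        Xs = rng.normal(size=(ns, 7))
        ys = rng.integers(0, 2, size=ns)
        ys[0], ys[1] = 0, 1
        Xq = rng.normal(size=(nq, 7))
        pred = model.adapt(Xs, ys)
        ours = pred.predict_proba(Xq)
        ref = brute_force_protonet(ext.forward(model.theta_nn_, Xs), ys,
                                   ext.forward(model.theta_nn_, Xq))
        assert np.allclose(ours, ref, atol=1e-10)
        assert np.array_equal(pred.predict(Xq), np.argmax(ref, axis=1))


def test_protonet_query_at_prototype_is_classified_there(rng):
    ext = MLPExtractor(4, hidden_sizes=(4,), out_dim=2)
    model = PrototypicalNetworkClassifier()
    model.extractor_ = ext
    model.theta_nn_ = ext.init_params(rng)
    model.classes_ = np.array([0, 1])
    Xs = rng.normal(size=(6, 4))
    ys = np.array([0, 0, 0, 1, 1, 1])
    pred = model.adapt(Xs, ys)
    Zs = ext.forward(model.theta_nn_, Xs)
    proto0 = Zs[:3].mean(axis=0)
    assert ((Zs[3:].mean(axis=0) - proto0) ** 2).sum() > 1e-8  # distinct
    # a query embedded exactly at class-0's prototype goes to class 0
    p = brute_force_protonet(Zs, ys, [proto0])
    assert p[0, 0] > 0.5
    assert np.argmax(p[0]) == 0


def test_protonet_equidistant_query_is_uncertain():
    Zs = np.array([[0.0, 0.0], [2.0, 0.0]])
    p = brute_force_protonet(Zs, [0, 1], [[1.0, 5.0]])
    assert p[0, 0] == pytest.approx(0.5, abs=1e-12)


def test_protonet_episode_loss_gradient_check(rng):
    ext = MLPExtractor(5, hidden_sizes=(4,), out_dim=2)
    w = ext.init_params(rng)
    Xs = rng.normal(size=(6, 5))
    ys = np.array([0, 1, 0, 1, 0, 1])
    Xq = rng.normal(size=(4, 5))
    yq = np.array([0, 1, 1, 0])
    _, dw = protonet_episode_loss(ext, w, Xs, ys, Xq, yq, with_grads=True)
    eps = 1e-6
    for i in rng.choice(w.size, size=6, replace=False):
        wp, wm = w.copy(), w.copy()
        wp[i] += eps
        wm[i] -= eps
        fd = (protonet_episode_loss(ext, wp, Xs, ys, Xq, yq)
              - protonet_episode_loss(ext, wm, Xs, ys, Xq, yq)) / (2 * eps)
        assert dw[i] == pytest.approx(fd, rel=1e-4, abs=1e-8)


# ---------------------------------------------------------------------------
# training determinism and meta-test protocol
# ---------------------------------------------------------------------------

@pytest.mark.parametrize("cls", [DKTClassifier, ADKFClassifier,
                                 ADKFPriorClassifier,
                                 PrototypicalNetworkClassifier])
def test_trainers_are_seed_deterministic(cls, suite):
    X, y, tasks = suite
    m1 = cls(random_state=7, **SMALL).fit(X, y, tasks[:3],
                                          valid_tasks=[tasks[3]])
    m2 = cls(random_state=7, **SMALL).fit(X, y, tasks[:3],
                                          valid_tasks=[tasks[3]])
    a1 = getattr(m1, "theta_nn_", getattr(m1, "phi_", None))
    a2 = getattr(m2, "theta_nn_", getattr(m2, "phi_", None))
    assert np.array_equal(a1, a2)
    assert m1.history_ == m2.history_


def test_meta_test_repeat_count_and_determinism(suite):
    X, y, tasks = suite
    model = DKTClassifier(random_state=0, **SMALL).fit(X, y, tasks[:3])
    s1 = meta_test(model, X, y, tasks[3], 10, 32, n_repeats=10, seed=5)
    s2 = meta_test(model, X, y, tasks[3], 10, 32, n_repeats=10, seed=5)
    assert s1.shape == (10,)
    assert np.array_equal(s1, s2)
    assert np.all((s1 >= 0) & (s1 <= 1))


@pytest.mark.parametrize("support_size", [5, 10, 15, 20])
def test_meta_test_accepts_small_supports(suite, support_size):
    X, y, tasks = suite
    model = ADKFPriorClassifier(random_state=0, **SMALL)
    model.fit(X, y, tasks[:3])
    scores = meta_test(model, X, y, tasks[3], support_size, 32,
                       n_repeats=2, seed=3)
    assert scores.shape == (2,)


def test_dkl_fit_predict_and_adapt(suite, rng):
    X, y, tasks = suite
    idx = np.concatenate([tasks[0].indices, tasks[1].indices])
    model = DeepKernelGPClassifier(hidden_sizes=(16,), latent_dim=4,
                                   n_iter=20, random_state=1)
    model.fit(X[idx], y[idx])
    proba = model.predict_proba(X[tasks[2].indices][:20])
    assert proba.shape == (20, 2)
    assert np.allclose(proba.sum(axis=1), 1.0)
    pred = model.adapt(X[tasks[2].indices][:10], y[tasks[2].indices][:10])
    assert pred.predict_proba(X[:5]).shape == (5, 2)


def test_dkl_rejects_single_class():
    X = np.random.default_rng(0).normal(size=(20, 4))
    with pytest.raises(ValueError):
        DeepKernelGPClassifier(n_iter=2).fit(X, np.zeros(20, dtype=int))


def test_single_class_support_flagged(suite):
    X, y, tasks = suite
    model = ADKFClassifier(random_state=0, **SMALL).fit(X, y, tasks[:3])
    idx = tasks[3].indices
    pos = idx[y[idx] == 1][:6]
    with pytest.warns(UserWarning, match="single-class"):
        pred = model.adapt(X[pos], y[pos])
    assert pred.adapt_state.single_class_support


def test_get_set_params_roundtrip():
    model = ADKFPriorClassifier(latent_dim=5, prior_variance_init=2e-3)
    params = model.get_params()
    assert params["latent_dim"] == 5
    clone = ADKFPriorClassifier(**params)
    assert clone.get_params() == params
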