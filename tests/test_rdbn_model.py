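"""RBM energy model, contrastive divergence, residual forward/backward."""

import itertools

import numpy as np
import pytest

from cmdsim import rdbn_model as rdbn
from cmdsim.rdbn_model import RBMLayer, TrainConfig


def brute_force_joint(v, h, layer):
    """Independent enumerator for P(v, h): raw loops, no shared code path."""
    def energy(vv, hh):
        e = 0.0
        for i in range(len(vv)):
            e -= layer.a[i] * vv[i]
        for j in range(len(hh)):
            e -= layer.b[j] * hh[j]
        for i in range(len(vv)):
            for j in range(len(hh)):
                e -= vv[i] * layer.W[i][j] * hh[j]
        return e
    z = sum(
        np.exp(-energy(vv, hh))
        for vv in itertools.product((0, 1), repeat=layer.n_visible)
        for hh in itertools.product((0, 1), repeat=layer.n_hidden)
    )
    return np.exp(-energy(v, h)) / z


def exact_loglik_grad(layer, data):
    """Exact gradient of mean log-likelihood for a tiny RBM (enumerated Z).

    d/dW_ij = <v_i h_j>_data - <v_i h_j>_model, and analogous bias terms.
    """
    nv, nh = layer.n_visible, layer.n_hidden
    # data expectations: h integrated analytically via p(h|v)
    ph = rdbn.sigmoid(data @ layer.W + layer.b)
    dW_data = data.T @ ph / len(data)
    da_data = data.mean(axis=0)
    db_data = ph.mean(axis=0)
    # model expectations by enumeration
    vs = np.array(list(itertools.product((0.0, 1.0), repeat=nv)))
    hs = np.array(list(itertools.product((0.0, 1.0), repeat=nh)))
    logw = np.array([[layer.a @ v + layer.b @ h + v @ layer.W @ h
                      for h in hs] for v in vs])
    w = np.exp(logw - logw.max())
    p = w / w.sum()
    dW_model = np.einsum("vh,vi,hj->ij", p, vs, hs)
    da_model = np.einsum("vh,vi->i", p, vs)
    db_model = np.einsum("vh,hj->j", p, hs)
    return dW_data - dW_model, da_data - da_model, db_data - db_model


def test_energy_hand_values():
    lay = RBMLayer(W=[[2.0]], a=[0.5], b=[-0.25])
    assert rdbn.rbm_energy(np.zeros(1), np.zeros(1), lay) == 0.0
    assert rdbn.rbm_energy(np.ones(1), np.ones(1), lay) == pytest.approx(-2.25)
    doubled = RBMLayer(W=[[2.0]], a=[1.0], b=[-0.25])
    # energy is linear in a: doubling a doubles that term's contribution
    assert rdbn.rbm_energy(np.ones(1), np.ones(1), doubled) == pytest.approx(-2.75)
    with pytest.raises(ValueError):
        rdbn.rbm_energy(np.ones(2), np.ones(1), lay)


def test_joint_probability_uniform_and_oracle(rng):
    flat = RBMLayer(W=np.zeros((2, 1)), a=np.zeros(2), b=np.zeros(1))
    assert rdbn.rbm_joint_probability(
        np.zeros(2), np.zeros(1), flat) == pytest.approx(1 / 8)
    lay = RBMLayer(W=rng.normal(0, 0.5, (2, 2)), a=rng.normal(0, 0.5, 2),
                   b=rng.normal(0, 0.5, 2))
    total = 0.0
    for v in itertools.product((0.0, 1.0), repeat=2):
        for h in itertools.product((0.0, 1.0), repeat=2):
            p = rdbn.rbm_joint_probability(np.array(v), np.array(h), lay)
            assert p == pytest.approx(brute_force_joint(v, h, lay), abs=1e-12)
            total += p
    assert total == pytest.approx(1.0, abs=1e-12)
    big = RBMLayer(W=np.zeros((10, 10)), a=np.zeros(10), b=np.zeros(10))
    with pytest.raises(ValueError):
        rdbn.rbm_joint_probability(np.zeros(10), np.zeros(10), big)


def test_gibbs_sampling_probabilities():
    flat = RBMLayer(W=np.zeros((3, 4)), a=np.zeros(3), b=np.zeros(4))
    rng = np.random.default_rng(1)
    draws = np.array([rdbn.sample_hidden(np.ones(3), flat, rng)
                      for _ in range(2000)])
    assert np.allclose(draws.mean(axis=0), 0.5, atol=0.05)
    hot = RBMLayer(W=np.zeros((3, 1)), a=np.zeros(3), b=np.array([10.0]))
    freq = np.mean([rdbn.sample_hidden(np.zeros(3), hot, rng)
                    for _ in range(1000)])
    assert freq > 0.99
    a = rdbn.sample_visible(np.ones(4), flat, np.random.default_rng(7))
    b = rdbn.sample_visible(np.ones(4), flat, np.random.default_rng(7))
    assert np.array_equal(a, b)


def test_cd_update_null_step_and_errors(rng):
    lay = RBMLayer(W=rng.normal(0, 0.1, (4, 3)), a=rng.normal(0, 0.1, 4),
                   b=rng.normal(0, 0.1, 3))
    batch = rng.integers(0, 2, (8, 4)).astype(float)
    out = rdbn.cd_update(lay, batch, lr=0.0, rng=rng)
    assert np.array_equal(out.W, lay.W) and np.array_equal(out.b, lay.b)
    with pytest.raises(ValueError):
        rdbn.cd_update(lay, np.empty((0, 4)), lr=0.1)


def test_cd_training_reduces_reconstruction_error():
    """CD-1 on one repeated pattern: epoch-averaged reconstruction error
    trends down (first-quarter mean > last-quarter mean)."""
    rng = np.random.default_rng(4)
    pattern = np.tile([1.0, 0.0, 1.0, 0.0], (16, 1))
    lay = RBMLayer(W=rng.normal(0, 0.01, (4, 3)), a=np.zeros(4), b=np.zeros(3))
    errs = []
    for _ in range(200):
        lay = rdbn.cd_update(lay, pattern, lr=0.2, rng=rng)
        ph = rdbn.sigmoid(pattern @ lay.W + lay.b)
        recon = rdbn.sigmoid(ph @ lay.W.T + lay.a)
        errs.append(float(np.mean((recon - pattern) ** 2)))
    q = len(errs) // 4
    assert np.mean(errs[:q]) > np.mean(errs[-q:])
    assert errs[-1] < 0.05


def test_cd_gradient_signs_match_exact(rng):
    """Expected CD-1 direction agrees in sign with the exact gradient on a
    2x1 RBM with a single visible pattern (>= 95% of parameters across
    several models)."""
    agree = total = 0
    for seed in range(5):
        r = np.random.default_rng(seed)
        lay = RBMLayer(W=r.normal(0, 0.5, (2, 1)), a=r.normal(0, 0.5, 2),
                       b=r.normal(0, 0.5, 1))
        data = np.array([[1.0, 0.0]])
        gW, ga, gb = exact_loglik_grad(lay, data)
        # average the stochastic CD-1 step over many draws
        dWs, das, dbs = [], [], []
        for _ in range(400):
            upd = rdbn.cd_update(lay, data, lr=1.0, cd_steps=1, rng=r)
            dWs.append(upd.W - lay.W)
            das.append(upd.a - lay.a)
            dbs.append(upd.b - lay.b)
        est = np.concatenate([np.mean(dWs, 0).ravel(), np.mean(das, 0),
                              np.mean(dbs, 0)])
        exact = np.concatenate([gW.ravel(), ga, gb])
        keep = np.abs(exact) > 1e-3  # sign of a near-zero gradient is noise
        agree += int(np.sum(np.sign(est[keep]) == np.sign(exact[keep])))
        total += int(keep.sum())
    assert total >= 20
    assert agree / total >= 0.95


def test_pretrain_shapes_and_degenerate_stack(rng):
    data = rng.random((32, 6))
    single = rdbn.pretrain_greedy(
        data, TrainConfig(hidden_layers=1, hidden_units=4, local_epochs=2,
                          batch_size=8, learning_rate=0.1, dropout=0.0, seed=1))
    assert len(single) == 1 and single[0].W.shape == (6, 4)
    stack = rdbn.pretrain_greedy(
        data, TrainConfig(hidden_layers=3, hidden_units=5, local_epochs=1,
                          batch_size=8, learning_rate=0.1, dropout=0.0, seed=1))
    assert [l.W.shape for l in stack] == [(6, 5), (5, 5), (5, 5)]
    with pytest.raises(ValueError):
        rdbn.pretrain_greedy(np.array([[np.nan, 1.0]]),
                             TrainConfig(hidden_layers=1, hidden_units=2,
                                         dropout=0.0))


def test_forward_residual_zero_weights(tiny_model):
    """With W=0, b=0 the post-activation rule gives h^l = 0.5 + h^{l-1}
    wherever the skip applies (equal widths)."""
    model = rdbn.set_flat_params(
        tiny_model, np.zeros(rdbn.n_params(tiny_model)))
    x = np.random.default_rng(0).random(4)
    hs = rdbn.forward_residual(x, model)
    # layer 1: input width 4 != hidden width 5, no skip -> sigmoid(0) = 0.5
    assert np.allclose(hs[1], 0.5)
    # layer 2: widths match, skip applies -> 0.5 + h^1 = 1.0
    assert np.allclose(hs[2], 1.0)


def test_residual_disabled_reduces_to_plain_dbn(tiny_model, rng):
    from dataclasses import replace
    x = rng.random((6, 4))
    plain = replace(tiny_model.copy(), residual_enabled=False)
    hs = rdbn.forward_residual(x, plain)
    # hand-rolled plain DBN forward
    h = x
    for lay in plain.layers:
        h = rdbn.sigmoid(h @ lay.W + lay.b)
    assert np.allclose(hs[-1], h)


def test_pre_vs_post_activation_modes(tiny_model, rng):
    from dataclasses import replace
    x = rng.random(4)
    # non-zero params so the two placements genuinely differ
    theta = rng.normal(0, 0.5, rdbn.n_params(tiny_model))
    post = rdbn.set_flat_params(tiny_model, theta)
    pre = replace(post.copy(), residual_mode="pre_activation")
    h_post = rdbn.forward_residual(x, post)[-1]
    h_pre = rdbn.forward_residual(x, pre)[-1]
    assert not np.allclose(h_post, h_pre)
    # both collapse to the same value when the skip source is zero
    nores_post = replace(post.copy(), residual_enabled=False)
    nores_pre = replace(pre.copy(), residual_enabled=False)
    assert np.allclose(rdbn.forward_residual(x, nores_post)[-1],
                       rdbn.forward_residual(x, nores_pre)[-1])


def test_predict_proba_contract(tiny_model, rng):
    X = rng.random((100, 4))
    P = rdbn.predict_proba(tiny_model, X)
    assert np.all(P >= 0)
    assert np.allclose(P.sum(axis=1), 1.0, atol=1e-9)
    # zero head -> uniform probabilities
    zeroed = tiny_model.copy()
    zeroed.output_W = np.zeros_like(zeroed.output_W)
    zeroed.output_b = np.zeros_like(zeroed.output_b)
    assert np.allclose(rdbn.predict_proba(zeroed, X), 1 / 3)
    # shift invariance of the softmax head
    shifted = tiny_model.copy()
    shifted.output_b = shifted.output_b + 7.0
    assert np.allclose(rdbn.predict_proba(shifted, X), P, atol=1e-12)
    # argmax consistency
    assert np.array_equal(rdbn.predict(tiny_model, X), np.argmax(P, axis=1))
    with pytest.raises(ValueError):
        rdbn.predict_proba(tiny_model, rng.random((3, 9)))


def test_flat_params_roundtrip(tiny_model, rng):
    theta = rng.normal(size=rdbn.n_params(tiny_model))
    back = rdbn.get_flat_params(rdbn.set_flat_params(tiny_model, theta))
    assert np.array_equal(back, theta)
    with pytest.raises(ValueError):
        rdbn.set_flat_params(tiny_model, theta[:-1])


def test_backprop_matches_finite_differences(tiny_model, rng):
    X = rng.random((7, 4))
    y = rng.integers(0, 3, 7)
    _, g = rdbn.loss_and_grads(tiny_model, X, y)
    theta = rdbn.get_flat_params(tiny_model)
    h = 1e-6
    fd = np.empty_like(theta)
    for i in range(len(theta)):
        up, dn = theta.copy(), theta.copy()
        up[i] += h
        dn[i] -= h
        fd[i] = (rdbn.cross_entropy_loss(rdbn.set_flat_params(tiny_model, up), X, y)
                 - rdbn.cross_entropy_loss(rdbn.set_flat_params(tiny_model, dn), X, y)) / (2 * h)
    assert np.max(np.abs(g - fd) / np.maximum(np.abs(fd), 1e-4)) < 1e-4


def test_fine_tune_null_and_separable(rng):
    cfg = TrainConfig(learning_rate=0.0, hidden_layers=2, hidden_units=8,
                      dropout=0.0, optimizer="sgd", seed=5)
    model = rdbn.build_model(2, 2, cfg)
    X = rng.random((40, 2))
    y = (X[:, 0] > 0.5).astype(int)
    frozen = rdbn.fine_tune(model, X, y, cfg, epochs=2)
    assert np.array_equal(rdbn.get_flat_params(frozen),
                          rdbn.get_flat_params(model))
    # linearly separable 2-feature task: >= 0.95 train accuracy in 50 epochs
    n = 200
    X2 = rng.normal(size=(n, 2))
    y2 = (X2[:, 0] + X2[:, 1] > 0).astype(int)
    from cmdsim.synthetic_data import scale_features
    X2 = scale_features(X2)
    cfg2 = TrainConfig(learning_rate=0.01, hidden_layers=2, hidden_units=8,
                       dropout=0.0, optimizer="adam", batch_size=32, seed=5)
    trained = rdbn.fine_tune(rdbn.build_model(2, 2, cfg2), X2, y2, cfg2,
                             epochs=50)
    acc = np.mean(rdbn.predict(trained, X2) == y2)
    assert acc >= 0.95


def test_training_is_deterministic(rng):
    X = rng.random((60, 3))
    y = rng.integers(0, 2, 60)
    cfg = TrainConfig(learning_rate=0.05, hidden_layers=2, hidden_units=6,
                      dropout=0.5, optimizer="adam", batch_size=16, seed=9)
    runs = [rdbn.fine_tune(rdbn.build_model(3, 2, cfg), X, y, cfg, epochs=3)
            for _ in range(2)]
    assert np.array_equal(rdbn.get_flat_params(runs[0]),
                          rdbn.get_flat_params(runs[1]))
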