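"""Network forward/backward, loss, splits, training and evaluation."""

import numpy as np
import pytest
from scipy import sparse

from scprs.cell_graph import CellGraph, norm_laplacian
from scprs.scprs_model import (ModelData, ModelParams, TrainConfig,
                               _forward_cache, _gradients, cross_validate,
                               evaluate, fit, forward, grid_search,
                               init_params, leaky_relu, loss, split_data)

from test_cell_graph import edge_sum_quadratic


def random_graph(m, rng, p=0.2):
    a = (rng.random((m, m)) < p).astype(float)
    a = np.triu(a, 1)
    a = a + a.T
    lap, deg = norm_laplacian(sparse.csr_matrix(a))
    return CellGraph(adjacency=sparse.csr_matrix(a), degrees=deg, k=0,
                     laplacian=lap)


def random_model_inputs(rng, n=8, m=6, f=4, n_layers=1):
    X = rng.normal(size=(n, m, f))
    g = random_graph(m, rng)
    p = init_params(f, m, n_layers, seed=int(rng.integers(1 << 30)))
    return X, g, p


def test_forward_trivial_logistic_half(rng):
    X, g, p = random_model_inputs(rng, n_layers=0)
    p.beta[:] = 0.0
    p.b = 0.0
    scores, latent = forward(p, X, g, task="binary")
    np.testing.assert_allclose(scores, 0.5)
    assert latent.shape == (8, 6)


def test_leaky_relu_slope():
    assert leaky_relu(np.array([-1.0]))[0] == pytest.approx(-0.1)
    assert leaky_relu(np.array([2.0]))[0] == pytest.approx(2.0)


@pytest.mark.parametrize("n_layers", [0, 1, 2])
def test_latent_monotone_in_inputs(n_layers, rng):
    X, g, p = random_model_inputs(rng, n_layers=n_layers)
    _, h = forward(p, X, g, task="regression")
    Xp = X.copy()
    Xp[2, 3, 1] += 1.0
    _, hp = forward(p, Xp, g, task="regression")
    assert (hp - h).min() >= -1e-12


def test_forward_shape_mismatch(rng):
    X, g, p = random_model_inputs(rng)
    with pytest.raises(ValueError, match="cells"):
        forward(p, X[:, :4, :], g)


def test_loss_trivial_and_edge_sum(rng):
    g = random_graph(6, rng)
    beta0 = np.zeros(6)
    y = np.array([0.0, 1.0, 1.0])
    perfect = np.array([1e-9, 1 - 1e-9, 1 - 1e-9])
    assert loss(perfect, y, beta0, g.laplacian, 0, 0, 0) < 1e-6
    # beta = 0: every penalty vanishes
    assert loss(np.full(3, 0.5), y, beta0, g.laplacian, 5, 7, 9) == \
        pytest.approx(loss(np.full(3, 0.5), y, beta0, g.laplacian, 0, 0, 0))
    beta = rng.normal(size=6)
    lam3 = 2.5
    with_lap = loss(perfect, y, beta, g.laplacian, 0, 0, lam3)
    without = loss(perfect, y, beta, g.laplacian, 0, 0, 0)
    assert with_lap - without == pytest.approx(
        lam3 * edge_sum_quadratic(g.adjacency, beta), abs=1e-10)


@pytest.mark.parametrize("task,n_layers", [("binary", 0), ("binary", 2),
                                           ("regression", 1)])
def test_gradients_match_finite_differences(task, n_layers, rng):
    X, g, p = random_model_inputs(rng, n=6, m=5, f=3, n_layers=n_layers)
    y = (rng.random(6) > 0.5).astype(float) if task == "binary" \
        else rng.normal(size=6)
    cfg = TrainConfig(task=task, n_layers=n_layers, lambda1=0.3,
                      lambda2=0.7, lambda3=1.1)
    P = g.propagation_matrix()
    L = g.laplacian

    def total_loss(params):
        z, hs, _ = _forward_cache(params, X, P, None)
        scores = 1 / (1 + np.exp(-z)) if task == "binary" else z
        return loss(scores, y, params.beta, L, cfg.lambda1, cfg.lambda2,
                    cfg.lambda3, task)

    _, grads = _gradients(p, X, y, P, L, cfg, None)
    names = ["W0", "w1", "w2", "beta", "b"]
    eps = 1e-6
    for gi, name in enumerate(names):
        arr = getattr(p, name) if name != "b" else None
        size = 1 if name == "b" else arr.size
        for j in range(size):
            q = p.copy()
            if name == "b":
                q.b += eps
            else:
                getattr(q, name).flat[j] += eps
            up = total_loss(q)
            if name == "b":
                q.b -= 2 * eps
            else:
                getattr(q, name).flat[j] -= 2 * eps
            dn = total_loss(q)
            num = (up - dn) / (2 * eps)
            got = grads[gi].flat[j] if name != "b" else grads[4][0]
            assert got == pytest.approx(num, abs=5e-5), f"{name}[{j}]"


def test_split_data_contract():
    y = np.array([0] * 50 + [1] * 50)
    tr, va, te = split_data(y, seed=3)
    assert (len(tr), len(va), len(te)) == (60, 20, 20)
    union = np.sort(np.concatenate([tr, va, te]))
    np.testing.assert_array_equal(union, np.arange(100))
    for part in (tr, va, te):
        assert abs(y[part].mean() - 0.5) < 0.05
    tr2, va2, te2 = split_data(y, seed=3)
    np.testing.assert_array_equal(tr, tr2)
    np.testing.assert_array_equal(te, te2)
    with pytest.raises(ValueError, match="class"):
        split_data(np.array([0, 0, 0, 0, 1, 1]), seed=0)


def separable_data(rng, n=60, m=20, task="binary"):
    y = np.concatenate([np.zeros(n // 2), np.ones(n // 2)])
    X = rng.normal(scale=0.3, size=(n, m, 21))
    X[:, 0, :] += y[:, None] * 2.0  # cell 0 carries the whole signal
    g = random_graph(m, rng)
    tr, va, te = split_data(y, seed=0, task=task)
    return ModelData(X=X, y=y, graph=g, train_idx=tr, val_idx=va,
                     test_idx=te)


def test_fit_separable_converges_and_is_deterministic(rng):
    data = separable_data(rng)
    cfg = TrainConfig(task="binary", n_layers=0, lambda2=0.01,
                      lambda3=0.01, epochs=60, seed=5)
    res = fit(data, cfg)
    assert res.loss_trace[9] < res.loss_trace[0]
    scores, _ = forward(res.params, data.X[data.train_idx], data.graph,
                        task="binary")
    assert evaluate(scores, data.y[data.train_idx])["auroc"] == 1.0
    res2 = fit(data, cfg)
    np.testing.assert_array_equal(res.loss_trace, res2.loss_trace)
    np.testing.assert_array_equal(res.params.beta, res2.params.beta)


def test_fit_signal_cell_gets_top_weight(rng):
    # one cell alone carries the signal; |beta| must concentrate there
    n, m = 200, 20
    y = np.concatenate([np.zeros(n // 2), np.ones(n // 2)])
    X = rng.normal(scale=0.5, size=(n, m, 21))
    X[:, 0, :] += y[:, None] * 1.5
    g = random_graph(m, rng)
    tr, va, te = split_data(y, seed=0)
    data = ModelData(X=X, y=y, graph=g, train_idx=tr, val_idx=va,
                     test_idx=te)
    cfg = TrainConfig(task="binary", n_layers=0, lambda2=1.0,
                      lambda3=0.0, epochs=200, seed=1)
    res = fit(data, cfg)
    assert np.argmax(np.abs(res.params.beta)) == 0


def test_ridge_monotonically_shrinks_beta(rng):
    data = separable_data(rng)
    norms = []
    for lam2 in (1.0, 1e6):
        cfg = TrainConfig(task="binary", n_layers=0, lambda2=lam2,
                          epochs=40, seed=2)
        norms.append(np.linalg.norm(fit(data, cfg).params.beta))
    assert norms[1] < norms[0]


def test_fit_regression_noiseless(tiny_pipe, tiny_bundle):
    from scprs.cell_prs import normalize_prs
    from scprs.synthetic_data import simulate

    from conftest import tiny_sim_config

    bundle = simulate(tiny_sim_config(sigma=0.0, seed=3))
    from scprs.workflows import prepare_features

    pipe = prepare_features(bundle)
    y = bundle["y_obs"]
    tr, va, te = split_data(y, seed=0, task="regression")
    tens = normalize_prs(pipe.tensor, tr)
    data = ModelData(X=tens.values, y=y, graph=pipe.graph, train_idx=tr,
                     val_idx=va, test_idx=te)
    res = fit(data, TrainConfig(task="regression", n_layers=0,
                                lambda2=1.0, lambda3=0.1, seed=0))
    assert res.test_metrics["pearson_r"] > 0.95


def test_evaluate_matches_pair_counting(rng):
    y = np.array([0, 0, 0, 0, 1, 1, 1, 0, 1, 1])
    s = np.array([0.1, 0.4, 0.35, 0.8, 0.65, 0.9, 0.9, 0.9, 0.2, 0.7])
    got = evaluate(s, y)["auroc"]
    pos = np.flatnonzero(y == 1)
    neg = np.flatnonzero(y == 0)
    conc = sum((s[i] > s[j]) + 0.5 * (s[i] == s[j])
               for i in pos for j in neg)
    assert got == pytest.approx(conc / (len(pos) * len(neg)), abs=1e-10)
    perfect = evaluate(np.array([0.1, 0.9]), np.array([0, 1]))
    assert perfect == {"auroc": 1.0, "auprc": 1.0}
    with pytest.raises(ValueError, match="single-class"):
        evaluate(np.array([0.1, 0.9]), np.array([1, 1]))


def test_evaluate_null_auroc_near_half(rng):
    y = rng.integers(0, 2, size=4000)
    s = rng.random(4000)
    assert evaluate(s, y)["auroc"] == pytest.approx(0.5, abs=0.05)


def test_grid_search_selection(rng):
    # weak multivariate signal: an untrained model cannot separate, a
    # trained one can, so the trained config strictly dominates
    n, m = 200, 20
    y = np.concatenate([np.zeros(n // 2), np.ones(n // 2)])
    X = rng.normal(size=(n, m, 21))
    X[:, :, 0] += y[:, None]
    g = random_graph(m, rng)
    tr, va, te = split_data(y, seed=0)
    data = ModelData(X=X, y=y, graph=g, train_idx=tr, val_idx=va,
                     test_idx=te)
    good = TrainConfig(task="binary", n_layers=0, lambda2=1.0, epochs=200,
                       seed=0)
    bad = TrainConfig(task="binary", n_layers=0, lambda2=1.0, epochs=2,
                      lr=1e-6, seed=0)
    best, fits = grid_search(data, [bad, good], seed=0)
    assert fits[1].val_metric > fits[0].val_metric
    assert best.config == good
    assert best.val_metric == max(f.val_metric for f in fits)
    only, _ = grid_search(data, [good])
    assert only.val_metric == pytest.approx(fit(data, good).val_metric)


def test_cross_validate_bookkeeping(rng):
    data = separable_data(rng, n=40)
    cfgs = [TrainConfig(task="binary", n_layers=0, lambda2=0.01, epochs=20,
                        seed=0),
            TrainConfig(task="binary", n_layers=0, lambda2=1e6, epochs=5,
                        seed=0)]
    best_cfg, final, means = cross_validate(data, cfgs, folds=4, repeats=2)
    assert best_cfg == cfgs[int(np.argmax(means))]
    assert len(final.splits["train"]) == 40  # final model uses all samples
    one_cfg, _, _ = cross_validate(data, [cfgs[0]], folds=4, repeats=1)
    assert one_cfg == cfgs[0]


def test_fit_extra_features_used(rng):
    n, m = 60, 6
    y = np.concatenate([np.zeros(n // 2), np.ones(n // 2)])
    X = rng.normal(scale=0.1, size=(n, m, 21))  # uninformative cells
    extra = np.column_stack([y * 2 + rng.normal(scale=0.1, size=n)])
    g = random_graph(m, rng)
    tr, va, te = split_data(y, seed=0)
    data = ModelData(X=X, y=y, graph=g, extra=extra, train_idx=tr,
                     val_idx=va, test_idx=te)
    cfg = TrainConfig(task="binary", n_layers=0, epochs=200, lambda2=1.0,
                      use_extra=True, seed=0)
    res = fit(data, cfg)
    assert res.test_metrics["auroc"] > 0.9
    assert res.params.gamma is not None
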