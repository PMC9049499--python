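"""Loss, optimization, best-loss selection, metrics and ablation wiring."""

import numpy as np
import pytest

from mvgat.multiview_graph import MultiViewNetwork
from mvgat.synthetic_data import fixture_toy_network
from mvgat.training_eval import (
    Adam,
    TrainConfig,
    TrainTrace,
    ablation_run,
    accuracy,
    cross_entropy,
    fit_network,
    metric_report,
    precision_recall_f1,
    select_best,
)

from conftest import random_network


# ------------------------------------------------------------- cross_entropy
def test_perfect_prediction_loss_near_zero():
    y = np.array([0, 1, 2], dtype=np.intp)
    p = np.eye(3)
    assert cross_entropy(y, p, np.ones(3, bool)) <= 3 * 1e-11


def test_binary_half_probabilities_closed_form():
    V = 7
    y = np.array([[1], [0], [1], [1], [0], [0], [1]], dtype=float)
    p = np.full((V, 1), 0.5)
    np.testing.assert_allclose(cross_entropy(y, p, np.ones(V, bool)), V * np.log(2), atol=1e-10)


def test_cross_entropy_matches_scalar_loop():
    rng = np.random.default_rng(0)
    # multiclass
    y = rng.integers(0, 3, 5).astype(np.intp)
    p = rng.dirichlet(np.ones(3), size=5)
    mask = np.array([True, False, True, True, True])
    expected = -sum(np.log(max(p[i, y[i]], 1e-12)) for i in range(5) if mask[i])
    np.testing.assert_allclose(cross_entropy(y, p, mask), expected, atol=1e-10)
    # multilabel
    yb = rng.integers(0, 2, (5, 4)).astype(float)
    pb = np.clip(rng.random((5, 4)), 1e-6, 1 - 1e-6)
    expected = 0.0
    for i in range(5):
        if not mask[i]:
            continue
        for c in range(4):
            expected -= yb[i, c] * np.log(pb[i, c]) + (1 - yb[i, c]) * np.log(1 - pb[i, c])
    np.testing.assert_allclose(cross_entropy(yb, pb, mask), expected, atol=1e-10)


def test_cross_entropy_empty_mask_raises():
    with pytest.raises(ValueError):
        cross_entropy(np.array([0]), np.array([[1.0]]), np.array([False]))


def test_loss_invariant_to_node_ordering():
    rng = np.random.default_rng(1)
    y = rng.integers(0, 3, 6).astype(np.intp)
    p = rng.dirichlet(np.ones(3), size=6)
    mask = np.array([True, True, False, True, True, True])
    perm = rng.permutation(6)
    np.testing.assert_allclose(
        cross_entropy(y, p, mask), cross_entropy(y[perm], p[perm], mask[perm]), atol=1e-12
    )


# --------------------------------------------------------------- select_best
def test_select_best_takes_argmin():
    trace = TrainTrace(
        selection_losses=[0.9, 0.4, 0.6],
        predictions=[np.array([0]), np.array([1]), np.array([2])],
    )
    assert trace.best_iteration == 1
    np.testing.assert_array_equal(select_best(trace), [1])


def test_select_best_strictly_decreasing_takes_last():
    trace = TrainTrace(
        selection_losses=[3.0, 2.0, 1.0],
        predictions=[np.array([0]), np.array([1]), np.array([2])],
    )
    np.testing.assert_array_equal(select_best(trace), [2])


def test_select_best_tie_takes_earliest():
    trace = TrainTrace(
        selection_losses=[0.5, 0.5],
        predictions=[np.array([7]), np.array([8])],
    )
    np.testing.assert_array_equal(select_best(trace), [7])


def test_select_best_invariant_to_appending_worse_iterations():
    trace = TrainTrace(selection_losses=[0.5, 0.3], predictions=[np.array([1]), np.array([2])])
    before = select_best(trace).copy()
    trace.selection_losses += [0.4, 0.9]
    trace.predictions += [np.array([3]), np.array([4])]
    np.testing.assert_array_equal(select_best(trace), before)


# ------------------------------------------------------------------- metrics
def test_accuracy_examples():
    y = np.array([0, 1, 2, 1])
    assert accuracy(y, y.copy()) == 1.0
    assert accuracy(y, (y + 1) % 3) == 0.0
    pred = y.copy()
    pred[0] = 9
    assert accuracy(y, pred) == 0.75


def test_accuracy_empty_mask_raises():
    with pytest.raises(ValueError):
        accuracy(np.array([0]), np.array([0]), np.array([False]))


def test_precision_recall_f1_counts():
    assert precision_recall_f1(np.array([1, 1, 0]), np.array([1, 1, 0])) == (1.0, 1.0, 1.0)
    # TP=1, FP=1, FN=1
    p, r, f1 = precision_recall_f1(np.array([1, 0, 1, 0]), np.array([1, 1, 0, 0]))
    assert (p, r, f1) == (0.5, 0.5, 0.5)
    # TP=0, FP=2, FN=3 -> zero convention
    p, r, f1 = precision_recall_f1(np.array([1, 1, 1, 0, 0]), np.array([0, 0, 0, 1, 1]))
    assert (p, r, f1) == (0.0, 0.0, 0.0)


def test_f1_equals_harmonic_mean_closed_form_and_sklearn():
    from sklearn.metrics import f1_score, precision_score, recall_score

    rng = np.random.default_rng(2)
    y = rng.integers(0, 2, (20, 5))
    pred = rng.integers(0, 2, (20, 5))
    p, r, f1 = precision_recall_f1(y, pred)
    assert 0.0 <= p <= 1.0 and 0.0 <= r <= 1.0 and 0.0 <= f1 <= 1.0
    np.testing.assert_allclose(f1, 2 * p * r / (p + r), atol=1e-12)
    np.testing.assert_allclose(p, precision_score(y, pred, average="micro"), atol=1e-12)
    np.testing.assert_allclose(r, recall_score(y, pred, average="micro"), atol=1e-12)
    np.testing.assert_allclose(f1, f1_score(y, pred, average="micro"), atol=1e-12)


def test_metrics_permutation_invariant():
    rng = np.random.default_rng(3)
    y = rng.integers(0, 3, 12)
    pred = rng.integers(0, 3, 12)
    perm = rng.permutation(12)
    assert accuracy(y, pred) == accuracy(y[perm], pred[perm])
    assert precision_recall_f1(y, pred) == precision_recall_f1(y[perm], pred[perm])


# ------------------------------------------------------------------ training
def test_zero_learning_rate_freezes_parameters_and_loss():
    net = fixture_toy_network()
    cfg = TrainConfig(epochs=3, learning_rate=0.0, seed=0)
    params, trace = fit_network(net, cfg)
    assert len(set(np.round(trace.train_losses, 12))) == 1
    fresh = fit_network(net, TrainConfig(epochs=1, learning_rate=0.0, seed=0))[0]
    for a, b in zip(params.parameters(), fresh.parameters()):
        np.testing.assert_array_equal(a.data, b.data)


def test_fixed_seed_reproduces_loss_trajectory():
    net = fixture_toy_network()
    cfg = TrainConfig(epochs=5, seed=3)
    _, t1 = fit_network(net, cfg)
    _, t2 = fit_network(net, cfg)
    assert t1.train_losses == t2.train_losses
    for a, b in zip(t1.predictions, t2.predictions):
        np.testing.assert_array_equal(a, b)


def test_loss_decreases_on_separable_fixture():
    net = fixture_toy_network()
    _, trace = fit_network(net, TrainConfig(epochs=51, seed=0))
    assert trace.train_losses[50] < trace.train_losses[0]


def test_non_finite_loss_raises_with_iteration():
    from mvgat.multiview_graph import neighborhoods
    from mvgat.training_eval import init_model_params, train_epoch

    rng = np.random.default_rng(9)
    net = random_network(rng, n_nodes=6)
    cfg = TrainConfig(epochs=2, seed=0)
    params = init_model_params(net, cfg)
    params.parameters()[0].data[:] = np.nan
    nbrs = [neighborhoods(v) for v in net.views]
    opt = Adam(params.parameters(), lr=cfg.learning_rate)
    with pytest.raises(FloatingPointError, match="iteration 0"):
        train_epoch(params, opt, net, nbrs, epoch=0)


def test_adam_moves_toward_minimum():
    from mvgat.autodiff import Tensor

    p = Tensor(np.array([5.0]), requires_grad=True)
    opt = Adam([p], lr=0.1)
    for _ in range(200):
        opt.zero_grad()
        loss = (p * p).sum()
        loss.backward()
        opt.step()
    assert abs(p.data[0]) < 0.1


# ----------------------------------------------------------------- ablations
def _single_view_net(rng):
    return random_network(rng, n_nodes=8, n_views=1, n_feat=3, n_classes=2)


def test_full_equals_mmv_on_single_view_network():
    rng = np.random.default_rng(21)
    net = _single_view_net(rng)
    cfg = TrainConfig(epochs=4, seed=5)
    rep_full, _, tr_full = ablation_run(net, "full", cfg)
    rep_mmv, _, tr_mmv = ablation_run(net, "mmv", cfg)
    assert tr_full.train_losses == tr_mmv.train_losses
    np.testing.assert_array_equal(select_best(tr_full), select_best(tr_mmv))


def test_sv_on_single_view_network_equals_full():
    rng = np.random.default_rng(22)
    net = _single_view_net(rng)
    cfg = TrainConfig(epochs=4, seed=5)
    _, _, tr_full = ablation_run(net, "full", cfg)
    _, _, tr_sv = ablation_run(net, "sv", cfg, view_index=0)
    assert tr_full.train_losses == tr_sv.train_losses


def test_ablation_rejects_unknown_variant():
    rng = np.random.default_rng(23)
    with pytest.raises(ValueError):
        ablation_run(_single_view_net(rng), "bogus", TrainConfig(epochs=1))


def test_metric_report_covers_available_splits():
    net = fixture_toy_network()
    rep = metric_report(net, net.labels.copy())
    assert set(rep) == {"train"}  # toy fixture is all-train
    assert rep["train"]["accuracy"] == 1.0
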