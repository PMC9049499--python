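"""Per-view attention encoder: hand oracles, dense-matrix oracles,
normalization, equivariance, locality and initialization."""

import numpy as np
import pytest

from mvgat.autodiff import Tensor
from mvgat.multiview_graph import EdgeSet, neighborhoods
from mvgat.node_attention import (
    AttentionHeadParams,
    GATLayerParams,
    ViewEncoderParams,
    attention_coefficients,
    head_update,
    init_encoder,
    layer_forward,
    view_encode,
)

from conftest import random_edge_set
from oracles import dense_adjacency, dense_attention, dense_encoder, dense_layer


def _head(W, a):
    return AttentionHeadParams(W=Tensor(np.asarray(W, float)), a=Tensor(np.asarray(a, float)))


def _path3():
    return neighborhoods(EdgeSet.from_pairs([(0, 1), (1, 2)], 3), include_self=True)


# ------------------------------------------------------ attention_coefficients
def test_single_neighbor_softmax_is_one():
    nbr = neighborhoods(EdgeSet.from_pairs([], 1), include_self=True)
    alpha = attention_coefficients(np.array([[3.0]]), nbr, _head([[2.0]], [1.0, 1.0]))
    np.testing.assert_allclose(alpha[0], [1.0])


def test_zero_weight_matrix_gives_uniform_coefficients():
    nbr = _path3()
    x = np.random.default_rng(0).normal(size=(3, 2))
    alpha = attention_coefficients(x, nbr, _head(np.zeros((2, 2)), np.ones(4)))
    for i, lst in enumerate(nbr.lists):
        np.testing.assert_allclose(alpha[i], np.full(len(lst), 1.0 / len(lst)))


def test_path_coefficients_match_dense_hand_enumeration():
    nbr = _path3()
    x = np.array([[1.0], [2.0], [3.0]])
    W, a, slope = np.array([[1.0]]), np.array([1.0, 1.0]), 0.2
    alpha = attention_coefficients(x, nbr, _head(W, a), leaky_slope=slope)
    A = dense_adjacency(EdgeSet.from_pairs([(0, 1), (1, 2)], 3), include_self=True)
    dense = dense_attention(x, A, W, a, slope)
    for i, lst in enumerate(nbr.lists):
        np.testing.assert_allclose(alpha[i], dense[i, list(lst)], atol=1e-10)


def test_empty_neighborhood_raises_with_hint():
    nbr = neighborhoods(EdgeSet.from_pairs([(0, 1)], 3), include_self=False)
    with pytest.raises(ValueError, match="include_self"):
        attention_coefficients(np.zeros((3, 1)), nbr, _head([[1.0]], [1.0, 1.0]))


def test_large_scores_do_not_overflow():
    nbr = _path3()
    x = np.array([[1e4], [-1e4], [5e3]])
    alpha = attention_coefficients(x, nbr, _head([[1.0]], [1.0, 1.0]))
    for arr in alpha:
        assert np.isfinite(arr).all()
        np.testing.assert_allclose(arr.sum(), 1.0, atol=1e-12)


# ------------------------------------------------------------------ head_update
def test_head_update_identity_on_self_one_hot():
    nbr = _path3()
    x = np.random.default_rng(1).normal(size=(3, 2))
    alpha = []
    for i, lst in enumerate(nbr.lists):
        w = np.zeros(len(lst))
        w[lst.index(i)] = 1.0
        alpha.append(w)
    out = head_update(x, alpha, nbr, _head(np.eye(2), np.ones(4)))
    np.testing.assert_allclose(out, x)


def test_head_update_convexity_identical_neighbors():
    nbr = neighborhoods(EdgeSet.from_pairs([(0, 1), (0, 2)], 3), include_self=False)
    shared = np.array([0.4, -0.7])
    x = np.vstack([[9.0, 9.0], shared, shared])
    alpha = [np.array([0.5, 0.5]), np.array([1.0]), np.array([1.0])]
    out = head_update(x, alpha, nbr, _head(np.eye(2), np.ones(4)))
    np.testing.assert_allclose(out[0], shared)


def test_head_update_matches_dense_matmul_oracle():
    rng = np.random.default_rng(8)
    es = random_edge_set(rng, 8, p=0.4)
    nbr = neighborhoods(es, include_self=True)
    x = rng.normal(size=(8, 3))
    head = _head(rng.normal(size=(3, 2)), rng.normal(size=4))
    alpha = attention_coefficients(x, nbr, head)
    out = head_update(x, alpha, nbr, head)
    dense_alpha = np.zeros((8, 8))
    for i, (lst, arr) in enumerate(zip(nbr.lists, alpha)):
        dense_alpha[i, list(lst)] = arr
    np.testing.assert_allclose(out, dense_alpha @ (x @ head.W.data), atol=1e-8)


def test_head_update_rejects_mismatched_alpha():
    nbr = _path3()
    with pytest.raises(ValueError):
        head_update(np.zeros((3, 1)), [np.array([1.0])] * 3, nbr, _head([[1.0]], [1.0, 1.0]))


# ---------------------------------------------------------------- layer_forward
def test_single_head_concat_equals_average_with_identity_activation():
    rng = np.random.default_rng(3)
    es = random_edge_set(rng, 6)
    nbr = neighborhoods(es, include_self=True)
    x = rng.normal(size=(6, 3))
    head = _head(rng.normal(size=(3, 2)), rng.normal(size=4))
    cat = layer_forward(x, nbr, GATLayerParams([head], mode="concat", activation="identity"))
    avg = layer_forward(x, nbr, GATLayerParams([head], mode="average", activation="identity"))
    np.testing.assert_array_equal(cat, avg)


def test_identical_heads_concat_duplicates():
    rng = np.random.default_rng(5)
    es = random_edge_set(rng, 6)
    nbr = neighborhoods(es, include_self=True)
    x = rng.normal(size=(6, 3))
    head = _head(rng.normal(size=(3, 2)), rng.normal(size=4))
    single = layer_forward(x, nbr, GATLayerParams([head], mode="concat"))
    quad = layer_forward(x, nbr, GATLayerParams([head] * 4, mode="concat"))
    np.testing.assert_array_equal(quad, np.hstack([single] * 4))


@pytest.mark.parametrize("mode", ["concat", "average"])
def test_two_head_layer_matches_dense_pipeline(mode):
    rng = np.random.default_rng(9)
    es = random_edge_set(rng, 9, p=0.4)
    nbr = neighborhoods(es, include_self=True)
    x = rng.normal(size=(9, 4))
    heads = [_head(rng.normal(size=(4, 3)), rng.normal(size=6)) for _ in range(2)]
    layer = GATLayerParams(heads, mode=mode, activation="elu")
    out = layer_forward(x, nbr, layer)
    A = dense_adjacency(es, include_self=True)
    expected = dense_layer(x, A, [(h.W.data, h.a.data) for h in heads], mode, "elu", 0.2)
    np.testing.assert_allclose(out, expected, atol=1e-8)


def test_layer_rejects_unknown_mode():
    with pytest.raises(ValueError):
        GATLayerParams([_head([[1.0]], [1.0, 1.0])], mode="stack")


# ------------------------------------------------------------------ view_encode
def test_depth_one_average_encoder_reduces_to_layer_forward():
    rng = np.random.default_rng(12)
    es = random_edge_set(rng, 7)
    nbr = neighborhoods(es, include_self=True)
    x = rng.normal(size=(7, 3))
    heads = [_head(rng.normal(size=(3, 2)), rng.normal(size=4)) for _ in range(2)]
    layer = GATLayerParams(heads, mode="average", activation="identity")
    enc = ViewEncoderParams([layer], dropout_input=0.0, dropout_attention=0.0)
    np.testing.assert_array_equal(view_encode(x, nbr, enc), layer_forward(x, nbr, layer))


def test_eval_mode_is_deterministic_without_rng():
    rng = np.random.default_rng(13)
    es = random_edge_set(rng, 8)
    nbr = neighborhoods(es, include_self=True)
    x = rng.normal(size=(8, 4))
    enc = init_encoder([4, 3, 2], n_heads=2, seed=0)
    a = view_encode(x, nbr, enc, training=False)
    b = view_encode(x, nbr, enc, training=False)
    np.testing.assert_array_equal(a, b)


def test_training_mode_reproduces_with_fixed_seed():
    rng = np.random.default_rng(14)
    es = random_edge_set(rng, 8)
    nbr = neighborhoods(es, include_self=True)
    x = rng.normal(size=(8, 4))
    enc = init_encoder([4, 3, 2], n_heads=2, seed=0)
    a = view_encode(x, nbr, enc, rng=np.random.default_rng(42), training=True)
    b = view_encode(x, nbr, enc, rng=np.random.default_rng(42), training=True)
    np.testing.assert_array_equal(a, b)
    c = view_encode(x, nbr, enc, rng=np.random.default_rng(43), training=True)
    assert not np.array_equal(a, c)


def test_two_layer_encoder_matches_dense_oracle_eval_mode():
    rng = np.random.default_rng(15)
    es = random_edge_set(rng, 10, p=0.35)
    nbr = neighborhoods(es, include_self=True)
    x = rng.normal(size=(10, 5))
    enc = init_encoder([5, 4, 3], n_heads=2, seed=7)
    out = view_encode(x, nbr, enc, training=False)
    A = dense_adjacency(es, include_self=True)
    layers = [
        ([(h.W.data, h.a.data) for h in layer.heads], layer.mode, layer.activation)
        for layer in enc.layers
    ]
    np.testing.assert_allclose(out, dense_encoder(x, A, layers, 0.2), atol=1e-8)


# -------------------------------------------------------- properties/invariants
@pytest.mark.parametrize("seed", range(8))
def test_attention_rows_normalize(seed):
    rng = np.random.default_rng(seed)
    es = random_edge_set(rng, 10)
    nbr = neighborhoods(es, include_self=True)
    x = rng.normal(size=(10, 3))
    head = _head(rng.normal(size=(3, 2)), rng.normal(size=4))
    for arr in attention_coefficients(x, nbr, head):
        np.testing.assert_allclose(arr.sum(), 1.0, atol=1e-6)


@pytest.mark.parametrize("seed", range(5))
def test_permutation_equivariance(seed):
    rng = np.random.default_rng(100 + seed)
    es = random_edge_set(rng, 9, p=0.4)
    nbr = neighborhoods(es, include_self=True)
    x = rng.normal(size=(9, 4))
    enc = init_encoder([4, 3, 2], n_heads=2, seed=seed)
    out = view_encode(x, nbr, enc)
    pi = rng.permutation(9)
    inv = np.argsort(pi)
    es_p = EdgeSet.from_pairs([(inv[i], inv[j]) for i, j in es.edges], 9)
    out_p = view_encode(x[pi], neighborhoods(es_p, include_self=True), enc)
    np.testing.assert_allclose(out_p, out[pi], atol=1e-6)


def test_locality_single_layer():
    rng = np.random.default_rng(77)
    es = EdgeSet.from_pairs([(0, 1), (2, 3)], 4)  # node 0 cannot see nodes 2, 3
    nbr = neighborhoods(es, include_self=True)
    x = rng.normal(size=(4, 3))
    heads = [_head(rng.normal(size=(3, 2)), rng.normal(size=4))]
    layer = GATLayerParams(heads, mode="concat")
    before = layer_forward(x, nbr, layer)
    x2 = x.copy()
    x2[3] += 10.0
    after = layer_forward(x2, nbr, layer)
    np.testing.assert_array_equal(before[0], after[0])
    np.testing.assert_array_equal(before[1], after[1])
    assert not np.array_equal(before[3], after[3])


# ------------------------------------------------------------------ init
def test_init_same_seed_bitwise_identical():
    a = init_encoder([5, 4, 3], n_heads=3, seed=9)
    b = init_encoder([5, 4, 3], n_heads=3, seed=9)
    for pa, pb in zip(a.parameters(), b.parameters()):
        np.testing.assert_array_equal(pa.data, pb.data)
    c = init_encoder([5, 4, 3], n_heads=3, seed=10)
    assert any(
        not np.array_equal(pa.data, pc.data) for pa, pc in zip(a.parameters(), c.parameters())
    )


def test_init_respects_glorot_bound():
    enc = init_encoder([6, 5, 4], n_heads=2, seed=1)
    for layer in enc.layers:
        for head in layer.heads:
            bound = np.sqrt(6.0 / (head.f_in + head.f_out))
            assert np.all(np.abs(head.W.data) <= bound)


def test_init_mean_near_zero_over_many_draws():
    f_in, f_out, n = 10, 10, 100
    draws = np.concatenate(
        [init_encoder([f_in, f_out], n_heads=1, seed=s).layers[0].heads[0].W.data.ravel()
         for s in range(n)]
    )
    bound = np.sqrt(6.0 / (f_in + f_out))
    se = (2 * bound / np.sqrt(12)) / np.sqrt(draws.size)
    assert abs(draws.mean()) < 4 * se


def test_init_rejects_nonchaining_dims():
    with pytest.raises(ValueError):
        init_encoder([5], n_heads=2, seed=0)
    with pytest.raises(ValueError):
        ViewEncoderParams(
            [init_encoder([5, 4], 2, 0).layers[0], init_encoder([3, 2], 2, 0).layers[0]]
        )
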