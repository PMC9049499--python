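"""Independent dense-matrix oracles for the sparse attention pipeline.

Everything here works on full V x V matrices with -inf masking and plain
numpy, sharing no code with the sparse implementation under test.
"""

import numpy as np


def dense_adjacency(edge_set, include_self=True) -> np.ndarray:
    V = edge_set.n_nodes
    A = np.zeros((V, V), dtype=bool)
    for i, j in edge_set.edges:
        A[i, j] = A[j, i] = True
    if include_self:
        np.fill_diagonal(A, True)
    return A


def dense_attention(x, A, W, a, slope) -> np.ndarray:
    """Row-softmax attention matrix restricted to the adjacency support."""
    h = x @ W
    F = W.shape[1]
    scores = np.add.outer(h @ a[:F], h @ a[F:])  # scores[i, j] = a.[h_i || h_j]
    scores = np.where(scores > 0, scores, slope * scores)
    scores = np.where(A, scores, -np.inf)
    scores = scores - scores.max(axis=1, keepdims=True)
    e = np.exp(scores)
    return e / e.sum(axis=1, keepdims=True)


def dense_head(x, A, W, a, slope) -> np.ndarray:
    alpha = dense_attention(x, A, W, a, slope)
    return alpha @ (x @ W)


def _elu(z):
    return np.where(z > 0, z, np.exp(np.minimum(z, 0)) - 1.0)


def dense_layer(x, A, heads, mode, activation, slope) -> np.ndarray:
    outs = [dense_head(x, A, W, a, slope) for W, a in heads]
    act = _elu if activation == "elu" else (lambda z: z)
    if mode == "concat":
        return np.concatenate([act(o) for o in outs], axis=1)
    return act(np.mean(outs, axis=0))


def dense_encoder(x, A, layers, slope) -> np.ndarray:
    h = x
    for heads, mode, activation in layers:
        h = dense_layer(h, A, heads, mode, activation, slope)
    return h
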