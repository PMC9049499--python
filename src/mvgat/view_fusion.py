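"""Attention over views and fusion into the global node representation.

Given per-view node representations X^(1)..X^(k) (each V x F), a view-level
attention scores every ordered view pair per node,

    s_ij(v)  = LeakyReLU( b^T [ T x_v^(i) || T x_v^(j) ] )
    beta_ij(v) = softmax_j( s_ij(v) )

and the fused representation is a per-node convex combination of the views,
Z_v = sum_j w_j(v) x_v^(j).  The scoring leaves the query view i free; the
default resolves it symmetrically by averaging beta over queries, which
reduces to the identity at k = 1 and keeps Z a convex combination.  An
alternative ("mean_view") scores a single query built from the elementwise
mean of the views, and a "global" scope pools node representations before
scoring so every node shares one weight per view.
"""

from __future__ import annotations

from dataclasses import dataclass

import numpy as np

from .autodiff import Tensor

__all__ = [
    "ViewFusionParams",
    "ViewAttention",
    "view_attention",
    "fuse",
    "mean_fuse",
    "predict",
]


@dataclass
class ViewFusionParams:
    T: Tensor  # F x F'
    b: Tensor  # 2 * F'
    leaky_slope: float = 0.2

    def __post_init__(self):
        if self.b.shape != (2 * self.T.shape[1],):
            raise ValueError(
                f"scoring vector b has shape {self.b.shape}, expected ({2 * self.T.shape[1]},)"
            )
        if not (np.isfinite(self.T.data).all() and np.isfinite(self.b.data).all()):
            raise ValueError("non-finite fusion parameters")

    def parameters(self) -> list[Tensor]:
        return [self.T, self.b]


@dataclass
class ViewAttention:
    """Per-node view-attention coefficients.

    beta has shape (V, k, k): beta[v, i, j] weights key view j for query
    view i at node v, each query row summing to 1.  marginal (V, k) is the
    per-view weight actually used for fusion.
    """

    beta: np.ndarray
    marginal: np.ndarray


def init_fusion(
    f_in: int,
    f_hidden: int | None = None,
    seed: int | np.random.Generator = 0,
    leaky_slope: float = 0.2,
) -> ViewFusionParams:
    rng = seed if isinstance(seed, np.random.Generator) else np.random.default_rng(seed)
    f_hidden = f_hidden if f_hidden is not None else f_in
    bound_T = np.sqrt(6.0 / (f_in + f_hidden))
    bound_b = np.sqrt(6.0 / (2 * f_hidden + 1))
    T = Tensor(rng.uniform(-bound_T, bound_T, size=(f_in, f_hidden)), requires_grad=True)
    b = Tensor(rng.uniform(-bound_b, bound_b, size=(2 * f_hidden,)), requires_grad=True)
    return ViewFusionParams(T=T, b=b, leaky_slope=leaky_slope)


# ---------------------------------------------------------------- internals
def _check_views(view_reps) -> tuple[int, int]:
    if len(view_reps) < 1:
        raise ValueError("need at least one view")
    V, F = view_reps[0].shape
    for m, X in enumerate(view_reps):
        if X.shape != (V, F):
            raise ValueError(f"view {m} has shape {X.shape}, expected {(V, F)}")
    return V, F


def _rowmax_softmax(scores: list[Tensor]) -> list[Tensor]:
    """Softmax across a list of same-shaped score tensors (per element)."""
    shift = np.max([s.data for s in scores], axis=0)  # constant; softmax is shift-invariant
    exps = [(s - Tensor(shift)).exp() for s in scores]
    denom = exps[0]
    for e in exps[1:]:
        denom = denom + e
    return [e / denom for e in exps]


def view_attention_t(
    view_reps: list[Tensor],
    params: ViewFusionParams,
    scope: str = "per_node",
    query: str = "mean_over_queries",
) -> tuple[list[Tensor], list[list[Tensor]]]:
    """Differentiable view attention.

    Returns (marginals, beta) where marginals is a list of k tensors of
    per-node weights (each shape (V,), summing to 1 across the list) and
    beta[i][j] are the per-query coefficient tensors (empty inner structure
    for query="mean_view", where beta has a single query row).
    """
    k = len(view_reps)
    V, F = _check_views([t.data for t in view_reps])
    if scope not in ("per_node", "global"):
        raise ValueError(f"unknown fusion scope {scope!r}")
    if query not in ("mean_over_queries", "mean_view"):
        raise ValueError(f"unknown fusion query {query!r}")

    if scope == "global":
        reps = [X.mean(axis=0, keepdims=True) for X in view_reps]  # 1 x F each
    else:
        reps = view_reps

    f_h = params.T.shape[1]
    from .autodiff import gather_rows

    b_i = gather_rows(params.b, np.arange(f_h))
    b_j = gather_rows(params.b, np.arange(f_h, 2 * f_h))
    H = [X @ params.T for X in reps]
    u = [h @ b_i for h in H]  # query-side score contribution, shape (n,)
    w = [h @ b_j for h in H]  # key-side score contribution

    if query == "mean_view":
        from .autodiff import stack_mean

        Hq = stack_mean(H)
        uq = Hq @ b_i
        scores = [(uq + w[j]).leaky_relu(params.leaky_slope) for j in range(k)]
        betas = [_rowmax_softmax(scores)]
        marginals = betas[0]
    else:
        betas = []
        for i in range(k):
            scores = [(u[i] + w[j]).leaky_relu(params.leaky_slope) for j in range(k)]
            betas.append(_rowmax_softmax(scores))
        marginals = [stack_mean_over_queries([betas[i][j] for i in range(k)]) for j in range(k)]

    if scope == "global":
        # broadcast the single pooled weight to every node
        ones = Tensor(np.ones((V, 1)))
        marginals = [ones @ m.reshape(1) for m in marginals]
        betas = [[ones @ b.reshape(1) for b in row] for row in betas]
    return marginals, betas


def stack_mean_over_queries(ts: list[Tensor]) -> Tensor:
    out = ts[0]
    for t in ts[1:]:
        out = out + t
    return out * (1.0 / len(ts))


def fuse_t(view_reps: list[Tensor], marginals: list[Tensor]) -> Tensor:
    if len(view_reps) != len(marginals):
        raise ValueError("one marginal weight per view required")
    V, F = _check_views([t.data for t in view_reps])
    Z = marginals[0].reshape(V, 1) * view_reps[0]
    for w_j, X in zip(marginals[1:], view_reps[1:]):
        Z = Z + w_j.reshape(V, 1) * X
    return Z


# ----------------------------------------------------------- public (numpy)
def view_attention(
    view_reps: list[np.ndarray],
    params: ViewFusionParams,
    scope: str = "per_node",
    query: str = "mean_over_queries",
) -> ViewAttention:
    k = len(view_reps)
    V, _ = _check_views(view_reps)
    marg_t, beta_t = view_attention_t(
        [Tensor(np.asarray(X, dtype=np.float64)) for X in view_reps], params, scope, query
    )
    marginal = np.stack([m.data.reshape(V) for m in marg_t], axis=1)
    n_query = len(beta_t)
    beta = np.zeros((V, k, k))
    for i in range(k):
        row = beta_t[i] if n_query == k else beta_t[0]
        for j in range(k):
            beta[:, i, j] = row[j].data.reshape(V)
    return ViewAttention(beta=beta, marginal=marginal)


def fuse(view_reps: list[np.ndarray], attn: ViewAttention) -> np.ndarray:
    """Per-node convex combination of view representations, weighted by the
    fusion marginal."""
    k = len(view_reps)
    if attn.marginal.shape[1] != k:
        raise ValueError(
            f"attention was computed for {attn.marginal.shape[1]} views, got {k}"
        )
    V, F = _check_views(view_reps)
    Z = np.zeros((V, F))
    for j, X in enumerate(view_reps):
        Z += attn.marginal[:, j : j + 1] * np.asarray(X)
    return Z


def mean_fuse(view_reps: list[np.ndarray]) -> np.ndarray:
    """Unweighted elementwise mean across views (the mean-fusion ablation)."""
    if len(view_reps) == 0:
        raise ValueError("need at least one view")
    _check_views(view_reps)
    return np.mean([np.asarray(X, dtype=np.float64) for X in view_reps], axis=0)


def predict(Z: np.ndarray, task: str = "multiclass") -> tuple[np.ndarray, np.ndarray]:
    """Class probabilities and hard labels from fused logits.

    multiclass: row softmax and argmax (lowest index wins ties).
    multilabel: elementwise sigmoid; the label set is entries > 0.5,
    returned as a binary matrix.
    """
    Z = np.asarray(Z, dtype=np.float64)
    if not np.isfinite(Z).all():
        raise ValueError("non-finite logits")
    if task == "multiclass":
        shifted = Z - Z.max(axis=1, keepdims=True)
        e = np.exp(shifted)
        probs = e / e.sum(axis=1, keepdims=True)
        labels = probs.argmax(axis=1)  # np.argmax returns the first (lowest) index on ties
        return probs, labels
    if task == "multilabel":
        probs = np.where(Z >= 0, 1.0 / (1.0 + np.exp(-np.abs(Z))), np.exp(-np.abs(Z)) / (1.0 + np.exp(-np.abs(Z))))
        return probs, (probs > 0.5).astype(np.intp)
    raise ValueError(f"unknown task {task!r}")
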