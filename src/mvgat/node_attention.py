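"""Per-view graph attention encoder.

Each view of the network is encoded independently by a stack of multi-head
neighbourhood-attention layers.  For node i with neighbourhood N_i (self
included), one head with weight matrix W and scoring vector a computes

    e_ij   = LeakyReLU( a^T [ W x_i || W x_j ] ),          j in N_i
    alpha_ij = softmax_{j in N_i}( e_ij )
    x_i'   = sum_{j in N_i} alpha_ij  W x_j

Hidden layers run Phi heads in parallel and concatenate their activated
outputs; the final layer averages head outputs instead, so its width is the
per-head output width (the class count, by default).  Softmaxes are
computed with per-neighbourhood max subtraction, so scores of magnitude up
to ~1e4 cannot overflow.

The public operations accept and return plain numpy arrays; the ``*_t``
twins operate on autodiff tensors and are what training differentiates
through.
"""

from __future__ import annotations

from dataclasses import dataclass, field

import numpy as np

from .autodiff import Tensor, concat, gather_rows, segment_sum, stack_mean
from .multiview_graph import NeighborIndex

__all__ = [
    "AttentionHeadParams",
    "GATLayerParams",
    "ViewEncoderParams",
    "attention_coefficients",
    "head_update",
    "layer_forward",
    "view_encode",
    "init_encoder",
]

DEFAULT_LEAKY_SLOPE = 0.2


@dataclass
class AttentionHeadParams:
    W: Tensor  # F_in x F_out
    a: Tensor  # 2 * F_out

    @property
    def f_in(self) -> int:
        return self.W.shape[0]

    @property
    def f_out(self) -> int:
        return self.W.shape[1]

    def __post_init__(self):
        if self.a.shape != (2 * self.f_out,):
            raise ValueError(
                f"scoring vector a has shape {self.a.shape}, expected ({2 * self.f_out},)"
            )
        if not (np.isfinite(self.W.data).all() and np.isfinite(self.a.data).all()):
            raise ValueError("non-finite attention parameters")


@dataclass
class GATLayerParams:
    heads: list[AttentionHeadParams]
    mode: str = "concat"  # "concat" | "average"
    activation: str = "elu"  # "elu" | "identity"
    leaky_slope: float = DEFAULT_LEAKY_SLOPE

    def __post_init__(self):
        if not self.heads:
            raise ValueError("a layer needs at least one head")
        if self.mode not in ("concat", "average"):
            raise ValueError(f"unknown layer mode {self.mode!r}")
        if self.activation not in ("elu", "identity"):
            raise ValueError(f"unknown activation {self.activation!r}")
        f_in, f_out = self.heads[0].f_in, self.heads[0].f_out
        for h in self.heads:
            if (h.f_in, h.f_out) != (f_in, f_out):
                raise ValueError("all heads in a layer must share F_in and F_out")

    @property
    def n_heads(self) -> int:
        return len(self.heads)

    @property
    def f_in(self) -> int:
        return self.heads[0].f_in

    @property
    def f_out(self) -> int:
        per_head = self.heads[0].f_out
        return per_head * self.n_heads if self.mode == "concat" else per_head


@dataclass
class ViewEncoderParams:
    layers: list[GATLayerParams]
    dropout_input: float = 0.6
    dropout_attention: float = 0.6

    def __post_init__(self):
        for prev, nxt in zip(self.layers, self.layers[1:]):
            if prev.f_out != nxt.f_in:
                raise ValueError(
                    f"layer dims do not chain: {prev.f_out} -> {nxt.f_in}"
                )

    @property
    def f_in(self) -> int:
        return self.layers[0].f_in

    @property
    def f_out(self) -> int:
        return self.layers[-1].f_out

    def parameters(self) -> list[Tensor]:
        out: list[Tensor] = []
        for layer in self.layers:
            for head in layer.heads:
                out.extend([head.W, head.a])
        return out


# ----------------------------------------------------------------- internals
def _check_neighborhoods(nbr: NeighborIndex) -> None:
    for i, lst in enumerate(nbr.lists):
        if len(lst) == 0:
            raise ValueError(
                f"node {i} has an empty neighbourhood; build the NeighborIndex "
                "with include_self=True so every softmax has support"
            )


def _dropout_t(t: Tensor, p: float, rng: np.random.Generator | None, training: bool) -> Tensor:
    if not training or p <= 0.0:
        return t
    if rng is None:
        raise ValueError("training-mode dropout requires an rng")
    keep = (rng.random(t.shape) >= p).astype(np.float64) / (1.0 - p)
    return t * Tensor(keep)


def _segment_softmax_t(scores: Tensor, seg: np.ndarray, n_seg: int) -> Tensor:
    # max-subtraction per segment; the shift is a constant, softmax is
    # shift-invariant so gradients are unaffected
    shift = np.full(n_seg, -np.inf)
    np.maximum.at(shift, seg, scores.data)
    e = (scores - Tensor(shift[seg])).exp()
    denom = segment_sum(e, seg, n_seg)
    return e / gather_rows(denom, seg)


def _edge_attention_t(
    x: Tensor,
    centers: np.ndarray,
    nbrs: np.ndarray,
    head: AttentionHeadParams,
    leaky_slope: float,
) -> tuple[Tensor, Tensor]:
    """Per-edge normalized coefficients and the transformed features W x."""
    if x.shape[1] != head.f_in:
        raise ValueError(f"feature dim {x.shape[1]} != head F_in {head.f_in}")
    V = x.shape[0]
    h = x @ head.W
    f_out = head.f_out
    a_i = gather_rows(head.a, np.arange(f_out))
    a_j = gather_rows(head.a, np.arange(f_out, 2 * f_out))
    s_i = h @ a_i  # score contribution of the centre node
    s_j = h @ a_j  # score contribution of the neighbour
    scores = (gather_rows(s_i, centers) + gather_rows(s_j, nbrs)).leaky_relu(leaky_slope)
    alpha = _segment_softmax_t(scores, centers, V)
    return alpha, h


def _head_forward_t(
    x: Tensor,
    centers: np.ndarray,
    nbrs: np.ndarray,
    head: AttentionHeadParams,
    leaky_slope: float,
    attn_dropout: float,
    rng: np.random.Generator | None,
    training: bool,
) -> Tensor:
    V = x.shape[0]
    alpha, h = _edge_attention_t(x, centers, nbrs, head, leaky_slope)
    alpha = _dropout_t(alpha, attn_dropout, rng, training)
    msg = alpha.reshape(-1, 1) * gather_rows(h, nbrs)
    return segment_sum(msg, centers, V)


def _activate(t: Tensor, activation: str) -> Tensor:
    return t.elu() if activation == "elu" else t


def layer_forward_t(
    x: Tensor,
    nbr: NeighborIndex,
    layer: GATLayerParams,
    rng: np.random.Generator | None = None,
    training: bool = False,
    attn_dropout: float = 0.0,
) -> Tensor:
    _check_neighborhoods(nbr)
    centers, nbrs = nbr.edge_arrays()
    outs = [
        _head_forward_t(x, centers, nbrs, head, layer.leaky_slope, attn_dropout, rng, training)
        for head in layer.heads
    ]
    if layer.mode == "concat":
        return concat([_activate(o, layer.activation) for o in outs], axis=1)
    return _activate(stack_mean(outs), layer.activation)


def view_encode_t(
    x: Tensor,
    nbr: NeighborIndex,
    enc: ViewEncoderParams,
    rng: np.random.Generator | None = None,
    training: bool = False,
) -> Tensor:
    if x.shape[1] != enc.f_in:
        raise ValueError(f"feature dim {x.shape[1]} does not chain to encoder F_in {enc.f_in}")
    h = _dropout_t(x, enc.dropout_input, rng, training)
    for layer in enc.layers:
        h = layer_forward_t(h, nbr, layer, rng, training, enc.dropout_attention)
    return h


# ----------------------------------------------------------- public ops (numpy)
def attention_coefficients(
    x: np.ndarray,
    nbr: NeighborIndex,
    head: AttentionHeadParams,
    leaky_slope: float = DEFAULT_LEAKY_SLOPE,
) -> list[np.ndarray]:
    """Normalized attention coefficients, one array per node aligned with
    the node's (sorted) neighbour list.  Each array sums to 1."""
    _check_neighborhoods(nbr)
    centers, nbrs = nbr.edge_arrays()
    alpha, _ = _edge_attention_t(Tensor(np.asarray(x, dtype=np.float64)), centers, nbrs, head, leaky_slope)
    flat = alpha.data
    out, pos = [], 0
    for lst in nbr.lists:
        out.append(flat[pos : pos + len(lst)].copy())
        pos += len(lst)
    return out


def head_update(
    x: np.ndarray,
    alpha: list[np.ndarray],
    nbr: NeighborIndex,
    head: AttentionHeadParams,
) -> np.ndarray:
    """Aggregate transformed neighbour features with given coefficients:
    row i = sum_{j in N_i} alpha_ij (W x_j).  No activation applied."""
    if len(alpha) != nbr.n_nodes:
        raise ValueError("alpha does not match the neighbour index (node count)")
    for i, (coeffs, lst) in enumerate(zip(alpha, nbr.lists)):
        if len(coeffs) != len(lst):
            raise ValueError(f"alpha[{i}] has {len(coeffs)} entries for {len(lst)} neighbours")
    x = np.asarray(x, dtype=np.float64)
    h = x @ head.W.data
    out = np.zeros((nbr.n_nodes, head.f_out))
    for i, (coeffs, lst) in enumerate(zip(alpha, nbr.lists)):
        out[i] = np.asarray(coeffs) @ h[list(lst)]
    return out


def layer_forward(
    x: np.ndarray,
    nbr: NeighborIndex,
    layer: GATLayerParams,
    rng: np.random.Generator | None = None,
    training: bool = False,
    attn_dropout: float = 0.0,
) -> np.ndarray:
    return layer_forward_t(Tensor(np.asarray(x, dtype=np.float64)), nbr, layer, rng, training, attn_dropout).data


def view_encode(
    x: np.ndarray,
    nbr: NeighborIndex,
    enc: ViewEncoderParams,
    rng: np.random.Generator | None = None,
    training: bool = False,
) -> np.ndarray:
    """Full per-view encoding: input dropout, then the layer stack."""
    return view_encode_t(Tensor(np.asarray(x, dtype=np.float64)), nbr, enc, rng, training).data


# ------------------------------------------------------------- initialization
def _glorot(rng: np.random.Generator, fan_in: int, fan_out: int, shape) -> np.ndarray:
    bound = np.sqrt(6.0 / (fan_in + fan_out))
    return rng.uniform(-bound, bound, size=shape)


def init_encoder(
    dims: list[int],
    n_heads: int = 8,
    seed: int | np.random.Generator = 0,
    dropout_input: float = 0.6,
    dropout_attention: float = 0.6,
    leaky_slope: float = DEFAULT_LEAKY_SLOPE,
    modes: list[str] | None = None,
) -> ViewEncoderParams:
    """Build a Glorot-initialized encoder.

    `dims` are per-head widths ``[F_in, h_1, ..., F_out]``; hidden layers
    concatenate their `n_heads` heads (so the next layer sees
    ``n_heads * h``), the last layer averages.  The last layer's activation
    is the identity so its output can serve directly as class logits.
    """
    if len(dims) < 2:
        raise ValueError("dims must list at least input and output widths")
    rng = seed if isinstance(seed, np.random.Generator) else np.random.default_rng(seed)
    n_layers = len(dims) - 1
    if modes is None:
        modes = ["concat"] * (n_layers - 1) + ["average"]
    if len(modes) != n_layers:
        raise ValueError("one mode per layer required")
    layers: list[GATLayerParams] = []
    f_in = dims[0]
    for ell in range(n_layers):
        f_out = dims[ell + 1]
        heads = []
        for _ in range(n_heads):
            W = Tensor(_glorot(rng, f_in, f_out, (f_in, f_out)), requires_grad=True)
            a = Tensor(_glorot(rng, 2 * f_out, 1, (2 * f_out,)), requires_grad=True)
            heads.append(AttentionHeadParams(W=W, a=a))
        mode = modes[ell]
        activation = "identity" if ell == n_layers - 1 else "elu"
        layers.append(
            GATLayerParams(heads=heads, mode=mode, activation=activation, leaky_slope=leaky_slope)
        )
        f_in = f_out * n_heads if mode == "concat" else f_out
    return ViewEncoderParams(
        layers=layers, dropout_input=dropout_input, dropout_attention=dropout_attention
    )
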