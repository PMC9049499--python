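"""Loss, optimization loop, best-loss label selection, metrics and ablations.

Training is semi-supervised and full-batch: every iteration encodes all
views, fuses them, evaluates the cross-entropy loss on the training-masked
nodes and takes one Adam step.  After each step the model is re-evaluated
without dropout; the hard predictions and the selection loss (validation
loss when a validation mask exists, training loss otherwise) are recorded
in the trace, and the final labels are the predictions of the iteration
with the minimum selection loss (earliest on ties).

Ablation variants: ``sv`` trains on a single view (the encoder pipeline
with k forced to 1), ``mmv`` replaces attention fusion by the unweighted
view mean, ``full`` is the complete model.
"""

from __future__ import annotations

from dataclasses import dataclass, field, replace

import numpy as np

from .autodiff import Tensor, gather_rows, stack_mean
from .multiview_graph import MultiViewNetwork, NeighborIndex, neighborhoods
from .node_attention import ViewEncoderParams, init_encoder, view_encode_t
from .view_fusion import (
    ViewFusionParams,
    fuse_t,
    init_fusion,
    predict,
    view_attention_t,
)

__all__ = [
    "TrainConfig",
    "TrainTrace",
    "MetricReport",
    "ModelParams",
    "Adam",
    "cross_entropy",
    "train_epoch",
    "select_best",
    "accuracy",
    "precision_recall_f1",
    "ablation_run",
    "fit_network",
    "forward_full",
    "init_model_params",
]

_CLIP = 1e-12


@dataclass
class TrainConfig:
    """Hyperparameters of the model and its training protocol.

    Defaults: 2 attention layers of width 8 with 8 heads, dropout 0.6 on
    input features and attention coefficients, Adam at learning rate 0.005
    with weight decay 5e-4, 200 iterations.
    """

    epochs: int = 200
    learning_rate: float = 0.005
    weight_decay: float = 5e-4
    dropout: float = 0.6
    attention_dropout: float = 0.6
    seed: int = 0
    selection: str = "auto"  # "auto" | "train_loss" | "val_loss"
    hidden_dim: int = 8
    heads: int = 8
    n_layers: int = 2
    leaky_slope: float = 0.2
    fusion_mode: str = "attention"  # "attention" | "mean"
    fusion_scope: str = "per_node"  # "per_node" | "global"
    fusion_query: str = "mean_over_queries"  # "mean_over_queries" | "mean_view"

    def __post_init__(self):
        if self.epochs < 1:
            raise ValueError("epochs must be >= 1")
        if self.learning_rate < 0:
            raise ValueError("learning rate must be >= 0")
        if self.selection not in ("auto", "train_loss", "val_loss"):
            raise ValueError(f"unknown selection {self.selection!r}")


@dataclass
class TrainTrace:
    """Per-iteration record used for best-loss label selection."""

    train_losses: list[float] = field(default_factory=list)
    val_losses: list[float | None] = field(default_factory=list)
    selection_losses: list[float] = field(default_factory=list)
    predictions: list[np.ndarray] = field(default_factory=list)
    fusion_weight_means: list[np.ndarray] = field(default_factory=list)

    def __len__(self) -> int:
        return len(self.selection_losses)

    @property
    def best_iteration(self) -> int:
        if not self.selection_losses:
            raise ValueError("empty trace")
        return int(np.argmin(self.selection_losses))  # argmin takes the earliest tie


MetricReport = dict[str, dict[str, float]]


@dataclass
class ModelParams:
    """All learnable parameters: one encoder per view plus the fusion head."""

    encoders: list[ViewEncoderParams]
    fusion: ViewFusionParams | None
    config: TrainConfig

    def parameters(self) -> list[Tensor]:
        out: list[Tensor] = []
        for enc in self.encoders:
            out.extend(enc.parameters())
        if self.fusion is not None:
            out.extend(self.fusion.parameters())
        return out


class Adam:
    """Adam with decoupled-from-nothing classic L2 weight decay added to
    the gradient (the convention of the attention-network literature)."""

    def __init__(self, params: list[Tensor], lr: float, weight_decay: float = 0.0,
                 betas: tuple[float, float] = (0.9, 0.999), eps: float = 1e-8):
        self.params = params
        self.lr = lr
        self.weight_decay = weight_decay
        self.beta1, self.beta2 = betas
        self.eps = eps
        self.t = 0
        self.m = [np.zeros_like(p.data) for p in params]
        self.v = [np.zeros_like(p.data) for p in params]

    def zero_grad(self) -> None:
        for p in self.params:
            p.grad = None

    def step(self) -> None:
        self.t += 1
        b1, b2 = self.beta1, self.beta2
        for i, p in enumerate(self.params):
            if p.grad is None:
                continue
            g = p.grad + self.weight_decay * p.data
            self.m[i] = b1 * self.m[i] + (1 - b1) * g
            self.v[i] = b2 * self.v[i] + (1 - b2) * g * g
            m_hat = self.m[i] / (1 - b1**self.t)
            v_hat = self.v[i] / (1 - b2**self.t)
            p.data -= self.lr * m_hat / (np.sqrt(v_hat) + self.eps)


# -------------------------------------------------------------------- loss
def cross_entropy(y: np.ndarray, p: np.ndarray, mask: np.ndarray) -> float:
    """Cross-entropy loss summed over the masked nodes.

    Multiclass (y an index vector, p a V x C probability matrix): the
    categorical form -sum_i log p_i[y_i].  Binary / multilabel (y an
    indicator array shaped like p): the full form
    -sum [y log p + (1-y) log(1-p)].  Probabilities are clipped to
    [1e-12, 1-1e-12] before taking logs.
    """
    mask = np.asarray(mask, dtype=bool)
    if mask.sum() == 0:
        raise ValueError("empty mask")
    p = np.clip(np.asarray(p, dtype=np.float64), _CLIP, 1.0 - _CLIP)
    y = np.asarray(y)
    if y.ndim == 1 and p.ndim == 2 and y.shape[0] == p.shape[0] and not np.issubdtype(y.dtype, np.floating):
        pm = p[mask]
        return float(-np.sum(np.log(pm[np.arange(pm.shape[0]), y[mask]])))
    y = y.astype(np.float64)
    ym, pm = y[mask], p[mask]
    return float(-np.sum(ym * np.log(pm) + (1.0 - ym) * np.log(1.0 - pm)))


def _loss_t(Z: Tensor, network: MultiViewNetwork, mask: np.ndarray) -> Tensor:
    """Differentiable Eq-9-style loss on logits, summed over masked nodes."""
    idx = np.where(np.asarray(mask, dtype=bool))[0]
    if idx.size == 0:
        raise ValueError("empty mask")
    Zm = gather_rows(Z, idx)
    if network.multilabel:
        p = Zm.sigmoid().clip(_CLIP, 1.0 - _CLIP)
        ym = Tensor(network.labels[idx].astype(np.float64))
        one = Tensor(np.ones_like(p.data))
        return -((ym * p.log() + (one - ym) * (one - p).log()).sum())
    shift = Zm.data.max(axis=1, keepdims=True)  # constant; log-softmax is shift-invariant
    e = (Zm - Tensor(shift)).exp()
    lse = e.sum(axis=1).log() + Tensor(shift.reshape(-1))
    onehot = np.zeros_like(Zm.data)
    onehot[np.arange(idx.size), network.labels[idx]] = 1.0
    picked = (Zm * Tensor(onehot)).sum(axis=1)
    return (lse - picked).sum()


# ----------------------------------------------------------------- pipeline
def _view_rng(seed: int, epoch: int, view: int) -> np.random.Generator:
    # one independent stream per (iteration, view): sub-cells can then run
    # in any order without changing the dropout masks any of them draws
    return np.random.default_rng([int(seed), int(epoch), int(view)])


def encode_views(
    params: ModelParams,
    network: MultiViewNetwork,
    nbrs: list[NeighborIndex],
    epoch: int,
    training: bool,
) -> list[Tensor]:
    x = Tensor(network.features)
    reps = []
    for m, (enc, nbr) in enumerate(zip(params.encoders, nbrs)):
        rng = _view_rng(params.config.seed, epoch, m) if training else None
        reps.append(view_encode_t(x, nbr, enc, rng, training))
    return reps


def fuse_views(params: ModelParams, view_reps: list[Tensor]) -> tuple[Tensor, list[Tensor] | None]:
    cfg = params.config
    if cfg.fusion_mode == "mean":
        return stack_mean(view_reps), None
    marginals, _ = view_attention_t(view_reps, params.fusion, cfg.fusion_scope, cfg.fusion_query)
    return fuse_t(view_reps, marginals), marginals


def forward_full(
    params: ModelParams,
    network: MultiViewNetwork,
    nbrs: list[NeighborIndex],
    epoch: int = 0,
    training: bool = False,
) -> tuple[Tensor, list[Tensor] | None, list[Tensor]]:
    """Encode every view, fuse, return (logits Z, fusion marginals, view reps)."""
    reps = encode_views(params, network, nbrs, epoch, training)
    Z, marginals = fuse_views(params, reps)
    return Z, marginals, reps


def init_model_params(network: MultiViewNetwork, config: TrainConfig) -> ModelParams:
    F = network.features.shape[1]
    C = network.n_classes
    dims = [F] + [config.hidden_dim] * (config.n_layers - 1) + [C]
    encoders = [
        init_encoder(
            dims,
            n_heads=config.heads,
            seed=np.random.default_rng([config.seed, 1000 + m]),
            dropout_input=config.dropout,
            dropout_attention=config.attention_dropout,
            leaky_slope=config.leaky_slope,
        )
        for m in range(network.n_views)
    ]
    fusion = None
    if config.fusion_mode == "attention":
        fusion = init_fusion(C, seed=np.random.default_rng([config.seed, 2000]),
                             leaky_slope=config.leaky_slope)
    return ModelParams(encoders=encoders, fusion=fusion, config=config)


def _selection_mode(config: TrainConfig, network: MultiViewNetwork) -> str:
    if config.selection != "auto":
        return config.selection
    return "val_loss" if network.val_mask is not None and network.val_mask.any() else "train_loss"


def _train_mask(network: MultiViewNetwork) -> np.ndarray:
    if network.train_mask is not None:
        return network.train_mask
    return np.ones(network.n_nodes, dtype=bool)


def evaluate_epoch(
    params: ModelParams, network: MultiViewNetwork, nbrs: list[NeighborIndex]
) -> tuple[np.ndarray, np.ndarray, float, float | None, np.ndarray | None]:
    """Dropout-free forward pass: (probs, hard labels, train loss, val loss,
    mean fusion weight per view)."""
    Z, marginals, _ = forward_full(params, network, nbrs, training=False)
    task = "multilabel" if network.multilabel else "multiclass"
    probs, labels = predict(Z.data, task)
    train_loss = cross_entropy(network.labels, probs, _train_mask(network))
    val_loss = None
    if network.val_mask is not None and network.val_mask.any():
        val_loss = cross_entropy(network.labels, probs, network.val_mask)
    weight_means = None
    if marginals is not None:
        weight_means = np.array([m.data.mean() for m in marginals])
    return probs, labels, train_loss, val_loss, weight_means


def train_epoch(
    params: ModelParams,
    optimizer: Adam,
    network: MultiViewNetwork,
    nbrs: list[NeighborIndex],
    epoch: int,
) -> tuple[float, np.ndarray, dict]:
    """One full-batch gradient step, then a dropout-free evaluation.

    Returns (selection loss after the step, hard predictions on all nodes,
    auxiliary record for the trace)."""
    mask = _train_mask(network)
    Z, _, _ = forward_full(params, network, nbrs, epoch=epoch, training=True)
    loss = _loss_t(Z, network, mask)
    if not np.isfinite(loss.data):
        raise FloatingPointError(f"non-finite training loss at iteration {epoch}")
    optimizer.zero_grad()
    loss.backward()
    optimizer.step()

    probs, labels, train_loss, val_loss, weight_means = evaluate_epoch(params, network, nbrs)
    mode = _selection_mode(params.config, network)
    selection_loss = val_loss if mode == "val_loss" else train_loss
    if selection_loss is None:
        raise ValueError("selection='val_loss' requires a validation mask")
    aux = {
        "train_loss": train_loss,
        "val_loss": val_loss,
        "probs": probs,
        "weight_means": weight_means,
    }
    return float(selection_loss), labels, aux


def select_best(trace: TrainTrace) -> np.ndarray:
    """Predictions stored at the iteration with minimum selection loss."""
    return trace.predictions[trace.best_iteration]


def fit_network(
    network: MultiViewNetwork, config: TrainConfig
) -> tuple[ModelParams, TrainTrace]:
    """Plain (scheduler-free) training loop; the membrane scheduler's
    `run` produces the identical trace by construction."""
    nbrs = [neighborhoods(v, include_self=True) for v in network.views]
    params = init_model_params(network, config)
    optimizer = Adam(params.parameters(), lr=config.learning_rate,
                     weight_decay=config.weight_decay)
    trace = TrainTrace()
    for epoch in range(config.epochs):
        sel, labels, aux = train_epoch(params, optimizer, network, nbrs, epoch)
        trace.selection_losses.append(sel)
        trace.train_losses.append(aux["train_loss"])
        trace.val_losses.append(aux["val_loss"])
        trace.predictions.append(labels)
        if aux["weight_means"] is not None:
            trace.fusion_weight_means.append(aux["weight_means"])
    return params, trace


# ------------------------------------------------------------------- metrics
def accuracy(y_true: np.ndarray, y_pred: np.ndarray, mask: np.ndarray | None = None) -> float:
    y_true, y_pred = np.asarray(y_true), np.asarray(y_pred)
    if y_true.shape != y_pred.shape:
        raise ValueError("label arrays must have equal shapes")
    if mask is None:
        mask = np.ones(y_true.shape[0], dtype=bool)
    mask = np.asarray(mask, dtype=bool)
    if mask.sum() == 0:
        raise ValueError("empty mask")
    # multilabel indicator matrices compare entrywise (micro accuracy)
    return float((y_true[mask] == y_pred[mask]).mean())


def precision_recall_f1(
    y_true: np.ndarray, y_pred: np.ndarray, averaging: str = "micro"
) -> tuple[float, float, float]:
    """Micro-averaged precision, recall and F1 from binary indicators.

    Multiclass index vectors are converted to one-hot indicators first.
    A zero denominator yields 0 for the affected metric; F1 is 0 when
    P + R = 0.
    """
    if averaging != "micro":
        raise ValueError("only micro averaging is supported")
    y_true, y_pred = np.asarray(y_true), np.asarray(y_pred)
    if y_true.ndim == 1 and (y_true.max(initial=0) > 1 or y_pred.max(initial=0) > 1):
        n_cls = int(max(y_true.max(), y_pred.max())) + 1
        y_true = np.eye(n_cls, dtype=int)[y_true]
        y_pred = np.eye(n_cls, dtype=int)[y_pred]
    yt = y_true.astype(bool)
    yp = y_pred.astype(bool)
    tp = int(np.sum(yt & yp))
    fp = int(np.sum(~yt & yp))
    fn = int(np.sum(yt & ~yp))
    precision = tp / (tp + fp) if (tp + fp) > 0 else 0.0
    recall = tp / (tp + fn) if (tp + fn) > 0 else 0.0
    f1 = 2 * precision * recall / (precision + recall) if (precision + recall) > 0 else 0.0
    return precision, recall, f1


def metric_report(network: MultiViewNetwork, y_pred: np.ndarray) -> MetricReport:
    report: MetricReport = {}
    splits = {
        "train": _train_mask(network),
        "val": network.val_mask,
        "test": network.test_mask,
    }
    for name, mask in splits.items():
        if mask is None or not mask.any():
            continue
        yt, yp = network.labels[mask], y_pred[mask]
        p, r, f1 = precision_recall_f1(yt, yp)
        report[name] = {
            "accuracy": accuracy(network.labels, y_pred, mask),
            "precision": p,
            "recall": r,
            "f1": f1,
        }
    return report


# ----------------------------------------------------------------- ablations
def ablation_run(
    network: MultiViewNetwork,
    variant: str,
    config: TrainConfig,
    view_index: int = 0,
) -> tuple[MetricReport, ModelParams, TrainTrace]:
    """Train one ablation variant and report metrics of the selected labels.

    full: attention fusion over all views.  sv: single-view pipeline on
    `view_index` (k forced to 1).  mmv: unweighted mean fusion.  The
    training protocol is identical across variants.
    """
    if variant == "full":
        net, cfg = network, replace(config, fusion_mode="attention")
    elif variant == "mmv":
        net, cfg = network, replace(config, fusion_mode="mean")
    elif variant == "sv":
        if not (0 <= view_index < network.n_views):
            raise ValueError(f"view_index {view_index} out of range")
        net = MultiViewNetwork(
            node_ids=network.node_ids,
            features=network.features,
            labels=network.labels,
            views=[network.views[view_index]],
            train_mask=network.train_mask,
            val_mask=network.val_mask,
            test_mask=network.test_mask,
            class_names=network.class_names,
        )
        cfg = config
    else:
        raise ValueError(f"unknown ablation variant {variant!r}")
    params, trace = fit_network(net, cfg)
    labels = select_best(trace)
    return metric_report(net, labels), params, trace
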