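"""Model/Results interface over the multi-view attention pipeline.

`MultiViewNodeClassifier` is constructed from a `MultiViewNetwork` plus
hyperparameters; `fit()` runs semi-supervised training through the coupled
membrane scheduler and returns a `NodeClassificationResults` carrying the
selected predictions, the training trace, per-split metrics, the learned
fusion weights and a text `summary()`.
"""

from __future__ import annotations

from dataclasses import asdict

import numpy as np

from . import coupled_p_system as cps
from .multiview_graph import MultiViewNetwork, validate
from .training_eval import (
    ModelParams,
    TrainConfig,
    TrainTrace,
    metric_report,
)

__all__ = ["MultiViewNodeClassifier", "NodeClassificationResults"]


class MultiViewNodeClassifier:
    """Multi-view graph attention classifier for node labels.

    Parameters mirror :class:`mvgat.training_eval.TrainConfig`; any keyword
    accepted there can be overridden here.

    Examples
    --------
    >>> from mvgat.synthetic_data import fixture_toy_network
    >>> model = MultiViewNodeClassifier(fixture_toy_network(), epochs=50, seed=1)
    >>> res = model.fit()
    >>> res.predicted_labels.shape
    (30,)
    """

    def __init__(self, network: MultiViewNetwork, config: TrainConfig | None = None, **overrides):
        problems = validate(network)
        if problems:
            raise ValueError("invalid network: " + "; ".join(problems))
        self.network = network
        base = asdict(config) if config is not None else {}
        base.update(overrides)
        self.config = TrainConfig(**base)

    @classmethod
    def from_config_dict(cls, network: MultiViewNetwork, cfg: dict) -> "MultiViewNodeClassifier":
        """Build from the nested config-file layout (model/fusion/train)."""
        flat: dict = {}
        model_cfg = cfg.get("model", {})
        flat.update({k: v for k, v in {
            "hidden_dim": model_cfg.get("hidden_dim"),
            "heads": model_cfg.get("heads"),
            "n_layers": model_cfg.get("layers"),
            "dropout": model_cfg.get("dropout"),
            "attention_dropout": model_cfg.get("attention_dropout"),
            "leaky_slope": model_cfg.get("leaky_slope"),
        }.items() if v is not None})
        fusion_cfg = cfg.get("fusion", {})
        flat.update({k: v for k, v in {
            "fusion_mode": fusion_cfg.get("mode"),
            "fusion_scope": fusion_cfg.get("scope"),
            "fusion_query": fusion_cfg.get("query"),
        }.items() if v is not None})
        train_cfg = cfg.get("train", {})
        flat.update({k: v for k, v in {
            "epochs": train_cfg.get("epochs"),
            "learning_rate": train_cfg.get("learning_rate"),
            "weight_decay": train_cfg.get("weight_decay"),
            "seed": train_cfg.get("seed"),
            "selection": train_cfg.get("selection"),
        }.items() if v is not None})
        return cls(network, **flat)

    def fit(self) -> "NodeClassificationResults":
        """Train through the coupled P system and select the best iteration."""
        state = cps.build_system(self.network, self.config)
        labels, trace = cps.run(state)
        return NodeClassificationResults(self, state.params, trace, labels)


class NodeClassificationResults:
    """Estimates and diagnostics of a fitted multi-view attention model."""

    def __init__(self, model: MultiViewNodeClassifier, params: ModelParams,
                 trace: TrainTrace, predicted_labels: np.ndarray):
        self.model = model
        self.params = params
        self.trace = trace
        self.predicted_labels = predicted_labels
        self.best_iteration = trace.best_iteration

    @property
    def network(self) -> MultiViewNetwork:
        return self.model.network

    @property
    def fusion_weights(self) -> np.ndarray | None:
        """Mean per-view fusion weight at the best iteration (None for mean
        fusion, where weights are uniform by construction)."""
        if not self.trace.fusion_weight_means:
            return None
        return self.trace.fusion_weight_means[self.best_iteration]

    def metrics(self) -> dict:
        return metric_report(self.network, self.predicted_labels)

    def probabilities(self) -> np.ndarray:
        """Class probabilities of the final (dropout-free) model state."""
        from .multiview_graph import neighborhoods
        from .training_eval import forward_full
        from .view_fusion import predict

        nbrs = [neighborhoods(v, include_self=True) for v in self.network.views]
        Z, _, _ = forward_full(self.params, self.network, nbrs, training=False)
        task = "multilabel" if self.network.multilabel else "multiclass"
        probs, _ = predict(Z.data, task)
        return probs

    def summary(self) -> str:
        net, cfg = self.network, self.model.config
        lines = [
            "Multi-view graph attention node classifier",
            "=" * 58,
            f"nodes: {net.n_nodes}   views: {net.n_views}   "
            f"classes: {net.n_classes}   features: {net.features.shape[1]}",
            f"layers: {cfg.n_layers} (hidden {cfg.hidden_dim}, heads {cfg.heads})   "
            f"fusion: {cfg.fusion_mode}/{cfg.fusion_scope}",
            f"iterations: {cfg.epochs}   lr: {cfg.learning_rate}   "
            f"dropout: {cfg.dropout}   seed: {cfg.seed}",
            f"best iteration: {self.best_iteration}   "
            f"selection loss: {self.trace.selection_losses[self.best_iteration]:.4f}",
        ]
        if self.fusion_weights is not None:
            w = ", ".join(f"view {m}: {v:.3f}" for m, v in enumerate(self.fusion_weights))
            lines.append(f"mean fusion weights: {w}")
        lines.append("-" * 58)
        lines.append(f"{'split':<8}{'accuracy':>10}{'precision':>11}{'recall':>9}{'f1':>9}")
        for split, vals in self.metrics().items():
            lines.append(
                f"{split:<8}{vals['accuracy']:>10.4f}{vals['precision']:>11.4f}"
                f"{vals['recall']:>9.4f}{vals['f1']:>9.4f}"
            )
        lines.append("=" * 58)
        return "\n".join(lines)
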