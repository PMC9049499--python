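"""Coupled membrane (P) system scheduler for the multi-view pipeline.

The computation is organised as k+4 cells: an input cell (cell1) holding
the multi-view network, k identical sub-cells under a cell2 fan-out
junction (one per view, all with the same evolution rules), a fusion cell
(cell3), a loss/selection cell (cell4) and the environment.  Directed
communication channels wire cell1 -> cell2 -> cell3 -> cell4 -> environment
one-way, cell1 <-> cell4 two-way (labels out, repeat signal back), and
cell2 <-> each sub-cell for the fan-out and collection of view
representations.  Every transfer is audited against the wired channels.

"Maximal parallelism" is realised as a synchronized bulk step: within one
iteration, every sub-cell's encoding is computed from the iteration's
entry state and all effects are committed together, so executing the
sub-cells in any order (or concurrently) yields an identical state.  One
optimizer step is attached to each iteration boundary.  At termination the
predictions of the iteration with the minimum selection loss are emitted
to the environment.
"""

from __future__ import annotations

from dataclasses import dataclass, field

import numpy as np

from .autodiff import Tensor
from .multiview_graph import MultiViewNetwork, neighborhoods, validate
from .training_eval import (
    Adam,
    ModelParams,
    TrainConfig,
    TrainTrace,
    _loss_t,
    _selection_mode,
    _train_mask,
    _view_rng,
    evaluate_epoch,
    fuse_views,
    init_model_params,
    select_best,
)
from .node_attention import view_encode_t
from .view_fusion import predict

__all__ = ["Cell", "Channel", "SystemState", "build_system", "apply_R1", "step", "run"]


@dataclass
class Cell:
    id: str
    objects: dict = field(default_factory=dict)
    rules: tuple = ()


@dataclass(frozen=True)
class Channel:
    src: str
    dst: str
    direction: str  # "one_way" | "two_way"


@dataclass
class SystemState:
    cells: dict  # id -> Cell; exactly k+4 entries (cell2 is a junction, not a store)
    channels: frozenset
    network: MultiViewNetwork
    params: ModelParams
    optimizer: Adam
    config: TrainConfig
    iteration: int = 0
    max_iterations: int = 200
    r1_applied: bool = False
    trace: TrainTrace = field(default_factory=TrainTrace)
    audit: list = field(default_factory=list)  # (src, dst, object name)

    @property
    def k(self) -> int:
        return self.network.n_views

    @property
    def sub_cell_ids(self) -> list[str]:
        return [f"cell2_sub{m + 1}" for m in range(self.k)]

    def _allowed(self, src: str, dst: str) -> bool:
        for ch in self.channels:
            if (ch.src, ch.dst) == (src, dst):
                return True
            if ch.direction == "two_way" and (ch.dst, ch.src) == (src, dst):
                return True
        return False

    def transfer(self, src: str, dst: str, name: str) -> None:
        if not self._allowed(src, dst):
            raise RuntimeError(f"no channel from {src} to {dst}")
        self.audit.append((src, dst, name))


def build_system(network: MultiViewNetwork, config: TrainConfig | None = None) -> SystemState:
    """Construct the (k+4)-cell system with the network loaded into cell1."""
    config = config or TrainConfig()
    k = network.n_views
    if k == 0:
        raise ValueError("network must have at least one view")
    problems = validate(network)
    if problems:
        raise ValueError("invalid network: " + "; ".join(problems))

    sub_rules = ("r21", "r22", "r23")  # identical in every sub-cell
    cells = {"cell1": Cell("cell1", {"G": network}, rules=("r11", "r12", "r13"))}
    for m in range(k):
        cells[f"cell2_sub{m + 1}"] = Cell(f"cell2_sub{m + 1}", rules=sub_rules)
    cells["cell3"] = Cell("cell3", rules=("r31", "r32", "r33"))
    cells["cell4"] = Cell("cell4", rules=("r41", "r42"))
    cells["environment"] = Cell("environment")

    channels = {
        Channel("cell1", "cell2", "one_way"),
        Channel("cell2", "cell3", "one_way"),
        Channel("cell3", "cell4", "one_way"),
        Channel("cell4", "environment", "one_way"),
        Channel("cell1", "cell4", "two_way"),
    }
    for m in range(k):
        channels.add(Channel("cell2", f"cell2_sub{m + 1}", "two_way"))

    params = init_model_params(network, config)
    optimizer = Adam(params.parameters(), lr=config.learning_rate,
                     weight_decay=config.weight_decay)
    return SystemState(
        cells=cells,
        channels=frozenset(channels),
        network=network,
        params=params,
        optimizer=optimizer,
        config=config,
        max_iterations=config.epochs,
    )


def apply_R1(state: SystemState) -> SystemState:
    """Decompose the network: features and per-view edge sets fan out to the
    sub-cells; true labels travel over the (cell1, cell4) channel.  The
    network object itself stays in cell1 (the loop re-reads it every
    iteration)."""
    if "G" not in state.cells["cell1"].objects:
        raise RuntimeError("cell1 does not hold the network object G")
    net = state.cells["cell1"].objects["G"]
    state.transfer("cell1", "cell2", "features+edge_sets")
    for m, sub_id in enumerate(state.sub_cell_ids):
        sub = state.cells[sub_id]
        sub.objects["features"] = net.features
        sub.objects["edge_set"] = net.views[m]
        sub.objects["nbr"] = neighborhoods(net.views[m], include_self=True)
        state.transfer("cell2", sub_id, f"view_{m}")
    state.cells["cell4"].objects["labels"] = net.labels
    state.transfer("cell1", "cell4", "labels")
    state.r1_applied = True
    return state


def step(state: SystemState, sub_cell_order: list[int] | None = None) -> SystemState:
    """One synchronized iteration: R2 in every sub-cell, R3 in cell3, R4 in
    cell4, then one optimizer step.

    `sub_cell_order` only controls the order in which the (independent)
    sub-cell computations are executed; the resulting state is identical
    for every order.
    """
    if not state.r1_applied:
        raise RuntimeError("apply_R1 must run before step")
    if state.iteration >= state.max_iterations:
        raise RuntimeError(f"iteration budget {state.max_iterations} exhausted")
    k = state.k
    order = list(range(k)) if sub_cell_order is None else list(sub_cell_order)
    if sorted(order) != list(range(k)):
        raise ValueError("sub_cell_order must be a permutation of the views")

    # --- R2: per-view encoding, one independent rng stream per sub-cell
    results: dict[int, Tensor] = {}
    for m in order:
        sub = state.cells[state.sub_cell_ids[m]]
        rng = _view_rng(state.config.seed, state.iteration, m)
        x = Tensor(sub.objects["features"])
        results[m] = view_encode_t(x, sub.objects["nbr"], state.params.encoders[m],
                                   rng, training=True)
    for m in range(k):  # commit in index order regardless of execution order
        state.cells[state.sub_cell_ids[m]].objects["X"] = results[m].data
        state.transfer(state.sub_cell_ids[m], "cell2", f"X_{m}")
    state.transfer("cell2", "cell3", "view_representations")

    # --- R3: view attention, fusion, prediction
    reps = [results[m] for m in range(k)]
    Z, marginals = fuse_views(state.params, reps)
    state.cells["cell3"].objects["Z"] = Z.data
    task = "multilabel" if state.network.multilabel else "multiclass"
    probs_step, labels_step = predict(Z.data, task)
    state.cells["cell3"].objects["predicted"] = labels_step
    state.transfer("cell3", "cell4", "predicted_labels")

    # --- R4: loss on the training nodes, then the parameter update
    loss = _loss_t(Z, state.network, _train_mask(state.network))
    if not np.isfinite(loss.data):
        raise FloatingPointError(f"non-finite loss at iteration {state.iteration}")
    state.optimizer.zero_grad()
    loss.backward()
    state.optimizer.step()

    nbrs = [state.cells[s].objects["nbr"] for s in state.sub_cell_ids]
    probs, labels, train_loss, val_loss, weight_means = evaluate_epoch(
        state.params, state.network, nbrs
    )
    mode = _selection_mode(state.config, state.network)
    selection_loss = val_loss if mode == "val_loss" else train_loss
    state.trace.selection_losses.append(float(selection_loss))
    state.trace.train_losses.append(train_loss)
    state.trace.val_losses.append(val_loss)
    state.trace.predictions.append(labels)
    if weight_means is not None:
        state.trace.fusion_weight_means.append(weight_means)
    state.cells["cell4"].objects["trace"] = state.trace
    state.transfer("cell4", "cell1", "repeat_signal")

    state.iteration += 1
    return state


def run(state: SystemState) -> tuple[np.ndarray, TrainTrace]:
    """Iterate to the budget, then emit the best-loss predictions to the
    environment."""
    if state.max_iterations < 1:
        raise ValueError("max_iterations must be >= 1")
    if not state.r1_applied:
        apply_R1(state)
    while state.iteration < state.max_iterations:
        step(state)
    best = select_best(state.trace)
    state.cells["environment"].objects["predictions"] = best
    state.transfer("cell4", "environment", "final_labels")
    return best, state.trace
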