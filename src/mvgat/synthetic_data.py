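"""Synthetic multi-view networks with controllable per-view informativeness.

Each view is a planted-community (stochastic block model) edge set over one
shared node partition: node pairs inside a community connect with
probability p_in, pairs across communities with p_out, independently per
view.  Setting p_in >> p_out makes a view informative about the labels;
p_in = p_out makes it pure noise.  Features are Gaussian blobs: community
c's mean sits at class_separation along coordinate axis c, with isotropic
noise_sd.  Splits are stratified so every class appears in every split.
"""

from __future__ import annotations

from dataclasses import dataclass, field
from pathlib import Path

import numpy as np

from .multiview_graph import (
    EdgeSet,
    MultiViewNetwork,
    build_similarity_view,
    write_edge_list,
    write_feature_table,
)

__all__ = [
    "SBMSpec",
    "generate_multiview_sbm",
    "informative_plus_noise_benchmark",
    "fixture_toy_network",
    "write_network",
]


@dataclass
class SBMSpec:
    """Specification of a multi-view planted-community network."""

    n: int = 120
    n_classes: int = 3
    views: list[tuple[float, float]] = field(default_factory=lambda: [(0.25, 0.02), (0.08, 0.08)])
    feature_dim: int = 10
    class_separation: float = 1.0
    noise_sd: float = 1.0
    train_frac: float = 0.2
    val_frac: float = 0.2
    seed: int = 0

    def __post_init__(self):
        for p_in, p_out in self.views:
            if not (0.0 <= p_in <= 1.0 and 0.0 <= p_out <= 1.0):
                raise ValueError(f"edge probabilities must lie in [0,1], got ({p_in},{p_out})")
        if self.train_frac + self.val_frac > 1.0:
            raise ValueError("train_frac + val_frac must not exceed 1")
        if self.n < self.n_classes:
            raise ValueError("need at least one node per class")
        if self.feature_dim < self.n_classes:
            raise ValueError("feature_dim must be >= n_classes (community means sit on axes)")


def _stratified_masks(labels: np.ndarray, train_frac: float, val_frac: float,
                      rng: np.random.Generator) -> tuple[np.ndarray, np.ndarray, np.ndarray]:
    n = labels.shape[0]
    train = np.zeros(n, dtype=bool)
    val = np.zeros(n, dtype=bool)
    for c in np.unique(labels):
        idx = np.where(labels == c)[0]
        idx = rng.permutation(idx)
        n_tr = max(1, int(round(train_frac * idx.size)))
        n_va = max(1, int(round(val_frac * idx.size))) if val_frac > 0 else 0
        train[idx[:n_tr]] = True
        val[idx[n_tr : n_tr + n_va]] = True
    test = ~(train | val)
    return train, val, test


def generate_multiview_sbm(spec: SBMSpec) -> MultiViewNetwork:
    """Sample a multi-view network from the spec, deterministically per seed."""
    rng = np.random.default_rng(spec.seed)
    n, C = spec.n, spec.n_classes
    labels = rng.permutation(np.arange(n) % C)  # round-robin sizes, shuffled order

    iu, ju = np.triu_indices(n, k=1)
    same = labels[iu] == labels[ju]
    views = []
    for p_in, p_out in spec.views:
        p = np.where(same, p_in, p_out)
        keep = rng.random(iu.size) < p
        views.append(EdgeSet.from_pairs(zip(iu[keep], ju[keep]), n))

    means = np.zeros((C, spec.feature_dim))
    means[np.arange(C), np.arange(C)] = spec.class_separation
    features = means[labels] + rng.normal(0.0, spec.noise_sd, size=(n, spec.feature_dim))

    train, val, test = _stratified_masks(labels, spec.train_frac, spec.val_frac, rng)
    class_names = [f"c{c}" for c in range(C)]
    return MultiViewNetwork(
        node_ids=[f"n{i:04d}" for i in range(n)],
        features=features,
        labels=labels.astype(np.intp),
        views=views,
        train_mask=train,
        val_mask=val,
        test_mask=test,
        class_names=class_names,
    )


def informative_plus_noise_benchmark(seed: int = 0) -> MultiViewNetwork:
    """The two-view contrast used for the fusion ablations: view 1 carries
    the community structure (p_in=0.25, p_out=0.02), view 2 is pure noise
    (p_in = p_out = 0.08).  120 nodes, 3 balanced classes, 10 Gaussian-blob
    features, 20% train / 20% validation."""
    spec = SBMSpec(
        n=120,
        n_classes=3,
        views=[(0.25, 0.02), (0.08, 0.08)],
        feature_dim=10,
        class_separation=1.0,
        noise_sd=1.0,
        train_frac=0.2,
        val_frac=0.2,
        seed=seed,
    )
    return generate_multiview_sbm(spec)


# ------------------------------------------------------------- toy fixture
def _toy_features() -> np.ndarray:
    """Deterministic, seed-free features: class mean 2*e_c plus exact
    decimal offsets, so the written fixture round-trips bit-identically."""
    V, F = 30, 4
    feats = np.zeros((V, F))
    for i in range(V):
        c = 0 if i < 15 else 1
        for f in range(F):
            offset = ((7 * i + 3 * f) % 11 - 5) / 10.0  # in {-0.5, ..., 0.5}
            feats[i, f] = (2.0 if f == c else 0.0) + offset
    return feats


def fixture_toy_network() -> MultiViewNetwork:
    """Hard-coded 30-node, 2-view, 2-class, linearly separable network.

    View 1 is two 15-cliques aligned with the classes; view 2 is the
    cosine-similarity view of the features at top_k=3.  All nodes are
    training nodes (the fixture exists to be overfit)."""
    feats = _toy_features()
    clique_pairs = [(i, j) for base in (0, 15) for i in range(base, base + 15)
                    for j in range(i + 1, base + 15)]
    view1 = EdgeSet.from_pairs(clique_pairs, 30)
    view2 = build_similarity_view(feats, top_k=3)
    labels = np.array([0] * 15 + [1] * 15, dtype=np.intp)
    return MultiViewNetwork(
        node_ids=[f"n{i:02d}" for i in range(30)],
        features=feats,
        labels=labels,
        views=[view1, view2],
        train_mask=np.ones(30, dtype=bool),
        class_names=["A", "B"],
    )


def write_network(network: MultiViewNetwork, out_dir) -> None:
    """Write a network in the plain-text formats the loaders read: one edge
    list per view, a ".content"-style feature table, and mask files."""
    out = Path(out_dir)
    out.mkdir(parents=True, exist_ok=True)
    for m, view in enumerate(network.views):
        write_edge_list(out / f"view{m + 1}.edges", view, network.node_ids)
    names = network.class_names or [str(c) for c in range(network.n_classes)]
    label_strings = [names[c] for c in network.labels] if not network.multilabel else [
        ",".join(str(v) for v in row) for row in network.labels
    ]
    write_feature_table(out / "nodes.content", network.node_ids, network.features, label_strings)
    for mask, fname in ((network.train_mask, "train.ids"), (network.val_mask, "val.ids"),
                        (network.test_mask, "test.ids")):
        if mask is not None:
            with open(out / fname, "w") as fh:
                for i in np.where(mask)[0]:
                    fh.write(network.node_ids[i] + "\n")
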