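"""Multi-view network data model and plain-text I/O.

A multi-view network is a single node set observed under k relations: each
view contributes its own undirected edge set over the shared nodes, while
features and labels are per node.  This is the natural container for, e.g.,
multi-evidence protein networks (physical interaction vs. co-expression
among the same proteins) or citation corpora with citation and
text-similarity views.

Readers cover the two text dialects common for these benchmarks: a
two-column whitespace edge list (the ".cites" layout) and a feature+label
table whose rows are ``id  f_1 ... f_F  label`` (the ".content" layout),
plus CSV with a header.  An extra view can be constructed from node-feature
cosine similarity with :func:`build_similarity_view`.
"""

from __future__ import annotations

import logging
from dataclasses import dataclass, field
from pathlib import Path

import numpy as np
import pandas as pd

logger = logging.getLogger(__name__)

__all__ = [
    "EdgeSet",
    "MultiViewNetwork",
    "NeighborIndex",
    "load_edge_list",
    "write_edge_list",
    "load_feature_table",
    "write_feature_table",
    "build_similarity_view",
    "neighborhoods",
    "validate",
    "write_predictions",
]


@dataclass(frozen=True)
class EdgeSet:
    """Undirected edge set over nodes ``0..n_nodes-1``.

    Self-loops are never stored here; the attention module injects them
    itself so every neighbourhood softmax has non-empty support.
    """

    edges: frozenset  # of frozenset-free canonical (min, max) tuples
    n_nodes: int

    def __post_init__(self):
        for i, j in self.edges:
            if i == j:
                raise ValueError(f"self-loop ({i},{i}) not allowed in EdgeSet")
            if not (0 <= i < self.n_nodes and 0 <= j < self.n_nodes):
                raise ValueError(f"edge ({i},{j}) outside [0,{self.n_nodes})")
            if i > j:
                raise ValueError(f"edge ({i},{j}) not in canonical (min,max) order")

    @staticmethod
    def from_pairs(pairs, n_nodes: int) -> "EdgeSet":
        canon = frozenset((min(i, j), max(i, j)) for i, j in pairs if i != j)
        return EdgeSet(edges=canon, n_nodes=n_nodes)

    @property
    def n_edges(self) -> int:
        return len(self.edges)

    def sorted_edges(self) -> list[tuple[int, int]]:
        return sorted(self.edges)


@dataclass
class MultiViewNetwork:
    """Shared node set with features, labels and k per-view edge sets."""

    node_ids: list[str]
    features: np.ndarray  # V x F float
    labels: np.ndarray  # (V,) int class indices, or (V, C) binary for multilabel
    views: list[EdgeSet]
    train_mask: np.ndarray | None = None
    val_mask: np.ndarray | None = None
    test_mask: np.ndarray | None = None
    class_names: list[str] = field(default_factory=list)

    @property
    def n_nodes(self) -> int:
        return len(self.node_ids)

    @property
    def n_views(self) -> int:
        return len(self.views)

    @property
    def multilabel(self) -> bool:
        return self.labels.ndim == 2

    @property
    def n_classes(self) -> int:
        if self.multilabel:
            return self.labels.shape[1]
        return int(self.labels.max()) + 1 if self.labels.size else 0


@dataclass(frozen=True)
class NeighborIndex:
    """Per-node sorted adjacency lists, optionally including the node itself."""

    lists: tuple  # tuple of tuples of ints, ascending
    include_self: bool

    @property
    def n_nodes(self) -> int:
        return len(self.lists)

    def edge_arrays(self) -> tuple[np.ndarray, np.ndarray]:
        """Flatten to (center, neighbor) arrays in deterministic order."""
        centers, nbrs = [], []
        for i, lst in enumerate(self.lists):
            centers.extend([i] * len(lst))
            nbrs.extend(lst)
        return np.asarray(centers, dtype=np.intp), np.asarray(nbrs, dtype=np.intp)


# --------------------------------------------------------------------- loaders
def load_edge_list(path, id_map: dict[str, int] | None = None) -> tuple[EdgeSet, dict[str, int]]:
    """Read a two-column edge list; returns the EdgeSet and the id mapping.

    Duplicate lines and reversed duplicates collapse to a single undirected
    edge; self-loop lines are dropped with a warning.  When `id_map` is
    absent, ids are assigned indices in order of first appearance.
    """
    path = Path(path)
    assign = id_map is None
    mapping: dict[str, int] = {} if assign else dict(id_map)
    pairs: list[tuple[int, int]] = []
    with open(path) as fh:
        for lineno, raw in enumerate(fh, start=1):
            line = raw.strip()
            if not line:
                continue
            tokens = line.split()
            if len(tokens) != 2:
                raise ValueError(
                    f"{path}:{lineno}: expected two whitespace-separated node ids, got {len(tokens)}"
                )
            idx = []
            for tok in tokens:
                if tok not in mapping:
                    if not assign:
                        raise KeyError(f"{path}:{lineno}: node id {tok!r} not in provided id_map")
                    mapping[tok] = len(mapping)
                idx.append(mapping[tok])
            if idx[0] == idx[1]:
                logger.warning("%s:%d: dropping self-loop on id %r", path, lineno, tokens[0])
                continue
            pairs.append((idx[0], idx[1]))
    n_nodes = len(mapping)
    return EdgeSet.from_pairs(pairs, n_nodes), mapping


def write_edge_list(path, edge_set: EdgeSet, node_ids: list[str] | None = None) -> None:
    """Write one edge per line, canonical (min,max) order, sorted."""
    path = Path(path)
    with open(path, "w") as fh:
        for i, j in edge_set.sorted_edges():
            a = node_ids[i] if node_ids else str(i)
            b = node_ids[j] if node_ids else str(j)
            fh.write(f"{a}\t{b}\n")


def load_feature_table(path, dialect: str = "content") -> tuple[list[str], np.ndarray, np.ndarray, list[str]]:
    """Read a per-node feature+label table.

    dialect "content": whitespace-separated, no header, columns are
    ``id  f_1 ... f_F  label``.  dialect "csv": comma-separated with a
    header; first column id, last column label.

    Returns (node_ids, features V x F, labels as contiguous class indices in
    sorted label-string order, class_names).
    """
    path = Path(path)
    if dialect == "content":
        df = pd.read_csv(path, sep=r"\s+", header=None, dtype=str)
    elif dialect == "csv":
        df = pd.read_csv(path, dtype=str)
    else:
        raise ValueError(f"unknown dialect {dialect!r}")
    if df.isna().any().any():
        bad = np.argwhere(df.isna().values)[0]
        raise ValueError(f"{path}: ragged or missing entry at row {bad[0]}, col {bad[1]}")
    if df.shape[1] < 2:
        raise ValueError(f"{path}: need at least id and label columns")
    node_ids = df.iloc[:, 0].tolist()
    raw_feats = df.iloc[:, 1:-1]
    try:
        features = raw_feats.astype(np.float64).to_numpy()
    except ValueError:
        for r in range(raw_feats.shape[0]):
            for c in range(raw_feats.shape[1]):
                try:
                    float(raw_feats.iat[r, c])
                except ValueError:
                    raise ValueError(
                        f"{path}: non-numeric feature token {raw_feats.iat[r, c]!r} at row {r}, feature col {c}"
                    ) from None
        raise
    if features.size == 0:
        features = features.reshape(len(node_ids), 0)
    label_strings = df.iloc[:, -1].tolist()
    class_names = sorted(set(label_strings))
    lut = {name: k for k, name in enumerate(class_names)}
    labels = np.asarray([lut[s] for s in label_strings], dtype=np.intp)
    return node_ids, features, labels, class_names


def write_feature_table(path, node_ids, features, label_strings, dialect: str = "content",
                        fmt: str = "%.6f") -> None:
    path = Path(path)
    with open(path, "w") as fh:
        if dialect == "csv":
            cols = ["id"] + [f"f{k}" for k in range(np.shape(features)[1])] + ["label"]
            fh.write(",".join(cols) + "\n")
            sep = ","
        elif dialect == "content":
            sep = "\t"
        else:
            raise ValueError(f"unknown dialect {dialect!r}")
        for nid, row, lab in zip(node_ids, np.asarray(features), label_strings):
            vals = sep.join(fmt % v for v in row)
            fh.write(f"{nid}{sep}{vals}{sep}{lab}\n" if vals else f"{nid}{sep}{lab}\n")


def write_predictions(path, node_ids, predicted_labels, probabilities) -> None:
    """TSV of (node_id, predicted_label, probability of that label)."""
    with open(Path(path), "w") as fh:
        fh.write("node_id\tpredicted_label\tprobability\n")
        for nid, lab, p in zip(node_ids, predicted_labels, probabilities):
            fh.write(f"{nid}\t{lab}\t{p:.6f}\n")


# ------------------------------------------------------------ similarity view
def build_similarity_view(features: np.ndarray, top_k: int) -> EdgeSet:
    """Link each node to its `top_k` most cosine-similar other nodes.

    The union over directions is taken, so degrees can exceed `top_k`.
    Zero-norm rows have cosine similarity 0 to everything; ties are broken
    by ascending node index.
    """
    features = np.asarray(features, dtype=np.float64)
    V = features.shape[0]
    if top_k <= 0:
        raise ValueError("top_k must be positive")
    if V < 2:
        raise ValueError("need at least two nodes to build a similarity view")
    if top_k >= V:
        raise ValueError(f"top_k={top_k} must be < number of nodes {V}")
    norms = np.linalg.norm(features, axis=1)
    safe = np.where(norms > 0, norms, 1.0)
    unit = features / safe[:, None]
    sim = unit @ unit.T
    sim[norms == 0, :] = 0.0
    sim[:, norms == 0] = 0.0
    np.fill_diagonal(sim, -np.inf)
    pairs = []
    for i in range(V):
        # stable sort on (-sim, index): descending similarity, ascending index on ties
        order = np.lexsort((np.arange(V), -sim[i]))
        for j in order[:top_k]:
            pairs.append((i, int(j)))
    return EdgeSet.from_pairs(pairs, V)


# ------------------------------------------------------------- neighborhoods
def neighborhoods(edge_set: EdgeSet, include_self: bool = True) -> NeighborIndex:
    """Adjacency lists in ascending order; with `include_self` every node
    lists itself even when isolated, so no neighbourhood is empty."""
    adj: list[set[int]] = [set() for _ in range(edge_set.n_nodes)]
    for i, j in edge_set.edges:
        adj[i].add(j)
        adj[j].add(i)
    if include_self:
        for i in range(edge_set.n_nodes):
            adj[i].add(i)
    return NeighborIndex(lists=tuple(tuple(sorted(s)) for s in adj), include_self=include_self)


# ------------------------------------------------------------------ validate
def validate(network: MultiViewNetwork) -> list[str]:
    """Return a list of invariant violations (empty means valid)."""
    report: list[str] = []
    V = network.n_nodes
    if network.n_views < 1:
        report.append("network has no views (k must be >= 1)")
    for m, view in enumerate(network.views):
        if view.n_nodes != V:
            report.append(f"view {m}: n_nodes={view.n_nodes} differs from V={V}")
    if network.features.shape[0] != V:
        report.append(f"features have {network.features.shape[0]} rows, expected V={V}")
    bad = np.argwhere(~np.isfinite(network.features))
    for r, c in bad[:10]:
        report.append(f"non-finite feature at row {r}, col {c}")
    if network.labels.shape[0] != V:
        report.append(f"labels have {network.labels.shape[0]} entries, expected V={V}")
    masks = [m for m in (network.train_mask, network.val_mask, network.test_mask) if m is not None]
    for m in masks:
        if m.shape != (V,):
            report.append(f"mask shape {m.shape} differs from ({V},)")
    if len(masks) > 1 and all(m.shape == (V,) for m in masks):
        overlap = np.zeros(V, dtype=int)
        for m in masks:
            overlap += m.astype(int)
        if (overlap > 1).any():
            report.append(f"masks overlap at {int((overlap > 1).sum())} node(s)")
    return report
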