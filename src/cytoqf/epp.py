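"""Exhaustive Projection Pursuit: recursive 2D-projection gating.

High-dimensional event data are split recursively: at each node every
axis-aligned channel pair is clustered with the 2D density-mode clusterer,
candidate two-way separations of the resulting clusters are scored by the
decision-boundary (Bayes-error) index, and the globally best split below the
error threshold partitions the node's events into two children.  Recursion
stops when no projection offers a sufficiently clean split; the leaves are
the final subsets.

The search over projections is exhaustive over measured-channel pairs, which
is tractable for typical panels (<= 20 channels).  General (rotated) linear
projections are not searched.
"""

from __future__ import annotations

import itertools
import json
from dataclasses import dataclass, field
from pathlib import Path

import numpy as np

from .dbm2d import DEFAULT_GRID_SIZE, DEFAULT_THETA, boundary_error, cluster_2d
from .errors import DegenerateAxisError, InsufficientDataError
from .io_fcs import EventMatrix
from .subsets import Subset, subsets_from_labels

__all__ = ["EPPConfig", "GatingTreeNode", "best_projection", "epp_cluster", "tree_to_json"]


@dataclass(frozen=True)
class EPPConfig:
    """Stopping and clustering thresholds of the recursion.

    max_error      largest acceptable boundary misclassification estimate
    min_leaf_size  smallest admissible subset (None -> max(200, 0.2% of n))
    """

    max_error: float = 0.05
    min_leaf_size: int | None = None
    grid_size: int = DEFAULT_GRID_SIZE
    theta: float = DEFAULT_THETA
    max_bipartition_clusters: int = 10  # full bipartition search up to this k

    def resolved_min_leaf(self, n_total: int) -> int:
        if self.min_leaf_size is not None:
            return self.min_leaf_size
        return max(200, int(0.002 * n_total))


@dataclass
class GatingTreeNode:
    event_indices: np.ndarray
    projection: tuple[int, int] | None = None  # channel column indices
    error: float | None = None
    children: list["GatingTreeNode"] = field(default_factory=list)
    leaf_id: int | None = None

    @property
    def is_leaf(self) -> bool:
        return not self.children


@dataclass
class _SplitCandidate:
    pair: tuple[int, int]
    error: float
    side1_mask: np.ndarray  # over the node's events
    clustering_labels: np.ndarray


def _bipartitions(k: int, cap_full: int):
    """All two-way partitions of cluster labels 1..k (side containing 1 listed)."""
    labels = list(range(1, k + 1))
    if k <= cap_full:
        for r in range(1, k):
            for combo in itertools.combinations(labels[1:], r - 1):
                yield (1,) + combo
    else:  # cluster-vs-rest only
        for lab in labels:
            yield (lab,)


def best_projection(
    values: np.ndarray,
    indices: np.ndarray,
    config: EPPConfig = EPPConfig(),
    min_leaf: int | None = None,
) -> _SplitCandidate | None:
    """Best admissible two-way split over all channel pairs, or None.

    For every unordered channel pair the 2D clusterer runs on the node's
    events; every bipartition of the resulting clusters is scored by the
    boundary-error index.  The candidate with the smallest error wins, with
    lexicographic (channel-pair, side) tie-breaking; None when no candidate
    has error <= max_error with both sides >= the minimum leaf size.
    """
    indices = np.asarray(indices)
    sub = values[indices]
    d = values.shape[1]
    if min_leaf is None:
        min_leaf = config.resolved_min_leaf(values.shape[0])
    best: _SplitCandidate | None = None
    for pair in itertools.combinations(range(d), 2):
        pts = sub[:, pair]
        try:
            clustering = cluster_2d(
                pts, grid_size=config.grid_size, theta=config.theta
            )
        except (InsufficientDataError, DegenerateAxisError):
            continue
        if clustering.n_clusters < 2:
            continue
        present = np.unique(clustering.labels)
        k = len(present)
        relabel = {int(lab): i + 1 for i, lab in enumerate(present)}
        labs = np.vectorize(relabel.get)(clustering.labels)
        for side1 in _bipartitions(k, config.max_bipartition_clusters):
            mask = np.isin(labs, side1)
            n1 = int(mask.sum())
            if n1 < min_leaf or len(mask) - n1 < min_leaf:
                continue
            err = boundary_error(pts, labs, side1, grid_size=config.grid_size)
            if err > config.max_error:
                continue
            if best is None or err < best.error:
                best = _SplitCandidate(pair, err, mask, labs)
    if best is None:
        return None
    # canonicalize: side 1 contains the lowest original event index
    lowest_pos = int(np.argmin(indices))
    if not best.side1_mask[lowest_pos]:
        best.side1_mask = ~best.side1_mask
    return best


def epp_cluster(
    events: EventMatrix | np.ndarray,
    channels: list[str] | None = None,
    config: EPPConfig = EPPConfig(),
) -> tuple[GatingTreeNode, list[Subset]]:
    """Recursive projection-pursuit clustering of one sample.

    Returns the binary gating tree and the leaf subsets, labeled 1..K in
    depth-first discovery order.  Deterministic for fixed input and config.
    """
    if isinstance(events, EventMatrix):
        if channels is not None:
            cols = [events.channel_index(c) for c in channels]
            values = events.values[:, cols]
        else:
            values = events.values
        sample_id = events.sample_id
    else:
        values = np.asarray(events, dtype=np.float64)
        sample_id = ""
    n, d = values.shape
    min_leaf = config.resolved_min_leaf(n)
    if d < 2:
        raise InsufficientDataError("need at least 2 channels")
    if n < 2 * min_leaf:
        raise InsufficientDataError(
            f"need at least {2 * min_leaf} events, got {n}"
        )

    root = GatingTreeNode(event_indices=np.arange(n))
    leaf_counter = itertools.count(1)
    labels = np.zeros(n, dtype=np.int64)

    def recurse(node: GatingTreeNode) -> None:
        cand = None
        if len(node.event_indices) >= 2 * min_leaf:
            cand = best_projection(values, node.event_indices, config, min_leaf)
        if cand is None:
            node.leaf_id = next(leaf_counter)
            labels[node.event_indices] = node.leaf_id
            return
        node.projection = cand.pair
        node.error = cand.error
        left = GatingTreeNode(event_indices=node.event_indices[cand.side1_mask])
        right = GatingTreeNode(event_indices=node.event_indices[~cand.side1_mask])
        node.children = [left, right]
        recurse(left)
        recurse(right)

    recurse(root)
    subsets = subsets_from_labels(values, labels, sample_id=sample_id)
    return root, subsets


def epp_labels(tree: GatingTreeNode, n_events: int) -> np.ndarray:
    """Leaf labels per event recovered from a gating tree."""
    labels = np.zeros(n_events, dtype=np.int64)

    def walk(node: GatingTreeNode) -> None:
        if node.is_leaf:
            labels[node.event_indices] = node.leaf_id
        else:
            for c in node.children:
                walk(c)

    walk(tree)
    return labels


def tree_to_json(tree: GatingTreeNode, path=None) -> str:
    """Serialize a gating tree (channels, error, sizes) as JSON text."""

    def encode(node: GatingTreeNode) -> dict:
        out = {"n_events": int(len(node.event_indices))}
        if node.is_leaf:
            out["leaf_id"] = node.leaf_id
        else:
            out["projection"] = list(node.projection)
            out["error"] = node.error
            out["children"] = [encode(c) for c in node.children]
        return out

    text = json.dumps(encode(tree), indent=2)
    if path is not None:
        Path(path).write_text(text)
    return text
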