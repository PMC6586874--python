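"""Adaptive binning and the quadratic-form dissimilarity.

Two samples are merged and partitioned by recursive median splits along the
locally highest-variance dimension, to a global depth L chosen so the mean
occupancy is about 2*ln(N) events per bin, N being the smaller sample size.
Splitting both samples back along the same bin tree gives each cluster a
frequency histogram over a common bin index space.  The dissimilarity
between two such histograms f and g is the quadratic form

    QF(f, g) = sqrt((f-g)^T A (f-g)),   A_ij = 1 - d_ij / d_max,

where d_ij is the Euclidean distance between bin centroids.  On the
zero-sum difference of two normalized histograms this form is positive
semidefinite (Euclidean distance matrices are conditionally negative
definite), so the square root is real up to round-off, which is clamped.
"""

from __future__ import annotations

import logging
import math
from dataclasses import dataclass

import numpy as np
from scipy.spatial.distance import pdist, squareform

from .errors import EmptyInputError

logger = logging.getLogger(__name__)

__all__ = [
    "Binning",
    "BinnedDistribution",
    "adaptive_bin",
    "bin_cluster",
    "similarity_matrix",
    "qf_distance",
]


@dataclass
class _SplitNode:
    dim: int = -1  # -1 marks a leaf
    threshold: float = 0.0
    left: "_SplitNode | None" = None
    right: "_SplitNode | None" = None
    bin_index: int = -1


@dataclass
class Binning:
    """Shared median-split partition of a merged sample pair."""

    root: _SplitNode
    bin_centroids: np.ndarray  # B x d
    n_small: int
    depth: int

    @property
    def B(self) -> int:
        return self.bin_centroids.shape[0]

    def assign(self, events: np.ndarray) -> np.ndarray:
        """Bin index of each event (events below a threshold go left, >= right)."""
        events = np.asarray(events, dtype=np.float64)
        out = np.empty(events.shape[0], dtype=np.int64)

        def walk(node: _SplitNode, idx: np.ndarray) -> None:
            if node.dim < 0:
                out[idx] = node.bin_index
                return
            go_left = events[idx, node.dim] < node.threshold
            walk(node.left, idx[go_left])
            walk(node.right, idx[~go_left])

        walk(self.root, np.arange(events.shape[0]))
        return out


@dataclass
class BinnedDistribution:
    """A cluster's event frequencies over the shared bins (sums to 1)."""

    frequencies: np.ndarray
    source: str = ""


def bin_depth(n_merged: int, n_small: int) -> int:
    """Global split depth L = round(log2(n_merged / (2 ln n_small))), >= 0."""
    target = 2.0 * math.log(n_small)
    if n_merged <= target or target <= 0:
        return 0
    return max(0, int(math.floor(math.log2(n_merged / target) + 0.5)))


def adaptive_bin(
    events_a: np.ndarray,
    events_b: np.ndarray,
    depth: int | None = None,
) -> Binning:
    """Adaptive binning of the merged pair of samples.

    Splits are at the median of the highest-variance dimension within each
    node (ties toward the lower dimension index; median-equal events go to
    the right child).  The depth is global, so B = 2^L bins.  Empty bins
    inherit the centroid of their nearest non-empty ancestor.
    """
    events_a = np.asarray(events_a, dtype=np.float64)
    events_b = np.asarray(events_b, dtype=np.float64)
    if events_a.shape[0] == 0 or events_b.shape[0] == 0:
        raise EmptyInputError("both samples must be non-empty for binning")
    if events_a.shape[1] != events_b.shape[1]:
        raise EmptyInputError("samples must share channel space")
    merged = np.vstack([events_a, events_b])
    n_small = min(events_a.shape[0], events_b.shape[0])
    L = bin_depth(merged.shape[0], n_small) if depth is None else depth

    n_bins = 2**L
    centroids = np.zeros((n_bins, merged.shape[1]))
    counter = iter(range(n_bins))

    def build(idx: np.ndarray, level: int, fallback: np.ndarray) -> _SplitNode:
        centroid = merged[idx].mean(axis=0) if idx.size else fallback
        if level == L:
            b = next(counter)
            centroids[b] = centroid
            return _SplitNode(bin_index=b)
        if idx.size:
            var = merged[idx].var(axis=0)
            dim = int(np.argmax(var))  # argmax takes the first max: lower index wins ties
            thr = float(np.median(merged[idx, dim]))
            go_left = merged[idx, dim] < thr
            left_idx, right_idx = idx[go_left], idx[~go_left]
        else:
            dim, thr = 0, 0.0
            left_idx = right_idx = idx
        node = _SplitNode(dim=dim, threshold=thr)
        node.left = build(left_idx, level + 1, centroid)
        node.right = build(right_idx, level + 1, centroid)
        return node

    root = build(np.arange(merged.shape[0]), 0, merged.mean(axis=0))
    return Binning(root=root, bin_centroids=centroids, n_small=n_small, depth=L)


def bin_cluster(
    binning: Binning, events: np.ndarray, member_indices=None, source: str = ""
) -> BinnedDistribution:
    """Frequency histogram of a cluster over the shared bins (normalized)."""
    events = np.asarray(events, dtype=np.float64)
    members = events if member_indices is None else events[np.asarray(member_indices)]
    if members.shape[0] == 0:
        raise EmptyInputError("empty cluster cannot be binned")
    counts = np.bincount(binning.assign(members), minlength=binning.B)
    return BinnedDistribution(
        frequencies=counts / counts.sum(), source=source
    )


def similarity_matrix(binning: Binning) -> np.ndarray:
    """Bin-similarity matrix A_ij = 1 - d_ij/d_max from the centroids."""
    if binning.B == 1:
        return np.ones((1, 1))
    d = squareform(pdist(binning.bin_centroids))
    d_max = d.max()
    if d_max == 0:
        logger.warning("all bin centroids identical; similarity degenerates to ones")
        return np.ones_like(d)
    return 1.0 - d / d_max


def qf_distance(
    f: BinnedDistribution | np.ndarray,
    g: BinnedDistribution | np.ndarray,
    sim: np.ndarray,
) -> float:
    """Quadratic-form dissimilarity sqrt((f-g)^T A (f-g)), >= 0."""
    fv = f.frequencies if isinstance(f, BinnedDistribution) else np.asarray(f, dtype=np.float64)
    gv = g.frequencies if isinstance(g, BinnedDistribution) else np.asarray(g, dtype=np.float64)
    if fv.shape != gv.shape or sim.shape != (fv.size, fv.size):
        raise ValueError(
            f"shape mismatch: f {fv.shape}, g {gv.shape}, A {sim.shape}"
        )
    diff = fv - gv
    val = float(diff @ sim @ diff)
    return math.sqrt(max(0.0, val))
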