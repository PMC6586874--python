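"""Cluster-level displays: MDS of subset medians and the QF-tree hierarchy.

The MDS display embeds the medians of all subsets of both samples jointly
with classical (Torgerson) scaling — double-centering of squared Euclidean
distances followed by the top-2 eigenvectors — so configurations that are
intrinsically planar are reproduced exactly and the embedding is
deterministic up to the canonicalized reflection.

The QF-tree agglomerates one sample's subsets bottom-up under the
dissimilarity QF + c*DM, where DM is the Euclidean distance between group
medians and c scales the largest DM to the smallest initial QF score so the
two terms are of the same order of magnitude.  Merged groups are pooled and
re-binned pairwise at each level.
"""

from __future__ import annotations

import logging
from dataclasses import dataclass, field
from pathlib import Path

import numpy as np
from scipy.linalg import eigh
from scipy.spatial.distance import pdist, squareform

from .errors import InsufficientDataError
from .qf_core import adaptive_bin, bin_cluster, qf_distance, similarity_matrix
from .qfmatch import MatchResult
from .subsets import Subset

logger = logging.getLogger(__name__)

__all__ = [
    "MDSLayout",
    "QFTreeNode",
    "classical_mds",
    "mds_embed",
    "scaling_factor",
    "qf_tree",
    "to_newick",
    "render",
]


def scaling_factor(qf_scores, dm_scores) -> float:
    """c = min(QF)/max(DM), putting the largest median distance on the same
    order of magnitude as the smallest quadratic-form score; 0 when all
    medians coincide (pure-QF fallback, logged by the caller)."""
    max_dm = max(dm_scores)
    if max_dm == 0:
        return 0.0
    return min(qf_scores) / max_dm


# ---------------------------------------------------------------------------
# MDS
# ---------------------------------------------------------------------------


@dataclass
class MDSLayout:
    coords: np.ndarray  # (n_subsets, 2), samples A then B
    radii: np.ndarray
    colors: np.ndarray  # matched subsets share a color id; -1 = unmatched
    sample_ids: list[str]
    labels: list[int]


def classical_mds(dist: np.ndarray, k: int = 2) -> np.ndarray:
    """Torgerson scaling of a distance matrix to k dimensions.

    Axes are ordered by decreasing eigenvalue; each axis sign is fixed so
    the first point with a nonzero coordinate on it is positive.
    """
    d2 = np.asarray(dist, dtype=np.float64) ** 2
    n = d2.shape[0]
    j = np.eye(n) - np.ones((n, n)) / n
    b = -0.5 * j @ d2 @ j
    vals, vecs = eigh(b)
    order = np.argsort(vals)[::-1][:k]
    lam = np.clip(vals[order], 0.0, None)
    coords = vecs[:, order] * np.sqrt(lam)
    for axis in range(coords.shape[1]):
        col = coords[:, axis]
        nz = np.flatnonzero(np.abs(col) > 1e-12)
        if nz.size and col[nz[0]] < 0:
            coords[:, axis] = -col
    return coords


def mds_embed(
    subsets_a: list[Subset],
    subsets_b: list[Subset] | None = None,
    match_result: MatchResult | None = None,
) -> MDSLayout:
    """Joint 2D embedding of subset medians of one or two samples.

    Circle radius is sqrt(relative frequency), so circle area is
    proportional to the subset's frequency in its sample.  When a match
    result is given, matched subsets receive the same color id.
    """
    subsets_b = subsets_b or []
    allsub = list(subsets_a) + list(subsets_b)
    if len(allsub) < 2:
        raise InsufficientDataError("MDS needs at least 2 subsets")
    medians = np.vstack([s.median for s in allsub])
    coords = classical_mds(squareform(pdist(medians)))

    colors = np.full(len(allsub), -1, dtype=np.int64)
    if match_result is not None:
        n_a = len(subsets_a)
        pos_a = {s.label: i for i, s in enumerate(subsets_a)}
        pos_b = {s.label: n_a + i for i, s in enumerate(subsets_b)}
        for color, m in enumerate(match_result.matches):
            for la in m.a_labels:
                if la in pos_a:
                    colors[pos_a[la]] = color
            for lb in m.b_labels:
                if lb in pos_b:
                    colors[pos_b[lb]] = color

    return MDSLayout(
        coords=coords,
        radii=np.sqrt([s.frequency for s in allsub]),
        colors=colors,
        sample_ids=[s.sample_id or ("A" if i < len(subsets_a) else "B") for i, s in enumerate(allsub)],
        labels=[s.label for s in allsub],
    )


# ---------------------------------------------------------------------------
# QF-tree
# ---------------------------------------------------------------------------


@dataclass
class QFTreeNode:
    members: tuple[int, ...]  # original subset labels
    height: float = 0.0  # merge dissimilarity QF + c*DM (monotonicity-clamped)
    edge_length: float = 0.0  # QF component of the merge score
    children: list["QFTreeNode"] = field(default_factory=list)

    @property
    def is_leaf(self) -> bool:
        return not self.children

    def leaves(self) -> list["QFTreeNode"]:
        if self.is_leaf:
            return [self]
        return [l for c in self.children for l in c.leaves()]


def _group_qf(events: np.ndarray, idx1: np.ndarray, idx2: np.ndarray) -> float:
    """QF dissimilarity between two event groups, rebinned pairwise."""
    binning = adaptive_bin(events[idx1], events[idx2])
    sim = similarity_matrix(binning)
    f = bin_cluster(binning, events[idx1])
    g = bin_cluster(binning, events[idx2])
    return qf_distance(f, g, sim)


def qf_tree(subsets: list[Subset], events: np.ndarray) -> QFTreeNode:
    """Agglomerative hierarchy of one sample's subsets under QF + c*DM.

    c = (smallest initial pairwise QF) / (largest initial pairwise DM),
    fixed once from the leaf-level tables.  At each level the current
    groups' pairwise dissimilarities are recomputed with pooled, pairwise
    re-binned events, and the closest pair merges; merge heights are clamped
    to be non-decreasing (re-computation can transiently decrease them).
    """
    if len(subsets) < 2:
        raise InsufficientDataError("QF-tree needs at least 2 subsets")
    events = np.asarray(events, dtype=np.float64)

    nodes = [QFTreeNode(members=(s.label,)) for s in subsets]
    groups = [np.asarray(s.event_indices) for s in subsets]

    def group_median(idx: np.ndarray) -> np.ndarray:
        return np.median(events[idx], axis=0)

    # initial pairwise tables fix the scaling factor c
    n = len(nodes)
    qf0 = {}
    dm0 = {}
    for i in range(n):
        for j in range(i + 1, n):
            qf0[(i, j)] = _group_qf(events, groups[i], groups[j])
            dm0[(i, j)] = float(
                np.linalg.norm(group_median(groups[i]) - group_median(groups[j]))
            )
    c = scaling_factor(qf0.values(), dm0.values())
    if c == 0.0:
        logger.warning("all subset medians identical; QF-tree uses pure QF scores")

    qf_cache = dict(qf0)
    dm_cache = dict(dm0)
    running_max = 0.0
    while len(nodes) > 1:
        best_key, best_score, best_qf = None, np.inf, np.inf
        for i in range(len(nodes)):
            for j in range(i + 1, len(nodes)):
                q = qf_cache[(i, j)]
                score = q + c * dm_cache[(i, j)]
                if score < best_score:
                    best_key, best_score, best_qf = (i, j), score, q
        i, j = best_key
        if best_score < running_max:
            logger.warning(
                "non-monotone merge height %.4g clamped to %.4g", best_score, running_max
            )
            best_score = running_max
        running_max = best_score
        merged = QFTreeNode(
            members=tuple(sorted(nodes[i].members + nodes[j].members)),
            height=best_score,
            edge_length=best_qf,
            children=[nodes[i], nodes[j]],
        )
        merged_idx = np.concatenate([groups[i], groups[j]])
        keep = [k for k in range(len(nodes)) if k not in (i, j)]
        new_nodes = [nodes[k] for k in keep] + [merged]
        new_groups = [groups[k] for k in keep] + [merged_idx]
        new_qf, new_dm = {}, {}
        remap = {k: p for p, k in enumerate(keep)}
        for (
            a,
            b,
        ) in qf_cache:
            if a in remap and b in remap:
                na, nb = sorted((remap[a], remap[b]))
                new_qf[(na, nb)] = qf_cache[(a, b)]
                new_dm[(na, nb)] = dm_cache[(a, b)]
        last = len(new_nodes) - 1
        for k in range(last):
            new_qf[(k, last)] = _group_qf(events, new_groups[k], merged_idx)
            new_dm[(k, last)] = float(
                np.linalg.norm(group_median(new_groups[k]) - group_median(merged_idx))
            )
        nodes, groups, qf_cache, dm_cache = new_nodes, new_groups, new_qf, new_dm
    return nodes[0]


def to_newick(root: QFTreeNode, names: dict[int, str] | None = None) -> str:
    """Newick string with branch lengths equal to the merge QF components."""

    def fmt(node: QFTreeNode, parent_edge: float) -> str:
        if node.is_leaf:
            label = node.members[0]
            name = names.get(label, f"S{label}") if names else f"S{label}"
            return f"{name}:{parent_edge:.6g}"
        inner = ",".join(fmt(c, node.edge_length) for c in node.children)
        return f"({inner}):{parent_edge:.6g}"

    return fmt(root, 0.0) + ";"


# ---------------------------------------------------------------------------
# rendering
# ---------------------------------------------------------------------------


def _render_mds(layout: MDSLayout, path: Path) -> list[Path]:
    import matplotlib

    matplotlib.use("Agg")
    import matplotlib.pyplot as plt
    import pandas as pd

    fig, ax = plt.subplots(figsize=(6, 6))
    cmap = plt.get_cmap("tab10")
    span = max(np.ptp(layout.coords[:, 0]), np.ptp(layout.coords[:, 1]), 1e-9)
    for (x, y), r, col, sid, lab in zip(
        layout.coords, layout.radii, layout.colors, layout.sample_ids, layout.labels
    ):
        face = cmap(int(col) % 10) if col >= 0 else "lightgray"
        ax.add_patch(
            plt.Circle((x, y), radius=0.08 * span * r / max(layout.radii), color=face, alpha=0.7)
        )
        ax.annotate(f"{sid}:{lab}", (x, y), ha="center", va="center", fontsize=8)
    ax.set_xlabel("MDS 1")
    ax.set_ylabel("MDS 2")
    ax.set_aspect("equal")
    ax.autoscale_view()
    ax.relim()
    pad = 0.15 * span
    ax.set_xlim(layout.coords[:, 0].min() - pad, layout.coords[:, 0].max() + pad)
    ax.set_ylim(layout.coords[:, 1].min() - pad, layout.coords[:, 1].max() + pad)
    fig.savefig(path, dpi=120)
    plt.close(fig)

    csv_path = path.with_suffix(".csv")
    pd.DataFrame(
        {
            "sample": layout.sample_ids,
            "label": layout.labels,
            "x": layout.coords[:, 0],
            "y": layout.coords[:, 1],
            "radius": layout.radii,
            "color": layout.colors,
        }
    ).to_csv(csv_path, index=False)
    return [path, csv_path]


def _render_tree(root: QFTreeNode, path: Path) -> list[Path]:
    import matplotlib

    matplotlib.use("Agg")
    import matplotlib.pyplot as plt

    leaves = root.leaves()
    xpos = {id(l): i for i, l in enumerate(leaves)}

    fig, ax = plt.subplots(figsize=(max(4, len(leaves)), 4))

    def draw(node: QFTreeNode) -> float:
        if node.is_leaf:
            x = xpos[id(node)]
            ax.annotate(
                f"S{node.members[0]}", (x, 0), ha="center", va="top", fontsize=9
            )
            return x
        xs = [draw(c) for c in node.children]
        heights = [c.height for c in node.children]
        for x, h in zip(xs, heights):
            ax.plot([x, x], [h, node.height], color="k", lw=1)
        ax.plot([xs[0], xs[-1]], [node.height, node.height], color="k", lw=1)
        return float(np.mean(xs))

    draw(root)
    ax.set_ylabel("merge dissimilarity (QF + c*DM)")
    ax.set_xticks([])
    fig.savefig(path, dpi=120)
    plt.close(fig)

    nwk_path = path.with_suffix(".nwk")
    nwk_path.write_text(to_newick(root) + "\n")
    return [path, nwk_path]


def render(layout_or_tree, path) -> list[Path]:
    """Write a static image plus a machine-readable export.

    MDS layouts get a PNG of scaled circles and a coordinates CSV; QF-trees
    get a dendrogram PNG and a Newick file with QF branch lengths.
    """
    path = Path(path)
    path.parent.mkdir(parents=True, exist_ok=True)
    if isinstance(layout_or_tree, MDSLayout):
        return _render_mds(layout_or_tree, path)
    if isinstance(layout_or_tree, QFTreeNode):
        return _render_tree(layout_or_tree, path)
    raise TypeError(f"cannot render object of type {type(layout_or_tree)!r}")
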