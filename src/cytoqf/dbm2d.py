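"""2D density-mode clustering and the decision-boundary error index.

A binned kernel density estimate on a regular grid drives a watershed-style
clustering: every grid cell hill-climbs to a local density mode, basins of
weakly separated modes are merged (the highest saddle between two basins
relative to the lower of the two peaks decides), and events falling in
low-density cells are assigned to the nearest clustered event so no event is
left unlabeled.  The misclassification index for a two-way split of the
clusters is the density-overlap (Bayes error) estimate
sum_cells min(pi1*p1, pi2*p2) * cell_area.
"""

from __future__ import annotations

from dataclasses import dataclass

import numpy as np
from scipy.ndimage import gaussian_filter
from scipy.spatial import cKDTree

from .errors import DegenerateAxisError, InsufficientDataError, InvalidSplitError

__all__ = [
    "DensityGrid",
    "Clustering2D",
    "estimate_density",
    "cluster_2d",
    "boundary_error",
]

DEFAULT_GRID_SIZE = 128
#: saddle/lower-peak ratio above which two modes are merged as one cluster
DEFAULT_THETA = 0.5
#: cells below this fraction of the peak density are outlier cells
OUTLIER_DENSITY_FRACTION = 1e-4
#: clusters holding less than this fraction of events are dissolved into
#: their neighbors (isolated tail bumps are disconnected from every other
#: basin, so the saddle rule alone cannot absorb them)
MIN_CLUSTER_FRACTION = 0.01


@dataclass
class DensityGrid:
    """Normalized binned KDE on a regular grid (integrates to 1)."""

    x_edges: np.ndarray
    y_edges: np.ndarray
    density: np.ndarray  # shape (grid_size, grid_size), [ix, iy]
    bandwidth: tuple[float, float]

    @property
    def cell_area(self) -> float:
        return float(
            (self.x_edges[1] - self.x_edges[0]) * (self.y_edges[1] - self.y_edges[0])
        )

    def cell_of(self, points: np.ndarray) -> tuple[np.ndarray, np.ndarray]:
        """Grid cell indices of each point (clipped to the grid)."""
        gx = self.density.shape[0]
        gy = self.density.shape[1]
        ix = np.clip(np.searchsorted(self.x_edges, points[:, 0], side="right") - 1, 0, gx - 1)
        iy = np.clip(np.searchsorted(self.y_edges, points[:, 1], side="right") - 1, 0, gy - 1)
        return ix, iy


@dataclass
class Clustering2D:
    labels: np.ndarray  # per-event, 1..n_clusters
    n_clusters: int
    mode_cells: list[tuple[int, int]]
    grid: DensityGrid | None = None


def _silverman_bandwidth(points: np.ndarray) -> np.ndarray:
    # per-axis plug-in rule for a 2D Gaussian kernel: h_i = sd_i * n^(-1/6)
    n = points.shape[0]
    return points.std(axis=0, ddof=1) * n ** (-1.0 / 6.0)


def estimate_density(points: np.ndarray, grid_size: int = DEFAULT_GRID_SIZE) -> DensityGrid:
    """Binned KDE with per-axis Silverman bandwidths.

    The grid spans the data range padded by 3 bandwidths on each side; the
    histogram is smoothed with a Gaussian kernel and renormalized to a
    proper density.
    """
    points = np.asarray(points, dtype=np.float64)
    n = points.shape[0]
    if n < 2 * grid_size:
        raise InsufficientDataError(
            f"need at least {2 * grid_size} points for a {grid_size}^2 density grid, got {n}"
        )
    if not np.isfinite(points).all():
        raise DegenerateAxisError("non-finite coordinates in density input")
    h = _silverman_bandwidth(points)
    if (h <= 0).any():
        raise DegenerateAxisError("zero variance on a projection axis")
    lo = points.min(axis=0) - 3.0 * h
    hi = points.max(axis=0) + 3.0 * h
    x_edges = np.linspace(lo[0], hi[0], grid_size + 1)
    y_edges = np.linspace(lo[1], hi[1], grid_size + 1)
    counts, _, _ = np.histogram2d(points[:, 0], points[:, 1], bins=[x_edges, y_edges])
    sigma_cells = (
        h[0] / (x_edges[1] - x_edges[0]),
        h[1] / (y_edges[1] - y_edges[0]),
    )
    density = gaussian_filter(counts, sigma=sigma_cells, mode="constant")
    area = (x_edges[1] - x_edges[0]) * (y_edges[1] - y_edges[0])
    density /= density.sum() * area
    return DensityGrid(x_edges, y_edges, density, (float(h[0]), float(h[1])))


def _basins(density: np.ndarray, active: np.ndarray) -> np.ndarray:
    """Steepest-ascent basin label (root flat index) for each active cell.

    Each active cell points to its best 8-neighbor by (density, -index)
    lexicographic order; ties are therefore deterministic.  Cells that are
    their own best neighbor are modes.
    """
    gx, gy = density.shape
    flat = density.ravel()
    n = flat.size
    idx = np.arange(n)
    # key = density, tie-broken toward the lower flat index
    best_key = flat.copy()
    best_ptr = idx.copy()
    ii, jj = np.divmod(idx, gy)
    for di in (-1, 0, 1):
        for dj in (-1, 0, 1):
            if di == 0 and dj == 0:
                continue
            ni, nj = ii + di, jj + dj
            ok = (ni >= 0) & (ni < gx) & (nj >= 0) & (nj < gy)
            nidx = np.where(ok, ni * gy + nj, idx)
            nd = np.where(ok, flat[np.clip(nidx, 0, n - 1)], -np.inf)
            better = (nd > best_key) | ((nd == best_key) & (nidx < best_ptr))
            best_ptr = np.where(better & ok, nidx, best_ptr)
            best_key = np.where(better & ok, nd, best_key)
    ptr = np.where(active.ravel(), best_ptr, idx)
    # pointer doubling to the root
    for _ in range(64):
        nxt = ptr[ptr]
        if np.array_equal(nxt, ptr):
            break
        ptr = nxt
    return ptr


def _merge_weak_modes(
    density: np.ndarray, roots: np.ndarray, active: np.ndarray, theta: float
) -> dict[int, int]:
    """Union weakly separated basins; returns root -> merged-root map."""
    gx, gy = density.shape
    flat = density.ravel()
    act = active.ravel()
    # saddle height between adjacent basins (8-connectivity)
    saddle: dict[tuple[int, int], float] = {}
    ii, jj = np.divmod(np.arange(flat.size), gy)
    for di, dj in ((0, 1), (1, 0), (1, 1), (1, -1)):
        ni, nj = ii + di, jj + dj
        ok = (ni >= 0) & (ni < gx) & (nj >= 0) & (nj < gy)
        a = np.arange(flat.size)[ok]
        b = (ni * gy + nj)[ok]
        both = act[a] & act[b]
        a, b = a[both], b[both]
        ra, rb = roots[a], roots[b]
        diff = ra != rb
        for ca, cb, qa, qb in zip(ra[diff], rb[diff], flat[a[diff]], flat[b[diff]]):
            key = (min(ca, cb), max(ca, cb))
            v = min(qa, qb)
            if v > saddle.get(key, -np.inf):
                saddle[key] = v

    parent = {r: r for r in np.unique(roots[act])}
    peak = {r: flat[r] for r in parent}

    def find(r: int) -> int:
        while parent[r] != r:
            parent[r] = parent[parent[r]]
            r = parent[r]
        return r

    while True:
        best_ratio, best_pair = theta, None
        merged_saddle: dict[tuple[int, int], float] = {}
        for (a, b), s in saddle.items():
            ra, rb = find(a), find(b)
            if ra == rb:
                continue
            key = (min(ra, rb), max(ra, rb))
            if s > merged_saddle.get(key, -np.inf):
                merged_saddle[key] = s
        for (ra, rb), s in merged_saddle.items():
            ratio = s / min(peak[ra], peak[rb])
            if ratio > best_ratio or (
                ratio == best_ratio and best_pair is not None and (ra, rb) < best_pair
            ):
                best_ratio, best_pair = ratio, (ra, rb)
        if best_pair is None:
            break
        ra, rb = best_pair
        # keep the root with the higher peak (ties -> lower index)
        keep, drop = (ra, rb) if (peak[ra], -ra) >= (peak[rb], -rb) else (rb, ra)
        parent[drop] = keep
    return {r: find(r) for r in parent}


def cluster_2d(
    points: np.ndarray,
    grid_size: int = DEFAULT_GRID_SIZE,
    theta: float = DEFAULT_THETA,
    outlier_fraction: float = OUTLIER_DENSITY_FRACTION,
    min_cluster_fraction: float = MIN_CLUSTER_FRACTION,
) -> Clustering2D:
    """Density-mode clustering of a 2D point set; every event gets a label.

    Modes of the binned KDE seed clusters, basins are merged when the
    saddle/lower-peak ratio exceeds ``theta``, clusters holding less than
    ``min_cluster_fraction`` of the events are dissolved, and events in
    outlier cells (below ``outlier_fraction`` of the peak density) or in
    dissolved clusters are assigned to the nearest clustered event.
    """
    points = np.asarray(points, dtype=np.float64)
    n = points.shape[0]
    if n < 50:
        raise InsufficientDataError(f"need >= 50 events to cluster, got {n}")
    grid = estimate_density(points, grid_size=grid_size)
    density = grid.density
    active = density > outlier_fraction * density.max()
    roots = _basins(density, active)
    root_map = _merge_weak_modes(density, roots, active, theta)

    final_roots = sorted(set(root_map.values()))
    root_label = {r: i + 1 for i, r in enumerate(final_roots)}
    gy = density.shape[1]
    cell_label = np.zeros(density.size, dtype=np.int64)
    act = active.ravel()
    cell_label[act] = [root_label[root_map[r]] for r in roots[act]]

    ix, iy = grid.cell_of(points)
    labels = cell_label[ix * gy + iy]

    # dissolve insignificant clusters (typically disconnected tail bumps)
    n = len(points)
    counts = np.bincount(labels, minlength=len(final_roots) + 1)
    keep = {
        lab
        for lab in range(1, len(final_roots) + 1)
        if counts[lab] >= min_cluster_fraction * n
    }
    if not keep and len(final_roots):
        keep = {int(np.argmax(counts[1:]) + 1)}
    labels[~np.isin(labels, list(keep))] = 0
    kept_roots = [r for r in final_roots if root_label[r] in keep]

    unassigned = labels == 0
    if unassigned.any():
        if (~unassigned).sum() == 0:  # pathological: everything below cutoff
            labels[:] = 1
            kept_roots = final_roots[:1]
        else:
            tree = cKDTree(points[~unassigned])
            _, nn = tree.query(points[unassigned])
            labels[unassigned] = labels[~unassigned][nn]

    # compact labels to 1..k in root order
    remap = {root_label[r]: i + 1 for i, r in enumerate(kept_roots)}
    labels = np.vectorize(remap.get)(labels)
    mode_cells = [divmod(int(r), gy) for r in kept_roots]
    return Clustering2D(
        labels=labels,
        n_clusters=int(len(np.unique(labels))),
        mode_cells=mode_cells,
        grid=grid,
    )


def boundary_error(
    points: np.ndarray,
    labels: np.ndarray,
    side1_clusters,
    grid_size: int = DEFAULT_GRID_SIZE,
) -> float:
    """Estimated Bayes error of the two-class split of a clustering.

    ``side1_clusters`` lists the cluster labels forming side 1; all other
    labels form side 2.  Each side's density is re-estimated on a common
    grid with its own bandwidth and the overlap
    sum min(pi1*p1, pi2*p2)*cell_area is returned (in [0, 0.5]).
    """
    points = np.asarray(points, dtype=np.float64)
    labels = np.asarray(labels)
    side1 = np.isin(labels, np.asarray(list(side1_clusters)))
    n1, n2 = int(side1.sum()), int((~side1).sum())
    if n1 == 0 or n2 == 0:
        raise InvalidSplitError("both sides of a split must be non-empty")

    h1 = _silverman_bandwidth(points[side1]) if n1 > 1 else np.array([0.0, 0.0])
    h2 = _silverman_bandwidth(points[~side1]) if n2 > 1 else np.array([0.0, 0.0])
    h = np.maximum(np.maximum(h1, h2), 1e-12)
    lo = points.min(axis=0) - 3.0 * h
    hi = points.max(axis=0) + 3.0 * h
    x_edges = np.linspace(lo[0], hi[0], grid_size + 1)
    y_edges = np.linspace(lo[1], hi[1], grid_size + 1)
    area = (x_edges[1] - x_edges[0]) * (y_edges[1] - y_edges[0])

    def side_density(pts: np.ndarray, hs: np.ndarray) -> np.ndarray:
        counts, _, _ = np.histogram2d(pts[:, 0], pts[:, 1], bins=[x_edges, y_edges])
        sigma = (
            max(hs[0], 1e-12) / (x_edges[1] - x_edges[0]),
            max(hs[1], 1e-12) / (y_edges[1] - y_edges[0]),
        )
        d = gaussian_filter(counts, sigma=sigma, mode="constant")
        s = d.sum() * area
        return d / s if s > 0 else d

    p1 = side_density(points[side1], np.maximum(h1, 1e-12))
    p2 = side_density(points[~side1], np.maximum(h2, 1e-12))
    pi1 = n1 / (n1 + n2)
    pi2 = n2 / (n1 + n2)
    err = float(np.minimum(pi1 * p1, pi2 * p2).sum() * area)
    return min(max(err, 0.0), 0.5)
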