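"""Hub-node clustering of (scale, shape) parameter pairs.

The number of clusters is not an input: it emerges from the inter-point
distances. A distance threshold T is set to a multiple of the mean pairwise
Euclidean distance; a single leader pass then seeds hubs (the first point
founds the first hub; each later point joins its nearest hub if within T,
else founds a new one), after which hubs are re-elected as cluster medoids
and points reassigned to their nearest hub until stable. Everything is
deterministic given the input order and configuration; ties break toward
the lowest hub index.
"""

from __future__ import annotations

from dataclasses import dataclass

import numpy as np
from scipy.spatial.distance import cdist, pdist

from .data_io import Partition
from .weibull import ParameterTable

__all__ = ["HubConfig", "hub_cluster", "pairwise_mean_distance"]


@dataclass(frozen=True)
class HubConfig:
    """Knobs of the hub algorithm.

    threshold_factor
        Multiplier on the mean pairwise distance giving the join threshold
        T; smaller factors yield more (never fewer) clusters.
    standardize
        Z-score each coordinate before computing distances. Off by default:
        raw (a, b) space is where the method plots and reasons.
    max_iter
        Hub re-election/reassignment iterations (1 = single leader pass).
    min_cluster_size
        Clusters smaller than this are merged into the nearest hub's
        cluster at the end.
    """

    threshold_factor: float = 0.5
    metric: str = "euclidean"
    standardize: bool = False
    max_iter: int = 20
    min_cluster_size: int = 1

    def __post_init__(self) -> None:
        if self.threshold_factor <= 0:
            raise ValueError("threshold_factor must be positive")
        if self.metric != "euclidean":
            raise ValueError("only the euclidean metric is supported")
        if self.max_iter < 1 or self.min_cluster_size < 1:
            raise ValueError("max_iter and min_cluster_size must be >= 1")


def pairwise_mean_distance(points: np.ndarray) -> float:
    """Mean Euclidean distance over all unordered point pairs."""
    pts = np.asarray(points, dtype=float)
    if pts.ndim != 2 or len(pts) < 2:
        raise ValueError("pairwise_mean_distance needs >= 2 points")
    return float(pdist(pts).mean())


def _medoid(pts: np.ndarray, members: np.ndarray) -> int:
    """Index (into the full array) of the member minimizing total distance
    to the other members; ties break to the lowest index."""
    sub = pts[members]
    d = cdist(sub, sub)
    return int(members[int(np.argmin(d.sum(axis=1)))])


def _merge_close_hubs(
    pts: np.ndarray, labels: np.ndarray, hub_idx: list[int], T: float
) -> tuple[np.ndarray, list[int]]:
    """Merge clusters whose hubs lie within T of each other (transitively).

    Merged components keep the lowest participating label; hubs are
    re-elected as medoids of the merged memberships. Deterministic.
    """
    k = len(hub_idx)
    if k < 2:
        return labels, hub_idx
    hubs = pts[np.asarray(hub_idx)]
    parent = list(range(k))

    def find(i: int) -> int:
        while parent[i] != i:
            parent[i] = parent[parent[i]]
            i = parent[i]
        return i

    d = cdist(hubs, hubs)
    for i in range(k):
        for j in range(i + 1, k):
            if d[i, j] <= T:
                ri, rj = find(i), find(j)
                if ri != rj:
                    parent[max(ri, rj)] = min(ri, rj)
    roots = [find(i) for i in range(k)]
    if len(set(roots)) == k:
        return labels, hub_idx
    order = sorted(set(roots))
    remap = {root: new for new, root in enumerate(order)}
    new_labels = np.array([remap[roots[l]] for l in labels])
    new_hub_idx = [
        _medoid(pts, np.flatnonzero(new_labels == lab)) for lab in range(len(order))
    ]
    return new_labels, new_hub_idx


def hub_cluster(table: ParameterTable, cfg: HubConfig | None = None) -> Partition:
    """Cluster a parameter table; the cluster count is auto-determined.

    Returns a :class:`Partition` whose ``hubs`` map each cluster label to
    its hub (medoid) gene. After convergence every point is at least as
    close to its own hub as to any other hub.
    """
    cfg = cfg or HubConfig()
    if len(table) == 0:
        raise ValueError("hub_cluster: empty parameter table")
    pts = np.asarray(table.points, dtype=float)
    if cfg.standardize:
        sd = pts.std(axis=0)
        sd[sd == 0] = 1.0
        pts = (pts - pts.mean(axis=0)) / sd

    m = len(pts)
    if m == 1:
        return Partition({table.gene_ids[0]: 0}, hubs={0: table.gene_ids[0]})

    T = cfg.threshold_factor * pairwise_mean_distance(pts)

    # Leader pass in input order.
    hub_idx: list[int] = [0]
    labels = np.zeros(m, dtype=int)
    for i in range(1, m):
        d = np.linalg.norm(pts[np.asarray(hub_idx)] - pts[i], axis=1)
        j = int(np.argmin(d))  # argmin takes the first (lowest) index on ties
        if d[j] <= T:
            labels[i] = j
        else:
            labels[i] = len(hub_idx)
            hub_idx.append(i)

    # Re-election / merge / reassignment until stable. The leader pass is
    # order-dependent and can seed several hubs inside one elongated cloud
    # (any cloud wider than T); two hubs within T of each other represent
    # the same cluster under the threshold semantics, so they are merged
    # before points are reassigned to their nearest hub.
    for _ in range(cfg.max_iter - 1):
        hub_idx = [
            _medoid(pts, np.flatnonzero(labels == lab)) for lab in range(len(hub_idx))
        ]
        labels, hub_idx = _merge_close_hubs(pts, labels, hub_idx, T)
        d = cdist(pts, pts[np.asarray(hub_idx)])
        new_labels = np.argmin(d, axis=1)  # ties -> lowest hub index
        # Drop clusters emptied by reassignment, preserving label order.
        used = np.unique(new_labels)
        if len(used) < len(hub_idx):
            remap = {old: new for new, old in enumerate(used)}
            new_labels = np.array([remap[l] for l in new_labels])
            hub_idx = [hub_idx[old] for old in used]
        if np.array_equal(new_labels, labels):
            labels = new_labels
            break
        labels = new_labels

    # Merge undersized clusters into the cluster of the nearest other hub.
    if cfg.min_cluster_size > 1 and len(hub_idx) > 1:
        changed = True
        while changed and len(hub_idx) > 1:
            changed = False
            sizes = np.bincount(labels, minlength=len(hub_idx))
            small = [lab for lab in range(len(hub_idx)) if sizes[lab] < cfg.min_cluster_size]
            if not small:
                break
            lab = small[0]
            hubs_arr = pts[np.asarray(hub_idx)]
            d = np.linalg.norm(hubs_arr - hubs_arr[lab], axis=1)
            d[lab] = np.inf
            target = int(np.argmin(d))
            labels[labels == lab] = target
            used = np.unique(labels)
            remap = {old: new for new, old in enumerate(used)}
            labels = np.array([remap[l] for l in labels])
            hub_idx = [hub_idx[old] for old in used]
            changed = True
        # Re-elect hubs once after merging so hubs remain medoids.
        hub_idx = [
            _medoid(pts, np.flatnonzero(labels == lab)) for lab in range(len(hub_idx))
        ]

    hubs = {lab: table.gene_ids[hub_idx[lab]] for lab in range(len(hub_idx))}
    return Partition(
        {g: int(lab) for g, lab in zip(table.gene_ids, labels)}, hubs=hubs
    )
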