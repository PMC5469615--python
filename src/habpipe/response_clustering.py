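"""Unbiased classification of response profiles into Type I / Type II.

Standardized (z-scored) response profiles are reduced with PCA; the first
three principal components define a Euclidean distance between units, and
complete-linkage agglomeration builds the cluster hierarchy, cut at k = 2
by default.  Clusters are then sorted in descending order of their total
Z-score in the post-reward evaluation window (5-10 s from cue onset), so
cluster 1 is the one with the strongest post-inhibitory rebound: the
"inhibition-then-excitation" Type II profile.  The other cluster shows
pure inhibition (Type I).

Profiles are mean-centered per timepoint but not re-scaled before PCA —
inputs are already standard scores, and double-scaling would distort the
between-unit geometry.  The procedure contains no randomness and is
invariant to the input order of units.
"""

from __future__ import annotations

import logging
from dataclasses import dataclass

import numpy as np
from scipy.cluster.hierarchy import dendrogram, fcluster, linkage
from scipy.spatial.distance import pdist
from sklearn.decomposition import PCA

log = logging.getLogger("habpipe")

__all__ = ["ClusterModel", "cluster_profiles", "assign_type", "ORDERING_WINDOW"]

#: Window (s from cue onset) whose total Z orders the clusters.
ORDERING_WINDOW = (5.0, 10.0)


@dataclass
class ClusterModel:
    """PCA + complete-linkage clustering of units x timepoints profiles.

    ``labels`` are 1-based cluster ids ordered so cluster 1 has the highest
    ``ordering_stat`` (mean total Z in the ordering window, descending).
    """

    profiles: np.ndarray
    time_axis: np.ndarray
    pc_scores: np.ndarray
    linkage: np.ndarray
    labels: np.ndarray
    ordering_stat: np.ndarray
    k: int
    ordering_window: tuple[float, float]
    rank_flagged: bool = False

    def cluster_sizes(self) -> dict[int, int]:
        return {int(c): int(np.sum(self.labels == c)) for c in range(1, self.k + 1)}

    def to_newick(self) -> str:
        """Newick-like text export of the dendrogram (leaf ids = unit indices)."""
        n = self.profiles.shape[0]
        nodes: dict[int, str] = {i: str(i) for i in range(n)}
        heights = {i: 0.0 for i in range(n)}
        for i, (a, b, h, _) in enumerate(self.linkage):
            a, b = int(a), int(b)
            la = h - heights[a]
            lb = h - heights[b]
            nodes[n + i] = f"({nodes[a]}:{la:.6g},{nodes[b]}:{lb:.6g})"
            heights[n + i] = h
        return nodes[n + len(self.linkage) - 1] + ";"


def cluster_profiles(
    profiles: np.ndarray,
    time_axis: np.ndarray,
    k: int = 2,
    n_components: int = 3,
    ordering_window: tuple[float, float] = ORDERING_WINDOW,
) -> ClusterModel:
    """Cluster units x timepoints standardized profiles.

    Mean-center per timepoint, project on the first ``n_components``
    principal components (3), build a complete-linkage tree on the
    Euclidean distances between score vectors, cut to ``k`` clusters, and
    relabel clusters by descending total Z over ``ordering_window``.
    """
    X = np.atleast_2d(np.asarray(profiles, dtype=float))
    time_axis = np.asarray(time_axis, dtype=float)
    n_units, n_t = X.shape
    if n_t != time_axis.size:
        raise ValueError("profiles and time_axis disagree on timepoints")
    if n_t < 3:
        raise ValueError("need at least 3 timepoints")
    if k > n_units:
        raise ValueError(f"cannot form k={k} clusters from {n_units} units")
    rank = np.linalg.matrix_rank(X - X.mean(axis=0))
    n_comp = min(n_components, rank, n_units - 1) if rank else 1
    flagged = n_comp < n_components
    if flagged:
        log.warning("profile rank %d < %d; using %d components", rank, n_components, n_comp)
    scores = PCA(n_components=n_comp, svd_solver="full").fit_transform(X)
    Z = linkage(pdist(scores, metric="euclidean"), method="complete")
    raw = fcluster(Z, t=k, criterion="maxclust")
    # total Z in the ordering window, per cluster (mean profile summed over bins)
    i0 = int(np.searchsorted(time_axis, ordering_window[0] - 1e-9))
    i1 = int(np.searchsorted(time_axis, ordering_window[1] - 1e-9))
    stats, sizes = [], []
    ids = sorted(set(raw.tolist()))
    for c in ids:
        members = X[raw == c]
        stats.append(float(members.mean(axis=0)[i0:i1].sum()))
        sizes.append(int(members.shape[0]))
    # descending total Z; ties broken deterministically by cluster size then id
    order = sorted(range(len(ids)), key=lambda i: (-stats[i], -sizes[i], ids[i]))
    if len(set(np.round(stats, 12))) < len(stats):
        log.warning("ordering-stat tie between clusters; broke tie by cluster size")
    relabel = {ids[j]: rank_i + 1 for rank_i, j in enumerate(order)}
    labels = np.array([relabel[c] for c in raw])
    ordering_stat = np.array([stats[j] for j in order])
    return ClusterModel(
        X, time_axis, scores, Z, labels, ordering_stat, k, ordering_window, rank_flagged=flagged
    )


def assign_type(model: ClusterModel) -> np.ndarray:
    """Per-unit 'typeI' / 'typeII' assignment from a k=2 model.

    The cluster with the higher post-reward (5-10 s) total Z is the
    rebounding Type II; the other is the pure-inhibition Type I.  A
    low-contrast split (both ordering stats nearly equal) is logged.
    """
    if model.k != 2:
        raise ValueError("type assignment requires k=2")
    if abs(model.ordering_stat[0] - model.ordering_stat[1]) < 1e-9:
        log.warning("type assignment is low-contrast: ordering stats nearly tie")
    return np.where(model.labels == 1, "typeII", "typeI")
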