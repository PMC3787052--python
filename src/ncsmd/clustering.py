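"""Pairwise-RMSD conformational clustering of trajectory frames.

Frames sampled every ``stride`` ps over the final ``window`` ns are compared
by superpose-then-RMSD over a fit set (the protein-core backbone in the
NCS-1 protocol), the resulting distance matrix is clustered hierarchically
with complete linkage, and the dendrogram is cut at a fixed height (2 Å in
the NCS-1 protocol). Complete linkage is used deliberately: cutting it at
height h certifies that every intra-cluster pairwise RMSD is ≤ h, which is
what makes "frames in one cluster belong to one conformational state" a
defensible statement. Each cluster is summarized by its medoid — the member
minimizing the summed RMSD to all other members.
"""

from __future__ import annotations

from dataclasses import dataclass
from typing import Sequence

import numpy as np
from scipy.cluster.hierarchy import fcluster, linkage as scipy_linkage
from scipy.spatial.distance import squareform

from .geometry import kabsch
from .structures import AtomIndexSet, Trajectory

__all__ = ["ClusterAssignment", "rmsd_matrix", "cluster", "representative"]


@dataclass
class ClusterAssignment:
    """Frame-to-cluster assignment with populations and representatives.

    Cluster ids are 1-based and ordered by population (descending); ties are
    broken by the smallest member frame index. ``labels[k]`` refers to the
    k-th row/column of the clustered matrix; ``representative[c]`` is the
    medoid row index of cluster ``c``.
    """

    labels: np.ndarray
    populations: dict[int, int]
    representative: dict[int, int]
    cutoff: float
    linkage: str

    @property
    def n_clusters(self) -> int:
        return len(self.populations)

    def members(self, cluster_id: int) -> np.ndarray:
        return np.nonzero(self.labels == cluster_id)[0]


def rmsd_matrix(
    traj: Trajectory,
    fit_set: AtomIndexSet,
    stride: float | None = None,
    window: float | None = None,
) -> np.ndarray:
    """Symmetric matrix of pairwise superpose-then-RMSD (Å) between sampled
    frames, over the fit-set atoms. Row k corresponds to
    ``traj.sample_indices(stride, window)[k]``."""
    frame_idx = traj.sample_indices(stride_ps=stride, window_ns=window)
    if frame_idx.size < 2:
        raise ValueError("need at least 2 sampled frames for an RMSD matrix")
    coords = traj.frames[np.ix_(frame_idx, fit_set.indices)]
    n = len(frame_idx)
    out = np.zeros((n, n))
    for a in range(n):
        for b in range(a + 1, n):
            try:
                _, _, r = kabsch(coords[a], coords[b])
            except ValueError as exc:
                raise ValueError(f"frame pair ({frame_idx[a]}, {frame_idx[b]}): {exc}") from exc
            out[a, b] = out[b, a] = r
    return out


def representative(matrix: np.ndarray, members: Sequence[int]) -> int:
    """Medoid of a cluster: the member minimizing the summed distance to all
    other members; ties go to the smallest frame index."""
    members = np.asarray(sorted(members), dtype=int)
    if members.size == 0:
        raise ValueError("empty member list")
    sub = matrix[np.ix_(members, members)]
    sums = sub.sum(axis=1)
    return int(members[int(np.argmin(sums))])  # argmin takes first (smallest index) on ties


def cluster(matrix: np.ndarray, cutoff: float, linkage: str = "complete") -> ClusterAssignment:
    """Cut a complete-linkage dendrogram of the RMSD matrix at ``cutoff`` Å.

    Returns cluster labels renumbered by population (1 = most populated,
    ties broken by smallest member frame index), cluster populations, and
    medoid representatives.
    """
    matrix = np.asarray(matrix, dtype=float)
    if matrix.ndim != 2 or matrix.shape[0] != matrix.shape[1]:
        raise ValueError(f"matrix must be square, got {matrix.shape}")
    if np.any(np.isnan(matrix)):
        raise ValueError("NaN in distance matrix")
    if linkage != "complete":
        raise ValueError(f"unsupported linkage {linkage!r}; only 'complete' is provided")
    n = matrix.shape[0]
    if n == 1:
        raw = np.array([1])
    else:
        condensed = squareform(matrix, checks=True)
        tree = scipy_linkage(condensed, method="complete")
        raw = fcluster(tree, t=cutoff, criterion="distance")
    # renumber by (population desc, smallest member frame index)
    order = sorted(
        set(raw),
        key=lambda c: (-int(np.sum(raw == c)), int(np.nonzero(raw == c)[0][0])),
    )
    relabel = {old: new for new, old in enumerate(order, start=1)}
    labels = np.array([relabel[c] for c in raw])
    populations = {c: int(np.sum(labels == c)) for c in range(1, len(order) + 1)}
    reps = {
        c: representative(matrix, np.nonzero(labels == c)[0]) for c in populations
    }
    return ClusterAssignment(
        labels=labels,
        populations=populations,
        representative=reps,
        cutoff=float(cutoff),
        linkage=linkage,
    )
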