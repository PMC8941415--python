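"""Spatial cohesion statistics: epsilon-graph clustering, the cohesion
parameter C, the cluster count Nc, and alternate cohesion measures.

A cluster is a maximal set of agents in which every member is *strictly less
than* ``epsilon`` away from at least one other member — the chained
(connected-component) form of density-based clustering; singletons form
their own clusters.  The cohesion parameter C is the fraction of the group
in the largest cluster, averaged over post-burn-in sample times (replicate
averaging happens in :mod:`stochflock.experiments_io`).  C = 1 means the
group never fragmented.
"""

from __future__ import annotations

from dataclasses import dataclass
from typing import Optional

import numpy as np
import pandas as pd
from scipy.sparse import csr_matrix
from scipy.sparse.csgraph import connected_components
from scipy.spatial import ConvexHull, QhullError, cKDTree
from scipy.spatial.distance import pdist, squareform

from .simulator import Trajectory

__all__ = [
    "epsilon_clusters",
    "largest_cluster_fraction",
    "cluster_sizes",
    "cohesion_parameter",
    "alternate_metrics",
    "CohesionSummary",
]


def epsilon_clusters(positions: np.ndarray, epsilon: float) -> np.ndarray:
    """Label agents by connected component of the strict epsilon-graph.

    Two agents are joined when their distance is ``< epsilon`` (strict: a
    pair exactly epsilon apart is disconnected).  Labels are 0-based,
    contiguous, and ordered by first occurrence, so the output is a
    deterministic function of the positions.

    Parameters
    ----------
    positions : ndarray, shape (N, 2)
    epsilon : float, > 0

    Returns
    -------
    ndarray of int, shape (N,)
        Cluster label of each agent, in ``0..Nc-1``.
    """
    if epsilon <= 0:
        raise ValueError("epsilon must be > 0")
    positions = np.asarray(positions, dtype=float)
    n = positions.shape[0]
    if n == 0:
        return np.empty(0, dtype=int)
    if n == 1:
        return np.zeros(1, dtype=int)
    adj = squareform(pdist(positions)) < epsilon
    np.fill_diagonal(adj, False)
    _, raw = connected_components(csr_matrix(adj), directed=False)
    # Relabel by first occurrence for a canonical order.
    remap: dict = {}
    labels = np.empty(n, dtype=int)
    for i, lab in enumerate(raw):
        if lab not in remap:
            remap[lab] = len(remap)
        labels[i] = remap[lab]
    return labels


def cluster_sizes(labels: np.ndarray) -> np.ndarray:
    """Sizes of the clusters given per-agent labels."""
    return np.bincount(np.asarray(labels, dtype=int))


def largest_cluster_fraction(labels: np.ndarray, n: Optional[int] = None) -> float:
    """Size of the largest cluster divided by the group size."""
    labels = np.asarray(labels, dtype=int)
    if n is None:
        n = labels.size
    if n <= 0:
        raise ValueError("group size must be positive")
    return float(cluster_sizes(labels).max()) / float(n)


@dataclass
class CohesionSummary:
    """Time-averaged cohesion of one realization.

    ``C`` is the mean largest-cluster fraction over post-burn-in samples and
    ``Nc_mean`` the mean cluster count; ``per_time`` holds the underlying
    time series.
    """

    C: float
    Nc_mean: float
    per_time: pd.DataFrame  # columns: time, largest_fraction, n_clusters
    epsilon: float


def cohesion_parameter(
    traj: Trajectory,
    epsilon: Optional[float] = None,
    burn_fraction: float = 0.2,
) -> CohesionSummary:
    """Cohesion parameter C and mean cluster count of one trajectory.

    Samples earlier than ``burn_fraction * t_end`` are discarded before
    averaging (``t_end`` taken as the last sample time).

    Raises
    ------
    ValueError
        If ``burn_fraction >= 1`` or no sample survives the burn-in.
    """
    if burn_fraction >= 1:
        raise ValueError("burn_fraction must be < 1")
    if epsilon is None:
        if traj.params is None:
            raise ValueError("epsilon not given and trajectory has no params")
        epsilon = traj.params.epsilon
    t_end = float(traj.sample_times[-1])
    keep = traj.sample_times >= burn_fraction * t_end - 1e-9
    if not keep.any():
        raise ValueError("no post-burn-in samples")
    n = traj.n_agents
    times, fracs, counts = [], [], []
    for i in np.flatnonzero(keep):
        labels = epsilon_clusters(traj.positions[i], epsilon)
        times.append(float(traj.sample_times[i]))
        fracs.append(largest_cluster_fraction(labels, n))
        counts.append(int(labels.max()) + 1)
    per_time = pd.DataFrame(
        {"time": times, "largest_fraction": fracs, "n_clusters": counts}
    )
    return CohesionSummary(
        C=float(np.mean(fracs)),
        Nc_mean=float(np.mean(counts)),
        per_time=per_time,
        epsilon=float(epsilon),
    )


def alternate_metrics(positions: np.ndarray):
    """Alternate cohesion measures for one snapshot.

    Returns
    -------
    (nnd, hull_area, barycenter_dist) : tuple of float
        Mean nearest-neighbour distance, convex-hull area (0 when fewer
        than 3 agents or the points are collinear), and mean distance to
        the group barycenter.
    """
    positions = np.asarray(positions, dtype=float)
    n = positions.shape[0]
    if n < 2:
        return 0.0, 0.0, 0.0
    tree = cKDTree(positions)
    dists, _ = tree.query(positions, k=2)
    nnd = float(np.mean(dists[:, 1]))
    hull_area = 0.0
    if n >= 3:
        try:
            hull_area = float(ConvexHull(positions).volume)  # 2-D: area
        except QhullError:
            hull_area = 0.0  # degenerate (collinear/coincident) point set
    bary = positions.mean(axis=0)
    bary_dist = float(np.mean(np.hypot(*(positions - bary).T)))
    return nnd, hull_area, bary_dist
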