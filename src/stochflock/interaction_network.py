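"""Windowed attraction-interaction networks and the network parameter Np.

Attraction events define a directed graph: an edge i -> j is present in a
time window when agent i performed an attraction interaction with j as a
partner during that window.  The graph is directed because each agent
chooses its partners randomly and asynchronously.  From the adjacency matrix
A the reachability matrix (transitive closure) is computed; *sub-groups*
are the classes of mutual reachability (strongly connected components), and
Np is the size of the largest sub-group normalized by the group size,
averaged over disjoint consecutive windows of length ``t_w = epsilon / s0``
— the time an agent needs to travel one cluster scale at cruising speed.
"""

from __future__ import annotations

import bisect
from dataclasses import dataclass
from typing import List, Sequence

import numpy as np
from scipy.sparse import csr_matrix
from scipy.sparse.csgraph import shortest_path

from .model_core import ModelParams
from .simulator import InteractionEvent

__all__ = [
    "compute_time_window",
    "build_adjacency",
    "reachability",
    "strongly_connected_subgroups",
    "window_graph",
    "network_parameter",
    "WindowGraph",
    "NetworkSummary",
]


def compute_time_window(epsilon: float, s0: float) -> float:
    """Analysis window t_w = epsilon / s0 (cluster scale over cruise speed)."""
    if s0 <= 0:
        raise ValueError("s0 must be > 0")
    if epsilon <= 0:
        raise ValueError("epsilon must be > 0")
    return epsilon / s0


def build_adjacency(
    events: Sequence[InteractionEvent], t_start: float, t_w: float, N: int
) -> np.ndarray:
    """Binary directed adjacency of attraction interactions in one window.

    ``A[i, j] = 1`` iff some attraction event with focal ``i`` and ``j``
    among its partners has time in ``[t_start, t_start + t_w)``.  Alignment
    and spontaneous-turn events are ignored; repeated edges collapse to 1;
    the diagonal is zero.
    """
    A = np.zeros((N, N), dtype=np.int8)
    t_stop = t_start + t_w
    for ev in events:
        if ev.t < t_start or ev.t >= t_stop or ev.etype != "attract":
            continue
        if not (0 <= ev.focal < N):
            raise ValueError(f"focal id {ev.focal} outside 0..{N - 1}")
        for j in ev.partners:
            if not (0 <= j < N):
                raise ValueError(f"partner id {j} outside 0..{N - 1}")
            if j != ev.focal:
                A[ev.focal, j] = 1
    return A


def reachability(A: np.ndarray) -> np.ndarray:
    """Transitive closure of a directed adjacency matrix.

    ``reach[i, j] = 1`` iff a directed path of length >= 1 exists from i to
    j; the diagonal is set to 1 by convention (every node reaches itself),
    so singleton sub-groups are well defined.
    """
    A = np.asarray(A)
    if A.ndim != 2 or A.shape[0] != A.shape[1]:
        raise ValueError("adjacency must be a square matrix")
    n = A.shape[0]
    if n == 0:
        return np.zeros((0, 0), dtype=np.int8)
    dist = shortest_path(csr_matrix(A != 0), method="D", directed=True, unweighted=True)
    reach = np.isfinite(dist).astype(np.int8)
    np.fill_diagonal(reach, 1)
    return reach


def strongly_connected_subgroups(reach: np.ndarray) -> List[List[int]]:
    """Partition nodes into classes of mutual reachability.

    Two nodes are in the same sub-group iff each reaches the other.  The
    partition is returned as lists of sorted ids, ordered by smallest
    member; nodes reachable from nobody form singleton classes.
    """
    reach = np.asarray(reach)
    n = reach.shape[0]
    mutual = (reach != 0) & (reach.T != 0)
    np.fill_diagonal(mutual, True)
    seen = np.zeros(n, dtype=bool)
    groups: List[List[int]] = []
    for i in range(n):
        if seen[i]:
            continue
        members = np.flatnonzero(mutual[i])
        seen[members] = True
        groups.append([int(m) for m in members])
    return groups


@dataclass
class WindowGraph:
    """Attraction network of one analysis window."""

    t_start: float
    t_end: float
    A: np.ndarray
    reach: np.ndarray
    subgroups: List[List[int]]
    largest_fraction: float


def window_graph(
    events: Sequence[InteractionEvent], t_start: float, t_w: float, N: int
) -> WindowGraph:
    """Build the full window analysis: adjacency, closure, sub-groups."""
    A = build_adjacency(events, t_start, t_w, N)
    reach = reachability(A)
    groups = strongly_connected_subgroups(reach)
    largest = max(len(g) for g in groups) / N
    return WindowGraph(
        t_start=t_start,
        t_end=t_start + t_w,
        A=A,
        reach=reach,
        subgroups=groups,
        largest_fraction=largest,
    )


@dataclass
class NetworkSummary:
    """Np of one realization with its per-window series."""

    Np: float
    t_w: float
    window_starts: np.ndarray
    largest_fractions: np.ndarray
    n_subgroups: np.ndarray

    def per_window_frame(self):
        import pandas as pd

        return pd.DataFrame(
            {
                "t_start": self.window_starts,
                "largest_fraction": self.largest_fractions,
                "n_subgroups": self.n_subgroups,
            }
        )


def network_parameter(
    events: Sequence[InteractionEvent],
    params: ModelParams,
    t_total: float,
    burn_fraction: float = 0.2,
) -> NetworkSummary:
    """Network parameter Np of one realization.

    The post-burn-in span ``[burn_fraction * t_total, t_total]`` is tiled
    into disjoint consecutive windows of length ``t_w = epsilon / s0``; Np
    is the mean over windows of the largest-sub-group fraction (replicate
    averaging happens in :mod:`stochflock.experiments_io`).

    Raises
    ------
    ValueError
        If the span holds no complete window.
    """
    t_w = compute_time_window(params.epsilon, params.s0)
    t_burn = burn_fraction * t_total
    n_windows = int((t_total - t_burn + 1e-9) // t_w)
    if n_windows < 1:
        raise ValueError("no complete analysis window after burn-in")
    events = sorted(events, key=lambda ev: ev.t)
    attract = [ev for ev in events if ev.etype == "attract"]
    times = [ev.t for ev in attract]
    starts = np.array([t_burn + w * t_w for w in range(n_windows)])
    fracs = np.empty(n_windows)
    n_groups = np.empty(n_windows, dtype=int)
    for w, t0 in enumerate(starts):
        lo = bisect.bisect_left(times, t0)
        hi = bisect.bisect_left(times, t0 + t_w)
        wg = window_graph(attract[lo:hi], t0, t_w, params.N)
        fracs[w] = wg.largest_fraction
        n_groups[w] = len(wg.subgroups)
    return NetworkSummary(
        Np=float(fracs.mean()),
        t_w=t_w,
        window_starts=starts,
        largest_fractions=fracs,
        n_subgroups=n_groups,
    )
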