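"""Planar geometry, visual perception and neighbour-choice primitives.

These are the building blocks shared by the event-driven simulator and the
analysis layers: angle wrapping, visual-field filtering, topological
(distance-ranked) neighbourhoods, uniform random choice of interaction
partners, and circular means of headings.

Agents live in an unbounded two-dimensional plane.  Each agent carries a
position ``x``, a scalar speed ``s`` and a heading angle, with velocity
``s * e`` where ``e = (cos(heading), sin(heading))``.  Neighbourhoods are
*topological*: an agent perceives its ``K`` nearest visible neighbours by
distance rank, irrespective of metric distance, restricted to a visual
field of total angle ``fov`` centred on its heading.  From those ``K`` it
interacts with ``k`` chosen uniformly at random (``k = 1`` is the
stochastic pairwise rule; ``k = K`` is the Vicsek-like averaging rule).
"""

from __future__ import annotations

import math
from dataclasses import dataclass
from typing import Iterable, Sequence

import numpy as np

__all__ = [
    "TWO_PI",
    "UNDEFINED_ANGLE",
    "AgentState",
    "ModelParams",
    "wrap_angle",
    "visible_neighbours",
    "rank_topological",
    "choose_partners",
    "circular_mean",
]

TWO_PI = 2.0 * math.pi

#: Sentinel returned by :func:`circular_mean` when the resultant vector is
#: numerically zero (e.g. an antipodal pair of headings).  Callers decide the
#: fallback; the simulator keeps the current heading.
UNDEFINED_ANGLE = float("nan")

_RESULTANT_TOL = 1e-12


def wrap_angle(theta):
    """Wrap an angle (scalar or array) to the half-open interval (-pi, pi].

    Odd multiples of pi map to +pi, so e.g. ``3*pi -> pi`` and
    ``-pi -> pi``.

    Parameters
    ----------
    theta : float or array-like
        Angle(s) in radians.  Must be finite.

    Returns
    -------
    float or ndarray
        Equivalent angle(s) modulo 2*pi, in (-pi, pi].
    """
    arr = np.asarray(theta, dtype=float)
    if not np.all(np.isfinite(arr)):
        raise ValueError("wrap_angle requires finite input")
    wrapped = -((math.pi - arr) % TWO_PI - math.pi)
    if arr.ndim == 0:
        return float(wrapped)
    return wrapped


@dataclass(frozen=True)
class AgentState:
    """State of one agent at one instant.

    Attributes
    ----------
    id : int
        Agent index; in a group of ``N`` agents ids are ``0..N-1``.
    x : ndarray, shape (2,)
        Position (arbitrary length units).
    s : float
        Speed, >= 0 (length / time).
    heading : float
        Direction of motion in radians, wrapped to (-pi, pi].
    """

    id: int
    x: np.ndarray
    s: float
    heading: float

    def __post_init__(self):
        x = np.asarray(self.x, dtype=float)
        if x.shape != (2,):
            raise ValueError("position must be a 2-vector")
        if not (self.s >= 0):
            raise ValueError("speed must be non-negative")
        object.__setattr__(self, "x", x)
        object.__setattr__(self, "s", float(self.s))
        object.__setattr__(self, "heading", wrap_angle(self.heading))

    @property
    def e(self) -> np.ndarray:
        """Unit orientation vector (cos(heading), sin(heading))."""
        return np.array([math.cos(self.heading), math.sin(self.heading)])


@dataclass
class ModelParams:
    """Parameters of the agent-based model.

    The defaults define the standard study conditions used throughout the
    package (see docs/methods.md for the calibration rationale): unit
    desired speed, alignment at rate 1 and attraction at rate 0.7,
    spontaneous turns at rate 0.5 with enough angular variance for wanderers
    to re-orient towards the group, a 285-degree visual field (75-degree
    blind cone behind), cluster scale epsilon = 1.5, and short-range
    collision avoidance.

    Attributes
    ----------
    N : int
        Group size.
    K : int
        Perceived-neighbourhood size, ``1 <= K <= N - 1``.
    k : int
        Interacting-subset size, ``1 <= k <= K``.  ``k = 1`` gives the
        stochastic pairwise interaction; ``k = K`` the averaging one.
    r_p, r_c, r_s : float
        Per-agent rates (1/time) of alignment, attraction and spontaneous
        turning.  ``r_a`` is accepted as a synonym for the attraction rate
        ``r_c``.
    s0 : float
        Desired (cruising) speed.
    sigma_a2 : float
        Variance of the wrapped-normal turn-angle distribution (rad^2).
    sigma_s2 : float
        Variance of the truncated-normal speed distribution ((length/time)^2).
    fov : float
        Total visual-field angle in radians (default 285 degrees).
    d_c : float
        Collision-avoidance trigger distance.
    avoid_turn_rate : float
        Angular speed of the avoidance turn (rad/time).
    avoid_slow_factor : float
        Multiplicative speed reduction applied per avoidance update, in
        (0, 1].
    s_min, s_max : float
        Hard speed clamp bounds.
    epsilon : float
        Cluster-distance scale (also the attraction speed reference).
    minimal : bool
        Minimal point-particle variant: full visual field, no collision
        avoidance, speed pinned at ``s0``.
    """

    N: int = 30
    K: int = 10
    k: int = 1
    r_p: float = 1.0
    r_c: float = 0.7
    r_s: float = 0.5
    s0: float = 1.0
    sigma_a2: float = 0.6
    sigma_s2: float = 0.01
    fov: float = TWO_PI * (285.0 / 360.0)
    d_c: float = 0.2
    avoid_turn_rate: float = math.pi
    avoid_slow_factor: float = 0.5
    s_min: float = 0.1
    s_max: float = 2.0
    epsilon: float = 1.5
    minimal: bool = False

    def __post_init__(self):
        if self.minimal:
            # Point particles: omnidirectional perception, constant speed.
            self.fov = TWO_PI
            self.s_min = self.s0
            self.s_max = self.s0
            self.sigma_s2 = 0.0
        self.validate()

    def validate(self) -> None:
        if self.N < 1:
            raise ValueError("N must be >= 1")
        for name in ("r_p", "r_c", "r_s"):
            if getattr(self, name) < 0:
                raise ValueError(f"{name} must be >= 0")
        if self.N > 1:
            if not (1 <= self.k <= self.K <= self.N - 1):
                raise ValueError(
                    f"need 1 <= k <= K <= N-1, got k={self.k}, K={self.K}, "
                    f"N={self.N}"
                )
        if not (0 <= self.s_min <= self.s0 <= self.s_max):
            raise ValueError("need 0 <= s_min <= s0 <= s_max")
        if self.epsilon <= 0:
            raise ValueError("epsilon must be > 0")
        if not (0 < self.fov <= TWO_PI + 1e-12):
            raise ValueError("fov must lie in (0, 2*pi]")
        if self.sigma_a2 < 0 or self.sigma_s2 < 0:
            raise ValueError("variances must be >= 0")
        if not (0 < self.avoid_slow_factor <= 1):
            raise ValueError("avoid_slow_factor must lie in (0, 1]")
        if self.d_c < 0 or self.avoid_turn_rate < 0:
            raise ValueError("avoidance parameters must be >= 0")

    @property
    def r_a(self) -> float:
        """Synonym for the attraction rate ``r_c``."""
        return self.r_c

    @property
    def total_rate(self) -> float:
        """Total event rate Lambda = N * (r_p + r_c + r_s)."""
        return self.N * (self.r_p + self.r_c + self.r_s)


# ---------------------------------------------------------------------------
# Array kernels (used directly by the simulator for speed); the AgentState
# wrappers below are the reference public surface.
# ---------------------------------------------------------------------------

def visible_id_array(
    pos_f: np.ndarray,
    heading_f: float,
    pos_others: np.ndarray,
    ids: np.ndarray,
    fov: float,
) -> np.ndarray:
    """Ids of ``ids`` whose bearing from the focal agent lies within the
    visual field.  Agents at zero distance are always visible."""
    ids = np.asarray(ids, dtype=int)
    if ids.size == 0:
        return ids
    vec = np.asarray(pos_others, dtype=float) - np.asarray(pos_f, dtype=float)
    dist = np.hypot(vec[:, 0], vec[:, 1])
    rel = wrap_angle(np.arctan2(vec[:, 1], vec[:, 0]) - heading_f)
    mask = (np.abs(rel) <= fov / 2.0) | (dist == 0.0)
    return ids[mask]


def rank_id_array(
    pos_f: np.ndarray,
    pos_candidates: np.ndarray,
    ids: np.ndarray,
    K: int,
) -> np.ndarray:
    """The min(K, len(ids)) candidate ids sorted by ascending distance from
    the focal position; distance ties broken by ascending id."""
    ids = np.asarray(ids, dtype=int)
    if ids.size == 0:
        return ids
    vec = np.asarray(pos_candidates, dtype=float) - np.asarray(pos_f, dtype=float)
    dist = np.hypot(vec[:, 0], vec[:, 1])
    order = np.lexsort((ids, dist))
    return ids[order][: int(K)]


# ---------------------------------------------------------------------------
# Public operations on AgentState objects
# ---------------------------------------------------------------------------

def visible_neighbours(
    focal: AgentState, others: Sequence[AgentState], fov: float
) -> set:
    """Return the set of ids of ``others`` inside the focal visual field.

    An agent j is visible when the absolute bearing
    ``|wrap_angle(atan2(x_j - x_f) - heading_f)|`` is at most ``fov / 2``;
    agents at zero distance from the focal agent are always visible.
    ``others`` must not contain the focal agent itself.
    """
    if not others:
        return set()
    pos = np.array([o.x for o in others])
    ids = np.array([o.id for o in others], dtype=int)
    vis = visible_id_array(focal.x, focal.heading, pos, ids, fov)
    return {int(i) for i in vis}


def rank_topological(
    focal: AgentState,
    visible: Iterable[int],
    states: Sequence[AgentState],
    K: int,
) -> list:
    """Rank the visible agents by distance from the focal agent.

    Returns the min(K, |visible|) visible ids sorted by ascending Euclidean
    distance, ties broken by ascending id (deterministic).  May return fewer
    than ``K`` ids, possibly none.
    """
    if K < 1:
        raise ValueError("K must be >= 1")
    visible = set(visible)
    cand = [st for st in states if st.id in visible]
    if not cand:
        return []
    pos = np.array([st.x for st in cand])
    ids = np.array([st.id for st in cand], dtype=int)
    ranked = rank_id_array(focal.x, pos, ids, K)
    return [int(i) for i in ranked]


def choose_partners(ranked: Sequence[int], k: int, rng: np.random.Generator):
    """Uniform sample without replacement of min(k, len(ranked)) ids.

    Returns a sorted integer array (a set of ids).  An empty ``ranked`` list
    yields an empty selection.  With ``k >= len(ranked)`` the whole ranked
    set is returned and no random draw is consumed.
    """
    if k < 1:
        raise ValueError("k must be >= 1")
    ranked = np.asarray(list(ranked), dtype=int)
    m = min(int(k), ranked.size)
    if m == 0:
        return ranked[:0]
    if m == ranked.size:
        return np.sort(ranked)
    chosen = rng.choice(ranked, size=m, replace=False)
    return np.sort(chosen)


def circular_mean(headings) -> float:
    """Circular mean of a non-empty list of headings.

    Returns the angle of the vector sum of the unit vectors, or the
    :data:`UNDEFINED_ANGLE` sentinel (NaN) when the resultant length is
    below 1e-12 (e.g. two antipodal headings).
    """
    arr = np.atleast_1d(np.asarray(headings, dtype=float))
    if arr.size == 0:
        raise ValueError("circular_mean of empty list is undefined")
    C = np.cos(arr).sum()
    S = np.sin(arr).sum()
    if math.hypot(C, S) < _RESULTANT_TOL:
        return UNDEFINED_ANGLE
    return wrap_angle(math.atan2(S, C))
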