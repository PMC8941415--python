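"""Continuous-time, asynchronous, event-driven engine for the agent-based model.

Behavioural events (alignment, attraction, spontaneous turn) occur one agent
at a time, at exponentially distributed waiting times, with type probabilities
proportional to the rates ``r_p``, ``r_c``, ``r_s`` — a global Gillespie
construction with total rate ``Lambda = N * (r_p + r_c + r_s)``, equivalent to
independent per-agent exponential clocks.  Between events every agent moves
ballistically (``dx/dt = s * e``) in micro-steps during which short-range
collision avoidance acts as a continuous control (turning away from the
nearest offender and slowing down).  The minimal point-particle variant turns
avoidance off, fixes the speed at ``s0`` and perceives omnidirectionally.

The four behavioural rules:

(i)   alignment at rate ``r_p``: copy the heading and speed of one randomly
      chosen neighbour (``k = 1``), or adopt the circular-mean heading and
      mean speed of ``k`` neighbours;
(ii)  attraction at rate ``r_c``: head towards the centroid of the chosen
      neighbours, with speed growing linearly with distance,
      ``s = clamp(s0 * d / epsilon, s_min, s_max)``;
(iii) spontaneous turn at rate ``r_s``: redraw the heading from a wrapped
      normal centred on the current heading (variance ``sigma_a2``) and the
      speed from a truncated normal around ``s0`` (variance ``sigma_s2``);
(iv)  collision avoidance within distance ``d_c``: rotate away from the
      nearest offender at ``avoid_turn_rate`` and multiply the speed by
      ``avoid_slow_factor`` per micro-step.
"""

from __future__ import annotations

import math
from dataclasses import dataclass, replace
from typing import List, Optional, Sequence, Tuple

import numpy as np

from .model_core import (
    AgentState,
    ModelParams,
    UNDEFINED_ANGLE,
    choose_partners,
    circular_mean,
    rank_id_array,
    visible_id_array,
    wrap_angle,
)

__all__ = [
    "InteractionEvent",
    "Trajectory",
    "sample_next_event",
    "apply_alignment",
    "apply_attraction",
    "apply_spontaneous_turn",
    "apply_collision_avoidance",
    "advance_positions",
    "run_simulation",
    "micro_step_length",
]

_COINCIDENT_TOL = 1e-9


@dataclass(frozen=True)
class InteractionEvent:
    """One behavioural event: who did what, with whom, when.

    ``partners`` is a sorted tuple of agent ids; it is empty for spontaneous
    turns and for alignment/attraction events that found no visible
    neighbour (the interaction failed but is still logged).
    """

    t: float
    focal: int
    etype: str  # "align" | "attract" | "turn"
    partners: Tuple[int, ...] = ()


@dataclass
class Trajectory:
    """Time-sampled snapshots of all agent states plus the event log.

    Snapshots are stored as arrays indexed ``[sample, agent]``; use
    :meth:`states_at` for an ``AgentState`` view of one snapshot.
    """

    sample_times: np.ndarray  # (T,)
    positions: np.ndarray     # (T, N, 2)
    speeds: np.ndarray        # (T, N)
    headings: np.ndarray      # (T, N)
    events: List[InteractionEvent]
    params: Optional[ModelParams]
    seed: Optional[int] = None

    @property
    def n_agents(self) -> int:
        return self.positions.shape[1]

    @property
    def n_samples(self) -> int:
        return self.positions.shape[0]

    def states_at(self, i: int) -> List[AgentState]:
        """AgentState list for snapshot index ``i``."""
        return [
            AgentState(
                id=j,
                x=self.positions[i, j],
                s=float(self.speeds[i, j]),
                heading=float(self.headings[i, j]),
            )
            for j in range(self.n_agents)
        ]


def micro_step_length(params: ModelParams) -> float:
    """Ballistic micro-step used between events.

    Small enough that an agent travels well under the cluster scale per
    step: ``min(0.01, epsilon / (10 * s_max))``.
    """
    return min(0.01, params.epsilon / (10.0 * params.s_max))


def sample_next_event(
    params: ModelParams, rng: np.random.Generator
) -> Tuple[float, int, str]:
    """Draw the next event: waiting time, focal agent and event type.

    The waiting time is Exponential(Lambda) with
    ``Lambda = N * (r_p + r_c + r_s)``; the focal agent is uniform over the
    group; the type is align/attract/turn with probabilities proportional to
    ``r_p``, ``r_c``, ``r_s``.
    """
    total = params.r_p + params.r_c + params.r_s
    lam = params.N * total
    if lam <= 0:
        raise ValueError("total event rate is zero: no dynamics")
    dt = float(rng.exponential(1.0 / lam))
    focal = int(rng.integers(params.N))
    u = float(rng.random())
    p_align = params.r_p / total
    p_attract = params.r_c / total
    if u < p_align:
        etype = "align"
    elif u < p_align + p_attract:
        etype = "attract"
    else:
        etype = "turn"
    return dt, focal, etype


# ---------------------------------------------------------------------------
# Behavioural kernels (array level)
# ---------------------------------------------------------------------------

def _alignment_kernel(
    focal: int,
    partners: np.ndarray,
    speeds: np.ndarray,
    headings: np.ndarray,
    params: ModelParams,
) -> Tuple[float, float]:
    """New (heading, speed) of the focal agent after an alignment event."""
    if partners.size == 0:
        return float(headings[focal]), float(speeds[focal])
    if partners.size == 1:
        j = int(partners[0])
        return float(headings[j]), float(speeds[j])
    mean_h = circular_mean(headings[partners])
    if math.isnan(mean_h):
        mean_h = float(headings[focal])
    mean_s = float(np.mean(speeds[partners]))
    mean_s = min(max(mean_s, params.s_min), params.s_max)
    return mean_h, mean_s


def _attraction_kernel(
    focal: int,
    partners: np.ndarray,
    positions: np.ndarray,
    speeds: np.ndarray,
    headings: np.ndarray,
    params: ModelParams,
) -> Tuple[float, float]:
    """New (heading, speed) of the focal agent after an attraction event.

    The agent heads towards the partner centroid with speed proportional to
    its distance from it (reference scale ``epsilon``), clamped to the speed
    bounds.  Sitting exactly on the centroid keeps the heading and resets
    the speed to ``s0``.
    """
    if partners.size == 0:
        return float(headings[focal]), float(speeds[focal])
    centroid = positions[partners].mean(axis=0)
    delta = centroid - positions[focal]
    d = float(np.hypot(delta[0], delta[1]))
    if d <= _COINCIDENT_TOL:
        return float(headings[focal]), params.s0
    heading = math.atan2(delta[1], delta[0])
    speed = params.s0 * d / params.epsilon
    speed = min(max(speed, params.s_min), params.s_max)
    return wrap_angle(heading), speed


def _spontaneous_kernel(
    heading: float, params: ModelParams, rng: np.random.Generator
) -> Tuple[float, float]:
    """New (heading, speed) after a spontaneous turn."""
    new_heading = wrap_angle(heading + rng.normal(0.0, math.sqrt(params.sigma_a2)))
    if params.minimal or params.sigma_s2 == 0.0:
        return new_heading, params.s0
    sd = math.sqrt(params.sigma_s2)
    for _ in range(1000):
        s = rng.normal(params.s0, sd)
        if params.s_min <= s <= params.s_max:
            return new_heading, float(s)
    # Pathologically narrow bounds: fall back to the clamped draw.
    return new_heading, min(max(s, params.s_min), params.s_max)


def _wrap(arr: np.ndarray) -> np.ndarray:
    """Fast array wrap to (-pi, pi] without the finiteness check of
    :func:`stochflock.model_core.wrap_angle` (inputs are internal)."""
    return -((math.pi - arr) % (2.0 * math.pi) - math.pi)


def _avoidance_kernel(
    positions: np.ndarray,
    speeds: np.ndarray,
    headings: np.ndarray,
    params: ModelParams,
    dt: float,
) -> None:
    """In-place collision-avoidance update for one micro-step.

    Every agent with at least one other agent closer than ``d_c`` rotates
    away from the nearest offender by at most ``avoid_turn_rate * dt``
    (never past facing directly away) and has its speed multiplied by
    ``avoid_slow_factor`` (clamped below by ``s_min``).  Coincident pairs
    rotate counter-clockwise.
    """
    n = positions.shape[0]
    if n < 2 or params.d_c <= 0:
        return
    diff = positions[:, None, :] - positions[None, :, :]
    dist = np.hypot(diff[:, :, 0], diff[:, :, 1])
    np.fill_diagonal(dist, np.inf)
    nearest = dist.argmin(axis=1)
    dmin = dist[np.arange(n), nearest]
    offenders = np.flatnonzero(dmin < params.d_c)
    if offenders.size == 0:
        return
    max_turn = params.avoid_turn_rate * dt
    j = nearest[offenders]
    dx = positions[offenders] - positions[j]
    away = np.arctan2(dx[:, 1], dx[:, 0])
    delta = _wrap(away - headings[offenders])
    turn = np.sign(delta) * np.minimum(max_turn, np.abs(delta))
    # Coincident pairs: away direction undefined; counter-clockwise turn.
    turn[dmin[offenders] <= _COINCIDENT_TOL] = max_turn
    headings[offenders] = _wrap(headings[offenders] + turn)
    speeds[offenders] = np.maximum(
        speeds[offenders] * params.avoid_slow_factor, params.s_min
    )


# ---------------------------------------------------------------------------
# Public operations on AgentState objects
# ---------------------------------------------------------------------------

def _pack(states: Sequence[AgentState]):
    order = sorted(states, key=lambda st: st.id)
    positions = np.array([st.x for st in order])
    speeds = np.array([st.s for st in order])
    headings = np.array([st.heading for st in order])
    return order, positions, speeds, headings


def apply_alignment(
    focal: int,
    partners: Sequence[int],
    states: Sequence[AgentState],
    params: ModelParams,
) -> AgentState:
    """Alignment rule: copy (k = 1) or average (k > 1) partner velocities.

    With a single partner the focal heading and speed become exactly the
    partner's.  With several, the heading becomes the circular mean of the
    partner headings (kept unchanged if the mean is undefined) and the speed
    the arithmetic mean of partner speeds clamped to the speed bounds.
    Empty ``partners`` is a no-op.
    """
    order, _, speeds, headings = _pack(states)
    idx = np.asarray(sorted(partners), dtype=int)
    h, s = _alignment_kernel(focal, idx, speeds, headings, params)
    st = order[focal]
    return replace(st, heading=h, s=s)


def apply_attraction(
    focal: int,
    partners: Sequence[int],
    states: Sequence[AgentState],
    params: ModelParams,
) -> AgentState:
    """Attraction rule: head for the partner centroid, faster when farther."""
    order, positions, speeds, headings = _pack(states)
    idx = np.asarray(sorted(partners), dtype=int)
    h, s = _attraction_kernel(focal, idx, positions, speeds, headings, params)
    st = order[focal]
    return replace(st, heading=h, s=s)


def apply_spontaneous_turn(
    state: AgentState, params: ModelParams, rng: np.random.Generator
) -> AgentState:
    """Spontaneous turn: wrapped-normal heading, truncated-normal speed."""
    h, s = _spontaneous_kernel(state.heading, params, rng)
    return replace(state, heading=h, s=s)


def apply_collision_avoidance(
    states: Sequence[AgentState], params: ModelParams, dt: float
) -> List[AgentState]:
    """One micro-step of the collision-avoidance control for all agents."""
    if dt <= 0:
        raise ValueError("dt must be > 0")
    order, positions, speeds, headings = _pack(states)
    _avoidance_kernel(positions, speeds, headings, params, dt)
    return [
        replace(st, heading=float(headings[i]), s=float(speeds[i]))
        for i, st in enumerate(order)
    ]


def advance_positions(
    states: Sequence[AgentState], dt: float
) -> List[AgentState]:
    """Ballistic motion: ``x <- x + s * e * dt``; speeds/headings untouched."""
    if dt < 0:
        raise ValueError("dt must be >= 0")
    return [
        replace(st, x=st.x + st.s * st.e * dt)
        for st in states
    ]


# ---------------------------------------------------------------------------
# Main event loop
# ---------------------------------------------------------------------------

def initial_condition(
    params: ModelParams, rng: np.random.Generator
) -> Tuple[np.ndarray, np.ndarray, np.ndarray]:
    """Default initial condition: positions uniform in a disc of radius
    ``epsilon * sqrt(N)`` (density independent of N), headings uniform in
    (-pi, pi], speeds at ``s0``."""
    n = params.N
    radius = params.epsilon * math.sqrt(n)
    r = radius * np.sqrt(rng.random(n))
    phi = rng.uniform(-math.pi, math.pi, n)
    positions = np.column_stack([r * np.cos(phi), r * np.sin(phi)])
    headings = wrap_angle(rng.uniform(-math.pi, math.pi, n))
    speeds = np.full(n, params.s0)
    return positions, speeds, headings


def run_simulation(
    params: ModelParams,
    t_end: float,
    sample_dt: float = 0.5,
    seed: int = 0,
    init: Optional[Tuple[np.ndarray, np.ndarray, np.ndarray]] = None,
) -> Trajectory:
    """Run one realization of the model and return its trajectory.

    Parameters
    ----------
    params : ModelParams
        Model parameters (validated on construction).
    t_end : float
        Simulation horizon; must be > 0.
    sample_dt : float
        Spacing of the snapshot grid (snapshots at 0, sample_dt, ...).
    seed : int
        Seed of the single RNG stream driving every random draw; identical
        seeds give bit-identical trajectories.
    init : tuple of arrays, optional
        ``(positions (N,2), speeds (N,), headings (N,))`` overriding the
        default disc initial condition.

    Returns
    -------
    Trajectory
        Snapshots on the sample grid plus the complete event log.
    """
    if t_end <= 0:
        raise ValueError("t_end must be > 0")
    if sample_dt <= 0:
        raise ValueError("sample_dt must be > 0")
    params.validate()
    rng = np.random.default_rng(seed)
    n = params.N

    if init is None:
        positions, speeds, headings = initial_condition(params, rng)
    else:
        positions = np.array(init[0], dtype=float)
        speeds = np.array(init[1], dtype=float)
        headings = wrap_angle(np.array(init[2], dtype=float))
        if positions.shape != (n, 2) or speeds.shape != (n,) or headings.shape != (n,):
            raise ValueError("init arrays have wrong shape for N")

    n_samples = int(math.floor(t_end / sample_dt + 1e-9)) + 1
    sample_times = np.array([i * sample_dt for i in range(n_samples)])
    snap_pos = np.empty((n_samples, n, 2))
    snap_speed = np.empty((n_samples, n))
    snap_heading = np.empty((n_samples, n))

    micro = micro_step_length(params)
    minimal = params.minimal
    all_ids = np.arange(n)

    t = 0.0
    si = 0
    snap_pos[0] = positions
    snap_speed[0] = speeds
    snap_heading[0] = headings
    si = 1

    events: List[InteractionEvent] = []

    def advance_to(target: float):
        """Ballistic micro-stepping (with avoidance) from t to target,
        recording snapshots crossed on the way."""
        nonlocal t, si
        while t < target - 1e-12:
            step_end = min(t + micro, target)
            if si < n_samples and sample_times[si] < step_end - 1e-12:
                step_end = float(sample_times[si])
            dt_step = step_end - t
            if dt_step > 0:
                vel = speeds[:, None] * np.column_stack(
                    [np.cos(headings), np.sin(headings)]
                )
                positions[:] = positions + vel * dt_step
                if not minimal:
                    _avoidance_kernel(positions, speeds, headings, params, dt_step)
            t = step_end
            while si < n_samples and sample_times[si] <= t + 1e-9:
                snap_pos[si] = positions
                snap_speed[si] = speeds
                snap_heading[si] = headings
                si += 1

    while True:
        dt, focal, etype = sample_next_event(params, rng)
        t_event = t + dt
        if t_event > t_end:
            advance_to(t_end)
            break
        advance_to(t_event)

        if etype == "turn":
            h, s = _spontaneous_kernel(float(headings[focal]), params, rng)
            headings[focal] = h
            speeds[focal] = s
            partners: Tuple[int, ...] = ()
        else:
            others = all_ids[all_ids != focal]
            vis = visible_id_array(
                positions[focal],
                float(headings[focal]),
                positions[others],
                others,
                params.fov,
            )
            ranked = rank_id_array(positions[focal], positions[vis], vis, params.K)
            chosen = choose_partners(ranked, params.k, rng)
            if chosen.size:
                if etype == "align":
                    h, s = _alignment_kernel(focal, chosen, speeds, headings, params)
                else:
                    h, s = _attraction_kernel(
                        focal, chosen, positions, speeds, headings, params
                    )
                headings[focal] = h
                speeds[focal] = s
            partners = tuple(int(c) for c in chosen)
        events.append(InteractionEvent(t_event, focal, etype, partners))

    # Any trailing sample times not yet recorded (world static after t_end).
    while si < n_samples:
        snap_pos[si] = positions
        snap_speed[si] = speeds
        snap_heading[si] = headings
        si += 1

    return Trajectory(
        sample_times=sample_times,
        positions=snap_pos,
        speeds=snap_speed,
        headings=snap_heading,
        events=events,
        params=params,
        seed=seed,
    )
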