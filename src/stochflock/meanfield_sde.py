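"""Mean-field stochastic differential equations for the polarization order
parameter m, contrasting pairwise copying with higher-order (averaging)
alignment.

Pairwise copying of a single random neighbour gives a linear restoring drift
with multiplicative noise,

    dm/dt = -a*m + sqrt((c*(1 - m^2) + a) / N) * eta(t),

so order (|m| near 1) is *noise-induced* and fades as the group size N
grows.  A higher-order interaction at rate h — the mean-field equivalent of
local averaging — adds a deterministic ordering term,

    dm/dt = -a*m + h*(1 - m^2)*m + sqrt(((c + h)*(1 - m^2) + a) / N) * eta(t),

whose drift has stable fixed points at m = +/- sqrt(1 - a/h) when h > a:
averaging holds the system at an ordered state deterministically.  Here
``a`` is the spontaneous (random-turn) rate, ``c`` the pairwise copy rate,
``eta`` Gaussian white noise, and m is treated as a scalar in [-1, 1].

Integration is Euler-Maruyama with clamping of m to [-1, 1] after each
step.  The noise radicand is isolated in :func:`diffusion` behind a
``noise_form`` switch so the alternative reading ``(1 - |m|)^2`` of the
multiplicative factor can be explored.
"""

from __future__ import annotations

import math
import warnings
from dataclasses import dataclass
from typing import Tuple

import numpy as np

__all__ = [
    "SDEParams",
    "SDETrace",
    "drift",
    "diffusion",
    "simulate_sde",
    "stationary_moments",
]

_MODELS = ("pairwise", "higher")
_NOISE_FORMS = ("quadratic", "linear_abs")


@dataclass
class SDEParams:
    """Parameters of the mean-field SDEs.

    Attributes
    ----------
    a : float
        Spontaneous (random-turn) rate, 1/time.
    c : float
        Pairwise copy rate, 1/time.
    h : float
        Higher-order interaction rate, 1/time (0 for the pairwise model).
    N : int
        Group size; fluctuations scale as 1/sqrt(N).
    dt : float
        Euler-Maruyama step.
    m0 : float
        Initial order parameter in [-1, 1].
    noise_form : str
        "quadratic" for the (1 - m^2) multiplicative factor (default);
        "linear_abs" for the alternative (1 - |m|)^2 reading.
    """

    a: float
    c: float
    h: float = 0.0
    N: int = 50
    dt: float = 1e-3
    m0: float = 0.0
    noise_form: str = "quadratic"

    def __post_init__(self):
        if self.a < 0 or self.c < 0 or self.h < 0:
            raise ValueError("rates must be >= 0")
        if self.N < 2:
            raise ValueError("N must be >= 2")
        if self.dt <= 0:
            raise ValueError("dt must be > 0")
        if abs(self.m0) > 1:
            raise ValueError("|m0| must be <= 1")
        if self.noise_form not in _NOISE_FORMS:
            raise ValueError(f"noise_form must be one of {_NOISE_FORMS}")


@dataclass
class SDETrace:
    """Recorded path of the order parameter."""

    times: np.ndarray
    m_values: np.ndarray
    params: SDEParams
    model: str
    seed: int


def _check_model(model: str) -> None:
    if model not in _MODELS:
        raise ValueError(f"model must be one of {_MODELS}")


def drift(m: float, params: SDEParams, model: str) -> float:
    """Deterministic part of dm/dt.

    Pairwise: ``-a*m`` (pure relaxation — no deterministic ordering).
    Higher:  ``-a*m + h*(1 - m^2)*m`` (pitchfork: ordered fixed points at
    ``+/- sqrt(1 - a/h)`` when ``h > a``).
    """
    _check_model(model)
    base = -params.a * m
    if model == "higher":
        base += params.h * (1.0 - m * m) * m
    return base


def diffusion(m: float, params: SDEParams, model: str) -> float:
    """Noise amplitude multiplying the Gaussian white noise.

    ``sqrt((c_eff * f(m) + a) / N)`` with ``c_eff = c`` (pairwise) or
    ``c + h`` (higher) and ``f(m) = 1 - m^2`` (default) or ``(1 - |m|)^2``.
    Vanishes at full order when a = 0; strictly positive when a > 0.
    """
    _check_model(model)
    c_eff = params.c if model == "pairwise" else params.c + params.h
    if params.noise_form == "quadratic":
        factor = 1.0 - m * m
    else:
        factor = (1.0 - abs(m)) ** 2
    radicand = (c_eff * factor + params.a) / params.N
    if radicand < -1e-15:
        raise ValueError("negative noise radicand")
    return math.sqrt(max(radicand, 0.0))


def simulate_sde(
    params: SDEParams,
    t_end: float,
    model: str = "pairwise",
    seed: int = 0,
    record_every: int = 1,
) -> SDETrace:
    """Euler-Maruyama integration of the chosen mean-field SDE.

    ``m <- m + drift * dt + diffusion * sqrt(dt) * z`` with standard-normal
    z, clamped to [-1, 1] after each step.  ``record_every`` thins the
    recorded path (the first and last points are always kept).
    """
    _check_model(model)
    if t_end <= 0:
        raise ValueError("t_end must be > 0")
    if record_every < 1:
        raise ValueError("record_every must be >= 1")
    total_rate = params.a + params.c + params.h
    if total_rate > 0 and params.dt >= 1.0 / (2.0 * total_rate):
        warnings.warn(
            "dt is large relative to the fastest rate; integration may be "
            "inaccurate",
            RuntimeWarning,
            stacklevel=2,
        )
    rng = np.random.default_rng(seed)
    n_steps = int(round(t_end / params.dt))
    z = rng.standard_normal(n_steps)
    sqrt_dt = math.sqrt(params.dt)
    a, c, h, N, dt = params.a, params.c, params.h, params.N, params.dt
    higher = model == "higher"
    quadratic = params.noise_form == "quadratic"
    c_eff = c + h if higher else c

    n_rec = n_steps // record_every + 1
    times = np.empty(n_rec + 1)
    ms = np.empty(n_rec + 1)
    m = float(params.m0)
    times[0] = 0.0
    ms[0] = m
    ri = 1
    for i in range(n_steps):
        dr = -a * m
        if higher:
            dr += h * (1.0 - m * m) * m
        factor = 1.0 - m * m if quadratic else (1.0 - abs(m)) ** 2
        dif = math.sqrt((c_eff * factor + a) / N)
        m += dr * dt + dif * sqrt_dt * z[i]
        if m > 1.0:
            m = 1.0
        elif m < -1.0:
            m = -1.0
        if (i + 1) % record_every == 0 or i == n_steps - 1:
            times[ri] = (i + 1) * dt
            ms[ri] = m
            ri += 1
    return SDETrace(
        times=times[:ri], m_values=ms[:ri], params=params, model=model, seed=seed
    )


def stationary_moments(
    trace: SDETrace, burn_fraction: float = 0.2
) -> Tuple[float, float, float]:
    """Sample (mean m, variance of m, mean |m|) of the post-burn-in path.

    Requires at least 100 post-burn-in samples.
    """
    if not (0 <= burn_fraction < 1):
        raise ValueError("burn_fraction must lie in [0, 1)")
    t_end = float(trace.times[-1])
    keep = trace.times >= burn_fraction * t_end - 1e-12
    m = trace.m_values[keep]
    if m.size < 100:
        raise ValueError("need at least 100 post-burn-in samples")
    return float(m.mean()), float(m.var()), float(np.abs(m).mean())
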