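"""Experiment orchestration: configuration files, replicate sweeps over
(N, K, interaction mode), the saturation-threshold estimator, CSV round
trips for trajectories and event logs, deterministic test fixtures, and
summary plots.

A sweep reproduces the core experiment at desk scale: for every combination
of group size N, neighbourhood size K and interaction mode (pairwise k = 1
versus averaging k = K) it runs several replicate realizations and records
the cohesion parameter C, the mean cluster count Nc and the network
parameter Np, then averages them over replicates.  The default horizon is
t_end = 200 with 10 replicates per point.
"""

from __future__ import annotations

import math
from dataclasses import dataclass, field, asdict
from pathlib import Path
from typing import Dict, List, Optional, Sequence, Tuple

import numpy as np
import pandas as pd
import yaml

from .cohesion_metrics import cohesion_parameter
from .interaction_network import network_parameter
from .model_core import AgentState, ModelParams
from .simulator import InteractionEvent, Trajectory, run_simulation

__all__ = [
    "ExperimentConfig",
    "SummaryTable",
    "load_config",
    "save_config",
    "run_sweep",
    "estimate_saturation_threshold",
    "make_fixture",
    "static_trajectory",
    "write_trajectory_csv",
    "read_trajectory_csv",
    "write_events_csv",
    "read_events_csv",
    "plot_summary",
]

_K_MODES = ("pairwise", "averaging", "explicit")

#: Model-parameter keys accepted flat in config files.
_MODEL_KEYS = (
    "r_p",
    "r_c",
    "r_s",
    "s0",
    "sigma_a2",
    "sigma_s2",
    "fov",
    "d_c",
    "avoid_turn_rate",
    "avoid_slow_factor",
    "s_min",
    "s_max",
    "epsilon",
    "minimal",
)

_EXPERIMENT_KEYS = (
    "N_list",
    "K_list",
    "k_mode",
    "k_explicit",
    "t_end",
    "sample_dt",
    "replicates",
    "base_seed",
    "burn_fraction",
    "outdir",
)


@dataclass
class ExperimentConfig:
    """Validated sweep configuration with defaults filled in."""

    N_list: List[int] = field(default_factory=lambda: [30])
    K_list: List[int] = field(default_factory=lambda: [1, 2, 5, 8, 10, 15, 29])
    k_mode: str = "pairwise"
    k_explicit: Optional[int] = None
    t_end: float = 200.0
    sample_dt: float = 0.5
    replicates: int = 10
    base_seed: int = 0
    burn_fraction: float = 0.2
    outdir: str = "."
    model: Dict = field(default_factory=dict)  # overrides for ModelParams

    def __post_init__(self):
        if self.replicates < 1:
            raise ValueError("replicates must be >= 1")
        if self.k_mode not in _K_MODES:
            raise ValueError(f"k_mode must be one of {_K_MODES}")
        if self.k_mode == "explicit" and self.k_explicit is None:
            raise ValueError("k_mode 'explicit' requires k_explicit")
        if not (0 <= self.burn_fraction < 1):
            raise ValueError("burn_fraction must lie in [0, 1)")
        if self.t_end <= 0 or self.sample_dt <= 0:
            raise ValueError("t_end and sample_dt must be > 0")
        unknown = set(self.model) - set(_MODEL_KEYS)
        if unknown:
            raise ValueError(f"unknown model keys: {sorted(unknown)}")
        for n in self.N_list:
            for K in self.K_list:
                if K >= n:
                    raise ValueError(
                        f"K={K} violates K <= N-1 for N={n}"
                    )
                if K < 1:
                    raise ValueError("K must be >= 1")

    def k_for(self, K: int) -> int:
        if self.k_mode == "pairwise":
            return 1
        if self.k_mode == "averaging":
            return K
        return min(self.k_explicit, K)

    def params_for(self, N: int, K: int) -> ModelParams:
        return ModelParams(N=N, K=K, k=self.k_for(K), **self.model)


def load_config(path) -> ExperimentConfig:
    """Read and validate a YAML experiment config.

    Model-parameter keys may appear flat alongside experiment keys or
    nested under ``model``.  Unknown keys raise a ``ValueError`` (typo
    safety); a K >= N pair raises its own distinct error.
    """
    path = Path(path)
    if not path.exists():
        raise FileNotFoundError(f"config file not found: {path}")
    with open(path) as fh:
        raw = yaml.safe_load(fh) or {}
    if not isinstance(raw, dict):
        raise ValueError("config must be a mapping")
    model = dict(raw.pop("model", {}))
    exp = {}
    for key, value in raw.items():
        if key in _EXPERIMENT_KEYS:
            exp[key] = value
        elif key in _MODEL_KEYS:
            model[key] = value
        else:
            raise ValueError(f"unknown config key: {key!r}")
    return ExperimentConfig(model=model, **exp)


def save_config(config: ExperimentConfig, path) -> None:
    """Write a config back to YAML (round-trips through load_config)."""
    data = asdict(config)
    with open(path, "w") as fh:
        yaml.safe_dump(data, fh, sort_keys=True)


@dataclass
class SummaryTable:
    """Sweep output: per-replicate rows and replicate-averaged rows.

    ``per_replicate`` has one row per (N, K, k_mode, replicate) with columns
    C, Nc_mean, Np; ``averaged`` carries replicate means and standard errors.
    """

    per_replicate: pd.DataFrame
    averaged: pd.DataFrame

    def to_csv(self, outdir) -> Tuple[Path, Path]:
        outdir = Path(outdir)
        outdir.mkdir(parents=True, exist_ok=True)
        p1 = outdir / "summary_per_replicate.csv"
        p2 = outdir / "summary_averaged.csv"
        self.per_replicate.to_csv(p1, index=False)
        self.averaged.to_csv(p2, index=False)
        return p1, p2


def _average(per_replicate: pd.DataFrame) -> pd.DataFrame:
    grouped = per_replicate.groupby(["N", "K", "k_mode"], as_index=False)
    mean = grouped[["C", "Nc_mean", "Np"]].mean()
    sem = (
        per_replicate.groupby(["N", "K", "k_mode"])[["C", "Nc_mean", "Np"]]
        .sem(ddof=1)
        .reset_index()
        .rename(columns={"C": "C_se", "Nc_mean": "Nc_mean_se", "Np": "Np_se"})
    )
    return mean.merge(sem, on=["N", "K", "k_mode"]).fillna(0.0)


def run_sweep(
    config: ExperimentConfig, return_trajectories: bool = False
) -> SummaryTable:
    """Run the full (N, K, replicate) sweep and aggregate C, Nc and Np.

    Replicate r uses seed ``base_seed + r`` (the same seeds across K, so
    K-contrasts share their random numbers).  The sweep is a deterministic
    function of the config.  With ``return_trajectories=True`` the table
    carries a ``trajectories`` attribute mapping
    ``(N, K, k_mode, replicate)`` to the Trajectory, for re-analysis
    without re-running.
    """
    rows = []
    trajectories: Dict[Tuple, Trajectory] = {}
    for N in config.N_list:
        for K in config.K_list:
            params = config.params_for(N, K)
            for r in range(config.replicates):
                seed = config.base_seed + r
                traj = run_simulation(
                    params, config.t_end, config.sample_dt, seed=seed
                )
                coh = cohesion_parameter(
                    traj, params.epsilon, config.burn_fraction
                )
                net = network_parameter(
                    traj.events, params, config.t_end, config.burn_fraction
                )
                rows.append(
                    {
                        "N": N,
                        "K": K,
                        "k_mode": config.k_mode,
                        "replicate": r,
                        "seed": seed,
                        "C": coh.C,
                        "Nc_mean": coh.Nc_mean,
                        "Np": net.Np,
                    }
                )
                if return_trajectories:
                    trajectories[(N, K, config.k_mode, r)] = traj
    per_replicate = pd.DataFrame(rows)
    table = SummaryTable(
        per_replicate=per_replicate, averaged=_average(per_replicate)
    )
    if return_trajectories:
        table.trajectories = trajectories
    return table


def estimate_saturation_threshold(
    table: SummaryTable,
    N: int,
    k_mode: str = "pairwise",
    factor: float = 0.95,
):
    """Smallest K/N at which the replicate-mean C reaches ``factor`` of its
    value at K = N - 1, by linear interpolation between sampled K.

    Returns ``None`` ("no saturation") when the curve never reaches the
    target.  Requires at least 5 sampled K values including K = N - 1.
    """
    df = table.averaged
    df = df[(df["N"] == N) & (df["k_mode"] == k_mode)].sort_values("K")
    if len(df) < 5:
        raise ValueError("need a C-vs-K curve with at least 5 K values")
    Ks = df["K"].to_numpy(dtype=float)
    Cs = df["C"].to_numpy(dtype=float)
    if int(Ks[-1]) != N - 1:
        raise ValueError("curve must include K = N - 1")
    target = factor * Cs[-1]
    above = np.flatnonzero(Cs >= target - 1e-12)
    if above.size == 0:
        return None
    i = int(above[0])
    if i == 0:
        return float(Ks[0]) / N
    k_star = Ks[i - 1] + (target - Cs[i - 1]) * (Ks[i] - Ks[i - 1]) / (
        Cs[i] - Cs[i - 1]
    )
    return float(k_star) / N


# ---------------------------------------------------------------------------
# Deterministic fixtures (known ground truth for every analysis stage)
# ---------------------------------------------------------------------------

def make_fixture(kind: str, **kwargs):
    """Deterministic agent configurations and synthetic event logs.

    Kinds
    -----
    line : n, spacing -> (n, 2) positions on the x-axis
    two_blobs : n1, n2, gap, spread -> two tight rings of agents
    ring : n, radius -> points on a circle
    event_log_cycle : n, t_w, n_windows -> attraction events forming a full
        directed cycle in every window (largest sub-group fraction 1)
    event_log_halves : n (even), t_w, n_windows -> directed cycles confined
        to the two halves of the group (largest sub-group fraction 0.5)
    """
    if kind == "line":
        n = int(kwargs.get("n", 10))
        spacing = float(kwargs.get("spacing", 0.9))
        return np.column_stack([spacing * np.arange(n), np.zeros(n)])
    if kind == "two_blobs":
        n1 = int(kwargs.get("n1", 5))
        n2 = int(kwargs.get("n2", 5))
        gap = float(kwargs.get("gap", 10.0))
        spread = float(kwargs.get("spread", 0.1))

        def blob(n, cx):
            ang = 2 * math.pi * np.arange(n) / max(n, 1)
            return np.column_stack(
                [cx + spread * np.cos(ang), spread * np.sin(ang)]
            )

        return np.vstack([blob(n1, 0.0), blob(n2, gap)])
    if kind == "ring":
        n = int(kwargs.get("n", 12))
        radius = float(kwargs.get("radius", 1.0))
        ang = 2 * math.pi * np.arange(n) / n
        return np.column_stack([radius * np.cos(ang), radius * np.sin(ang)])
    if kind == "event_log_cycle":
        n = int(kwargs.get("n", 10))
        t_w = float(kwargs.get("t_w", 1.0))
        n_windows = int(kwargs.get("n_windows", 5))
        t_offset = float(kwargs.get("t_offset", 0.0))
        events = []
        for w in range(n_windows):
            for j in range(n):
                t = t_offset + w * t_w + (j + 0.5) / n * t_w
                events.append(
                    InteractionEvent(t, j, "attract", ((j + 1) % n,))
                )
        return events
    if kind == "event_log_halves":
        n = int(kwargs.get("n", 10))
        if n % 2:
            raise ValueError("event_log_halves needs an even n")
        t_w = float(kwargs.get("t_w", 1.0))
        n_windows = int(kwargs.get("n_windows", 5))
        t_offset = float(kwargs.get("t_offset", 0.0))
        half = n // 2
        events = []
        for w in range(n_windows):
            for j in range(n):
                t = t_offset + w * t_w + (j + 0.5) / n * t_w
                if j < half:
                    target = (j + 1) % half
                else:
                    target = half + (j - half + 1) % half
                events.append(InteractionEvent(t, j, "attract", (target,)))
        return events
    raise ValueError(f"unknown fixture kind: {kind!r}")


def static_trajectory(
    positions: np.ndarray,
    n_samples: int = 100,
    sample_dt: float = 0.5,
    params: Optional[ModelParams] = None,
) -> Trajectory:
    """A trajectory in which nothing moves: the given positions repeated at
    every sample time, with an empty event log.  Useful as a fixture with
    known cluster structure."""
    positions = np.asarray(positions, dtype=float)
    n = positions.shape[0]
    if params is None:
        params = ModelParams(N=max(n, 2), K=1, k=1)
    times = np.arange(n_samples) * sample_dt
    return Trajectory(
        sample_times=times,
        positions=np.broadcast_to(positions, (n_samples, n, 2)).copy(),
        speeds=np.zeros((n_samples, n)),
        headings=np.zeros((n_samples, n)),
        events=[],
        params=params,
        seed=None,
    )


# ---------------------------------------------------------------------------
# CSV round trips
# ---------------------------------------------------------------------------

_FLOAT_FMT = "%.17g"  # exact binary round trip (>= 12 significant digits)


def write_trajectory_csv(traj: Trajectory, path) -> None:
    """Write snapshots as CSV: time, id, x, y, speed, heading (radians)."""
    T, n = traj.n_samples, traj.n_agents
    df = pd.DataFrame(
        {
            "time": np.repeat(traj.sample_times, n),
            "id": np.tile(np.arange(n), T),
            "x": traj.positions[:, :, 0].ravel(),
            "y": traj.positions[:, :, 1].ravel(),
            "speed": traj.speeds.ravel(),
            "heading": traj.headings.ravel(),
        }
    )
    df.to_csv(path, index=False, float_format=_FLOAT_FMT)


def read_trajectory_csv(path, params: Optional[ModelParams] = None) -> Trajectory:
    """Read a trajectory CSV written by :func:`write_trajectory_csv`.

    The returned trajectory has an empty event log; pair it with
    :func:`read_events_csv` for network analysis.
    """
    df = pd.read_csv(path)
    times = np.sort(df["time"].unique())
    n = df["id"].nunique()
    df = df.sort_values(["time", "id"])
    T = times.size
    return Trajectory(
        sample_times=times,
        positions=np.column_stack([df["x"], df["y"]]).reshape(T, n, 2),
        speeds=df["speed"].to_numpy().reshape(T, n),
        headings=df["heading"].to_numpy().reshape(T, n),
        events=[],
        params=params,
        seed=None,
    )


def write_events_csv(events: Sequence[InteractionEvent], path) -> None:
    """Write an event log as CSV: time, focal, etype, partners
    (semicolon-joined ids; empty allowed)."""
    df = pd.DataFrame(
        {
            "time": [ev.t for ev in events],
            "focal": [ev.focal for ev in events],
            "etype": [ev.etype for ev in events],
            "partners": [";".join(str(j) for j in ev.partners) for ev in events],
        }
    )
    df.to_csv(path, index=False, float_format=_FLOAT_FMT)


def read_events_csv(path) -> List[InteractionEvent]:
    """Read an event-log CSV written by :func:`write_events_csv`."""
    df = pd.read_csv(path, keep_default_na=False, dtype={"partners": str})
    events = []
    for row in df.itertuples(index=False):
        partners = tuple(
            int(p) for p in str(row.partners).split(";") if p != ""
        )
        events.append(
            InteractionEvent(float(row.time), int(row.focal), row.etype, partners)
        )
    return events


# ---------------------------------------------------------------------------
# Plots
# ---------------------------------------------------------------------------

def plot_summary(table: SummaryTable, outdir) -> List[Path]:
    """Write the standard sweep plots (C vs K, Np vs K, and a pairwise vs
    averaging comparison when both modes are present).  Returns the paths."""
    import matplotlib

    matplotlib.use("Agg")
    import matplotlib.pyplot as plt

    outdir = Path(outdir)
    outdir.mkdir(parents=True, exist_ok=True)
    paths = []
    df = table.averaged
    for metric, fname in (("C", "cohesion_vs_K.png"), ("Np", "network_vs_K.png")):
        fig, ax = plt.subplots(figsize=(5, 4))
        for (N, mode), sub in df.groupby(["N", "k_mode"]):
            sub = sub.sort_values("K")
            ax.errorbar(
                sub["K"],
                sub[metric],
                yerr=sub[f"{metric}_se"],
                marker="o",
                label=f"N={N}, {mode}",
            )
        ax.set_xlabel("K")
        ax.set_ylabel(metric)
        ax.set_ylim(0, 1.05)
        ax.legend(fontsize=8)
        fig.tight_layout()
        p = outdir / fname
        fig.savefig(p, dpi=120)
        plt.close(fig)
        paths.append(p)
    return paths
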