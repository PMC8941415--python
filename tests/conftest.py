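"""Shared fixtures.

The replicate sweep at N = 30 is the workhorse of the acceptance-level
checks (saturation threshold, break-up cluster sizes, network-cohesion
correlation).  It is expensive, so it runs once per session and is shared.
The sweep carries 16 replicates: the saturation-threshold and break-up
measurements use the first 10 (their standard design), while the
network-cohesion rank correlation uses all 16 for tighter replicate means.
"""

import numpy as np
import pandas as pd
import pytest

from stochflock.cohesion_metrics import cluster_sizes, epsilon_clusters
from stochflock.experiments_io import ExperimentConfig, SummaryTable, run_sweep
from stochflock.experiments_io import _average

BASE_SEED = 1234
SWEEP_K = [1, 2, 5, 8, 10, 15, 29]
SWEEP_REPLICATES = 16
STANDARD_REPLICATES = 10


@pytest.fixture(scope="session")
def pairwise_sweep():
    """Stochastic pairwise sweep: N = 30, K over the standard grid,
    16 replicates, t_end = 200, default model parameters."""
    config = ExperimentConfig(
        N_list=[30],
        K_list=SWEEP_K,
        k_mode="pairwise",
        replicates=SWEEP_REPLICATES,
        t_end=200.0,
        sample_dt=0.5,
        base_seed=BASE_SEED,
    )
    return run_sweep(config, return_trajectories=True)


@pytest.fixture(scope="session")
def pairwise_sweep_ten(pairwise_sweep):
    """The first 10 replicates of the shared sweep, re-aggregated: the
    standard design for the saturation-threshold estimate."""
    sub = pairwise_sweep.per_replicate.query(
        f"replicate < {STANDARD_REPLICATES}"
    ).reset_index(drop=True)
    return SummaryTable(per_replicate=sub, averaged=_average(sub))


@pytest.fixture(scope="session")
def averaging_k5():
    """Averaging-mode (k = K) runs at the intermediate K = 5, same seeds
    as the pairwise sweep so the contrast is paired."""
    config = ExperimentConfig(
        N_list=[30],
        K_list=[5],
        k_mode="averaging",
        replicates=STANDARD_REPLICATES,
        t_end=200.0,
        sample_dt=0.5,
        base_seed=BASE_SEED,
    )
    return run_sweep(config)


@pytest.fixture(scope="session")
def k1_cluster_size_pool(pairwise_sweep):
    """Cluster sizes pooled over post-burn-in snapshots and the first 10
    replicates of the K = 1 (nearest-neighbour-only) runs."""
    sizes = []
    for (N, K, mode, r), traj in pairwise_sweep.trajectories.items():
        if K != 1 or r >= STANDARD_REPLICATES:
            continue
        eps = traj.params.epsilon
        t_end = float(traj.sample_times[-1])
        for i in np.flatnonzero(traj.sample_times >= 0.2 * t_end):
            sizes.extend(cluster_sizes(epsilon_clusters(traj.positions[i], eps)))
    return np.array(sizes)
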