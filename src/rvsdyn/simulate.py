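"""Monte-Carlo forward simulation of the RVS dynamics.

Each generation is sampled directly as one multinomial draw of N slots
with the selection probabilities of the current composition — variation
and selection collapsed into a single draw, which is distributionally
identical to varying each organism first and then resampling, and much
faster.  Trajectories are reproducible: a single NumPy generator seeded
per trajectory, with replicate seeds derived by SeedSequence spawning.
"""

from __future__ import annotations

import json
from dataclasses import dataclass
from typing import Sequence

import numpy as np
import pandas as pd

from .equilibrium import MuFamily
from .model import ModelSpec, check_composition, model_hash, selection_probabilities
from .robustness import population_sensitivity_profile
from .transition import CompositionSpace


def step(spec: ModelSpec, n, rng: np.random.Generator) -> np.ndarray:
    """Sample the next composition: multinomial(N, selection probabilities).

    The distribution of outputs equals the exact one-generation transition
    kernel column of ``n``.
    """
    p = selection_probabilities(spec, n)
    return rng.multinomial(spec.N, p)


@dataclass(frozen=True)
class Trajectory:
    """A simulated composition path; ``compositions[t]`` is generation t."""

    compositions: np.ndarray  # (T+1, K) int64
    seed: int | None
    spec: ModelSpec

    @property
    def T(self) -> int:
        return self.compositions.shape[0] - 1

    def to_frame(self) -> pd.DataFrame:
        """Long-format table (generation, type_id, count)."""
        T1, K = self.compositions.shape
        return pd.DataFrame(
            {
                "generation": np.repeat(np.arange(T1), K),
                "type_id": np.tile(self.spec.labels, T1),
                "count": self.compositions.ravel(),
            }
        )

    def metadata(self, burn_in: int | None = None) -> dict:
        return {
            "seed": self.seed,
            "generations": int(self.T),
            "burn_in": burn_in,
            "spec_hash": model_hash(self.spec),
        }


def trajectory(spec: ModelSpec, n0, T: int, seed=None) -> Trajectory:
    """Simulate ``T`` generations starting from ``n0`` (length T+1 path)."""
    if T < 1:
        raise ValueError("T must be >= 1")
    n = check_composition(spec, n0)
    rng = np.random.default_rng(seed)
    path = np.empty((T + 1, spec.K), dtype=np.int64)
    path[0] = n
    pi_T = spec.pi.T
    f = spec.f
    N = spec.N
    for t in range(T):
        weights = f * (path[t] @ pi_T)
        total = weights.sum()
        if total <= 0:
            # route through the standard error message
            selection_probabilities(spec, path[t])
        path[t + 1] = rng.multinomial(N, weights / total)
    return Trajectory(
        compositions=path,
        seed=int(seed) if isinstance(seed, (int, np.integer)) else None,
        spec=spec,
    )


@dataclass(frozen=True)
class OccupancyEstimate:
    """Time-averaged per-type frequencies with block-bootstrap errors."""

    frequency: np.ndarray  # sums to 1
    stderr: np.ndarray
    burn_in: int
    total_generations: int

    def to_frame(self, labels: Sequence[str]) -> pd.DataFrame:
        return pd.DataFrame(
            {"type_id": list(labels), "frequency": self.frequency, "stderr": self.stderr}
        )


def occupancy(
    traj: Trajectory,
    burn_in: int | None = None,
    block_length: int = 100,
    n_boot: int = 200,
    seed: int = 0,
) -> OccupancyEstimate:
    """Time-averaged type frequencies after a burn-in window.

    Standard errors come from a moving-block bootstrap (default block of
    100 generations) to respect the autocorrelation of the chain.
    """
    if burn_in is None:
        burn_in = traj.T // 10
    if burn_in >= traj.compositions.shape[0] - 1:
        raise ValueError("burn-in leaves no post-burn-in generations")
    X = traj.compositions[burn_in + 1 :] / traj.spec.N  # (M, K) frequencies
    freq = X.mean(axis=0)
    M = X.shape[0]
    B = min(block_length, M)
    n_blocks = int(np.ceil(M / B))
    rng = np.random.default_rng(seed)
    starts = rng.integers(0, M - B + 1, size=(n_boot, n_blocks))
    boot = np.empty((n_boot, X.shape[1]))
    for b in range(n_boot):
        idx = (starts[b][:, None] + np.arange(B)[None, :]).ravel()[:M]
        boot[b] = X[idx].mean(axis=0)
    return OccupancyEstimate(
        frequency=freq,
        stderr=boot.std(axis=0, ddof=1),
        burn_in=burn_in,
        total_generations=traj.T,
    )


def visit_distribution(traj: Trajectory, space: CompositionSpace, burn_in: int = 0) -> np.ndarray:
    """Empirical visit frequencies over the states of an enumerated space."""
    counts = np.zeros(len(space))
    for row in traj.compositions[burn_in:]:
        counts[space.index(row)] += 1
    return counts / counts.sum()


def mu_scan(
    family: MuFamily,
    mu_grid: Sequence[float],
    T: int = 2000,
    replicates: int = 4,
    seed: int = 0,
    n0=None,
    burn_in: int | None = None,
) -> pd.DataFrame:
    """Sampled mean and SD of the population sensitivity Ω across a μ grid.

    For each μ, ``replicates`` independent trajectories are run from
    ``n0`` (default: monomorphic in the fastest type) and Ω is averaged
    over all post-burn-in generations; the SD pools all samples and the
    standard error of the mean comes from the spread of replicate means.
    Columns: mu, mean_omega, sd_omega, se_mean, n_samples.
    """
    if burn_in is None:
        burn_in = T // 10
    ss = np.random.SeedSequence(seed)
    rows = []
    for mu in mu_grid:
        spec = family.spec(float(mu))
        if n0 is None:
            start = np.zeros(spec.K, dtype=np.int64)
            start[int(np.argmax(spec.f))] = spec.N
        else:
            start = check_composition(spec, n0)
        child_seeds = ss.spawn(replicates)
        samples = []
        rep_means = []
        for cs in child_seeds:
            traj = trajectory(spec, start, T, seed=cs)
            omegas = population_sensitivity_profile(
                spec, traj.compositions[burn_in + 1 :], mu
            )
            samples.append(omegas)
            rep_means.append(omegas.mean())
        pooled = np.concatenate(samples)
        rows.append(
            {
                "mu": float(mu),
                "mean_omega": float(pooled.mean()),
                "sd_omega": float(pooled.std(ddof=1)),
                "se_mean": float(np.std(rep_means, ddof=1) / np.sqrt(replicates)),
                "n_samples": int(pooled.size),
            }
        )
    return pd.DataFrame(rows)


def write_run_metadata(path, traj: Trajectory, burn_in: int | None = None) -> None:
    with open(path, "w") as fh:
        json.dump(traj.metadata(burn_in), fh, indent=2)
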