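"""Synthetic data generators for the genotype-phenotype-fitness pipeline.

Two generators live here.  The first draws a low-rank mutant x environment
fitness matrix from an explicit phenotype model: mutants and environments are
points in a k-dimensional phenotype space, sampled uniformly inside n-balls,
and fitness is the inner product of a mutant's phenotype coordinates with an
environment's phenotype weights, plus heteroscedastic Gaussian measurement
noise.  The second is a forward model of a pooled barcode competition assay:
lineages compete against a high-frequency ancestral reference over serial
transfer cycles, and sequencing reads are a multinomial draw over the
non-reference lineages (the reference barcode is destroyed before sequencing).
"""

from __future__ import annotations

from dataclasses import dataclass, field
from typing import Mapping

import numpy as np
import pandas as pd

__all__ = [
    "SimConfig",
    "BarSeqSimConfig",
    "PhenotypeSim",
    "sample_uniform_ball",
    "simulate_phenotype_fitness",
    "simulate_barcode_experiment",
    "expected_frequencies",
]


def _as_rng(seed) -> np.random.Generator:
    if isinstance(seed, np.random.Generator):
        return seed
    return np.random.default_rng(seed)


def sample_uniform_ball(k: int, center, radius: float, n: int, seed=None) -> np.ndarray:
    """Draw ``n`` points uniformly from the k-ball of given center and radius.

    Uses the rejection-free construction: an isotropic Gaussian direction
    scaled by ``radius * U**(1/k)``, which is uniform over the ball's volume.

    Parameters
    ----------
    k : dimension of the ball (>= 1).
    center : length-k array-like, ball center.
    radius : non-negative ball radius.
    n : number of points (>= 1).
    seed : int seed or ``numpy.random.Generator``.

    Returns
    -------
    (n, k) array; every row is within ``radius`` of ``center``.
    """
    if k < 1:
        raise ValueError(f"dimension k must be >= 1, got {k}")
    if n < 1:
        raise ValueError(f"sample count n must be >= 1, got {n}")
    if radius < 0:
        raise ValueError(f"radius must be non-negative, got {radius}")
    center = np.asarray(center, dtype=float)
    if center.shape != (k,):
        raise ValueError(f"center must have shape ({k},), got {center.shape}")
    rng = _as_rng(seed)
    direction = rng.standard_normal((n, k))
    norms = np.linalg.norm(direction, axis=1, keepdims=True)
    # a zero Gaussian vector has probability 0; guard anyway
    norms[norms == 0] = 1.0
    direction /= norms
    r = radius * rng.random(n) ** (1.0 / k)
    return center + direction * r[:, None]


@dataclass
class SimConfig:
    """Configuration of the n-ball phenotype-fitness simulation.

    Defaults mirror the validation setup: 100 mutants uniform in the k-ball
    centered at (1, 0, ..., 0) with radius 1 (so the first component carries
    most fitness variation, as in the real data), and 50 environments uniform
    in the k-ball centered at (1, 1, ..., 1) with small radius 0.1 so all
    environments are subtle perturbations of one another.
    """

    true_dim: int
    n_mutants: int = 100
    n_envs: int = 50
    mutant_center: np.ndarray | None = None
    mutant_radius: float = 1.0
    env_center: np.ndarray | None = None
    env_radius: float = 0.1
    noise_sd: float | np.ndarray = 0.0
    seed: int = 0

    def __post_init__(self):
        if self.true_dim < 1:
            raise ValueError("true_dim must be >= 1")
        if self.n_mutants < 1 or self.n_envs < 1:
            raise ValueError("n_mutants and n_envs must be >= 1")
        if self.mutant_radius < 0 or self.env_radius < 0:
            raise ValueError("radii must be non-negative")
        if self.mutant_center is None:
            c = np.zeros(self.true_dim)
            c[0] = 1.0
            self.mutant_center = c
        else:
            self.mutant_center = np.asarray(self.mutant_center, dtype=float)
        if self.env_center is None:
            self.env_center = np.ones(self.true_dim)
        else:
            self.env_center = np.asarray(self.env_center, dtype=float)
        sd = np.asarray(self.noise_sd, dtype=float)
        if np.any(sd < 0):
            raise ValueError("noise_sd must be non-negative entrywise")


@dataclass
class PhenotypeSim:
    """Result bundle of :func:`simulate_phenotype_fitness`."""

    mutant_coords: np.ndarray  # (n_mutants, k) true phenotype coordinates P
    env_weights: np.ndarray    # (k, n_envs) true environment weights E
    fitness_true: np.ndarray   # (n_mutants, n_envs) noiseless P @ E
    fitness: np.ndarray        # noisy observed matrix
    errors: np.ndarray         # per-entry noise sd

    def to_frames(self, mutant_prefix="mut", env_prefix="env"):
        """Observed fitness and error matrices as labeled DataFrames."""
        mutants = [f"{mutant_prefix}{i:04d}" for i in range(self.fitness.shape[0])]
        envs = [f"{env_prefix}{j:03d}" for j in range(self.fitness.shape[1])]
        F = pd.DataFrame(self.fitness, index=mutants, columns=envs)
        E = pd.DataFrame(self.errors, index=mutants, columns=envs)
        return F, E


def simulate_phenotype_fitness(config: SimConfig) -> PhenotypeSim:
    """Simulate a low-rank fitness matrix with known true dimension.

    The noiseless matrix is exactly the inner product of mutant phenotype
    coordinates with environment weights, hence has rank <= ``true_dim``.
    Gaussian noise with the configured per-entry sd is added independently.
    """
    rng = np.random.default_rng(config.seed)
    k = config.true_dim
    P = sample_uniform_ball(k, config.mutant_center, config.mutant_radius,
                            config.n_mutants, rng)
    E = sample_uniform_ball(k, config.env_center, config.env_radius,
                            config.n_envs, rng).T
    F_true = P @ E
    errors = np.broadcast_to(
        np.asarray(config.noise_sd, dtype=float), F_true.shape
    ).copy()
    F = F_true + rng.standard_normal(F_true.shape) * errors
    return PhenotypeSim(P, E, F_true, F, errors)


@dataclass
class BarSeqSimConfig:
    """Configuration of the pooled barcode competition forward model.

    ``true_fitness`` maps lineage id -> relative fitness per transfer cycle
    (log-frequency advantage over the reference per cycle).  The reference
    strain starts at ``reference_start_frequency`` (0.9: lineages are mixed
    1:9 with the reference) and its barcode never appears in the sequencing
    output.  ``n_cycles`` transfers give ``n_cycles + 1`` time-points.
    """

    true_fitness: Mapping[str, float] | pd.Series
    neutral_ids: frozenset = field(default_factory=frozenset)
    n_cycles: int = 4
    reads_per_timepoint: int = 500_000
    reference_start_frequency: float = 0.9
    n_replicates: int = 1
    seed: int = 0

    def __post_init__(self):
        self.true_fitness = pd.Series(self.true_fitness, dtype=float)
        self.neutral_ids = frozenset(self.neutral_ids)
        if self.reads_per_timepoint <= 0:
            raise ValueError("reads_per_timepoint must be positive")
        if not self.neutral_ids:
            raise ValueError("at least one neutral lineage is required")
        if not self.neutral_ids <= set(self.true_fitness.index):
            raise ValueError("neutral_ids must be a subset of lineages")
        if not np.allclose(self.true_fitness[list(self.neutral_ids)], 0.0):
            raise ValueError("neutral lineages must have true_fitness exactly 0")
        if not 0 < self.reference_start_frequency < 1:
            raise ValueError("reference_start_frequency must be in (0, 1)")
        if self.n_cycles < 1 or self.n_replicates < 1:
            raise ValueError("n_cycles and n_replicates must be >= 1")


def expected_frequencies(config: BarSeqSimConfig) -> pd.DataFrame:
    """Deterministic lineage population frequencies at each time-point.

    Per cycle every lineage's frequency is multiplied by exp(true fitness)
    (the reference has fitness 0) and the whole population, reference
    included, is renormalized — so the rising mean fitness of the population
    emerges from the frequency dynamics themselves.  Rows are lineages
    (reference excluded), columns time-points 0..n_cycles; columns do not sum
    to 1 because the reference holds the remaining mass.
    """
    s = config.true_fitness
    freq = np.empty((len(s), config.n_cycles + 1))
    f_lin = (1.0 - config.reference_start_frequency) * np.full(len(s), 1.0 / len(s))
    f_ref = config.reference_start_frequency
    growth = np.exp(s.to_numpy())
    freq[:, 0] = f_lin
    for t in range(1, config.n_cycles + 1):
        f_lin = f_lin * growth
        total = f_lin.sum() + f_ref
        f_lin /= total
        f_ref /= total
        freq[:, t] = f_lin
    return pd.DataFrame(freq, index=s.index, columns=range(config.n_cycles + 1))


def simulate_barcode_experiment(config: BarSeqSimConfig) -> pd.DataFrame:
    """Simulate barcode read counts for each replicate of one experiment.

    Sequencing is modeled as one multinomial bottleneck per time-point over
    the non-reference lineages (probabilities proportional to their expected
    population frequencies); replicates are independent draws.  Growth,
    dilution and PCR noise are not modeled separately — the inference's noise
    model absorbs them.

    Returns a long-format count table with columns
    ``lineage_id, replicate, timepoint, reads``.
    """
    rng = np.random.default_rng(config.seed)
    freq = expected_frequencies(config)
    probs = freq.to_numpy() / freq.to_numpy().sum(axis=0, keepdims=True)
    records = []
    for rep in range(1, config.n_replicates + 1):
        for t in range(config.n_cycles + 1):
            counts = rng.multinomial(config.reads_per_timepoint, probs[:, t])
            records.append(pd.DataFrame({
                "lineage_id": freq.index,
                "replicate": rep,
                "timepoint": t,
                "reads": counts,
            }))
    return pd.concat(records, ignore_index=True)
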