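"""How many phenotypic components are real?

Two complementary rank-selection procedures.  The measurement-noise null
simulates matrices whose entries are pure Gaussian measurement error (per-
entry sd from the noise model), takes the largest singular value of each, and
averages its squared size across simulations; components of the real matrix
explaining less than that fraction of total variation are indistinguishable
from noise.  Bi-cross-validation (the Owen-Perry holdout) splits both mutants
and environments into train/test blocks and predicts the held-out block A
from the complementary blocks as ``A_hat = B pinv(D_k) C``; the k with the
best held-out prediction marks the number of components carrying signal.
"""

from __future__ import annotations

from dataclasses import dataclass, field

import numpy as np
import pandas as pd

from .evaluation import weighted_r2_per_env
from .model import fit_svd, variance_fractions

__all__ = [
    "TrainTestSplit",
    "DetectionResult",
    "make_training_split",
    "simulate_noise_threshold",
    "detect_components",
    "detect_dimension",
    "bicv_predict",
    "predict_environments",
    "loo_environment_bicv",
]


@dataclass
class TrainTestSplit:
    """Mutation-type-balanced division of mutants."""

    train: list
    test: list
    per_type: pd.DataFrame | None = field(default=None, repr=False)


def make_training_split(types: pd.Series, seed: int = 0,
                        max_train: int = 20) -> TrainTestSplit:
    """Assign half of each mutation type to training, capped per type.

    Per type the training count is ``min(floor(size/2), max_train)`` drawn
    uniformly without replacement; types represented by a single mutant go
    entirely to the test set.
    """
    rng = np.random.default_rng(seed)
    train, rows = [], []
    for t in sorted(types.unique()):
        members = sorted(types.index[types == t])
        n_train = min(len(members) // 2, max_train)
        chosen = sorted(rng.choice(members, size=n_train, replace=False))
        train.extend(chosen)
        rows.append((t, len(members), n_train))
    train_set = set(train)
    test = [m for m in types.index if m not in train_set]
    per_type = pd.DataFrame(rows, columns=["type", "size", "n_train"])
    return TrainTestSplit(train=sorted(train), test=test, per_type=per_type)


@dataclass
class DetectionResult:
    """Variance fractions, noise threshold, and the detected component count."""

    fractions: np.ndarray
    threshold: float
    n_detected: int


def simulate_noise_threshold(errors, total_sq: float, n_sims: int = 1000,
                             seed=None, statistic: str = "largest"):
    """Detection threshold as a fraction of the real matrix's total variation.

    Simulates ``n_sims`` matrices with independent N(0, errors_ij^2) entries.
    With ``statistic="largest"`` (default) the threshold is the mean squared
    largest singular value across simulations divided by ``total_sq`` (the
    squared Frobenius norm of the real matrix).  ``statistic="per_rank"``
    instead returns the full vector of mean squared singular values by rank,
    divided by ``total_sq``.
    """
    if n_sims <= 0:
        raise ValueError("n_sims must be positive")
    if total_sq <= 0:
        raise ValueError("total_sq must be positive")
    E = np.asarray(errors, dtype=float)
    if np.any(E < 0):
        raise ValueError("errors must be non-negative")
    rng = seed if isinstance(seed, np.random.Generator) \
        else np.random.default_rng(seed)
    if not E.any():
        return (0.0 if statistic == "largest"
                else np.zeros(min(E.shape)))
    acc = np.zeros(min(E.shape))
    for _ in range(n_sims):
        noise = rng.standard_normal(E.shape) * E
        sv = np.linalg.svd(noise, compute_uv=False)
        acc += sv**2
    acc /= n_sims
    if statistic == "largest":
        return float(acc[0] / total_sq)
    if statistic == "per_rank":
        return acc / total_sq
    raise ValueError(f"unknown statistic {statistic!r}")


def detect_components(fractions, threshold) -> int:
    """Count of leading variance fractions strictly above the threshold.

    ``threshold`` may be a scalar (largest-noise-component reading) or a
    per-rank vector; detection stops at the first component at or below its
    threshold, so the detected components are contiguous from component 1.
    """
    fractions = np.asarray(fractions, dtype=float)
    thr = np.broadcast_to(np.asarray(threshold, dtype=float), fractions.shape)
    above = fractions > thr
    n = 0
    for flag in above:
        if not flag:
            break
        n += 1
    return n


def detect_dimension(F, errors, n_sims: int = 1000, seed=None) -> DetectionResult:
    """Full detection: SVD variance fractions vs. the simulated noise null."""
    A = F.to_numpy(dtype=float) if isinstance(F, pd.DataFrame) else np.asarray(F, float)
    model = fit_svd(A)
    fractions, _ = variance_fractions(model)
    total_sq = float((A**2).sum())
    threshold = simulate_noise_threshold(
        errors.to_numpy() if isinstance(errors, pd.DataFrame) else errors,
        total_sq, n_sims=n_sims, seed=seed)
    return DetectionResult(fractions=fractions, threshold=threshold,
                           n_detected=detect_components(fractions, threshold))


def _truncated_pinv(D: np.ndarray, k: int) -> np.ndarray:
    """Moore-Penrose inverse of the rank-k truncation of D, built directly
    from the k retained SVD triples (exact for the rank-k object)."""
    if not 1 <= k <= min(D.shape):
        raise ValueError(f"k must be in [1, {min(D.shape)}], got {k}")
    U, s, Vt = np.linalg.svd(D, full_matrices=False)
    # drop numerically zero singular values inside the truncation
    tol = max(D.shape) * np.finfo(float).eps * (s[0] if len(s) else 0.0)
    r = min(k, int((s > tol).sum()))
    if r == 0:
        return np.zeros((D.shape[1], D.shape[0]))
    return (Vt[:r].T / s[:r]) @ U[:, :r].T


def bicv_predict(F: pd.DataFrame, split: TrainTestSplit, test_envs,
                 k: int, train_envs=None) -> pd.DataFrame:
    """Predict the held-out block A (test mutants x test environments).

    ``A_hat = B pinv(D_k) C`` where D is train mutants x train environments,
    B test mutants x train environments, and C train mutants x test
    environments — equivalent to sequentially least-squares-fitting the test
    environments' weights and test mutants' coordinates against the first k
    training components.
    """
    test_envs = list(test_envs)
    if train_envs is None:
        train_envs = [e for e in F.columns if e not in set(test_envs)]
    train_envs = list(train_envs)
    D = F.loc[split.train, train_envs].to_numpy(dtype=float)
    B = F.loc[split.test, train_envs].to_numpy(dtype=float)
    C = F.loc[split.train, test_envs].to_numpy(dtype=float)
    A_hat = B @ _truncated_pinv(D, k) @ C
    return pd.DataFrame(A_hat, index=split.test, columns=test_envs)


def predict_environments(F: pd.DataFrame, train_envs, target_envs,
                         split: TrainTestSplit, k: int) -> pd.DataFrame:
    """Predict test mutants in target environments from training columns."""
    return bicv_predict(F, split, test_envs=list(target_envs), k=k,
                        train_envs=list(train_envs))


def loo_environment_bicv(F: pd.DataFrame, subtle_envs, split: TrainTestSplit,
                         k_range, type_counts: pd.Series) -> pd.DataFrame:
    """Leave-one-environment-out bi-cross-validation over the subtle set.

    Each subtle environment in turn is the testing environment with the
    remaining ones as training columns; the held-out block (test mutants x
    that environment) is predicted for every k and scored with the per-
    environment mutation-type-weighted R^2.

    Returns long-format rows ``(held_out_env, k, weighted_r2)``.
    """
    subtle_envs = list(subtle_envs)
    if len(subtle_envs) < 2:
        raise ValueError("need at least 2 subtle environments")
    rows = []
    for env in subtle_envs:
        train_envs = [e for e in subtle_envs if e != env]
        obs = F.loc[split.test, [env]]
        for k in k_range:
            A_hat = bicv_predict(F, split, test_envs=[env], k=k,
                                 train_envs=train_envs)
            r2 = weighted_r2_per_env(obs, A_hat, type_counts)
            rows.append((env, int(k), float(r2.iloc[0])))
    return pd.DataFrame(rows, columns=["held_out_env", "k", "weighted_r2"])
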