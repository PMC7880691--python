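"""Mutation-type-weighted scoring and component/mutant attribution.

Because mutation types are wildly unbalanced (e.g. diploids dominating the
collection), an unweighted coefficient of determination mostly measures the
ability to predict the most common type.  The weighted R^2 used throughout
down-weights each mutant's squared error by the number of mutants sharing its
mutation type, so each *type* contributes equally.  It reduces to ordinary
R^2 when every type has one member, and can be negative when a model predicts
worse than the scope mean.
"""

from __future__ import annotations

import numpy as np
import pandas as pd

__all__ = [
    "weighted_r2",
    "weighted_r2_per_env",
    "component_improvement",
    "minor_component_share",
    "mutant_improvement",
    "robustness_env_subsample",
    "robustness_type_subsample",
]


def _type_weights(index, type_counts: pd.Series) -> np.ndarray:
    n = type_counts.reindex(index).to_numpy(dtype=float)
    if np.isnan(n).any():
        raise ValueError("missing type counts for some mutants")
    return 1.0 / n


def weighted_r2(observed: pd.DataFrame, predicted: pd.DataFrame,
                type_counts: pd.Series) -> float:
    """Overall mutation-type-weighted R^2 across all mutants and conditions.

    ``1 - sum_ij w_i (f_ij - fhat_ij)^2 / sum_ij w_i (f_ij - fbar)^2`` with
    ``w_i = 1/n_type(i)`` and ``fbar`` the plain (unweighted) mean of the
    observed values over the whole scope.
    """
    obs = pd.DataFrame(observed)
    pred = pd.DataFrame(predicted).reindex(index=obs.index, columns=obs.columns)
    w = _type_weights(obs.index, type_counts)[:, None]
    fbar = float(obs.to_numpy().mean())
    num = float((w * (obs.to_numpy() - pred.to_numpy()) ** 2).sum())
    den = float((w * (obs.to_numpy() - fbar) ** 2).sum())
    if den == 0:
        raise ZeroDivisionError("constant observed values: R^2 undefined")
    return 1.0 - num / den


def weighted_r2_per_env(observed: pd.DataFrame, predicted: pd.DataFrame,
                        type_counts: pd.Series) -> pd.Series:
    """Per-environment weighted R^2, with the scope mean taken per column."""
    obs = pd.DataFrame(observed)
    pred = pd.DataFrame(predicted).reindex(index=obs.index, columns=obs.columns)
    w = _type_weights(obs.index, type_counts)
    out = {}
    for env in obs.columns:
        o = obs[env].to_numpy()
        p = pred[env].to_numpy()
        den = float((w * (o - o.mean()) ** 2).sum())
        if den == 0:
            raise ZeroDivisionError(f"constant observed column {env!r}")
        out[env] = 1.0 - float((w * (o - p) ** 2).sum()) / den
    return pd.Series(out, name="weighted_r2")


def component_improvement(per_k_r2: pd.DataFrame) -> pd.DataFrame:
    """Per-component improvement Delta R^2(k) = R^2(k) - R^2(k-1).

    ``per_k_r2`` is environments x k (columns are consecutive component
    counts).  The improvement for the smallest k is taken from an implicit
    zero-component baseline of R^2 = 0 (predicting the scope mean).
    """
    ks = sorted(per_k_r2.columns)
    delta = per_k_r2[ks].diff(axis=1)
    delta[ks[0]] = per_k_r2[ks[0]]
    return delta[ks]


def minor_component_share(r2_full: float, r2_major: float) -> float:
    """Share of a model's explanatory power due to its minor components,
    ``(R2_full - R2_major) / R2_full`` (e.g. full = 8, major = 5 components).
    Undefined (NaN) when the full model explains nothing positive."""
    if r2_full <= 0:
        return float("nan")
    return (r2_full - r2_major) / r2_full


def mutant_improvement(f_hat_k, f_hat_km1, f_obs, eps,
                       literal: bool = False):
    """Improvement from component k for one mutant/environment, in error SDs.

    Default: the reduction in absolute prediction error,
    ``(|fhat_{k-1} - f| - |fhat_k - f|) / eps`` — positive when component k
    moves the prediction toward the measurement.  ``literal=True`` computes
    the raw signed difference ``(fhat_{k-1} - fhat_k) / eps`` instead.
    """
    f_hat_k = np.asarray(f_hat_k, dtype=float)
    f_hat_km1 = np.asarray(f_hat_km1, dtype=float)
    f_obs = np.asarray(f_obs, dtype=float)
    eps = np.asarray(eps, dtype=float)
    if np.any(eps <= 0):
        raise ValueError("eps must be positive")
    if literal:
        return (f_hat_km1 - f_hat_k) / eps
    return (np.abs(f_hat_km1 - f_obs) - np.abs(f_hat_k - f_obs)) / eps


def robustness_env_subsample(F: pd.DataFrame, errors: pd.DataFrame,
                             subtle_envs, strong_envs, split, type_counts,
                             sizes, reps: int = 25, seed: int = 0,
                             n_noise_sims: int = 200,
                             k_predict: int | None = None) -> pd.DataFrame:
    """Rebuild the model on random subsets of the subtle environments.

    For each subset size and repetition: refit the SVD on the training
    mutants over the environment subset, re-detect the number of components
    against the noise null, and predict the test mutants in the strong
    environments with ``k = n_detected`` (or ``k_predict`` if given), scoring
    with the mean per-environment weighted R^2.

    Returns long-format rows ``(size, rep, n_detected, mean_strong_r2)``.
    """
    from .dimensionality import detect_dimension, predict_environments

    rng = np.random.default_rng(seed)
    subtle_envs = list(subtle_envs)
    strong_envs = list(strong_envs)
    rows = []
    for size in sizes:
        if size > len(subtle_envs):
            raise ValueError(f"subset size {size} exceeds {len(subtle_envs)}")
        seen = set()
        for rep in range(reps):
            subset = tuple(sorted(rng.choice(subtle_envs, size=size,
                                             replace=False)))
            # spec of the sweep: subsets must not repeat (when possible)
            tries = 0
            while subset in seen and tries < 100:
                subset = tuple(sorted(rng.choice(subtle_envs, size=size,
                                                 replace=False)))
                tries += 1
            seen.add(subset)
            sub = list(subset)
            det = detect_dimension(F.loc[split.train, sub],
                                   errors.loc[split.train, sub],
                                   n_sims=n_noise_sims,
                                   seed=int(rng.integers(2**31)))
            k = k_predict if k_predict is not None else max(det.n_detected, 1)
            k = min(k, min(len(split.train), len(sub)))
            A_hat = predict_environments(F, sub, strong_envs, split, k)
            r2 = weighted_r2_per_env(F.loc[split.test, strong_envs], A_hat,
                                     type_counts)
            rows.append((size, rep, det.n_detected, float(r2.mean())))
    return pd.DataFrame(rows, columns=["size", "rep", "n_detected",
                                       "mean_strong_r2"])


def robustness_type_subsample(F: pd.DataFrame, types: pd.Series,
                              subtle_envs, strong_envs, split, type_counts,
                              n_types_list, reps: int = 25, seed: int = 0,
                              k: int = 8) -> pd.DataFrame:
    """Restrict the training set to random subsets of mutation types.

    For each requested number of types, sample that many types (from those
    present in the training set), keep only training mutants of those types,
    rebuild, and predict the test mutants in the strong environments with a
    fixed k (capped by the reduced matrix).  ``n_types_list`` may include the
    string ``"loo"`` to run leave-one-type-out.

    Returns rows ``(n_types, rep, excluded_type, mean_strong_r2)``.
    """
    from .dimensionality import TrainTestSplit, predict_environments

    rng = np.random.default_rng(seed)
    train_types = sorted(types.loc[split.train].unique())
    rows = []
    for spec in n_types_list:
        if spec == "loo":
            for left_out in train_types:
                keep = [t for t in train_types if t != left_out]
                sub_train = [m for m in split.train if types[m] in set(keep)]
                sub = TrainTestSplit(train=sub_train, test=split.test)
                kk = min(k, len(sub_train), len(list(subtle_envs)))
                A_hat = predict_environments(F, list(subtle_envs),
                                             list(strong_envs), sub, kk)
                r2 = weighted_r2_per_env(F.loc[split.test, list(strong_envs)],
                                         A_hat, type_counts)
                rows.append((len(keep), 0, left_out, float(r2.mean())))
        else:
            n = int(spec)
            for rep in range(reps):
                keep = list(rng.choice(train_types, size=n, replace=False))
                sub_train = [m for m in split.train if types[m] in set(keep)]
                sub = TrainTestSplit(train=sub_train, test=split.test)
                kk = min(k, len(sub_train), len(list(subtle_envs)))
                A_hat = predict_environments(F, list(subtle_envs),
                                             list(strong_envs), sub, kk)
                r2 = weighted_r2_per_env(F.loc[split.test, list(strong_envs)],
                                         A_hat, type_counts)
                rows.append((n, rep, "", float(r2.mean())))
    return pd.DataFrame(rows, columns=["n_types", "rep", "excluded_type",
                                       "mean_strong_r2"])
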