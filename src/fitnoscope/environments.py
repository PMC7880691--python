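"""Classification of environments as subtle or strong perturbations.

The benchmark for "subtle" is the batch-to-batch variation of repeated
fitness assays in the evolution condition (EC batches).  For each mutant the
typical spread of its fitness across EC batches defines a per-mutant scale;
an environment's Z-score is the mutation-type-weighted average of each
mutant's deviation from its EC mean in units of that scale.  Environments
with Z below a threshold (2 by default) perturb fitness no more than EC
batch effects do and are called subtle; the rest are strong.
"""

from __future__ import annotations

import warnings
from dataclasses import dataclass

import numpy as np
import pandas as pd

__all__ = [
    "ECReferenceStats",
    "ec_reference_stats",
    "weighted_z_score",
    "classify_environments",
]


@dataclass
class ECReferenceStats:
    """Per-mutant EC-batch reference statistics.

    ``fbar`` is the mean fitness over EC batches; ``sigma`` the mean absolute
    deviation around it (an SD variant is available via ``stat="sd"`` in
    :func:`ec_reference_stats`); ``n_batches`` the number of EC batches used.
    """

    fbar: pd.Series
    sigma: pd.Series
    n_batches: int


def ec_reference_stats(F_ec: pd.DataFrame, stat: str = "mad") -> ECReferenceStats:
    """Reference statistics from the fitness matrix restricted to EC batches.

    Parameters
    ----------
    F_ec : mutants x EC-batch fitness submatrix (>= 2 columns).
    stat : "mad" for the mean absolute deviation around the batch mean
        (default), "sd" for the sample standard deviation.
    """
    if F_ec.shape[1] < 2:
        raise ValueError("need at least 2 EC-batch columns")
    complete = F_ec.dropna(axis=0)
    if len(complete) < len(F_ec):
        warnings.warn(
            f"{len(F_ec) - len(complete)} mutants missing in some EC batch; "
            "excluded from reference statistics")
    fbar = complete.mean(axis=1)
    if stat == "mad":
        sigma = complete.sub(fbar, axis=0).abs().mean(axis=1)
    elif stat == "sd":
        sigma = complete.std(axis=1, ddof=1)
    else:
        raise ValueError(f"unknown stat {stat!r}")
    return ECReferenceStats(fbar=fbar, sigma=sigma, n_batches=F_ec.shape[1])


def weighted_z_score(f_col: pd.Series, stats: ECReferenceStats,
                     type_counts: pd.Series, normalize: bool = True) -> float:
    """Mutation-type-weighted Z-score of one environment column.

    Each mutant contributes ``|f_ij - fbar_i| / sigma_i`` down-weighted by
    the number of mutants sharing its mutation type, so every type counts
    equally.  With ``normalize`` (default) the weighted sum is divided by the
    sum of weights, making the score an average deviation in units of
    EC-batch spread; ``normalize=False`` gives the raw weighted sum.

    Mutants with ``sigma == 0`` would carry infinite weight and are excluded
    with a warning (they can occur on noiseless synthetic data).
    """
    idx = f_col.index.intersection(stats.fbar.index)
    missing = f_col.index.difference(idx)
    if len(missing):
        raise ValueError(f"no EC reference stats for mutants: {list(missing)[:5]}")
    sigma = stats.sigma.loc[idx]
    usable = sigma > 0
    if not usable.all():
        warnings.warn(f"{(~usable).sum()} mutants with zero EC-batch spread "
                      "excluded from Z-score")
    idx = idx[usable]
    if len(idx) == 0:
        raise ValueError("no usable mutants for Z-score (all sigma == 0)")
    n_type = type_counts.loc[idx].astype(float)
    dev = (f_col.loc[idx] - stats.fbar.loc[idx]).abs() / stats.sigma.loc[idx]
    z = float((dev / n_type).sum())
    if normalize:
        z /= float((1.0 / n_type).sum())
    return z


def classify_environments(F: pd.DataFrame, stats: ECReferenceStats,
                          type_counts: pd.Series, ec_batches,
                          threshold: float = 2.0,
                          normalize: bool = True) -> pd.DataFrame:
    """Label every environment subtle or strong by its weighted Z-score.

    Non-EC environments are subtle iff ``z < threshold`` (strictly), strong
    otherwise.  EC batches are subtle by definition; their reported z is the
    leave-that-batch-out score against the remaining batches, a diagnostic
    expected to be of order 1.

    Returns a DataFrame indexed by environment with columns
    ``z, label, is_ec_batch``.
    """
    ec_batches = [e for e in F.columns if e in set(ec_batches)]
    rows = []
    for env in F.columns:
        if env in ec_batches:
            others = [e for e in ec_batches if e != env]
            loo_stats = ec_reference_stats(F[others]) if len(others) >= 2 else stats
            z = weighted_z_score(F[env], loo_stats, type_counts, normalize)
            rows.append((env, z, "subtle", True))
        else:
            z = weighted_z_score(F[env], stats, type_counts, normalize)
            label = "subtle" if z < threshold else "strong"
            rows.append((env, z, label, False))
    return pd.DataFrame(rows, columns=["environment", "z", "label",
                                       "is_ec_batch"]).set_index("environment")
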