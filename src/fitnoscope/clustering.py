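"""Do mutants of the same gene cluster in phenotype space?

Annotation-defined groups (e.g. all nonsense mutants of one gene) are tested
for tightness with a permutation test on the median pairwise Euclidean
distance: the observed median is compared to 10,000 same-size random subsets
of an eligible pool.  The median, not the mean, is used so a single outlier
mutant cannot mask an otherwise tight cluster.  UMAP is only a visualization
aid — all statistics are computed in the original component space.
"""

from __future__ import annotations

from dataclasses import dataclass

import numpy as np
import pandas as pd
from scipy.spatial.distance import pdist

__all__ = [
    "ClusterTestResult",
    "median_pairwise_distance",
    "cluster_permutation_test",
    "embed_umap",
]


def median_pairwise_distance(coords) -> float:
    """Median of all pairwise Euclidean distances among >= 2 points."""
    X = np.asarray(coords, dtype=float)
    if X.ndim != 2 or X.shape[0] < 2:
        raise ValueError("need at least 2 points")
    return float(np.median(pdist(X)))


@dataclass
class ClusterTestResult:
    group: str
    size: int
    observed: float
    n_perm: int
    p_value: float


def cluster_permutation_test(coords: pd.DataFrame, group_ids, pool_ids,
                             n_perm: int = 10_000, seed: int = 0,
                             group_label: str = "") -> ClusterTestResult:
    """Empirical p-value for a group being tighter than random same-size sets.

    Null sets are drawn (without replacement within a draw) from ``pool_ids``
    — callers should exclude strains whose only mutation is diploidy, since
    their sheer abundance would dominate random draws.  The p-value uses the
    add-one correction ``(1 + #{null <= observed}) / (1 + n_perm)``, so its
    floor with 10,000 draws is ~0.0001.
    """
    group_ids = list(group_ids)
    pool_ids = list(pool_ids)
    if len(group_ids) > len(pool_ids):
        raise ValueError("group size exceeds pool size")
    if len(group_ids) < 2:
        raise ValueError("group must have at least 2 members")
    X = coords.loc[group_ids].to_numpy(dtype=float)
    observed = float(np.median(pdist(X)))
    pool = coords.loc[pool_ids].to_numpy(dtype=float)
    rng = np.random.default_rng(seed)
    m = len(group_ids)
    hits = 0
    for _ in range(n_perm):
        idx = rng.choice(len(pool), size=m, replace=False)
        if np.median(pdist(pool[idx])) <= observed:
            hits += 1
    p = (1 + hits) / (1 + n_perm)
    return ClusterTestResult(group=group_label or str(group_ids[:1]),
                             size=m, observed=observed,
                             n_perm=n_perm, p_value=p)


def embed_umap(coords: pd.DataFrame, n_neighbors: int = 20,
               seed: int = 0) -> pd.DataFrame:
    """2-D UMAP embedding of mutant phenotype coordinates (visualization
    only).  Deterministic for a fixed seed."""
    X = coords.to_numpy(dtype=float)
    if X.shape[0] < n_neighbors + 1:
        raise ValueError(
            f"need at least n_neighbors+1={n_neighbors + 1} points, "
            f"got {X.shape[0]}")
    import umap  # deferred: heavy numba import

    reducer = umap.UMAP(n_neighbors=n_neighbors, n_components=2,
                        random_state=seed)
    emb = reducer.fit_transform(X)
    return pd.DataFrame(emb, index=coords.index, columns=["umap1", "umap2"])
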