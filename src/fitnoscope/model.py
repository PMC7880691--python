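"""SVD decomposition of the mutant x environment fitness matrix.

The fitness matrix F is modeled as F = P Sigma E^T: each mutant is a point in
an abstract phenotype space (rows of P), each environment a vector of weights
saying how much each phenotype contributes to fitness there (columns of E),
and fitness is their inner product.  The decomposition is a plain thin SVD —
no centering and no scaling, because the reference strain (relative fitness 0
everywhere) defines a meaningful origin and the first component deliberately
captures each mutant's average fitness.  By the Eckart-Young theorem the
first k components form the best rank-k linear model of the data.
"""

from __future__ import annotations

from dataclasses import dataclass, field

import numpy as np
import pandas as pd

__all__ = [
    "PhenotypeModel",
    "fit_svd",
    "variance_fractions",
    "reconstruct_rank_k",
    "predict_fitness",
    "project_rows",
]


@dataclass
class PhenotypeModel:
    """Thin SVD factors of a fitness matrix.

    ``U`` (mutants x r) and ``Vt`` (r x environments) have orthonormal
    columns/rows; ``s`` holds the non-increasing singular values.  By the
    default reporting convention the singular values are folded into the
    environment weights, so mutant coordinates are rows of U and environment
    weights are ``diag(s) @ Vt``.
    """

    U: np.ndarray
    s: np.ndarray
    Vt: np.ndarray
    mutant_ids: list = field(default_factory=list)
    env_ids: list = field(default_factory=list)
    fold: str = "env"  # where the singular values go when reporting

    @property
    def k_max(self) -> int:
        return len(self.s)

    def mutant_coords(self, k: int | None = None) -> pd.DataFrame:
        k = self.k_max if k is None else k
        cols = [f"PC{i+1}" for i in range(k)]
        M = self.U[:, :k] if self.fold == "env" else self.U[:, :k] * self.s[:k]
        return pd.DataFrame(M, index=self.mutant_ids, columns=cols)

    def env_weights(self, k: int | None = None) -> pd.DataFrame:
        k = self.k_max if k is None else k
        cols = [f"PC{i+1}" for i in range(k)]
        W = self.Vt[:k] * self.s[:k, None] if self.fold == "env" else self.Vt[:k]
        return pd.DataFrame(W.T, index=self.env_ids, columns=cols)


def fit_svd(F) -> PhenotypeModel:
    """Thin SVD of the fitness matrix with a deterministic sign convention.

    Accepts a DataFrame (labels preserved) or ndarray.  Neither rows nor
    columns are centered or scaled.  Each left-singular vector is flipped so
    its largest-magnitude entry is positive, which pins factor signs across
    platforms and runs.
    """
    if isinstance(F, pd.DataFrame):
        mutant_ids, env_ids = list(F.index), list(F.columns)
        A = F.to_numpy(dtype=float)
    else:
        A = np.asarray(F, dtype=float)
        mutant_ids = list(range(A.shape[0])) if A.size else []
        env_ids = list(range(A.shape[1])) if A.size else []
    if A.size == 0:
        raise ValueError("empty fitness matrix")
    if np.isnan(A).any():
        raise ValueError("fitness matrix has missing entries; analyze a "
                         "complete submatrix")
    U, s, Vt = np.linalg.svd(A, full_matrices=False)
    for i in range(len(s)):
        j = np.argmax(np.abs(U[:, i]))
        if U[j, i] < 0:
            U[:, i] = -U[:, i]
            Vt[i, :] = -Vt[i, :]
    return PhenotypeModel(U=U, s=s, Vt=Vt,
                          mutant_ids=mutant_ids, env_ids=env_ids)


def variance_fractions(model: PhenotypeModel):
    """Fraction of total squared variation per component.

    Returns ``(total, excluding_first)``: ``total[k] = s_k^2 / sum(s^2)`` and
    ``excluding_first`` renormalizes components 2..r, the convention used to
    report the relative sizes of the genotype-by-environment interaction
    components next to a dominant first component.
    """
    sq = model.s**2
    total = sq / sq.sum()
    rest = sq[1:]
    excl = rest / rest.sum() if rest.sum() > 0 else np.zeros_like(rest)
    return total, excl


def reconstruct_rank_k(model: PhenotypeModel, k: int) -> np.ndarray:
    """Best rank-k approximation of F (Eckart-Young optimal)."""
    if not 1 <= k <= model.k_max:
        raise ValueError(f"k must be in [1, {model.k_max}], got {k}")
    return (model.U[:, :k] * model.s[:k]) @ model.Vt[:k]


def predict_fitness(p_row, e_col) -> float:
    """Fitness of a mutant in an environment: inner product of coordinates
    with weights.  The reference strain sits at the origin and maps to 0."""
    p = np.asarray(p_row, dtype=float)
    e = np.asarray(e_col, dtype=float)
    if p.shape != e.shape:
        raise ValueError(f"length mismatch: {p.shape} vs {e.shape}")
    return float(p @ e)


def project_rows(new_rows, model: PhenotypeModel, k: int):
    """Least-squares phenotype coordinates for new mutants.

    Environment weights of the first k components are held fixed and each new
    fitness row (over the model's training environments) is regressed onto
    them.  With the default fold convention the recovered coordinates live on
    the same scale as ``model.U``: a training mutant's own noiseless rank-k
    row maps back to its truncated U row exactly.

    Returns ``(coords, residual_norms)``.
    """
    if not 1 <= k <= model.k_max:
        raise ValueError(f"k must be in [1, {model.k_max}], got {k}")
    if isinstance(new_rows, pd.DataFrame):
        ids = list(new_rows.index)
        R = new_rows.to_numpy(dtype=float)
    else:
        R = np.atleast_2d(np.asarray(new_rows, dtype=float))
        ids = list(range(R.shape[0]))
    if R.shape[1] != len(model.env_ids):
        raise ValueError("new rows must span the model's environments")
    W = model.s[:k, None] * model.Vt[:k]  # k x n_envs, sigma folded into E
    coords, *_ = np.linalg.lstsq(W.T, R.T, rcond=None)
    resid = np.linalg.norm(R - coords.T @ W, axis=1)
    cols = [f"PC{i+1}" for i in range(k)]
    return (pd.DataFrame(coords.T, index=ids, columns=cols),
            pd.Series(resid, index=ids, name="residual"))
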