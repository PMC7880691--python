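"""Relative fitness inference from barcode count trajectories.

The estimator follows the standard pooled-competition logic: for each lineage
and each pair of consecutive retained time-points, the log-frequency change
is an estimate of fitness relative to the (mostly unsequenced) reference
strain once it is corrected by the mean fitness of the population.  The mean
fitness correction is inferred from lineages known to be neutral: since a
neutral lineage's true fitness is zero, the decline of the pooled neutral
frequency measures how fast the population mean is rising.  Pairwise
estimates are then combined by inverse-variance weighting under a two-part
noise model — a read-depth term that scales like counting noise, and a
frequency-independent additive term fit from between-replicate scatter.

Fitness is reported per transfer cycle; positive values mean the lineage
outcompetes the reference.
"""

from __future__ import annotations

import warnings
from dataclasses import dataclass

import numpy as np
import pandas as pd
from scipy.special import erf

__all__ = [
    "EmptyExperimentError",
    "UndefinedPairError",
    "CannotFitNoiseError",
    "NoiseModelParams",
    "qc_filter_timepoints",
    "estimate_mean_fitness",
    "pairwise_fitness",
    "fit_noise_model",
    "combine_pairwise",
    "merge_replicates",
    "identify_neutrals",
    "calibrate_against_identical_lineages",
    "infer_fitness",
]

COUNT_COLUMNS = ("lineage_id", "replicate", "timepoint", "reads")


class EmptyExperimentError(RuntimeError):
    """All time-points of an experiment were removed by QC."""


class UndefinedPairError(RuntimeError):
    """A time-point pair has zero pooled neutral counts."""


class CannotFitNoiseError(RuntimeError):
    """Too few neutral lineages with usable pairs to fit the noise model."""


def _check_counts(counts: pd.DataFrame) -> None:
    missing = set(COUNT_COLUMNS) - set(counts.columns)
    if missing:
        raise ValueError(f"count table is missing columns: {sorted(missing)}")
    if (counts["reads"] < 0).any():
        raise ValueError("read counts must be non-negative")


def qc_filter_timepoints(counts: pd.DataFrame, min_reads: int = 2500,
                         min_lineages: int = 400) -> pd.DataFrame:
    """Drop (replicate, timepoint) groups with too few reads or lineages.

    A time-point is retained when it has at least ``min_reads`` mapped reads
    and at least ``min_lineages`` lineages with nonzero counts.  Downstream
    estimates use pairs of consecutive *retained* time-points only.
    """
    _check_counts(counts)
    grouped = counts.groupby(["replicate", "timepoint"])["reads"]
    totals = grouped.sum()
    n_lineages = grouped.apply(lambda r: int((r > 0).sum()))
    keep = totals[(totals >= min_reads) & (n_lineages >= min_lineages)].index
    if len(keep) == 0:
        raise EmptyExperimentError(
            "no time-point passed QC "
            f"(min_reads={min_reads}, min_lineages={min_lineages})")
    idx = pd.MultiIndex.from_frame(counts[["replicate", "timepoint"]])
    return counts[idx.isin(keep)].reset_index(drop=True)


def _pivot(counts: pd.DataFrame, replicate) -> pd.DataFrame:
    sub = counts[counts["replicate"] == replicate]
    mat = sub.pivot_table(index="lineage_id", columns="timepoint",
                          values="reads", aggfunc="sum", fill_value=0)
    return mat[sorted(mat.columns)]


def estimate_mean_fitness(counts: pd.DataFrame, neutral_ids) -> pd.DataFrame:
    """Mean-fitness correction per time-point pair from pooled neutral reads.

    For each pair of consecutive retained time-points (t0, t1) the correction
    is ``xbar = -ln(nu1 / nu0) / (t1 - t0)`` where ``nu`` is the pooled
    frequency of the neutral lineages (summed reads over total reads); the
    gap division keeps units per cycle when a QC'd time-point is skipped.

    Returns a DataFrame with columns ``replicate, t0, t1, mean_fitness``.
    """
    _check_counts(counts)
    neutral_ids = set(neutral_ids)
    rows = []
    for rep in sorted(counts["replicate"].unique()):
        mat = _pivot(counts, rep)
        tps = list(mat.columns)
        total = mat.sum(axis=0)
        neut = mat.loc[mat.index.isin(neutral_ids)].sum(axis=0)
        for t0, t1 in zip(tps[:-1], tps[1:]):
            if neut[t0] == 0 or neut[t1] == 0:
                raise UndefinedPairError(
                    f"zero pooled neutral counts in replicate {rep} "
                    f"pair ({t0}, {t1})")
            ratio = (neut[t1] / total[t1]) / (neut[t0] / total[t0])
            rows.append((rep, t0, t1, -np.log(ratio) / (t1 - t0)))
    return pd.DataFrame(rows, columns=["replicate", "t0", "t1", "mean_fitness"])


def pairwise_fitness(counts: pd.DataFrame, meanfit: pd.DataFrame) -> pd.DataFrame:
    """Per-lineage, per-pair fitness estimates (per cycle).

    ``s = ln(f1/f0) / (t1 - t0) + xbar`` with ``f = reads / total reads``.
    Pairs where the lineage has a zero count at either end are omitted (no
    pseudocount: sparse pairs are handled by the inverse-variance weights).

    The returned frame carries the read counts and the read-depth weight
    ``w = (1/r0 + 1/r1) / (t1-t0)^2`` used by the noise model.
    """
    _check_counts(counts)
    key = meanfit.set_index(["replicate", "t0"])
    frames = []
    for rep in sorted(counts["replicate"].unique()):
        mat = _pivot(counts, rep)
        total = mat.sum(axis=0)
        tps = list(mat.columns)
        for t0, t1 in zip(tps[:-1], tps[1:]):
            try:
                row = key.loc[(rep, t0)]
            except KeyError:
                continue
            xbar = float(row["mean_fitness"])
            r0, r1 = mat[t0], mat[t1]
            ok = (r0 > 0) & (r1 > 0)
            if not ok.any():
                continue
            dt = t1 - t0
            f0 = r0[ok] / total[t0]
            f1 = r1[ok] / total[t1]
            s = np.log(f1 / f0) / dt + xbar
            frames.append(pd.DataFrame({
                "lineage_id": mat.index[ok],
                "replicate": rep,
                "t0": t0,
                "t1": t1,
                "r0": r0[ok].to_numpy(),
                "r1": r1[ok].to_numpy(),
                "s_pair": s.to_numpy(),
                "w": ((1.0 / r0[ok] + 1.0 / r1[ok]) / dt**2).to_numpy(),
            }))
    if not frames:
        return pd.DataFrame(columns=["lineage_id", "replicate", "t0", "t1",
                                     "r0", "r1", "s_pair", "w"])
    return pd.concat(frames, ignore_index=True)


@dataclass
class NoiseModelParams:
    """Two-part noise model.

    ``kappa`` scales the read-depth variance per (replicate, pair):
    ``var_pair = kappa[rep, t0] * (1/r0 + 1/r1) / dt^2``.  ``c_add`` is the
    frequency-independent additive variance observed between simultaneous
    replicates, added to each per-replicate combined estimate.
    """

    kappa: pd.Series  # indexed by (replicate, t0)
    c_add: float = 0.0

    def var_pair(self, pairs: pd.DataFrame) -> np.ndarray:
        k = self.kappa.reindex(
            pd.MultiIndex.from_frame(pairs[["replicate", "t0"]])).to_numpy()
        if np.isnan(k).any():
            raise KeyError("noise model has no kappa for some pairs")
        return k * pairs["w"].to_numpy()


def fit_noise_model(counts: pd.DataFrame, neutral_ids,
                    min_neutral_pairs: int = 2) -> NoiseModelParams:
    """Fit the two-part noise model from neutral lineages and replicates.

    ``kappa`` per pair is the mean over neutral lineages of ``s^2 / w``
    (unbiased when var = kappa * w and neutral s has mean 0).  ``c_add`` is
    the mean excess of between-replicate variance of high-coverage lineages
    over their read-depth variance, clipped at 0; it is 0 with a single
    replicate.
    """
    meanfit = estimate_mean_fitness(counts, neutral_ids)
    pairs = pairwise_fitness(counts, meanfit)
    neut = pairs[pairs["lineage_id"].isin(set(neutral_ids))]
    kappa = {}
    for (rep, t0), grp in neut.groupby(["replicate", "t0"]):
        if len(grp) < min_neutral_pairs:
            raise CannotFitNoiseError(
                f"fewer than {min_neutral_pairs} neutral lineages with usable "
                f"pairs in replicate {rep} pair starting at {t0}")
        # floor guards the degenerate zero-dispersion case (e.g. literally
        # identical counts) so downstream variances stay positive
        kappa[(rep, t0)] = max(float(np.mean(grp["s_pair"] ** 2 / grp["w"])),
                               1e-12)
    kappa = pd.Series(kappa).rename_axis(["replicate", "t0"])
    noise = NoiseModelParams(kappa=kappa, c_add=0.0)

    reps = counts["replicate"].unique()
    if len(reps) >= 2:
        per_rep = combine_pairwise(pairs, noise)
        coverage = pairs.groupby("lineage_id")["r0"].mean()
        high = coverage[coverage >= coverage.median()].index
        est = per_rep[per_rep["lineage_id"].isin(high)]
        excesses = []
        for _, grp in est.groupby("lineage_id"):
            if len(grp) < 2:
                continue
            excesses.append(grp["fitness"].var(ddof=1)
                            - np.mean(grp["error"] ** 2))
        if excesses:
            noise.c_add = max(0.0, float(np.mean(excesses)))
    return noise


def combine_pairwise(pairs: pd.DataFrame,
                     noise: NoiseModelParams) -> pd.DataFrame:
    """Inverse-variance weighted average of pairwise estimates per replicate.

    Combined variance is ``1 / sum(1/var_pair) + c_add``.  Lineages with no
    usable pairs simply do not appear (callers should treat absence as a
    flagged missing estimate, never as fitness 0).
    """
    if pairs.empty:
        return pd.DataFrame(columns=["lineage_id", "replicate",
                                     "fitness", "error", "n_pairs"])
    pairs = pairs.copy()
    var = noise.var_pair(pairs)
    if np.any(var <= 0):
        raise ValueError("non-positive pairwise variance")
    pairs["_w"] = 1.0 / var
    pairs["_ws"] = pairs["_w"] * pairs["s_pair"]
    g = pairs.groupby(["lineage_id", "replicate"], sort=True)
    wsum = g["_w"].sum()
    out = pd.DataFrame({
        "fitness": g["_ws"].sum() / wsum,
        "error": np.sqrt(1.0 / wsum + noise.c_add),
        "n_pairs": g.size(),
    }).reset_index()
    return out


def merge_replicates(estimates: pd.DataFrame) -> pd.DataFrame:
    """Inverse-variance average of per-replicate estimates per lineage."""
    if estimates.empty:
        return pd.DataFrame(columns=["lineage_id", "fitness", "error",
                                     "n_replicates"])
    est = estimates.copy()
    est["_w"] = 1.0 / est["error"] ** 2
    est["_wf"] = est["_w"] * est["fitness"]
    g = est.groupby("lineage_id", sort=True)
    wsum = g["_w"].sum()
    return pd.DataFrame({
        "fitness": g["_wf"].sum() / wsum,
        "error": np.sqrt(1.0 / wsum),
        "n_replicates": g.size(),
    }).reset_index()


def identify_neutrals(first_pass: pd.DataFrame, high_confidence,
                      z_cut: float = 2.0) -> set:
    """Expand a high-confidence neutral set with neutral-behaving lineages.

    A lineage joins the expanded set when its first-pass fitness (computed
    against the high-confidence neutrals alone) satisfies |f| < z_cut * err.
    The caller re-runs mean-fitness estimation with the expanded set.
    """
    high_confidence = set(high_confidence)
    if not high_confidence:
        raise ValueError("high-confidence neutral set must be non-empty")
    near_zero = first_pass[
        first_pass["fitness"].abs() < z_cut * first_pass["error"]]
    return high_confidence | set(near_zero["lineage_id"])


def calibrate_against_identical_lineages(estimates: pd.DataFrame,
                                         groups) -> pd.DataFrame:
    """Percentile diagnostic from groups of genetically identical lineages.

    For each lineage the deviation from its group's inverse-variance-weighted
    mean is converted to a nominal two-sided Gaussian percentile using the
    deviation's theoretical sd ``sqrt(err_i^2 - 1/W)`` (the subtraction
    accounts for the lineage's own contribution to the group mean).  If the
    noise model is calibrated the percentiles are uniform on [0, 1]; a
    conservative model yields percentiles piling up near 0.
    """
    groups = pd.Series(groups)
    rows = []
    est = estimates.set_index("lineage_id")
    for label, members in groups.groupby(groups):
        ids = [i for i in members.index if i in est.index]
        if len(ids) < 2:
            warnings.warn(f"group {label!r} has fewer than 2 measured members;"
                          " skipped")
            continue
        f = est.loc[ids, "fitness"].to_numpy()
        e = est.loc[ids, "error"].to_numpy()
        w = 1.0 / e**2
        W = w.sum()
        mu = (w * f).sum() / W
        var_dev = np.maximum(e**2 - 1.0 / W, 1e-300)
        z = (f - mu) / np.sqrt(var_dev)
        pct = erf(np.abs(z) / np.sqrt(2.0))
        for i, lid in enumerate(ids):
            rows.append((lid, label, f[i] - mu, z[i], pct[i]))
    return pd.DataFrame(rows, columns=["lineage_id", "group", "deviation",
                                       "z", "percentile"])


def infer_fitness(counts: pd.DataFrame, neutral_ids,
                  min_reads: int = 2500, min_lineages: int = 400,
                  expand_neutrals: bool = False, z_cut: float = 2.0):
    """Full per-experiment inference: counts -> fitness per lineage.

    Runs QC, mean-fitness correction, noise-model fitting, pairwise
    estimation, inverse-variance combination and replicate merging.  With
    ``expand_neutrals`` the whole chain is run twice, the second time with
    the neutral set expanded by lineages whose first-pass fitness is within
    ``z_cut`` errors of zero.

    Returns ``(merged, per_replicate, noise)``.
    """
    counts = qc_filter_timepoints(counts, min_reads, min_lineages)

    def _one_pass(neutrals):
        noise = fit_noise_model(counts, neutrals)
        meanfit = estimate_mean_fitness(counts, neutrals)
        pairs = pairwise_fitness(counts, meanfit)
        per_rep = combine_pairwise(pairs, noise)
        return merge_replicates(per_rep), per_rep, noise

    merged, per_rep, noise = _one_pass(set(neutral_ids))
    if expand_neutrals:
        expanded = identify_neutrals(merged, neutral_ids, z_cut)
        merged, per_rep, noise = _one_pass(expanded)
    return merged, per_rep, noise
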