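#!/usr/bin/env python
"""Bi-cross-validation and out-of-sample prediction.

Splits mutants into a mutation-type-balanced train/test division, runs
leave-one-environment-out bi-cross-validation over the subtle perturbations
for k = 1..10, then predicts the test mutants in the strong perturbations
from all subtle columns, scoring everything with the mutation-type-weighted
R^2.  Also attributes per-component and per-mutant improvements."""

from pathlib import Path

import pandas as pd

from fitnoscope.dimensionality import (loo_environment_bicv,
                                       make_training_split,
                                       predict_environments)
from fitnoscope.evaluation import (component_improvement,
                                   minor_component_share, mutant_improvement,
                                   weighted_r2_per_env)
from fitnoscope.io import read_fitness_with_errors, read_matrix

OUT = Path(__file__).resolve().parent.parent / "results" / "synthetic"
SEED = 17
K_RANGE = range(1, 11)
K_FULL, K_MAJOR = 5, 3


def main() -> None:
    F, errors = read_fitness_with_errors(OUT / "fitness.csv")
    classes = read_matrix(OUT / "environment_classification.csv")
    types = pd.read_csv(OUT / "types.csv", index_col=0).iloc[:, 0]
    counts = types.map(types.value_counts())
    subtle = list(classes.index[classes["label"] == "subtle"])
    strong = list(classes.index[classes["label"] == "strong"])

    split = make_training_split(types, seed=SEED)
    print(f"train/test split: {len(split.train)}/{len(split.test)} mutants "
          f"({types.loc[split.train].nunique()} types in training)")

    bicv = loo_environment_bicv(F, subtle, split, K_RANGE, counts)
    bicv.to_csv(OUT / "bicv_loo.csv", index=False, float_format="%.10g")
    mean_r2 = bicv.groupby("k")["weighted_r2"].mean()
    print("leave-one-out weighted R^2 on held-out subtle environments:")
    for k in (1, K_MAJOR, K_FULL, max(K_RANGE)):
        print(f"  k={k}: {mean_r2[k]:.3f}")

    rows = []
    for k in K_RANGE:
        A_hat = predict_environments(F, subtle, strong, split, k)
        r2 = weighted_r2_per_env(F.loc[split.test, strong], A_hat, counts)
        rows += [(env, k, val) for env, val in r2.items()]
    strong_r2 = pd.DataFrame(rows, columns=["environment", "k",
                                            "weighted_r2"])
    strong_r2.to_csv(OUT / "strong_env_r2.csv", index=False,
                     float_format="%.10g")
    per_k = strong_r2.pivot(index="environment", columns="k",
                            values="weighted_r2")
    print(f"strong-environment predictions (k={K_FULL}): mean weighted R^2 "
          f"{per_k[K_FULL].mean():.3f}, range {per_k[K_FULL].min():.2f}"
          f"-{per_k[K_FULL].max():.2f} (k=1: {per_k[1].mean():.3f})")
    share = [minor_component_share(r_full, r_major)
             for r_full, r_major in zip(per_k[K_FULL], per_k[K_MAJOR])]
    print(f"  mean share of improvement from minor components "
          f"(k>{K_MAJOR}): {pd.Series(share).mean():.2f}")

    delta = component_improvement(per_k)
    delta.to_csv(OUT / "strong_env_delta_r2.csv", float_format="%.10g")

    # per-mutant improvement from the last detected component, in error SDs
    A_k = predict_environments(F, subtle, strong, split, K_FULL)
    A_km1 = predict_environments(F, subtle, strong, split, K_FULL - 1)
    imp = mutant_improvement(A_k.to_numpy(), A_km1.to_numpy(),
                             F.loc[split.test, strong].to_numpy(),
                             errors.loc[split.test, strong].to_numpy())
    imp = pd.DataFrame(imp, index=split.test, columns=strong)
    imp.to_csv(OUT / "mutant_improvement.csv", index_label="mutant",
               float_format="%.10g")
    by_type = imp.mean(axis=1).groupby(types.loc[split.test]).mean()
    print("mean per-type improvement from the last component (error SDs):")
    print("  " + ", ".join(f"{t}: {v:+.1f}"
                           for t, v in by_type.sort_values().items()))


if __name__ == "__main__":
    main()
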