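#!/usr/bin/env python
"""Generate the synthetic study inputs.

Two data sets are produced under results/synthetic/:

1. A barcode competition experiment in a single environment (two replicates,
   five time-points, 100 lineages of which 40 are neutral, sequenced at
   500k reads per time-point against a 90%-frequency unsequenced reference)
   together with the true per-lineage fitnesses.

2. A mutant x environment fitness matrix with known low-rank structure:
   100 mutants in a 5-dimensional phenotype space, organized into unbalanced
   mutation types (each type a tight cluster around a type center inside the
   unit ball centered at (1,0,...,0)); 45 environments = 9 EC batches plus
   16 further subtle perturbations (weight vectors in the 0.1-radius ball
   around (1,...,1)) and 20 strong perturbations (radius-1 ball), with
   Gaussian measurement noise of sd 0.005 recorded in a parallel error
   matrix.
"""

from pathlib import Path

import numpy as np
import pandas as pd

from fitnoscope.io import write_counts, write_fitness_with_errors, write_matrix
from fitnoscope.simulate import (BarSeqSimConfig, sample_uniform_ball,
                                 simulate_barcode_experiment)

OUT = Path(__file__).resolve().parent.parent / "results" / "synthetic"
SEED = 20_260_926
TRUE_DIM = 5
NOISE_SD = 0.005
TYPE_SIZES = {"diploid": 40, "geneA_nonsense": 15, "geneA_missense": 10,
              "geneB": 8, "geneC": 8, "geneD": 6, "geneE": 6,
              "diploid_chr11": 4, "geneF": 2, "geneG_solo": 1}


def main() -> None:
    OUT.mkdir(parents=True, exist_ok=True)
    rng = np.random.default_rng(SEED)

    # --- barcode experiment with known truth --------------------------
    ids = [f"L{i:03d}" for i in range(100)]
    s_true = pd.Series(np.concatenate([np.zeros(40),
                                       rng.uniform(0.1, 1.0, 60)]),
                       index=ids, name="true_fitness")
    cfg = BarSeqSimConfig(true_fitness=s_true,
                          neutral_ids=frozenset(ids[:40]), n_cycles=4,
                          reads_per_timepoint=500_000, n_replicates=2,
                          seed=int(rng.integers(2**31)))
    counts = simulate_barcode_experiment(cfg)
    write_counts(counts, OUT / "counts.tsv")
    s_true.to_csv(OUT / "true_lineage_fitness.csv", index_label="lineage_id")
    (OUT / "neutral_ids.txt").write_text("\n".join(ids[:40]) + "\n")

    # --- typed mutants in phenotype space ------------------------------
    mutant_center = np.zeros(TRUE_DIM)
    mutant_center[0] = 1.0
    rows, labels = [], []
    for t, size in TYPE_SIZES.items():
        center = sample_uniform_ball(TRUE_DIM, mutant_center, 0.85, 1,
                                     seed=rng)[0]
        rows.append(sample_uniform_ball(TRUE_DIM, center, 0.15, size,
                                        seed=rng))
        labels += [t] * size
    P = np.vstack(rows)
    mutants = [f"mut{i:04d}" for i in range(len(labels))]
    types = pd.Series(labels, index=mutants, name="mutation_type")

    # --- environments: EC batches, subtle, strong ----------------------
    env_center = np.ones(TRUE_DIM)
    subtle = sample_uniform_ball(TRUE_DIM, env_center, 0.1, 25, seed=rng)
    strong = sample_uniform_ball(TRUE_DIM, env_center, 1.0, 20, seed=rng)
    E = np.vstack([subtle, strong]).T
    envs = ([f"EC-{b+1}" for b in range(9)]
            + [f"subtle-{j+1}" for j in range(16)]
            + [f"strong-{j+1}" for j in range(20)])

    F_true = P @ E
    F = F_true + rng.normal(0, NOISE_SD, F_true.shape)
    F = pd.DataFrame(F, index=mutants, columns=envs)
    errors = pd.DataFrame(NOISE_SD, index=mutants, columns=envs)

    write_fitness_with_errors(F, errors, OUT / "fitness.csv")
    write_matrix(pd.DataFrame(F_true, index=mutants, columns=envs),
                 OUT / "fitness_true.csv")
    write_matrix(pd.DataFrame(P, index=mutants,
                              columns=[f"phi{i+1}" for i in range(TRUE_DIM)]),
                 OUT / "true_mutant_coords.csv")
    types.to_csv(OUT / "types.csv", index_label="mutant")
    (OUT / "ec_batches.txt").write_text(
        "\n".join(e for e in envs if e.startswith("EC-")) + "\n")

    print(f"wrote inputs to {OUT}")
    print(f"  barcode counts: {counts.shape[0]} rows "
          f"({cfg.n_replicates} replicates x 5 time-points x 100 lineages)")
    print(f"  fitness matrix: {F.shape[0]} mutants x {F.shape[1]} "
          f"environments, true dimension {TRUE_DIM}, noise sd {NOISE_SD}")
    print(f"  mutation types: {types.nunique()} "
          f"(largest {types.value_counts().iloc[0]})")


if __name__ == "__main__":
    main()
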