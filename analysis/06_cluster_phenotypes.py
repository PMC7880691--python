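#!/usr/bin/env python
"""Test whether mutation types cluster in phenotype space.

Coordinates come from the SVD of the training mutants over the subtle
perturbations, with the test mutants projected in by least squares; the
first (average-fitness) component is dropped.  Each mutation type with at
least two members is tested with the median-pairwise-distance permutation
test against 10,000 random same-size draws from the pool of mutants whose
mutation is not plain diploidy.  A 2-D UMAP embedding is written for
visualization only."""

from pathlib import Path

import numpy as np
import pandas as pd

from fitnoscope.clustering import cluster_permutation_test, embed_umap
from fitnoscope.dimensionality import make_training_split
from fitnoscope.io import read_fitness_with_errors, read_matrix
from fitnoscope.model import fit_svd, project_rows

OUT = Path(__file__).resolve().parent.parent / "results" / "synthetic"
SEED = 23
K = 5


def main() -> None:
    F, _ = read_fitness_with_errors(OUT / "fitness.csv")
    classes = read_matrix(OUT / "environment_classification.csv")
    types = pd.read_csv(OUT / "types.csv", index_col=0).iloc[:, 0]
    subtle = list(classes.index[classes["label"] == "subtle"])

    split = make_training_split(types, seed=17)
    model = fit_svd(F.loc[split.train, subtle])
    test_ids = [m for m in split.test if types[m] != "diploid"]
    projected, _ = project_rows(F.loc[test_ids, subtle], model, k=K)
    coords = pd.concat([model.mutant_coords(K), projected])
    cl = coords.iloc[:, 1:]  # drop the average-fitness component

    pool = [m for m in cl.index if types[m] != "diploid"]
    rng = np.random.default_rng(SEED)
    rows = []
    for t in sorted(types.loc[cl.index].unique()):
        ids = [m for m in cl.index if types[m] == t]
        members = ids if t == "diploid" else [m for m in ids if m in pool]
        if len(members) < 2:
            continue
        test_pool = sorted(set(pool) | set(members))
        res = cluster_permutation_test(cl, members, test_pool,
                                       n_perm=10_000,
                                       seed=int(rng.integers(2**31)),
                                       group_label=t)
        rows.append((t, res.size, res.observed, res.p_value))
    table = pd.DataFrame(rows, columns=["group", "size", "observed_median",
                                        "p"])
    table.to_csv(OUT / "cluster_tests.csv", index=False,
                 float_format="%.10g")
    print("median-pairwise-distance permutation tests "
          "(components 2-5, 10,000 draws):")
    for _, r in table.iterrows():
        print(f"  {r['group']:<16} n={int(r['size']):>3} "
              f"median={r['observed_median']:.3f} p={r['p']:.4f}")

    emb = embed_umap(cl, n_neighbors=20, seed=SEED)
    emb.to_csv(OUT / "umap_embedding.csv", index_label="mutant",
               float_format="%.10g")
    print(f"wrote UMAP embedding for {len(emb)} mutants")


if __name__ == "__main__":
    main()
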