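#!/usr/bin/env python
"""Classify the synthetic environments as subtle or strong perturbations.

Per-mutant reference statistics (mean and mean absolute deviation of fitness
across the nine EC batches) feed the mutation-type-weighted Z-score of every
environment; environments with Z < 2 are subtle."""

from pathlib import Path

import pandas as pd

from fitnoscope.environments import classify_environments, ec_reference_stats
from fitnoscope.io import read_matrix

OUT = Path(__file__).resolve().parent.parent / "results" / "synthetic"


def main() -> None:
    F = read_matrix(OUT / "fitness.csv")
    types = pd.read_csv(OUT / "types.csv", index_col=0).iloc[:, 0]
    counts = types.map(types.value_counts())
    ec = (OUT / "ec_batches.txt").read_text().split()

    stats = ec_reference_stats(F[ec])
    result = classify_environments(F, stats, counts, ec, threshold=2.0)
    result.to_csv(OUT / "environment_classification.csv",
                  float_format="%.10g")

    non_ec = result[~result["is_ec_batch"]]
    n_subtle = int((non_ec["label"] == "subtle").sum())
    n_strong = int((non_ec["label"] == "strong").sum())
    print(f"{len(ec)} EC batches (subtle by definition), "
          f"{n_subtle} further subtle and {n_strong} strong perturbations")
    truth_strong = {e for e in F.columns if e.startswith("strong")}
    called_strong = set(non_ec.index[non_ec["label"] == "strong"])
    agree = len(truth_strong & called_strong)
    print(f"  {agree}/{len(truth_strong)} environments simulated as strong "
          "perturbations are classified strong")
    print(f"  Z-score range: subtle {non_ec[non_ec['label'] == 'subtle']['z'].max():.2f} max, "
          f"strong {non_ec[non_ec['label'] == 'strong']['z'].min():.2f} min")


if __name__ == "__main__":
    main()
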