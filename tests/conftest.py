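import numpy as np
import pandas as pd
import pytest

from fitnoscope.simulate import (BarSeqSimConfig, SimConfig,
                                 simulate_barcode_experiment,
                                 simulate_phenotype_fitness)


@pytest.fixture(scope="session")
def lowrank_sim():
    """Noiseless rank-3 phenotype simulation (40 mutants x 20 environments)."""
    return simulate_phenotype_fitness(
        SimConfig(true_dim=3, n_mutants=40, n_envs=20, noise_sd=0.0, seed=11))


@pytest.fixture(scope="session")
def barseq_counts():
    """Simulated barcode experiment with known truth: 40 neutral lineages and
    60 adaptive ones, 2 replicates, depth 1e6."""
    rng = np.random.default_rng(42)
    ids = [f"L{i:03d}" for i in range(100)]
    s = pd.Series(np.concatenate([np.zeros(40),
                                  rng.uniform(0.1, 1.0, 60)]), index=ids)
    neutrals = frozenset(ids[:40])
    cfg = BarSeqSimConfig(true_fitness=s, neutral_ids=neutrals, n_cycles=4,
                          reads_per_timepoint=10**6, n_replicates=2, seed=7)
    return simulate_barcode_experiment(cfg), s, neutrals


def toy_counts(rows):
    """Build a count table from (lineage, replicate, timepoint, reads) rows."""
    return pd.DataFrame(rows, columns=["lineage_id", "replicate",
                                       "timepoint", "reads"])


@pytest.fixture
def type_series():
    """Mutation types: one abundant type, two recurrent, two singletons."""
    labels = (["diploid"] * 12 + ["IRA1_nonsense"] * 4 + ["GPB2"] * 2
              + ["SSK2"] + ["TOR1"])
    ids = [f"m{i:02d}" for i in range(len(labels))]
    return pd.Series(labels, index=ids, name="mutation_type")
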