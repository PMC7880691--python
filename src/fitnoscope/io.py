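"""Readers and writers for the pipeline's plain-text formats.

Count tables are TSV with columns ``lineage_id, replicate, timepoint, reads``.
Fitness matrices are CSV with mutant rows and environment columns, with a
parallel ``*_err`` CSV holding per-entry standard deviations.  Floats are
written at 10 significant digits so reruns are byte-identical.
"""

from __future__ import annotations

from pathlib import Path

import pandas as pd
import yaml

FLOAT_FORMAT = "%.10g"


def write_counts(counts: pd.DataFrame, path) -> None:
    counts.to_csv(path, sep="\t", index=False)


def read_counts(path) -> pd.DataFrame:
    counts = pd.read_csv(path, sep="\t",
                         dtype={"lineage_id": str, "replicate": str})
    counts["timepoint"] = counts["timepoint"].astype(int)
    counts["reads"] = counts["reads"].astype(int)
    return counts


def write_matrix(F: pd.DataFrame, path) -> None:
    F.to_csv(path, index_label="mutant", float_format=FLOAT_FORMAT)


def read_matrix(path) -> pd.DataFrame:
    return pd.read_csv(path, index_col=0)


def write_fitness_with_errors(F: pd.DataFrame, errors: pd.DataFrame,
                              path) -> None:
    """Write a fitness matrix CSV and its parallel ``<stem>_err.csv``."""
    path = Path(path)
    write_matrix(F, path)
    write_matrix(errors, path.with_name(path.stem + "_err" + path.suffix))


def read_fitness_with_errors(path):
    path = Path(path)
    F = read_matrix(path)
    err_path = path.with_name(path.stem + "_err" + path.suffix)
    errors = read_matrix(err_path) if err_path.exists() else None
    return F, errors


def write_fitness_table(merged_by_env: dict, types: pd.Series | None,
                        path) -> None:
    """Write a wide per-lineage fitness table.

    One row per lineage; per environment a final-estimate column, per-
    replicate columns suffixed ``-R1``, ``-R2``, ... and an error column
    ``<env>_err`` — the layout of a published mutant-by-environment fitness
    source table.  ``merged_by_env`` maps environment -> (merged, per_rep)
    frames as returned by :func:`fitnoscope.inference.infer_fitness`.
    """
    blocks = []
    for env, (merged, per_rep) in merged_by_env.items():
        blk = merged.set_index("lineage_id")[["fitness", "error"]]
        blk.columns = [env, f"{env}_err"]
        for i, (rep, grp) in enumerate(per_rep.groupby("replicate"), start=1):
            col = grp.set_index("lineage_id")["fitness"]
            blk[f"{env}-R{i}"] = col
            blk[f"{env}-R{i}_err"] = grp.set_index("lineage_id")["error"]
        blocks.append(blk)
    table = pd.concat(blocks, axis=1)
    if types is not None:
        table.insert(0, "mutation_type", types.reindex(table.index))
    table.to_csv(path, index_label="lineage_id", float_format=FLOAT_FORMAT)


def load_config(path) -> dict:
    with open(path) as fh:
        return yaml.safe_load(fh)


def dump_config(config: dict, path) -> None:
    with open(path, "w") as fh:
        yaml.safe_dump(config, fh, sort_keys=True)
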