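"""End-to-end orchestration with deterministic seeds and a run manifest.

``run_pipeline`` chains the stages — fitness inference (when counts are
given), environment classification, SVD phenotype model, dimensionality
detection, leave-one-environment-out bi-cross-validation, strong-environment
prediction and scoring, and phenotype-space clustering — writing each stage's
tables into the run directory plus a ``manifest.json`` recording versions,
seeds and input hashes.  Re-running with an unchanged configuration and
inputs is a no-op.
"""

from __future__ import annotations

import hashlib
import json
import logging
from dataclasses import dataclass, field, asdict
from pathlib import Path

import numpy as np
import pandas as pd

from . import __version__, io
from .clustering import cluster_permutation_test
from .dimensionality import (detect_dimension, loo_environment_bicv,
                             make_training_split, predict_environments)
from .environments import classify_environments, ec_reference_stats
from .evaluation import (component_improvement, mutant_improvement,
                         weighted_r2_per_env)
from .model import fit_svd, variance_fractions
from .simulate import SimConfig, simulate_phenotype_fitness

log = logging.getLogger("fitnoscope")

FLOAT_FORMAT = io.FLOAT_FORMAT


class StageError(RuntimeError):
    """A pipeline stage failed; partial outputs are retained."""


@dataclass
class RunConfig:
    """Configuration of a full pipeline run.

    Either ``fitness_csv`` (with a parallel ``*_err.csv``) or ``synthetic``
    (keyword arguments of :class:`fitnoscope.simulate.SimConfig`) must be
    given.  ``ec_batches`` lists the environment columns that are EC batches;
    for synthetic data the first ``n_ec_batches`` columns are used.
    """

    outdir: str = "run"
    fitness_csv: str | None = None
    types_csv: str | None = None
    synthetic: dict | None = None
    ec_batches: list = field(default_factory=list)
    n_ec_batches: int = 9
    z_threshold: float = 2.0
    k_max: int = 12
    n_noise_sims: int = 1000
    n_permutations: int = 10_000
    seed: int = 0

    @classmethod
    def from_yaml(cls, path) -> "RunConfig":
        return cls(**io.load_config(path))

    def to_dict(self) -> dict:
        return asdict(self)


def _sha256(path) -> str:
    h = hashlib.sha256()
    with open(path, "rb") as fh:
        for chunk in iter(lambda: fh.read(65536), b""):
            h.update(chunk)
    return h.hexdigest()


def _config_hash(config: RunConfig) -> str:
    payload = json.dumps(config.to_dict(), sort_keys=True, default=str)
    return hashlib.sha256(payload.encode()).hexdigest()


def run_pipeline(config: RunConfig) -> dict:
    """Execute all stages; return the manifest dictionary."""
    outdir = Path(config.outdir)
    outdir.mkdir(parents=True, exist_ok=True)
    manifest_path = outdir / "manifest.json"
    chash = _config_hash(config)
    if manifest_path.exists():
        previous = json.loads(manifest_path.read_text())
        if previous.get("config_hash") == chash and all(
                (outdir / f).exists() for f in previous.get("outputs", [])):
            log.info("run directory is up to date; nothing to do")
            return previous

    manifest = {
        "fitnoscope_version": __version__,
        "numpy_version": np.__version__,
        "pandas_version": pd.__version__,
        "config": config.to_dict(),
        "config_hash": chash,
        "input_hashes": {},
        "outputs": [],
        "stages": {},
    }

    def _save(frame: pd.DataFrame, name: str, **kw) -> None:
        frame.to_csv(outdir / name, float_format=FLOAT_FORMAT, **kw)
        manifest["outputs"].append(name)

    # ---- stage: inputs -------------------------------------------------
    try:
        if config.synthetic is not None:
            sim = simulate_phenotype_fitness(
                SimConfig(**{**config.synthetic, "seed": config.seed}))
            F, errors = sim.to_frames()
            io.write_fitness_with_errors(F, errors, outdir / "fitness.csv")
            manifest["outputs"] += ["fitness.csv", "fitness_err.csv"]
        elif config.fitness_csv is not None:
            F, errors = io.read_fitness_with_errors(config.fitness_csv)
            manifest["input_hashes"][config.fitness_csv] = _sha256(config.fitness_csv)
            if errors is None:
                raise StageError("fitness input requires a parallel _err CSV")
        else:
            raise StageError("config must provide synthetic or fitness_csv")
        if config.types_csv is not None:
            types = pd.read_csv(config.types_csv, index_col=0).iloc[:, 0]
            manifest["input_hashes"][config.types_csv] = _sha256(config.types_csv)
        else:
            # without annotation each mutant is its own type (equal weights)
            types = pd.Series(F.index, index=F.index, name="mutation_type")
        type_counts = types.map(types.value_counts())
    except StageError:
        raise
    except Exception as exc:  # noqa: BLE001 - stage-labeled failure
        raise StageError(f"stage 'inputs' failed: {exc}") from exc

    # ---- stage: environment classification -----------------------------
    try:
        ec = list(config.ec_batches) or list(F.columns[:config.n_ec_batches])
        stats = ec_reference_stats(F[ec])
        classification = classify_environments(
            F, stats, type_counts, ec, threshold=config.z_threshold)
        _save(classification, "environment_classification.csv")
        subtle = list(classification.index[classification["label"] == "subtle"])
        strong = list(classification.index[classification["label"] == "strong"])
        manifest["stages"]["classification"] = {
            "n_subtle": len(subtle), "n_strong": len(strong)}
    except Exception as exc:  # noqa: BLE001
        raise StageError(f"stage 'classify' failed: {exc}") from exc

    # ---- stage: phenotype model + detection ----------------------------
    try:
        model = fit_svd(F[subtle])
        fractions, excl_first = variance_fractions(model)
        det = detect_dimension(F[subtle], errors[subtle],
                               n_sims=config.n_noise_sims, seed=config.seed)
        _save(model.mutant_coords(), "mutant_coords.csv", index_label="mutant")
        _save(model.env_weights(), "env_weights.csv", index_label="environment")
        report = {
            "fractions": fractions.tolist(),
            "fractions_excluding_first": excl_first.tolist(),
            "threshold": det.threshold,
            "n_detected": det.n_detected,
        }
        (outdir / "detection.json").write_text(json.dumps(report, indent=2))
        manifest["outputs"].append("detection.json")
        manifest["stages"]["detection"] = {"n_detected": det.n_detected,
                                           "threshold": det.threshold}
    except Exception as exc:  # noqa: BLE001
        raise StageError(f"stage 'model' failed: {exc}") from exc

    # ---- stage: bi-cross-validation + prediction -----------------------
    try:
        split = make_training_split(types, seed=config.seed)
        k_hi = min(config.k_max, len(split.train), len(subtle) - 1)
        k_range = range(1, max(k_hi, 1) + 1)
        bicv = loo_environment_bicv(F, subtle, split, k_range, type_counts)
        _save(bicv, "bicv_loo.csv", index=False)
        k_use = max(det.n_detected, 1)
        k_use = min(k_use, len(split.train), len(subtle))
        rows = []
        preds = {}
        for k in range(1, (k_use + 1) if strong else 1):
            A_hat = predict_environments(F, subtle, strong, split, k)
            preds[k] = A_hat
            r2 = weighted_r2_per_env(F.loc[split.test, strong], A_hat,
                                     type_counts)
            for env, val in r2.items():
                rows.append((env, k, val))
        strong_r2 = pd.DataFrame(rows, columns=["environment", "k",
                                                "weighted_r2"])
        _save(strong_r2, "strong_env_r2.csv", index=False)
        if strong:
            per_k = strong_r2.pivot(index="environment", columns="k",
                                    values="weighted_r2")
            _save(component_improvement(per_k), "strong_env_delta_r2.csv")
        have_errors = bool((errors.loc[split.test, strong].to_numpy() > 0).all()) \
            if strong else False
        if strong and k_use >= 2 and have_errors:
            imp = mutant_improvement(
                preds[k_use].to_numpy(), preds[k_use - 1].to_numpy(),
                F.loc[split.test, strong].to_numpy(),
                errors.loc[split.test, strong].to_numpy())
            imp = pd.DataFrame(imp, index=split.test, columns=strong)
            _save(imp, "mutant_improvement_last_component.csv",
                  index_label="mutant")
        manifest["stages"]["bicv"] = {
            "n_train": len(split.train), "n_test": len(split.test),
            "mean_loo_r2_at_detected": float(
                bicv[bicv["k"] == min(k_use, k_hi)]["weighted_r2"].mean()),
        }
    except Exception as exc:  # noqa: BLE001
        raise StageError(f"stage 'bicv' failed: {exc}") from exc

    # ---- stage: clustering ---------------------------------------------
    try:
        coords = model.mutant_coords(max(det.n_detected, 2))
        # drop the first (average-fitness) component for clustering
        cl_coords = coords.iloc[:, 1:] if coords.shape[1] > 1 else coords
        groups = types.value_counts()
        rows = []
        rng = np.random.default_rng(config.seed)
        for t, n in groups.items():
            if n < 2:
                continue
            ids = list(types.index[types == t])
            res = cluster_permutation_test(
                cl_coords, ids, list(cl_coords.index),
                n_perm=config.n_permutations,
                seed=int(rng.integers(2**31)), group_label=str(t))
            rows.append((res.group, res.size, res.observed, res.p_value))
        if rows:
            cluster = pd.DataFrame(rows, columns=["group", "size",
                                                  "observed_median", "p"])
            _save(cluster, "cluster_tests.csv", index=False)
        manifest["stages"]["clustering"] = {"n_groups": len(rows)}
    except Exception as exc:  # noqa: BLE001
        raise StageError(f"stage 'cluster' failed: {exc}") from exc

    manifest_path.write_text(json.dumps(manifest, indent=2, sort_keys=True))
    return manifest
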