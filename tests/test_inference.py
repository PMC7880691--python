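"""Tests of fitness inference: QC, mean-fitness correction, pairwise slopes,
the two-part noise model, inverse-variance combination, neutral expansion and
the identical-lineage calibration diagnostic."""

import numpy as np
import pandas as pd
import pytest
from scipy import stats

from conftest import toy_counts
from fitnoscope.inference import (CannotFitNoiseError, EmptyExperimentError,
                                  NoiseModelParams,
                                  calibrate_against_identical_lineages,
                                  combine_pairwise, estimate_mean_fitness,
                                  fit_noise_model, identify_neutrals,
                                  infer_fitness, merge_replicates,
                                  pairwise_fitness, qc_filter_timepoints)
from fitnoscope.simulate import BarSeqSimConfig, simulate_barcode_experiment


class TestQC:
    def test_zero_read_timepoint_excluded(self):
        counts = toy_counts([("a", 1, 0, 3000), ("b", 1, 0, 3000),
                             ("a", 1, 1, 0), ("b", 1, 1, 0)])
        kept = qc_filter_timepoints(counts, min_reads=100, min_lineages=2)
        assert set(kept["timepoint"]) == {0}

    def test_boundary_exactly_at_thresholds_is_retained(self):
        # "at least": a timepoint with exactly min_reads over exactly
        # min_lineages lineages stays in
        rows = [(f"l{i}", 1, 0, 25) for i in range(100)]
        counts = toy_counts(rows)
        kept = qc_filter_timepoints(counts, min_reads=2500, min_lineages=100)
        assert len(kept) == 100
        with pytest.raises(EmptyExperimentError):
            qc_filter_timepoints(counts, min_reads=2501, min_lineages=100)

    def test_all_dropped_signals_empty_experiment(self):
        counts = toy_counts([("a", 1, 0, 5)])
        with pytest.raises(EmptyExperimentError):
            qc_filter_timepoints(counts)


class TestMeanFitness:
    def test_constant_pooled_neutral_frequency_gives_zero(self):
        counts = toy_counts([("n", 1, 0, 100), ("m", 1, 0, 900),
                             ("n", 1, 1, 100), ("m", 1, 1, 900)])
        mf = estimate_mean_fitness(counts, {"n"})
        assert mf["mean_fitness"].iloc[0] == pytest.approx(0.0)

    def test_halving_neutral_frequency_gives_ln2(self):
        # pooled neutral frequency 0.10 -> 0.05 means mean fitness rose ln 2
        counts = toy_counts([("n", 1, 0, 100), ("m", 1, 0, 900),
                             ("n", 1, 1, 50), ("m", 1, 1, 950)])
        mf = estimate_mean_fitness(counts, {"n"})
        assert mf["mean_fitness"].iloc[0] == pytest.approx(np.log(2.0))

    def test_time_relabeling_equivariance(self):
        # shifting all timepoint labels by a constant changes nothing
        base = [("n", 1, 0, 100), ("m", 1, 0, 900),
                ("n", 1, 1, 50), ("m", 1, 1, 950)]
        shifted = [(l, r, t + 3, c) for l, r, t, c in base]
        mf0 = estimate_mean_fitness(toy_counts(base), {"n"})
        mf3 = estimate_mean_fitness(toy_counts(shifted), {"n"})
        assert mf0["mean_fitness"].iloc[0] == pytest.approx(
            mf3["mean_fitness"].iloc[0])


class TestPairwise:
    def test_mutant_tracking_neutrals_has_zero_fitness(self):
        counts = toy_counts([("n", 1, 0, 200), ("m", 1, 0, 200),
                             ("x", 1, 0, 600),
                             ("n", 1, 1, 100), ("m", 1, 1, 100),
                             ("x", 1, 1, 800)])
        mf = estimate_mean_fitness(counts, {"n"})
        pairs = pairwise_fitness(counts, mf)
        s = pairs.set_index("lineage_id")["s_pair"]
        assert s["m"] == pytest.approx(0.0)

    def test_doubling_against_constant_neutrals_gives_ln2(self):
        counts = toy_counts([("n", 1, 0, 100), ("m", 1, 0, 100),
                             ("x", 1, 0, 800),
                             ("n", 1, 1, 100), ("m", 1, 1, 200),
                             ("x", 1, 1, 700)])
        mf = estimate_mean_fitness(counts, {"n"})
        pairs = pairwise_fitness(counts, mf)
        assert pairs.set_index("lineage_id")["s_pair"]["m"] == pytest.approx(
            np.log(2.0))

    def test_zero_count_pairs_are_omitted(self):
        counts = toy_counts([("n", 1, 0, 100), ("m", 1, 0, 0),
                             ("n", 1, 1, 100), ("m", 1, 1, 50)])
        mf = estimate_mean_fitness(counts, {"n"})
        pairs = pairwise_fitness(counts, mf)
        assert "m" not in set(pairs["lineage_id"])


def _pairs_frame(entries):
    """entries: (lineage, rep, t0, s_pair, w)."""
    return pd.DataFrame(
        [(l, r, t, t + 1, 100, 100, s, w) for l, r, t, s, w in entries],
        columns=["lineage_id", "replicate", "t0", "t1", "r0", "r1",
                 "s_pair", "w"])


class TestCombine:
    def test_equal_variances_give_plain_mean(self):
        pairs = _pairs_frame([("a", 1, 0, 0.4, 0.01), ("a", 1, 1, 0.6, 0.01)])
        noise = NoiseModelParams(kappa=pd.Series({(1, 0): 1.0, (1, 1): 1.0}))
        out = combine_pairwise(pairs, noise)
        assert out["fitness"].iloc[0] == pytest.approx(0.5)

    def test_inverse_variance_algebra(self):
        # values 1.0 (var .01) and 2.0 (var .04): (100*1+25*2)/125 = 1.2,
        # combined sd sqrt(1/125) ~ 0.0894
        pairs = _pairs_frame([("a", 1, 0, 1.0, 0.01), ("a", 1, 1, 2.0, 0.04)])
        noise = NoiseModelParams(kappa=pd.Series({(1, 0): 1.0, (1, 1): 1.0}))
        out = combine_pairwise(pairs, noise)
        assert out["fitness"].iloc[0] == pytest.approx(1.2)
        assert out["error"].iloc[0] == pytest.approx(np.sqrt(1 / 125))

    def test_order_invariance(self):
        entries = [("a", 1, 0, 1.0, 0.01), ("a", 1, 1, 2.0, 0.04),
                   ("b", 1, 0, -0.5, 0.02)]
        noise = NoiseModelParams(kappa=pd.Series({(1, 0): 1.0, (1, 1): 1.0}))
        fwd = combine_pairwise(_pairs_frame(entries), noise)
        rev = combine_pairwise(_pairs_frame(entries[::-1]), noise)
        pd.testing.assert_frame_equal(fwd, rev)

    def test_c_add_inflates_combined_variance(self):
        pairs = _pairs_frame([("a", 1, 0, 0.4, 0.01)])
        base = combine_pairwise(
            pairs, NoiseModelParams(kappa=pd.Series({(1, 0): 1.0})))
        inflated = combine_pairwise(
            pairs, NoiseModelParams(kappa=pd.Series({(1, 0): 1.0}),
                                    c_add=0.03))
        assert inflated["error"].iloc[0] ** 2 == pytest.approx(
            base["error"].iloc[0] ** 2 + 0.03)


class TestMergeReplicates:
    def test_identical_replicates_pass_through(self):
        est = pd.DataFrame({"lineage_id": ["a", "a"], "replicate": [1, 2],
                            "fitness": [0.7, 0.7], "error": [0.1, 0.1]})
        out = merge_replicates(est)
        assert out["fitness"].iloc[0] == pytest.approx(0.7)

    def test_inverse_variance_merge(self):
        est = pd.DataFrame({"lineage_id": ["a", "a"], "replicate": [1, 2],
                            "fitness": [1.0, 2.0], "error": [0.1, 0.2]})
        out = merge_replicates(est)
        assert out["fitness"].iloc[0] == pytest.approx(1.2)
        assert out["error"].iloc[0] == pytest.approx(np.sqrt(1 / 125))


class TestNoiseModel:
    def test_kappa_matches_multinomial_oracle(self):
        """Fitted kappa agrees within 20% with a brute-force multinomial
        variance oracle over 100 simulated experiments."""
        ids = [f"n{i}" for i in range(50)]
        s = pd.Series(0.0, index=ids)
        fitted, s_pairs, ws = [], {}, []
        for i in range(100):
            cfg = BarSeqSimConfig(true_fitness=s, neutral_ids=frozenset(ids),
                                  n_cycles=1, reads_per_timepoint=50_000,
                                  seed=1000 + i)
            counts = simulate_barcode_experiment(cfg)
            noise = fit_noise_model(counts, set(ids))
            fitted.append(noise.kappa.mean())
            mf = estimate_mean_fitness(counts, set(ids))
            pairs = pairwise_fitness(counts, mf).set_index("lineage_id")
            for lid in ids:
                s_pairs.setdefault(lid, []).append(pairs.loc[lid, "s_pair"])
            ws.append(pairs["w"].mean())
        # oracle: across-experiment variance of each lineage's slope,
        # divided by the mean read-depth weight
        oracle = np.mean([np.var(v, ddof=1) for v in s_pairs.values()])
        oracle /= np.mean(ws)
        assert np.mean(fitted) == pytest.approx(oracle, rel=0.2)

    def test_identical_replicates_give_zero_additive_noise(self):
        # two replicates with the exact same counts: no excess variance
        rows = []
        for rep in (1, 2):
            for t in (0, 1):
                for i in range(10):
                    rows.append((f"n{i}", rep, t, 100 + 7 * i))
        counts = toy_counts(rows)
        noise = fit_noise_model(counts, {f"n{i}" for i in range(10)})
        assert noise.c_add == 0.0

    def test_too_few_neutrals_cannot_fit(self):
        counts = toy_counts([("n", 1, 0, 100), ("m", 1, 0, 900),
                             ("n", 1, 1, 100), ("m", 1, 1, 900)])
        with pytest.raises(CannotFitNoiseError):
            fit_noise_model(counts, {"n"})


class TestNeutralIdentification:
    def test_no_neutral_behavior_returns_seed_set_unchanged(self):
        fp = pd.DataFrame({"lineage_id": ["a", "b"], "fitness": [1.0, -0.8],
                           "error": [0.05, 0.05]})
        assert identify_neutrals(fp, {"hc1"}, z_cut=2.0) == {"hc1"}

    def test_empty_seed_set_rejected(self):
        fp = pd.DataFrame({"lineage_id": ["a"], "fitness": [0.0],
                           "error": [0.1]})
        with pytest.raises(ValueError):
            identify_neutrals(fp, set())

    def test_simulated_recovery_of_true_zeros(self):
        """With deep sequencing, >=90% of true-zero lineages are admitted and
        <=5% of strongly non-neutral (|s|>0.3) lineages leak in."""
        rng = np.random.default_rng(3)
        zeros = [f"z{i}" for i in range(50)]
        adaptive = [f"a{i}" for i in range(40)]
        s = pd.Series(np.concatenate([np.zeros(50),
                                      rng.uniform(0.35, 1.0, 40)]),
                      index=zeros + adaptive)
        high_conf = set(zeros[:10])
        cfg = BarSeqSimConfig(true_fitness=s, neutral_ids=frozenset(zeros),
                              n_cycles=4, reads_per_timepoint=10**6, seed=4)
        counts = simulate_barcode_experiment(cfg)
        merged, _, _ = infer_fitness(counts, high_conf,
                                     min_reads=1000, min_lineages=10)
        expanded = identify_neutrals(merged, high_conf, z_cut=2.0)
        recovered = len(expanded & set(zeros)) / len(zeros)
        leaked = len(expanded & set(adaptive)) / len(adaptive)
        assert recovered >= 0.90
        assert leaked <= 0.05


class TestCalibration:
    def test_correct_errors_give_uniform_percentiles(self):
        rng = np.random.default_rng(5)
        n = 1000
        eps = rng.uniform(0.05, 0.2, n)
        est = pd.DataFrame({
            "lineage_id": [f"d{i}" for i in range(n)],
            "fitness": 0.4 + eps * rng.standard_normal(n),
            "error": eps,
        })
        groups = pd.Series("diploid", index=est["lineage_id"])
        diag = calibrate_against_identical_lineages(est, groups)
        p = stats.kstest(diag["percentile"], "uniform").pvalue
        assert p > 0.01

    def test_identical_members_degenerate_at_zero(self):
        est = pd.DataFrame({"lineage_id": ["a", "b", "c"],
                            "fitness": [0.5, 0.5, 0.5],
                            "error": [0.1, 0.1, 0.1]})
        groups = pd.Series("g", index=est["lineage_id"])
        diag = calibrate_against_identical_lineages(est, groups)
        assert np.allclose(diag["deviation"], 0.0)
        assert np.allclose(diag["percentile"], 0.0)

    def test_singleton_groups_skipped_with_warning(self):
        est = pd.DataFrame({"lineage_id": ["a"], "fitness": [0.5],
                            "error": [0.1]})
        groups = pd.Series("solo", index=["a"])
        with pytest.warns(UserWarning):
            diag = calibrate_against_identical_lineages(est, groups)
        assert diag.empty


class TestEndToEnd:
    def test_pooled_neutral_fitness_is_zero_by_construction(self, barseq_counts):
        counts, _, neutrals = barseq_counts
        merged, _, _ = infer_fitness(counts, neutrals,
                                     min_reads=1000, min_lineages=50)
        neut = merged[merged["lineage_id"].isin(neutrals)]
        w = 1.0 / neut["error"] ** 2
        pooled = (w * neut["fitness"]).sum() / w.sum()
        pooled_se = np.sqrt(1.0 / w.sum())
        assert abs(pooled) < 2 * pooled_se + 1e-3

    def test_known_fitness_recovered_within_three_se(self, barseq_counts):
        counts, truth, neutrals = barseq_counts
        merged, _, _ = infer_fitness(counts, neutrals,
                                     min_reads=1000, min_lineages=50)
        m = merged.set_index("lineage_id")
        z = (m["fitness"] - truth).abs() / m["error"]
        # every lineage individually within 3 reported SE at depth 1e6
        assert (z < 3).mean() > 0.97
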