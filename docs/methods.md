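# Methods

## The model

Fitness of mutant *i* in environment *j* is modeled as a linear combination
of abstract phenotypic effects:

    f_ij = p_i1 e_1j + p_i2 e_2j + ... + p_ik e_kj

Each mutant is a point `p_i` in a k-dimensional phenotype space; each
environment is a weight vector `e_j` saying how much each phenotype
contributes to fitness there. The components are abstract — they are
directions of causal effect on fitness, not directly measured cell traits; a
nonlinearly-acting measurable trait may appear as several linear components.
Because fitness is measured relative to a reference strain (fitness 0 by
definition), the reference sits at the origin and the decomposition is an
**uncentered, unscaled SVD** of the fitness matrix, `F = P Σ Eᵀ`. Centering
would destroy the first component, which deliberately captures each mutant's
average fitness in the home (evolution) condition. By Eckart–Young the first
k components are the best rank-k linear model of the data in squared error.
The model can only contain phenotypes that (a) at least one mutant alters and
(b) matter to fitness in at least one measured environment.

Conventions: singular values fold into the environment weights for reporting
(mutant coordinates are rows of U); each left-singular vector's
largest-magnitude entry is made positive so factor signs are reproducible.
Per-entry measurement errors are *not* used to weight the SVD; they enter
only the detection threshold and the improvement metrics.

## Fitness inference

For each pair of consecutive retained time-points, a lineage's log-frequency
change per cycle, `ln(f_{t+1}/f_t)/Δt`, underestimates its true relative
fitness by the population's mean fitness gain; that correction
`x̄_t = −ln(ν_{t+1}/ν_t)/Δt` is inferred from the pooled frequency ν of known
neutral lineages (pooling reads before the log is robust to individual
neutral dropout). Pairs with a zero count at either end are dropped rather
than pseudocounted — the inverse-variance weights already down-weight sparse
data, and pseudocounts bias slopes. Time-points are retained when they carry
≥ 2500 mapped reads over ≥ 400 represented lineages (defaults; both are
parameters, and the synthetic studies lower them to match their smaller
pools).

Pairwise variances follow the standard counting-noise form
`var = κ_t (1/r_t + 1/r_{t+1})/Δt²`, with κ_t fit per time-point pair as the
mean over neutral lineages of `s²/w` (unbiased when neutral s has mean zero).
A frequency-independent additive variance `c_add` is fit from the mean excess
of between-replicate variance of high-coverage lineages over their read-depth
variance, clipped at zero, and added to each per-replicate combined variance.
Final estimates are inverse-variance averages over pairs and then over
replicates. A lineage with no usable pairs yields a flagged missing record,
never a silent zero.

Neutral identification is two-pass: fitness is first inferred against a
high-confidence neutral seed set; lineages with `|f| < 2ε` are then added and
the mean-fitness correction re-estimated. The z-cut of 2 is a package
default, not a published constant. A calibration diagnostic compares, within
groups of genetically identical lineages, each member's deviation from the
group's inverse-variance-weighted mean against its theoretical sd
`sqrt(ε_i² − 1/W)` (the subtraction accounts for the member's own weight in
the mean); calibrated errors give uniform percentiles, a conservative model
piles percentiles near zero.

## Environment classification

Per mutant, the reference scale σ_i is the **mean absolute deviation** of its
fitness across the EC batches (the repeated home-condition assays); an SD
variant is available behind a switch. An environment's score is the
mutation-type-weighted average of `|f_ij − f̄_i|/σ_i` with weights
`1/n_type(i)`, normalized by the summed weights so each mutation type
contributes equally and the score reads as an average deviation in units of
EC-batch spread (an unnormalized raw-sum variant is exposed). Subtle means
strictly `z < 2`; EC batches are subtle by definition and report a
leave-that-batch-out z as a diagnostic. Mutants with σ_i = 0 (possible on
noiseless synthetic data) are excluded with a warning rather than given
infinite weight.

## Dimensionality detection

**Noise null.** 1000 matrices with independent `N(0, ε_ij²)` entries are
simulated from the error matrix; the mean squared largest singular value,
divided by the real matrix's total squared variation, is the detection
threshold, and the detected count is the number of leading variance fractions
strictly above it (contiguous from component 1). The mean—not an upper
quantile—follows the source procedure; a consequence, verified on synthetic
data, is that detection at low true dimension can report k+1 in a sizable
minority of runs, because the (k+1)-th singular value of signal-plus-noise is
the noise edge of the signal's orthocomplement and fluctuates around the null
mean regardless of the noise scale. A per-rank variant of the null (mean
squared singular value at every rank) is exposed as an option.

**Bi-cross-validation.** Mutants are split so that half of each mutation
type, capped at 20, trains (singleton types all test); environments split
into train/test columns. The held-out block is predicted as
`Â = B (D̂⁽ᵏ⁾)⁺ C`, with the pseudoinverse built directly from the k retained
SVD triples of the training block (exact for the rank-k object, no tolerance
cutoff). For rank selection each subtle environment is held out in turn; for
out-of-sample prediction all subtle environments train and the strong ones
are targets. Predictions are scored with the mutation-type-weighted R²
(weights `1/n_type(i)`, scope mean unweighted), which reduces to ordinary R²
for singleton types and is reported even when negative.

**Attribution.** Per-component improvement is the simple difference of
consecutive-k R² values; per-mutant improvement is the reduction in absolute
prediction error when adding component k, in units of that measurement's
error sd, `I = (|f̂⁽ᵏ⁻¹⁾ − f| − |f̂⁽ᵏ⁾ − f|)/ε`. A literal telescoping form
`(f̂⁽ᵏ⁻¹⁾ − f̂⁽ᵏ⁾)/ε` is available behind a flag but cannot measure accuracy
and is not used.

## Clustering

Cluster tests run in the original component space (never on the UMAP
embedding), by default on components 2..k — the first component is each
mutant's average home-condition fitness, and same-gene mutants are already
known to share it. The statistic is the median pairwise Euclidean distance
(robust to a single outlier mutant); the null is 10,000 same-size draws from
a pool excluding strains whose only mutation is diploidy (their abundance
would otherwise dominate every draw), and the empirical p uses the add-one
correction, flooring at 1/10001. UMAP (20 neighbors, fixed seed) is
visualization only.

## Synthetic data

The phenotype simulator draws mutants uniformly in the k-ball centered
(1, 0, ..., 0) with radius 1 — so the first axis carries most variation, as
in real data — and environments uniformly in the k-ball centered (1, ..., 1)
with radius 0.1, making them subtle perturbations of one another; fitness is
the inner product plus independent Gaussian noise with configurable per-entry
sd (exposed as a free parameter rather than a fixed grid). Ball sampling uses
the rejection-free Gaussian-direction × `radius·U^(1/k)` construction,
verified against a rejection-sampling oracle and a χ² test of the radial CDF.

The barcode simulator updates lineage frequencies multiplicatively by
`exp(fitness)` per cycle against a reference starting at 90% frequency and
renormalizes the whole population, so the rising mean fitness emerges from
the dynamics with no separate drift term. Sequencing is one multinomial
bottleneck per time-point over the non-reference lineages (the reference
barcode is removed before sequencing, as by restriction digestion); growth,
dilution and PCR noise are not modeled separately — the inference's noise
model is designed to absorb them, and with only the multinomial bottleneck
the fitted κ_t comes out slightly below 1 and the noise model is mildly
conservative, matching the calibration diagnostic. The simulator does not
model PCR jackpotting, UMI collisions, index hopping, or chemostat dynamics;
passing tests therefore demonstrate correctness of the estimators under the
stated noise structure, not robustness to those artifacts.

The `analysis/` study additionally organizes mutants into unbalanced
mutation types (tight 0.15-radius clusters around type centers inside the
mutant ball, sizes 40 down to 1) and environments into 9 EC batches plus 16
subtle and 20 strong perturbations, mirroring the structure of a real
barcoded-mutant panel; noise sd 0.005 per cycle is of the order of the
measurement errors such experiments report.

## Numerical choices and problem sizes

- Floats in all emitted tables carry 10 significant digits; reruns with the
  same configuration are byte-identical, and every stochastic operation takes
  an explicit seed threaded from one root generator.
- κ_t is floored at 1e-12 so degenerate zero-dispersion neutral sets cannot
  produce zero variances.
- Truncated pseudoinverses drop singular values below
  `max(dim)·eps·σ_max` inside the truncation.
- Test-suite simulations use 30–100 replicate experiments, matrices up to
  100 × 50, and 100–1000 noise simulations per threshold — sizes chosen so
  the whole suite runs in a few minutes on one CPU while keeping Monte-Carlo
  error well inside the asserted tolerances; the acceptance script uses the
  full 1000-simulation null over 20 repetitions.

## Known limitations

- The exact κ/c_add estimators of the original lineage-tracking noise model
  are described only in prior work; the forms here are faithful to the
  two-component description but not bit-identical.
- Missing mutant × environment entries are handled by excluding the mutant
  from matrix analyses; there is no imputation.
- The mean-based noise-null threshold is a central, not conservative,
  boundary (see Dimensionality detection above); bi-cross-validation is the
  cross-check when the component count sits near the noise floor.
- Strong-environment prediction spreads over leave-one-subtle-out models are
  reported as min/max over the 25 reduced models.
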