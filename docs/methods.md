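# Methods

## Model

For one gene set and one condition, each data type's sub-matrix
(`d` genes × `n` samples) is modelled as a multivariate normal
N(µ, Σ). µ is the vector of per-gene means over the condition's samples.
Σ is a Schäfer–Strimmer shrinkage estimate: the sample correlation matrix
R is replaced by (1 − λ*) R + λ* I with the analytic intensity

    λ* = Σ_{i≠j} V̂ar(r_ij) / Σ_{i≠j} r_ij²,   clipped to [0, 1],

and rescaled by the unbiased sample variances. Variances themselves are
not shrunk. For λ* > 0 the estimate is positive definite even when
`n < d`, which is the regime pathway-sized sets with cohort-sized
condition groups live in. When no real correlation exists, V̂ar(r)
dominates r² and λ* → 1 (diagonal covariance); this is correct behaviour,
not a failure mode. The precision matrix and log-determinant come from a
Cholesky factorization of the shrunk covariance.

The divergence between two samples is the log ratio of their estimated
densities, D₂(Sᵢ‖Sⱼ) = log f̂(Sᵢ) − log f̂(Sⱼ). Under the Gaussian model
the normalising constants cancel and the entry equals −½ the difference
of Mahalanobis quadratic forms; the whole n × n matrix is built from the
n per-sample log densities in O(n·d²), never per pair. The matrix is
antisymmetric with rank-one difference structure (entries aᵢ − aⱼ), a
signed "distance" used exactly as defined — no absolute value is taken.

The interaction score (IAS) of a set within a condition is the Pearson
correlation of the upper triangles (row-major, i < j) of the copy-number
and expression divergence matrices. In the permutation hot loop the IAS
is computed by an O(n) closed form valid for rank-one difference
matrices; a test pins its equality (1e−9) with the literal
upper-triangle construction. A zero-variance distance vector makes the
correlation undefined; the set is then flagged intractable (NaN) rather
than erroring — this is the known failure mode of the kernel baseline on
mostly-neutral copy-number data.

## Differential statistic and test

Conditions are contrasted on the Fisher-z scale,
diffIAS = [atanh(IASₐ) − atanh(IAS_b)] / √(1/(mₐ−3) + 1/(m_b−3)) with
m = n(n−1)/2 upper-triangle pairs per group and correlations clipped at
±(1 − 1e−12). The m pairs are not independent, so the statistic's
nominal scale is not trusted: significance always comes from a
label-permutation null — sample-to-group assignments reshuffled with
group sizes preserved and each sample's copy-number/expression pairing
kept intact (the only scheme under which the null is exchangeable) — with
densities, divergence matrices and both IASs recomputed inside every
permutation. The two-sided p-value uses the add-one estimator
(#{|null| ≥ |observed|} + 1)/(B + 1), so p ≥ 1/(B+1) and is never zero;
an undefined null statistic counts toward the numerator (conservative).
The reference group (whose IAS enters first) defaults to the
alphabetically first label. Per-set permutation streams are derived from
(master seed, set name), so results are independent of processing order
and safely parallelizable. Bonferroni correction over the analyzed family
sets the per-test threshold α/N; both directions of diffIAS are reported
as significant.

Per-condition, per-data-type, per-set fitting of (µ, Σ) is used
throughout; pooling across conditions would leak the contrast being
tested into the null model.

## Preprocessing

Expression matrices are optionally log2(x + 1)-transformed (the standard
RNA-seq convention; the offset is configurable) and quantile-normalized:
every column is mapped onto the reference distribution of rank-wise
means, ties within a column receiving the mean of the reference values
over their tied ranks, matching the widely used `normalize.quantiles`
behaviour. Quantile normalization is idempotent on tie-free data; with
ties the tie rule changes the pooled distribution, so exact idempotence
cannot hold (the property test is accordingly tie-free). Five-level
copy-number calls {−2…2} are collapsed by sign to {−1, 0, +1} at
ingestion. Gene sets are kept when they have strictly more than
`min_size` members (default 10); the count can be taken before or after
intersection with the measured genes (`count_mapped`), defaulting to the
raw membership count. Batch correction and missing-value imputation are
upstream responsibilities.

## Comparators

* dCoxS kernel baseline: the same scaffold with a product-kernel density
  (Gaussian kernels, per-gene Silverman bandwidths
  h = sd·(4/(3n))^{1/5}, leave-self-in). Its exponents are all ≤ 0 with
  the self term exactly 0, so the exponential sum lies in [1, n] and is
  computed directly, without log-sum-exp rescaling.
* Differential Mantel tests: the same permutation scaffold with symmetric
  Euclidean, Manhattan or Mahalanobis distances (the latter using the
  shrinkage precision, so singularity cannot arise).
* Single-pair differential correlation: per (CNA gene, expression gene)
  pair, within-group Pearson correlations contrasted by the two-sample
  Fisher-z test with a two-sided normal p-value; the pair family is
  restricted to genes appearing in at least one analyzed set.

All set-wise methods share one permutation engine and seed derivation,
so power comparisons are paired.

## Simulation designs

The generators define the study conditions used by the tests and the
acceptance script.

**Copy number.** Per variable, an alteration frequency f is drawn
uniformly from {0.1, 0.2, 0.3, 0.4, 0.5}; exactly round(f·n) samples (at
least one) are altered, each +1 or −1 with probability ½ (one Bernoulli
trial, 0 mapped to −1). The deterministic count makes frequency
invariants exact; a Bernoulli-per-sample variant would only blur them.

**Similarity ladder.** GE₁ = CNA + N(0, 0.01²) elementwise; each further
level adds fresh noise with SD 0.1, 0.2, 0.3, 0.4 to its predecessor, so
similarity to the copy-number matrix decays down the ladder. 100
samples; 20, 50 or 100 variables (extra expression rows, when requested,
resample copy-number rows with replacement). The expected behaviour —
mean IAS strictly decreasing in noise, ≈ 1 at near-zero noise — is what
the similarity tests check.

**Power design.** Two conditions of n samples each with independently
simulated copy-number matrices; one shared expression matrix equal to
condition A's copy numbers plus ge_noise_sd × N(0, 1), used in both
conditions. Condition A therefore truly interacts and condition B does
not. A literal variant in which the shared expression matrix is pure
standard normal, independent of both copy-number matrices, was measured
first and rejected: both conditions' IAS then have expectation zero and
the permutation test's rejection rate sits at α for every n and set size
(0.02–0.08 at n = 100), i.e. that variant contains no differential
interaction to detect. ge_noise_sd defaults to 0.7, chosen once as the
level at which the divergence method's power grows visibly with
n ∈ {100, 200, 400} without saturating at n = 100 while the kernel
baseline retains measurable power at set size 10 that collapses by set
size 30; it is a fixed study condition, not a per-analysis knob.

**Type-I design.** One copy-number/expression draw over 2n samples
(same coupling), split into two groups of n: samples are exchangeable
and no differential interaction exists. Duplicating one condition's
matrix into both groups is *not* used as a null: identical groups give
an observed statistic of exactly 0 and p ≡ 1, a degenerate design that
cannot estimate the type-I error.

What the simulations do not emulate: segment-level correlation along the
genome (variables are independent), expression measurement noise beyond
additive Gaussian, batch structure, and survival-time label mechanisms.
Passing tests therefore validate the statistical machinery, not
robustness to those real-data features.

## Numerical choices and degenerate inputs

* Variance floor 1e−8 for constant genes (all-neutral copy-number rows in
  small groups), with a warning on the observed fit; the same floor feeds
  Silverman bandwidths so they are never zero.
* If λ* is estimated exactly 0 on a rank-deficient sample covariance, a
  minimal intensity (1e−6) restores positive definiteness before the
  Cholesky factorization.
* Matrix TSVs are written with %.17g and parsed with numpy's float
  parser, so write→read round-trips are bit exact.
* Groups need ≥ 4 samples (m > 3 pairs) for the Fisher-z denominator;
  sets with < 2 member genes in either matrix are skipped with a logged
  reason, not an error.
* Permutation p-values are deterministic given (seed, set name, B);
  result tables hash-identically across reruns.

## Problem sizes

The test suite and acceptance script run everything at desk scale chosen
as: similarity study 100 replicates × {20, 50, 100} variables; power
study 100 replicates at B = 100 permutations over n ∈ {100, 200, 400};
type-I error 500 replicates at B = 199 (50 samples per group); screen
examples with 5 sets × 12 genes. The acceptance script uses smaller
replicate counts (30–200) since it reports point estimates rather than
testing orderings. The real-data scale of the method (hundreds of
pathways, ~500 samples, B = 26,000) is reachable through the same API;
the CLI default is B = 1,000 with `--permutations` to raise it.

## Known limitations

* The Gaussian model is applied to ternary copy-number data; the
  shrinkage covariance captures co-alteration structure but the marginal
  normality assumption is knowingly wrong there. The divergence is still
  well defined (it is a fixed quadratic function of the data), and the
  permutation null does not rely on the model being true.
* The Fisher-z scale of diffIAS treats m = n(n−1)/2 dependent pairs as
  if independent; its magnitude is interpretable only relative to the
  permutation null, and diffIAS values are not comparable across designs
  with different n.
* Intractable sets (zero-variance distances) are reported, not rescued;
  under the kernel baseline they are common for mostly-neutral
  copy-number sets, which is itself a finding about that baseline.
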