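# Methods

`gwasint` studies a single question: when does integrating a per-variant
functional meta-score (a CADD- or Eigen-style deleteriousness summary)
with GWAS summary statistics improve the power of the GWAS, and at what
cost in error control and robustness?  The package implements four
integration methods, the evaluation statistics used to compare them, and
synthetic-data generators that reproduce the statistical structure of the
study conditions at desk scale.

## Notation and model

For SNP *i* = 1…*m*, the GWAS supplies a z-statistic *z_i* (standard
normal under the null of no association) and a two-sided p-value
*p_i* = 2Φ(−|z_i|).  An annotation source, independent of the GWAS,
supplies a raw meta-score per SNP.  All uses of the score are rank-based:

- **phred scale**: −10·log₁₀(rank/m), rank 1 = most deleterious.  Because
  rank/m is uniform, the phred scores of *m* variants behave like a
  (10/ln 10)/2 · χ²₂ ≈ 2.17 χ²₂ sample; a phred of 10 marks the top 10 %,
  20 the top 1 %.
- **rank-uniform p**: p_add = rank/m (small p = deleterious), used by
  Fisher's method.
- **inverse-normal rescale**: v = Φ⁻¹((r − 0.5)/m) with ascending rank
  *r*; the half offset keeps the extremes finite.  The statistic handed
  to meta-analysis is sign(z_i)·v_i, so an above-median score pushes the
  combined statistic outward in the direction of the observed z while a
  below-median score attenuates it.  This direction alignment is the
  best case for meta-analysis; the alternative convention sign(z_i)·|v_i|
  (every score pushes outward) roughly doubles the null rejection rate
  at genome scale and is not what the reported error rates imply.

Ties in raw scores are resolved by stable competition ranking (first
occurrence gets the more deleterious rank); sign(0) counts as +1.
p-values are floored at 1e-300 before any logarithm.

## Integration methods

- **Meta-analysis**: Z_meta = (√(1/v)·z + √(1/v_add)·z_add)/√(1/v + 1/v_add);
  with equal unit variances (the default for rescaled scores),
  (z + z_add)/√2.  Two-sided normal p.
- **Fisher**: −2(ln p + ln p_add), χ² with 4 df.
- **Weighted p-value**: w_i ≥ 0 with mean exactly 1, built from the
  scores alone.  Cumulative scheme (default): w_i ∝ Φ(s_i − β), β = 2.
  Exponential scheme: w_i ∝ exp(β·s_i), computed with a max-shift;
  it is highly sensitive to large scores (phred values reach ~80), so
  cumulative is the default.  p_weighted = min(p/w, 1).
- **Stratified FDR (sFDR)**: SNPs split by score alone into k = 2 strata
  (group 1 = top 5 % of scores, `top_fraction` and `k` configurable; for
  k > 2 the non-top mass is split into equal-count score quantiles).
  Within each stratum: the conservative null-proportion estimate
  π̂₀ = #{p > 0.5}/(0.5·m_k), clamped into [1/(0.5·m_k), 1]; step-up
  q-values q_(i) = min(π̂₀·m_k·p_(i)/i, q_(i+1)); rejection at q < γ
  (γ = 0.05 default).  With α^(k) the largest rejected p per group
  (0 if none), the group weights are w^(k) = m·α^(k)/Σ_j α^(j)m^(j);
  if no group rejects, all weights are 1 (the unweighted case).
  p_sFDR = min(p/w^(g(i)), 1), with a zero weight mapping to 1.

For *ranking* (relative efficiency), sFDR uses its per-group q-values
merged across strata, with the raw GWAS p as tiebreaker.  The weighted
p_sFDR is the right object for threshold decisions, but when a stratum
has no FDR rejections its weight is 0 and p_sFDR collapses to 1 for the
whole stratum, erasing its internal order; the q-values rank every SNP
under all circumstances and reduce to (a monotone transform of) p within
each stratum.  This choice is what makes the measured robustness of sFDR
(relative efficiency ≈ 0 under uninformative scores) visible; ranking by
p_sFDR instead shows RE ≈ −0.35 driven entirely by the degenerate
zero-weight stratum.

## Error-rate evaluation (design I)

A fixed synthetic score track is drawn once; each replicate draws m iid
null z-scores, applies every method, and rejects at a fixed per-test
threshold (Bonferroni: family α/m).  For baseline, meta, Fisher and
weighted-p the per-SNP rejection events are independent once the track is
fixed, so the FWER has an exact closed form 1 − Π(1 − r_i); the Monte
Carlo machinery is validated against these oracles at 3 binomial SEs.

The sFDR group weights are data-dependent.  Re-fitting them inside every
null replicate and then applying Bonferroni to p_sFDR inflates the FWER
to ≈ 2α: the per-group FDR gate at γ = α coincides with that group's
Bonferroni bar, so the two strata contribute two nearly-disjoint
baseline-sized rejection events.  The error-rate study therefore
calibrates the weights once, on a pilot null replicate, and holds them
fixed across replicates (`sfdr_weight_mode="fixed"`), mirroring the
principle that prioritization must not be re-fit to the data under test.
Any fixed mean-one weight vector gives FWER = 1 − Π(1 − w_i·thr) ≈
1 − e^(−α), which is what the reported sFDR error rate reflects.  The
per-replicate mode is retained and its inflation is asserted by a test.

The headline design-I numbers are computed at m = 422,923 (the common
1000-Genomes SNPs with meta-scores available) at the study's stated
per-test level 1.2×10⁻⁷ (0.05/422923 as printed); the sFDR Monte Carlo
uses m = 100,000 and 10,000 replicates, sizes chosen so the run completes
in well under a minute while the binomial SE (≈ 0.002) stays far inside
the comparison band.

## Robustness evaluation (design II)

A block-exchangeable genome: SNPs in blocks of 5–10 at 10 kb spacing,
within-block LD r² = 0.8, zero across blocks.  z-statistics within a
block share a common factor so corr(z_i, z_j) = r = √r² (the z-score
correlation LD implies); the first SNP of a causal block is causal with
mean ncp ∈ [6, 10], block mates inherit the attenuated mean r·ncp.  Each
of 300 traits draws 1–200 causal blocks.  Baseline loci are formed by
greedy LD clumping (1 Mb window, r² > 0.1 strictly, index = smallest p,
ties by position) at α = 5×10⁻⁸; the score track is permuted once per
trait (scores become pure noise while conserving their multiset); each
method is applied and loci re-clumped on the integrated p-values.
Locus-level Recall/Precision use shared-member matching between the two
clumpings (TP is the minimum of matched-post and matched-baseline counts,
which coincide except in split/merge edge cases).  Per convention,
Recall is reported only for traits with ≥ 1 baseline locus, and a trait
with no post-integration findings has Precision 1 and FDR 0.

## Informativeness evaluation (design III)

m = 10,000 independent SNPs, the first m₁ = 100 truly associated with
z ~ N(3, 1).  The annotation statistic z_add ~ N(μ_add, 1) for m_add
enriched SNPs (overlap of them coinciding with the truth; enriched-null
positions redrawn per replicate), N(0, 1) elsewhere.  Eight catalogued
scenarios span completely informative (m_add = 100, μ_add = 3, overlap
100) through partially informative, misleading (overlap 50 or 0) to pure
white noise (m_add = 0).  z_add is used directly as the score (it is
already normal-scale): meta combines it with equal weights, Fisher takes
its rank-uniform p, the cumulative scheme weights it with β = 2, sFDR
stratifies on its top 5 %.

Per scenario, 1,000 replicates; power under three rejection rules
(Bonferroni 0.05/m; top-k with k = m₁; q-value FDR at 5 % and 20 %) and
relative efficiency RE = 1 − R̄_method/R̄_baseline, where R̄ is the mean
rank of the truth SNPs averaged over SNPs and replicates.  Measured
behavior: all methods gain (RE > 0) when the information is completely
informative; meta and Fisher are counter-productive (RE < 0) under
misleading or noise scores, and fail to gain once the truth overlap drops
below ~80 % at moderate informativeness (μ_add = 1.5; at μ_add = 3
Fisher retains a small gain down to ~50 % overlap); sFDR stays within
|RE| ≈ 0.06 of zero under misleading and noise scores.  The residual
−0.06 is systematic, not sampling noise: with real signals present both
strata reject at FDR 5 % in most replicates, so the weights do not
collapse to 1, and merging per-stratum q-values across randomly-composed
strata adds finite-stratum rank noise.

## What the generators do and do not emulate

The generators reproduce the marginal distributions the methods actually
consume — null z-scores, rank-derived phred scores (exact 2.17 χ²₂
structure), exchangeable LD blocks with correlated z, clustered
significant loci — but not: realistic LD decay or variable block
correlation, allele-frequency-dependent power, correlated scores between
neighbouring SNPs (real meta-scores of SNPs in LD are themselves nearly
uncorrelated, which the permutation design exploits), or genuine
polygenic architectures.  Passing tests therefore certify the methods'
statistical behavior under the stated models, not performance on any
particular biobank.

## Numerical choices and edge cases

- FWER products computed via Σ log1p(−r) for precision; any per-SNP rate
  reaching 1 short-circuits to FWER 1.
- π̂₀ clamping keeps q-values valid when the printed estimator leaves
  (0, 1].
- Ties in q (step-up plateaus) and capped weighted p-values rank by the
  underlying GWAS p.
- r² exactly equal to the clumping threshold does not join a clump;
  windows are inclusive at ±1 Mb from the index SNP.
- Replicate r of a run derives its generator from SeedSequence(seed,
  spawn_key=(stream, r)), so runs are reproducible and replicates
  independent.
- Missing z with present p is never back-filled (the sign is
  unknowable); methods needing the sign raise a precondition error.

## Known limitations

- Design I omits LD entirely (independent SNPs); the closed-form oracles
  are exact only under that independence, and small joint-dependence
  effects on real genomes are absorbed by the comparison bands.
- The γ level behind sFDR weighting in applications is a judgment call;
  0.05 is the default and exposed.
- k > 2 strata use equal-count quantiles below the top group; other
  partitions are plausible and would change power, not validity.
- Locus matching across clumpings by shared members is one of several
  defensible conventions; alternatives shift Recall by at most the rate
  of locus split/merge events.
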