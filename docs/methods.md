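# Methods

This package implements a genomic-feature analysis chain for dairy-cattle-
like data: a two-step mixed-model association scan, a sum-of-t² feature
enrichment test with a cyclical-permutation null, and variance-partitioning
genomic prediction (GBLUP vs GFBLUP).  Because the motivating cattle data
(de-regressed proofs and imputed sequence genotypes for Holstein and Jersey
populations) are not public, the chain ships with a synthetic-data generator
that reproduces the statistical structure the methods assume; every result
the tests and `scripts/acceptance.py` report is computed on that synthetic
cohort at desk scale.

## Models

**Phenotypes.** The response is a de-regressed proof (DRP) per individual
with reliability r².  All models are intercept-only in the fixed effects
(DRP arrive pre-adjusted for known fixed effects) and weight residuals by
the diagonal matrix `D` with entries `(1 − r²)/r²`, so a fully reliable
record has zero extra residual variance.

**GBLUP.** `y = 1μ + g + e`, `g ~ N(0, G σ²_g)`, `e ~ N(0, D σ²_e)`, with G
the VanRaden method-2 genomic relationship matrix:
`G_ij = (1/m) Σ_k (x_ik − 2p_k)(x_jk − 2p_k) / (2p_k(1−p_k))`.
Genomic heritability is `h² = σ²_g/(σ²_g + σ²_e)`.

**GFBLUP.** `y = 1μ + g_f + g_R + e` with independent `g_f ~ N(0, G_f σ²_f)`
over the variants of one feature term and `g_R ~ N(0, G_R σ²_R)` over the
remaining genome.  Both matrices use one set of allele frequencies, so
`m_f G_f + m_R G_R = m G` holds exactly; the remainder matrix is computed
through this identity rather than a second full matrix product.  Summaries:
`H²_f = σ²_f/(σ²_f + σ²_R)` (share of genomic variance in the feature),
`SNP_f = m_f/(m_f + m_R)` (share of markers in the feature), and
`h² = (σ²_f + σ²_R)/(σ²_f + σ²_R + σ²_e)`.

**REML.** Variance components maximize the restricted likelihood
`−½[(n−1)ln 2π + ln|V| + ln|1ᵀV⁻¹1| + yᵀPy]` by average-information
updates with step-halving; whenever an AI step would leave the parameter
space or lower the likelihood, a monotone EM-REML step is taken instead.
Variances are floored at `1e-8·Var(y)`, convergence is declared when the
likelihood changes by less than 1e-6 (default), and at most 100 iterations
are run; non-convergence is flagged on the result, never silent.  Standard
errors come from the inverse AI matrix at the optimum.

**BLUP and prediction.** Component effects for training animals are
`ĝ_k = σ²_k G_k V⁻¹(y − 1μ̂)` with μ̂ by generalized least squares; the
GEBV is their sum.  Validation animals are predicted by the conditional
mean `ĝ_k(target) = σ²_k G_k[target, train] V_train⁻¹ (y − 1μ̂)`, which is
algebraically identical to solving the joint mixed-model equations with the
targets' records missing (verified against that oracle in the tests).
Variance components for prediction are always estimated on the training set
only.

**GWAS.** The association scan is the canonical two-step approximation:
per chromosome, a one-component model `y = 1μ + a + e` with a
leave-one-chromosome-out (LOCO) G estimates `(σ²_a, σ²_e)`; each variant on
that chromosome is then tested by GLS under the fixed covariance
`V = G σ²_a + I σ²_e`, giving effect b, standard error, `t = b/se` and a
two-sided p-value from the standard normal.  The residual structure in the
scan is `I` (the printed form of the two-step model); a flag substitutes the
DRP weights `D`.  Inflation is summarized by
`λ = median(t²)/0.4549` and the genome-wide threshold by Bonferroni
`α/n_tests`.

**Set test.** For a feature with variant positions F on the genome-ordered
statistic vector, `T_sum = Σ_{i∈F} t²_i`.  The null is built by cyclic
rotation: the vector is shifted so a random element becomes first while
order is preserved (wrapping across chromosome boundaries), which uncouples
features from statistics while keeping the LD-driven autocorrelation of the
sequence.  With m ≤ n_perm all m rotations are enumerated and
`p = #(T_rot ≥ T_obs)/m` (the identity rotation bounds p below by 1/m);
otherwise offsets are sampled with replacement and
`p = (1 + #(T_perm ≥ T_obs))/(1 + n_perm)`, the standard small-sample
correction that cannot return zero.  Ties count against the observed
statistic (conservative).

**Evaluation.** Accuracy is the Pearson correlation of GEBV with validation
DRP; bias is the regression of DRP on GEBV (1 = unbiased scale); a term is
"predictive" when it lifts accuracy by at least 0.001 over GBLUP.  The
within-population split assigns animals born in or after the cutoff year
(default 2006, the younger animals) to validation; the boundary year's side
is configurable because either convention is defensible.

## Synthetic cohort

The generator emulates, at desk scale, the features of the cattle data the
methods rely on; its defaults are the study-like conditions used throughout
the tests.

* **Two populations by drift.** Ancestral allele frequencies are uniform on
  (0.05, 0.5); each population's frequencies are Balding–Nichols draws
  `Beta(p(1−F)/F, (1−p)(1−F)/F)` with `fst` (default 0.1; 0.15 in the
  between-population experiments) controlling divergence.
* **Block LD.** Within blocks of `ld_block_length` variants (default 25)
  the 2N haplotypes of a population are ranked by a random assignment to
  `pool_size` (default 8) haplotype pools, and each variant's carriers are
  filled from the top of that ranking.  The per-variant allele count itself
  is drawn Binomial(2N, p_pop), so sample frequencies carry only binomial
  noise and between-population divergence is governed solely by the drift
  parameter — a literal copy-from-pool scheme would add roughly 1/(2·pool)
  of spurious drift and distort F_ST.  Within a block this yields strong
  nested positive LD; across blocks variants are independent.  Real LD
  decays smoothly with distance and includes negative r; neither is
  emulated, which the set test does not require (it only needs local
  correlation of the t² sequence).
* **Genes and terms.** Non-overlapping genes of equal variant count tile a
  configurable fraction (default 0.5) of each chromosome; terms are random
  gene sets of `genes_per_term` (default 15, at least 10 — mirroring the
  convention of analysing only terms with ten or more annotated genes).
* **Phenotypes.** Effects are i.i.d. normal at a subset of variants
  (default 200 causal, a tenth of them inside the focal term) and rescaled
  exactly so the focal term's realized share of genetic variance equals
  `feature_share` (default 0.3) and heritability equals `h2` (default 0.39,
  the production-trait value).  DRP noise is `N(0, σ²_e(1−r²)/r²)` with
  reliabilities uniform on (0.80, 0.98); birth years put ~79% of animals
  before the 2006 cutoff, matching the training fraction of the real
  design.  Causal effects are shared between populations, so between-
  population prediction is limited by drift and LD differences only —
  breed-specific QTL are out of scope.

Passing tests on this cohort demonstrate internal correctness and
statistical calibration of the chain, not performance on real cattle data:
real DRP arise from national evaluations, real LD from pedigree and
selection history, and real annotations from curated databases, none of
which the generator attempts to model.

## Numerical choices

* GRMs carry a 1e-6 diagonal ridge (feature matrices built from few
  variants are otherwise rank-deficient); the ridge is uniform so the
  weighted-sum identity is preserved.  Variants with allele frequency 0 or
  1 are excluded from a matrix with a warning.
* Allele frequencies default to those observed in the individuals entering
  the matrix; between-population runs use the pooled training+validation
  frequencies (the merge rule is not dictated by the method; pooled is the
  default and the alternatives are selectable).
* Hardy–Weinberg testing on (imputed) dosages rounds to the nearest hard
  genotype and uses the one-d.f. chi-square goodness-of-fit test —
  adequate at the sample sizes involved; an exact test would matter only
  for very small cohorts.  QC is applied per population because the two
  populations segregate differently.
* Zero-variance variants produce missing association rows rather than
  errors; monomorphic markers return Hardy–Weinberg p = 1.
* Report TSVs are written with fixed 6-significant-digit formatting, so
  identical seeds give byte-identical outputs.

## Problem sizes

The shipped experiments run on one CPU: the within-population experiment
uses 1500 individuals × 5000 variants with 30 terms (about two minutes);
the between-population experiment 800 per population × 4000 variants with
20 terms; calibration suites use 500 null simulations for the set test, 20
replicates at n = 2000 for H²_f recovery and 10 replicates for the
between-population accuracy gain.  These sizes were chosen as the smallest
at which the stochastic checks are stable; the algebraic oracles run at toy
size.

## Known limitations

* The AI-REML solver is dense (O(n³) per iteration) and is intended for
  cohorts up to a few thousand individuals.
* The scan's step-1 matrices are built from all post-QC variants rather
  than a sparser array subset; with sequence-density panels a subset would
  be the pragmatic choice.
* p-values for single variants use the normal approximation to t; at
  training sizes in the hundreds or more the difference is negligible.
* The combined top-k feature is chosen by set-test p on the same training
  data used for fitting, as in the motivating design; its accuracy gain is
  therefore mildly optimistic.
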