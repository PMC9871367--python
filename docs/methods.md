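# Methods

## Model

For n individuals and p genetic variants with dosages X ∈ [0, 2]^{n×p}
(counts of a designated effect allele), the package fits the sparse linear
model

    E[y_i | X] = β₀ + Σ_j β_j x_ij          (continuous traits)
    logit P(y_i = 1 | X) = β₀ + Σ_j β_j x_ij (binary traits)

by component-wise gradient boosting.  Starting from ŷ⁽⁰⁾ = 0, each iteration

1. computes the negative gradient u⁽ᵐ⁾ of the mean loss at the current
   prediction (the residual y − ŷ for squared error; y − σ(η) for log loss),
2. selects the variant j* with the largest absolute Pearson correlation
   ρ(x_j, u⁽ᵐ⁾),
3. fits a univariate linear base-learner (intercept + x_j*, plus any
   mandatory covariates) to u⁽ᵐ⁾ by ordinary least squares, and
4. adds ν times that fit to the predictor.

Early stopping provides the regularization; the model stays sparse because
only selected variants ever acquire coefficients.

## Batch screening

Scanning all p variants every iteration is the bottleneck at biobank scale,
so the fitter works on *batches*: before boosting, it screens the p_batch
variants with the highest |ρ(x_j, u)| and records the largest absolute
correlation among the *excluded* variants, c_stop.  Boosting then iterates
inside the batch until either (a) m_batch updates have been made, or (b) the
best in-batch screening statistic falls below the frozen out-of-batch bound,
at which point a new batch is screened from the current gradient.  Only the
active batch's dosage columns need to be resident, so peak genotype memory is
O(n·p_batch).

One numerical subtlety: c_stop is a correlation whose denominator contains
the gradient norm *at batch creation*, while in-batch correlations are
computed against the current, shrinking gradient.  Compared literally, the
in-batch side is inflated and batch turnover fires too late — which breaks
the defining property that, for mutually orthogonal variants, batched and
non-batched boosting select the identical variant at every step.  The
comparison is therefore made on the covariance scale (correlation × centered
gradient norm at the respective evaluation time); out-of-batch covariances
are invariant under orthogonal in-batch updates, making the frozen bound
exact in the orthogonal case.  The two scales coincide at the moment a batch
is created.  This is verified in the acceptance suite by exact selection-order
agreement with the non-batched reference over 200 iterations at batch sizes
5, 20 and 50.

## Validation monitoring and early stopping

A held-out validation set is scored continuously while fitting:

* the **returned model** is the snapshot from the iteration with minimal
  validation loss (MSEP for squared error, mean log loss for binary traits) —
  the validation set chooses the number of boosting iterations;
* the **outer loop** stops when the batch-end validation loss has not
  improved on its running best for b_stop consecutive batches, or after
  b_max batches.

Iteration-level snapshotting matters at desk scale: when p_batch is a large
fraction of p, a single batch can overfit long before its end, and any
batch-granular snapshot would be strictly worse.  With iteration-level
selection, held-out R² is insensitive to the batch size (range < 0.001 across
p_batch ∈ {10, 100, 1000} on the fixed-dataset experiment) while the variant
counts still differ, as expected.

## Hyperparameters

| parameter | default | meaning |
|-----------|---------|---------|
| ν         | 0.1     | learning rate; matches common boosting practice — small enough to avoid overfitting single base-learners, large enough to converge in reasonable iterations |
| p_batch   | 1000    | batch size; medium batches balance per-step correlation cost against batch-rebuild cost |
| m_batch   | p_batch | max updates per batch; with small ν and the correlation stop this rarely binds in high-dimensional panels |
| b_max     | 20000   | hard cap on batches, a safety net only |
| b_stop    | 2       | outer stopping lag in batches |
| m_total   | None    | optional hard cap on total iterations, for fixed-budget comparisons across batch sizes |

Covariates supplied at fit time are *mandatory*: they enter every
base-learner design and are updated with the same ν at every step, never
competing with variants for selection.  Screening correlations are computed
against the raw negative gradient without pre-residualizing on covariates;
each base-learner's own covariate terms absorb confounding step by step.
Genotype columns are used unstandardized — Pearson correlation is
scale-invariant for selection and the base-learner slope absorbs scale.
Zero-variance columns receive correlation 0 and can never be selected.  Ties
in screening and selection break toward the lowest variant index, so fits are
bit-reproducible.

## Losses

Mean (not sum) conventions throughout, so validation losses are comparable
across sample sizes.  For binary traits the linear predictor is boosted and
the negative gradient is y − σ(η).  Probabilities are clipped to
[1e-12, 1 − 1e-12] inside the log loss so saturated predictors keep a finite
loss; the logistic link itself clips only at the floating-point boundary so
that logit(σ(η)) = η holds to |η| ≈ 30.  The monitored binary validation
criterion is the mean log loss; AUC is reported but never optimized.

## Synthetic data

The generator emulates a biobank-style experiment without external data:

* **Genotypes** — per variant a MAF is drawn uniformly (default 1%–50%,
  common variants); dosages are Binomial(2, maf) hard calls.  Optional
  linkage disequilibrium is block-structured: each allele copy derives from a
  latent Gaussian shared within a block (pairwise correlation ld_rho)
  thresholded at the Hardy–Weinberg quantile, so marginals stay Binomial
  while within-block dosages correlate.
* **Continuous phenotypes** — round(s·p) causal variants drawn uniformly,
  effects standard Gaussian (unscaled by allele frequency), genetic component
  g = X_causal β.  Noise variance is solved from the *realized* sample
  variance of g, var(ε) = var(g)(1 − h²)/h², so the realized variance ratio
  matches the target heritability tightly even at small n.
* **Binary phenotypes** — g is rescaled so its share of the logistic
  liability variance (π²/3 residual) equals h², the intercept is solved by
  root-finding to hit a target prevalence, and cases are Bernoulli draws.
* **Splits** — random disjoint train/validation/test partition, default
  50/20/30.

What this does *not* emulate: realistic population structure and relatedness,
imputation dosage uncertainty, allele-frequency-dependent effect sizes,
ascertained case-control sampling, and real LD beyond block exchangeability.
Passing tests therefore demonstrate algorithmic correctness and statistical
behaviour under the stated generative model, not performance on real cohort
data.

## Evaluation

R² is reported as the squared Pearson correlation between predicted and
observed phenotype (affine-invariant, the PRS-benchmarking convention), not
1 − SSE/SST.  AUC uses the Mann–Whitney rank formulation with ties counted
one half.  Selection accuracy against simulated truth: TP rate
|selected ∩ causal|/|causal|, precision |selected ∩ causal|/|selected|, and
coefficient MSE averaged over all p variants with absent entries counted as
zero.  Percentile bootstrap CIs are available for any sample-wise metric.

For LDL-cholesterol analyses a statin adjustment helper multiplies measured
values by 0.684 for treated individuals.  Whether the conventional factor
should multiply the measured value or divide it (to reconstruct the untreated
value) is ambiguous in the PRS literature; the multiplicative form is
implemented and the choice is isolated in one function.

## Problem sizes

The experiment suite runs at desk scale, chosen so the full set completes in
minutes on one core while keeping p > n_train in the recovery settings:
reduction/orthogonality checks at n = 300 with p = 150/60; signal recovery at
n = 4000, p = 2000, h² ∈ {0, 0.5}, s = 1%, p_batch = 200, 20 replicates;
batch-size insensitivity at n = 4000, p = 2000, s = 0.1%; the binary
extension at n = 5000, p = 1000, prevalence 0.2, liability h² = 0.5,
20 replicates.  Under these conditions median held-out R² at h² = 0.5 sits
just below the heritability ceiling, and the null (h² = 0) yields R² ≈ 0.

## Known limitations

* PLINK 1 hard-call .bed/.bim/.fam only; no .pgen/BGEN/VCF dosages.
* Linear, additive base-learners only — no dominance, interactions, or
  non-linear effects.
* No standard errors or confidence intervals for boosted coefficients;
  boosting provides no closed-form inference.
* Validation-set monitoring only; no cross-validation for the iteration
  count.
* The in-memory dosage matrix is dense float64; the streaming contract is
  honoured at the batch level but the current reader materializes the panel.
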