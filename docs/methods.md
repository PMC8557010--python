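# Methods

This note records the statistical model behind each module, the default
parameters and why they hold those values, the synthetic generator's scope
and limits, and the main numerical choices. Empirical claims below are
either implemented invariants (tested in `tests/`) or measured by
`scripts/acceptance.py`.

## 1. GReX prediction (`grexfine.grex`)

A weight model for (gene, tissue) is a sparse linear predictor over SNP
dosages. Prediction reconciles each model variant against the dosage
panel by allele pair:

* model (ref, effect) equals panel (ref, effect): use the dosage;
* model alleles are the panel pair swapped: use `2 − dosage` (counting the
  other allele);
* any other combination is irreconcilable: the variant is skipped, and the
  skip is counted in the prediction report (never silently ignored).

Model quality filters are strict inequalities (`cv_R² > 0.01`,
`cv_p < 0.05`): a model sitting exactly on a boundary is excluded, and a
missing quality record is an error rather than a pass. All-zero predicted
columns (no usable variant) are dropped with a log, because a constant
column is untestable and would poison standardization downstream.

Observed-expression normalization (used when real measurements enter the
correlation step) follows the conventional sequence: Tukey-fence outlier
removal (3 × IQR), residualization on expression and covariate principal
components, rank-based inverse normal transform `Φ⁻¹(r/(n+1))`, a second
residualization, and a final fence pass. The INT is monotone, so ranks are
preserved; with a sample small enough that the transformed extremes stay
inside the fences, the procedure is idempotent to numerical precision.

## 2. Cross-tissue joint test (`grexfine.assoc`)

Tissue-level GReX columns of one gene are highly collinear (they share
eQTL SNPs), so the joint test operates on principal components:
standardize columns, take the SVD, and keep components whose eigenvalues
satisfy `λ_max / λ_i ≤ 30`. The condition-number limit of 30 is the
published MultiXcan default; it trades a small loss of signal in
near-degenerate directions for numerical stability of the regression.
Components that are exact linear combinations of the covariates (which
happens when conditioning on every model SNP of a gene) are dropped, and a
gene with no testable component is flagged untestable, never given a
fabricated p.

* Quantitative traits: partial F-test of the retained components against
  the covariate-only ordinary-least-squares model.
* Binary traits: likelihood-ratio χ² between the logistic model with and
  without the components.

The joint statistic is unsigned. The reported direction is the sign of the
unweighted mean of the per-tissue Wald Z statistics, with an exact zero
mean resolved to +1 so the mapping is total and deterministic.

## 3. Meta-analysis

Cohorts are combined with the sample-size-weighted Z scheme:
`Z_i = Φ⁻¹(1 − p_i/2) · dir_i` and `Z_meta = Σ√N_i Z_i / √ΣN_i`.
Properties relied on (and tested): a single cohort is the identity; k
identical cohorts give `√k · Z`; `p = 0` is clamped to the smallest
positive double with a warning; cohorts lacking a direction are dropped
with a warning rather than entering with an arbitrary sign.

## 4. Significance thresholds

* Study-wide Bonferroni: `0.05 / (n_traits × n_genes)`; the reference
  configuration (5 traits × 127 genes) gives 7.87 × 10⁻⁵.
* Phenome-wide: `0.05 / 1531 ≈ 3.3 × 10⁻⁵` and `0.05 / 1795 ≈ 2.79 × 10⁻⁵`
  for the two phecode panels.
* Category enrichment: `0.05 / 17` across clinical categories.
* A permutation alternative draws windows of adjacent genes matched to the
  region on gene count and genomic span (both within 10%), reruns the
  joint test in each window, and takes the 5th percentile of the pooled
  null p (i.e. the 95th percentile of significance). The matching
  tolerance and the ≥ 10× genome-to-region size requirement keep windows
  comparable while leaving enough candidates to draw without replacement.

## 5. Conditional fine-mapping (`grexfine.conditioning`)

For a target gene, each conditioning gene enters a tissue's regression only
if its pairwise Spearman correlation with the target has `p < 0.05` in
that tissue (the gate). Gated genes are regressed out of the target's
GReX by least squares with intercept; rank-deficient conditioning sets are
reduced greedily, keeping the first independent columns in the caller's
order. The residuals re-enter the joint PC test. Interpretation at a
threshold T: `p_cond < T` labels the gene an independent signal,
otherwise a correlated passenger.

SNP-level conditioning appends named dosage columns to the covariates, so
the joint test measures GReX association conditional on those SNPs. When a
trait is mediated entirely by one causal eQTL, conditioning on that SNP
removes the gene's whole signal — the acceptance suite checks this pattern
explicitly.

A caution discovered during development and worth recording: linear
residualization removes only linear dependence. GReX scores built from
discrete dosages are not Gaussian, and the residual of a passenger on a
very strong driver retains a small *nonlinear* dependence (correlation
with the driver's square on the order of 0.1). With implausibly large
driver effects this leaks into the conditional p. At realistic effect
sizes (liability-scale heritability of a few percent) the leakage is
negligible; the acceptance fine-mapping scenario uses `heritability =
0.02` for this reason — a realism constraint, not a tuned number.

## 6. Phecode PheWAS (`grexfine.phewas`)

Case/control status follows the phecode convention: case = events on at
least two distinct calendar days; control = zero events for the code and
for every code in its exclusion set; one event day is neither. Codes with
fewer than 20 cases are dropped (logged); the threshold is the
conventional minimum for stable logistic estimates.

Gene-level PheWAS runs the cross-tissue joint test per (gene, code);
carrier-level PheWAS is a logistic regression of each code on carrier
status. When carrier status perfectly separates case status (every carrier
a case, say), maximum-likelihood logistic regression has no finite
estimate, so the implementation falls back to Fisher's exact test on the
2×2 carrier-by-case table (covariates ignored in the fallback); anything
degenerate beyond that is flagged inestimable rather than dropped.

Top phenomes take the `floor(0.01 × n_codes)` smallest-p codes per
predictor (15 of 1531), ties broken by code order for determinism.
Category enrichment is a one-sided binomial upper-tail test of the pooled
top lists against the category's share of analyzed codes, significant at
`0.05/17`. A prevalence filter drops traits that are cases in strictly
less than 5% of carriers before interpretation.

## 7. Phenome overlap (`grexfine.overlap`)

Extreme-expression labeling: per (gene, tissue) measurement, individuals
beyond the 2nd-percentile tails (both directions pooled, since eQTL
direction can differ by tissue) are "extreme" and those inside the
25th–75th band are "normal". Gene-level and individual-level aggregation
rank by extreme counts; the top 2% form the mimic group and the half of
the cohort with the fewest extreme (and most normal) labels forms the
control group. All ranking ties break by individual id, so the assignment
is deterministic. At least 100 individuals are required for the
percentiles to be meaningful.

The rank-overlap test ranks the carrier PheWAS by p (rank 1 = most
carrier-associated, average ranks on ties) and applies a one-tailed
Wilcoxon rank-sum test (exact when both sides have ≤ 25 observations) to
the candidate traits' ranks against the rest. The textbook check: with
candidates at ranks {1, 2, 3} of 6, the p-value is `1/C(6,3) = 0.05` by
enumeration.

## 8. Synthetic generator (`grexfine.simdata`)

Scope: the generator reproduces the *statistical structure* the pipeline
assumes, not any real biology.

* **Genotypes** — per block, two latent standard-normal AR(1) chains
  (lag-one correlation `ld_rho`) thresholded at `Φ⁻¹(MAF)` give haplotype
  alleles; the two alleles sum to a dosage. Adjacent-variant LD is a
  closed-form-checkable function of `ld_rho` and the MAFs; blocks are
  independent. Defaults: `ld_rho = 0.5`, MAF uniform on (0.05, 0.5) —
  common variants, moderate LD.
* **Weight models** — each gene takes a contiguous SNP window in its
  block; adjacent same-block genes overlap by `cross_gene_sharing ×
  weights_per_gene` SNPs (with independently drawn weights), which is what
  induces correlated GReX between neighbors; tissues share
  `cross_tissue_sharing` of a gene's SNP/weight pairs (default 0.8 —
  tissues mostly agree). Weights are `N(0,1)/√w` so GReX variance is
  approximately weight-count invariant.
* **Phenotypes** — quantitative: noisy linear function of standardized
  true GReX with noise scaled so the genetic variance share equals
  `heritability`; binary: the same construction on a liability thresholded
  at `Φ⁻¹(1 − prevalence)`. Covariates (age, sex, 3 PCs) are independent
  unless `confound_strength > 0`.
* **Phecodes** — Poisson event counts per (individual, code) on distinct
  days in a 10-year window; baseline rates uniform on
  `phecode_base_rate = (0.1, 0.6)` (chosen so typical codes clear the
  20-case filter at n = 2000); carrier-enriched codes multiply carriers'
  rates, and an optional nonnegative `expression_score` applies the same
  multipliers to high-scoring non-carriers, coupling the phenome to
  expression for the overlap analysis.
* **Reproducibility** — one global seed fans out to fixed per-stage child
  seeds, so each stage is individually reproducible and a full cohort is
  bit-identical across runs.

Limits: no sample overlap between "cohorts", no population stratification
beyond the optional PC leak, haplotypes are exchangeable (no phase
structure beyond AR(1)), Poisson event counts ignore visit clustering, and
weight models are noiseless linear truths rather than elastic-net fits to
finite reference panels.

## 9. Numerical choices

* p-values are clamped to `[tiny, 1]` (`tiny` = smallest positive double)
  — a reported 0 would break the meta-analysis inverse-normal step.
* Rank checks use `numpy.linalg.matrix_rank` defaults; PCs come from the
  SVD of the standardized matrix, eigenvalues as `s²/(n−1)`.
* The dosage writer round-trips floats bit-exactly via `repr`.
* Exact Wilcoxon enumeration is used when both groups have ≤ 25
  observations; the normal approximation beyond that.
* All tie-breaking (direction at Z = 0, top-list ordering, mimic/control
  assignment) is deterministic and documented at the function level.

## 10. Open design decisions

* The permutation threshold's "95th percentile" is implemented as the 5th
  percentile of the pooled null p (95th percentile of *significance*),
  with a `orientation="literal"` escape hatch, because the literal 95th
  percentile of null p (~0.95) is not a usable significance cutoff.
* `conditional_multixcan` conditions each candidate on all other
  candidates simultaneously (gated per tissue) rather than pairwise;
  pairwise behavior can be recovered by calling it with two genes.
* The carrier-PheWAS separation fallback prefers Fisher's exact test over
  penalized logistic regression to keep the dependency set small and the
  p-value exact; covariate adjustment is lost in that branch, which is
  acceptable because separation occurs only at extreme effect sizes.
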