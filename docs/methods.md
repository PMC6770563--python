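# Methods

This note records the statistical models the package implements, the
defaults and why they were chosen, what the synthetic-data generator does
and does not emulate, and the numerical decisions a maintainer would want
written down.  It states no empirical result that the test suite or the
analysis scripts do not themselves compute.

## Synthetic cohorts

The generator (`ubcsig.synthetic`) draws the inputs every downstream stage
assumes, with all truth recorded:

* **Counts.** For gene *g*, sample *s* in batch *b*:
  `log2 μ_gs = baseline_g + Δ·1{g∈signature, s basal} + shift_b·1{g affected}
  + ε_gs + log2(libfactor_s)`, and `Y_gs ~ NegBin(μ_gs, φ)` with variance
  `μ + φμ²`.  `baseline_g` is log-normal(meanlog 4, sdlog 1.5) on the count
  scale, mimicking bulk RNA-seq dynamic range; `ε_gs ~ N(0, σ_g²)` is
  biological log-normal noise (default sd 0.3 log2 units) whose variance is
  multiplied by `batch_scale` for batch-affected genes — exactly the
  location/scale structure the ComBat adjustment assumes.  Batch effects hit
  a random half of genes by default (`batch_affected_fraction = 0.5`).
* **Survival.** `T = (−log U / (λ₀·exp(η)))^(1/k)` (Weibull, default shape
  k = 1.2, rate λ₀ = 0.1/year) with `η = Σ β_g z_gs` over per-gene z-scores
  of library-corrected log2 counts.  The library correction matters: the
  hazard is driven by biological expression, which is what normalized
  expression can recover; tying it to raw counts would attenuate every
  downstream hazard estimate by the library-size noise.
* **Censoring.** Exponential, with the rate found by bisection against the
  *same* uniform draws later used for the censoring times, so the realized
  censoring fraction lands on the target up to 1/n granularity.  The study
  cohort's censoring fraction is not published; the default 60% is a typical
  value for a large observational tumor cohort and is a placeholder, not an
  estimate.
* **Defaults** follow the cohort the analysis was designed around: 388
  samples, a 13-gene signature at Δ = 2 log2 units, balanced subtypes,
  NB dispersion φ = 0.15 (biological CV ≈ 0.39, typical for human bulk
  tissue).
* **IHC panels** draw percent-positive values from subtype-conditional Beta
  distributions (concentration 15) whose means encode the expected staining
  biology: basal cases high in CK5/6 (0.70) and CK14 (0.50), luminal cases
  high in CK20 (0.70) and UPK2 (0.40), with pSTAT3/MYC/FOSL1 enriched in
  basal cases.  These means are stated once in
  `synthetic.DEFAULT_IHC_MEANS` and were not adjusted afterwards.

What the generator does **not** emulate: read-level structure, GC/length
bias within a gene, isoforms, gene–gene correlation beyond the shared
subtype/batch factors, informative censoring, or covariate-dependent
missingness.  A green test therefore establishes that an algorithm recovers
the stated generative structure, not that it is robust to every artifact of
real cohorts.

## Normalization

TMM follows the published recipe: the reference sample is the one whose
75th-percentile count fraction is closest to the mean; M (log-ratio of
count fractions) and A (mean log abundance) are computed on genes positive
in both samples; rank-based double trimming removes the top/bottom 30% of M
and 5% of A; the factor is `2^(weighted mean M)` with inverse binomial
delta-method variances as weights, and factors are rescaled to geometric
mean 1.  The trim fractions and weighting are the canonical defaults; only
the method name is fixed by the study design.

log2-RPKM uses TMM-effective library sizes (column sum × factor) and a
pseudocount of 0.5; log-CPM uses prior 0.5 with the `lib + 2·prior`
denominator convention.  Both choices avoid log(0) and are uniform across
samples, so downstream regularized models are insensitive to the constant.
Duplicate columns are averaged and rounded half-to-even to preserve integer
count semantics.  FFPE exclusion is a metadata filter (an `ffpe` flag in the
annotation), not an assay-based detector.

## Batch adjustment

Parametric ComBat: per-gene standardization against the batch-weighted
grand mean and pooled variance, per-batch location (γ) and scale (δ²)
estimates, normal and inverse-gamma priors fitted by method of moments
across genes, and the coupled posterior updates iterated to relative
tolerance 1e-6 (max 5000 iterations; non-convergence is an error reporting
the last change).  The implementation agrees with `scanpy.pp.combat` to
~1e-3 per entry on shared fixtures.

Two properties often claimed for ComBat hold only approximately: the grand
per-gene mean is preserved up to O(1e-3) residuals (EB shrinkage keeps
γ* ≠ γ̂), and post-adjustment between-batch variance ratios keep the
F-distribution sampling noise of the batch sizes, so at 100 samples/batch
only ~85–90% of null genes fall inside a [0.8, 1.25] ratio band — the same
fractions the scanpy reference produces.  Tests assert the attainable
levels.

Subtype is *not* included as a covariate by default when adjusting for
cross-dataset classification: at external-validation time the labels of the
new dataset are unknown, so protecting them would leak.  A `covariates`
argument exposes the other mode.

## Subtype classification

Elastic-net logistic regression in the glmnet parameterization, solved by
scikit-learn's saga with `C = 1/(nλ)` and `l1_ratio = α` on internally
standardized genes (coefficients back-transformed).  The α grid defaults to
{0, 0.25, 0.5, 0.75, 1} and the λ path to 100 values spanning four decades
down from λ_max (for α = 0 the path is anchored at the α = 0.001 λ_max, the
glmnet convention).  CV minimizes binomial deviance; ties break toward the
larger λ.  Because saga's stopping rule can fire after one epoch when every
coefficient is shrunk to zero, the unpenalized intercept is re-polished by a
one-dimensional Newton step at fixed coefficients — this makes the
full-shrinkage intercept equal the class log-odds exactly.

The 70–30 split stratifies by class with round-half-up per-class training
sizes.  Accuracy CIs are exact Clopper–Pearson by default (a bootstrap
percentile option exists).  The probability threshold is fixed at 0.5 and
basal is the positive class.

Stability selection draws class-stratified half-samples without
replacement, runs the LARS lasso path on the 0/1-coded response, and marks
the first q genes to enter, with
`q = max{q : q² ≤ PCER·(2π−1)·p²}` from the published per-comparison
error bound; the stable set is thresholded at π (default 0.8, PCER 0.1,
100 subsamples).  The linear-lasso path on coded labels is the original
stability-path formulation and is an order of magnitude faster than a
logistic path; with strong signatures the entry order is the same.  Note
that q is deliberately conservative for small panels (q = 3 at p = 13), so
an empty stable set on a small gene list is expected behavior, not a bug.

## Survival analysis

Ties are handled by Breslow everywhere (the scikit-survival convention, and
exact for the generator's continuous times).

* **Ridge Cox** maximizes the penalized partial likelihood
  `ℓ(β) − λ/2·‖β‖²` (scikit-survival backend) with λ chosen on a 13-point
  log-grid spanning 1e-3–1e3 by the Verweij–van Houwelingen cross-validated
  partial likelihood, ties toward the larger λ.  The baseline cumulative
  hazard is Breslow on the training data.
* **Boot Lasso** draws B bootstrap resamples (default 200; resamples with
  fewer than three events are redrawn), fits a lasso-Cox path on each, and
  picks the per-bootstrap λ by held-out partial likelihood with the
  **one-standard-error rule**.  Plain argmax-CV chases noise and retains
  spurious genes on null data; the 1-SE rule is the standard parsimony
  convention for sparse selection and collapses to the empty model when
  there is nothing to find.  Genes selected in ≥ 50% of resamples are
  refit with ridge Cox; an empty retained set yields a flagged
  covariate-free Kaplan-Meier model rather than an error.
* **Brier score / IBS.** IPCW with the censoring Kaplan-Meier G estimated
  on the scoring data, left limits at event times; weights below 1e-8 raise
  a named error rather than silently truncating.  The Brier curve is
  evaluated on the observed-time grid restricted to (0, t_max] with the
  endpoints appended, and the IBS is the trapezoidal average divided by
  t_max (default 3 years).  Cross-validated curves pool the out-of-fold
  survival predictions and score them in one pass (the alternative,
  averaging per-fold scores, is not implemented because pooling is the
  better-behaved estimator at 10 folds; fold assignment is stratified on
  the event indicator so every training fold contains events).
* **Conditional Kaplan-Meier** uses a rectangular nearest-neighbor kernel:
  the ⌈span·n⌉ samples closest to the smallest, median and largest
  signature value (ties by sample order), span defaulting to 0.25.
* **Maximally selected log-rank.**  Candidate cuts are observed values with
  left-group proportion inside the ε-window (default [0.1, 0.9]); the
  statistic is the standardized two-group log-rank, computed for all cuts
  at once from cumulative sums of the membership matrix.  The adjusted p is
  the Lausen–Schumacher Brownian-bridge improved Bonferroni
  `φ(b)(b−1/b)·log[t₂(1−t₁)/(t₁(1−t₂))] + 4φ(b)/b`, floored at the
  pointwise two-sided normal p (the formula does not degenerate to the
  pointwise value as the window collapses — it tends to roughly twice it —
  so a single-candidate window returns the pointwise p directly) and capped
  at 1.

## Differential expression and qPCR

voom-style weights: log-CPM (prior 0.5), per-gene least squares on the
design, lowess (span 0.5) of √(residual sd) on average log-count, and
per-observation weights `predicted-sd⁻⁴` interpolated at each observation's
fitted log-count.  Moderated t: empirical-Bayes variance shrinkage
`s²_post = (d₀s₀² + d_g s²_g)/(d₀ + d_g)` with (d₀, s₀²) from
moment-matching on log-variances (digamma/trigamma inversion by Newton);
p-values from t with d₀ + d_g df and BH FDR.  Forcing d₀ = 0 reproduces the
ordinary weighted t exactly; d₀ = ∞ gives the normal test with the pooled
prior variance — both limits are exercised in tests.

ΔΔCT: duplicate wells averaged per sample, ΔCT = CT_target − CT_reference,
ΔΔCT against the control condition's mean ΔCT, FC = 2^(−ΔΔCT), two-sided
pooled-variance Student t on replicate ΔCT values (Welch behind a flag),
BH across genes within each comparison condition.

## IHC subtyping

Tier quantization uses half-open intervals with the published "≥" anchors:
standard markers 0 below 5%, then [5, 25), [25, 50), [50, 100]; UPK2 scores
0 only when truly negative (0%), then (0, 10), [10, 25), [25, 100].  The
source wording's ranges overlap at their endpoints, so a convention is
required and this one honors every stated "≥" boundary.

The decision rule evaluates basal and luminal criteria independently:
basal = a score-3 basal marker, or both basal markers at 2 with luminal
markers ≤ 1; luminal = CK20 at 3, or UPK2 at 2–3 with basal markers ≤ 1,
or CK20 and UPK2 both 1–2 with basal markers ≤ 1.  Score-3 claims are
unconditional; weaker evidence requires the opposite lineage to be
absent/focal.  This attachment is the only reading consistent with both a
mixed moderate-expression case being non-type and a CK5/6-3/CK20-3 case
being a conflict; the rule fired and any conflict are reported per case, and
conflicts are always called non-type.  An independently transcribed
truth-table oracle in the test suite checks all 256 score combinations.

Contingency tests default to Pearson chi-square without continuity
correction (Yates and Fisher available); the variant is recorded in output.

## Pipeline

One global seed expands into per-stage seeds via SHA-256 of
`"{seed}:{stage}"` (taken mod 2³¹), so stages are independently
reproducible and adding a stage never shifts another stage's stream.  Stage
failures abort with the stage name; no stage mutates its inputs; every
reported metric points at a written artifact.  The demo configuration is
sized (240 samples, 300 genes, B = 25) to finish in a few minutes on one
CPU.

## Known limitations

* Only overall survival is modeled; no competing risks or time-varying
  covariates.
* ComBat is the parametric variant only; no reference-batch or
  non-parametric mode.
* The stability path and Boot Lasso report this package's own selections on
  synthetic data; published gene lists from the original cohorts are
  cohort-specific and are not reproduced here.
* The moderated-t implementation assumes equal residual df across genes
  (no missing values within a gene).
* Gene identifiers match by exact string only.
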