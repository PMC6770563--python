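# ubcsig

Gene-signature analysis of urothelial bladder cancer (UBC) subtypes and
prognosis, packaged as a reusable, fully tested pipeline.

Muscle-invasive bladder cancers fall into transcriptome-defined **basal** and
**luminal** subtypes with different clinical behaviour.  This package
implements the computational workflow used to study a STAT3/FOSL1-driven
gene signature in that setting, for bioinformaticians and biostatisticians
who want to re-run or adapt each stage on their own cohorts:

1. **Expression normalization** — TMM (trimmed mean of M-values) library-size
   factors, log2-RPKM and log-CPM transforms, duplicate-sample averaging.
2. **Batch adjustment** — parametric empirical-Bayes location/scale
   correction (the ComBat model) for merging datasets.
3. **Subtype classification** — elastic-net logistic regression
   (glmnet parameterization: `-(1/n)·loglik + λ[α‖β‖₁ + (1−α)/2‖β‖₂²]`)
   with joint (α, λ) 10-fold cross-validation, balanced 70–30 splitting,
   Clopper–Pearson accuracy intervals, and **stability-path** gene selection
   over class-stratified half-samples with the per-comparison error-rate
   bound `q² ≤ PCER·(2π−1)·p²`.
4. **Survival prediction** — univariate Cox screening, ridge-penalized Cox
   (λ by cross-validated partial likelihood), the **Boot Lasso** procedure
   (B bootstrap lasso-Cox selections, genes kept when selected in ≥ 50% of
   resamples, ridge refit), model comparison by the cross-validated
   **IPCW Brier score** `BS(t) = n⁻¹Σ[S(t|xᵢ)²·1{Tᵢ≤t,δᵢ=1}/G(Tᵢ⁻) +
   (1−S(t|xᵢ))²·1{Tᵢ>t}/G(t)]` integrated over three years, conditional
   Kaplan-Meier curves, and maximally selected log-rank cut points with the
   Lausen–Schumacher adjusted p-value.
5. **Differential expression / qPCR** — voom-style precision weights with
   empirical-Bayes moderated t statistics, and comparative-CT (ΔΔCT)
   quantification with `FC = 2^(−ΔΔCT)`.
6. **IHC subtyping** — four-tier scoring of CK5/6, CK14, CK20 and UPK2
   staining, the basal/luminal/non-type decision rule, high/low
   dichotomization and chi-square contingency comparisons.
7. **Synthetic cohorts** — negative-binomial counts with a planted
   basal-vs-luminal signature, batch structure, and Weibull survival whose
   hazard is linear in signature expression; every stage above is testable
   without any external download.

## Worked example

The numbered scripts under `analysis/` run the whole study on a synthetic
388-sample cohort (13 signature genes at +2 log2 units, five of them
prognostic with standardized log-hazard 0.5, two batches, 60% censoring):

```bash
python analysis/01_simulate_cohort.py
python analysis/02_normalize_expression.py
python analysis/03_adjust_batches.py
python analysis/04_classify_subtypes.py
python analysis/05_predict_survival.py
python analysis/06_differential_expression.py
python analysis/07_call_ihc_subtypes.py
```

Output of a run (seed 1), abridged:

```
mean |batch difference| before: 0.499
mean |batch difference| after:  0.020
test accuracy 1.000 (95% CI 0.969-1.000), sensitivity 1.000, specificity 1.000
ridge lambda 10; Boot Lasso retained ['G0000', 'G0001', 'G0002', 'G0003', 'G0004', 'G0009', 'G0011', 'G0012']
cross-validated IBS over 3 years: null=0.202, full_signature=0.098, boot_lasso=0.097
maxstat cut point at the 56th quantile (M = 16.57, adjusted p = 6.46e-59)
calls: {'luminal': 100, 'basal': 100}; agreement with truth 1.000
pSTAT3: 91.0% vs 15.0% high (basal vs luminal), chi2 = 115.9, p = 4.9e-27
```

Reading this: ComBat removes the simulated between-dataset shift (0.50 →
0.02 log2 units); the elastic-net classifier separates the held-out 30%
perfectly on this strong-signal cohort; Boot Lasso retains all five truly
prognostic genes (G0000–G0004) plus three passengers; the signature halves
the three-year integrated Brier score relative to the covariate-free
Kaplan-Meier model (0.098 vs 0.202); and the IHC decision rule recovers
every simulated case's subtype, with pSTAT3 high in 91% of basal vs 15% of
luminal cases.

A `ubcsig` console script wraps the same stages (`ubcsig demo --out DIR`,
`ubcsig run --config cfg.yaml`, `ubcsig ihc-call --panel panel.tsv --out
calls.tsv`).

## Acceptance script

`python scripts/acceptance.py --seed 1 --out results/acceptance.json`
re-runs the full pipeline on a freshly simulated cohort (synthesize →
normalize → batch-adjust → classify → survival → IHC), prints the per-stage
metrics, and writes the results summary JSON.

## Layout

```
src/ubcsig/          library: synthetic, normalization, combat, classify,
                     survival, diffexpr, ihc, pipeline, cli
analysis/            numbered narrative drivers (write under results/)
tests/               pytest suite incl. oracle-based acceptance checks
docs/methods.md      the statistical methods, assumptions and limitations
```
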