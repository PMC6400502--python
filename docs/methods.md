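# Methods

## The product statistic

For two traits y₁, y₂ measured across n individuals, the Pearson correlation
is r = (1/n) Σᵢ z₁ᵢ z₂ᵢ up to the degrees-of-freedom factor, where z is the
mean-centered, variance-scaled trait.  `cilp` keeps the per-individual
products pᵢ = z₁ᵢ z₂ᵢ as a continuous outcome: E[pᵢ | x] is (proportional to)
the correlation conditional on the predictor x, so an ordinary regression of
p on x tests whether x predicts the correlation.  The statistic's key
practical property is that power grows with the number of individuals, unlike
two-group contrasts of estimated correlation coefficients, and that
covariates and continuous or repeated-measures predictors come for free from
the regression machinery.

Scaling uses the sample variance (ddof = 1) throughout; with a single stratum
and complete data this makes (n/(n−1))·mean(p) equal the Pearson r to machine
precision, which the test suite asserts.

### Two normalization modes

- **`stratum_zscore`** — each trait is z-scored within every stratum ×
  group cell (e.g. year × health status) before products are formed.  Mean
  and variance differences between cells are removed exactly, so only
  correlation differences remain.  This is the mode for two-group or
  few-group contrasts.
- **`residualize_then_scale`** — covariate mean effects are removed once by
  OLS, the residuals are z-scored, and the products are reused for every
  predictor tested.  This is what makes a genome-wide SNP scan feasible (one
  product matrix, millions of SNP tests).  The cost is a known failure mode:
  a SNP with mean effects on *both* traits of a pair (at a skewed allele
  frequency) shifts the products and can masquerade as a correlation QTL.
  The test suite contains a characterization test reproducing this, and the
  QTL pipeline annotates every hit with per-gene eQTL/varQTL tests so such
  hits can be flagged.

### Inference

Per pair, the predictor coefficient is tested with a two-sided Wald t (OLS)
or Wald z (random-intercept mixed model, fitted by REML through statsmodels
MixedLM).  The mixed-model reference distribution is the normal
approximation; we deliberately avoid Satterthwaite/Kenward–Roger machinery —
at the sample sizes this method needs (hundreds of individuals) the
difference is negligible, and the choice keeps results reproducible across
linear-algebra backends.  Singular mixed fits fall back to OLS and carry a
`lmm_fallback_lm` warning flag on the result.  Multiple testing uses
Benjamini–Hochberg q-values over the tested pairs (pairs that fail to fit are
excluded from the FDR denominator and counted in the run report).

Missing data are handled pairwise-complete: a sample contributes to a pair
only when both traits are observed; model fits drop missing rows per pair.
Degenerate inputs (constant traits, strata with fewer than 3 samples,
constant predictors, rank-deficient designs) raise explicit errors naming the
offending trait/stratum/column rather than silently returning NA.

## The generative model

The simulator draws, per individual with minor-allele count g ∈ {0, 1, 2}
(Binomial(2, MAF), i.e. Hardy–Weinberg), a bivariate normal pair with

    means      (m₁ + b₁·g,  m₂ + b₂·g)
    covariance [[σ₁² + v₁·g,  b·g],
                [b·g,  σ₂² + v₂·g]]

b is the correlation-QTL effect (covariance slope per allele), b₁/b₂ are
eQTL-like mean effects, v₁/v₂ varQTL-like variance effects.  Positive
semi-definiteness (|b·g| ≤ √(var₁·var₂) for every genotype/confounder cell)
is validated before any sampling.  Sampling uses the conditional
construction y₂ = μ₂ + sd₂(ρ z₁ + √(1−ρ²) z₂), which realizes the target
covariance exactly per genotype class.

Default study conditions: n = 1000 individuals per pair, MAF 0.5, unit
baseline variances, zero baseline means, b = 0.3; the confound grid uses mean
effect 1 and variance effect 10.

**Non-genetic confounders** (the scenario-grid rows where a variable
unrelated to genotype shifts a trait's mean or variance) are driven by an
independent Binomial(2, 1/2) variable per individual — a "pseudo-genotype"
with the same support and the same effect magnitudes as the genetic effects
it mirrors.  A gaussian driver was rejected because σ² + 10·c with c ~ N(0,1)
is negative almost half the time, i.e. not a valid variance.

**Counts.**  The negative-binomial variant draws the latent gaussian pair,
standardizes each margin by its conditional moments, maps through the normal
CDF and the negative-binomial quantile function (mean/dispersion
parameterization).  This gaussian copula preserves the genotype-dependent
rank correlation while keeping the count margins fixed; it is a modeling
choice — the coupling mechanism for correlated counts is not otherwise
constrained.

**The transcriptome-wide confound** option adds a latent factor loading on
both traits for a random half of samples, shifting the correlation of every
pair independent of genotype.

### Synthetic cohorts

`simulate_cohort` builds full datasets for pipeline recovery tests.  Planted
decoherent pairs occupy disjoint trait sets (correlation 0.6 in the healthy
group, 0.2 in the disease group by default — the regime the decoherence
pipeline is designed for); the remaining traits are independent noise.  An
alternative block mode plants a factor-driven module whose within-block
correlation collapses in disease, which is the structure needed for the
PC1 composite score (traits decoherent with *many* partners).  Repeated
measures add an individual-level random intercept (sd 0.5); the prospective
design marks a fraction of healthy individuals as future converters and
shifts their baseline values on the planted traits.  Every planted effect is
recorded in a manifest used by the recovery tests.  Defaults (200 traits, 50
planted pairs, 500 per group) are the package's reference fixture; at these
conditions the pipeline recovers ≥ 80% of planted pairs at FDR 5% with the
false-call rate below the FDR level.

Planted correlation-QTL SNPs use per-genotype correlation ρ = b·g at the
spec's `qtl_maf` (default 0.5); background SNPs draw MAF ~ U(0.1, 0.5) with
no LD structure (LD pruning is exercised by dedicated constructed fixtures).

## Power evaluation

`replicate_scenario_grid` runs eight scenarios crossing the correlation
effect with (1) nothing, (2–3) eQTL effects on one/both genes, (4–5) a gene-1
varQTL without/with an eQTL, (6) non-genetic mean effects on both genes,
(7–8) non-genetic variance effects on one/both genes.  Each batch simulates
fresh genotypes per pair (pairs are independent), applies the product
pipeline (global z-score → product → OLS on dosage), and tabulates rates at
p < 0.05 and at the Bonferroni threshold 0.05/batch size.  Null pairs are
scenario-matched: same nuisance effects, covariance slope zero.  Including
both genes' expression levels as covariates is available
(`include_expression_covariates`) and, as expected, does not change power
materially.

**Measured rates under the written model.**  At full scale (10,000 pairs,
n = 1000, MAF 0.5, b = 0.3) this implementation measures ~100% nominal and
~96% Bonferroni power for the baseline scenario, ~0.5% Bonferroni power under
a gene-1 varQTL of effect 10, a nominal type-I error of ~5.2%, and a
Bonferroni false-positive rate of 0 in every scenario.  Reference values
reported previously for the same design (98.19% nominal / 50.91% Bonferroni
baseline power, 7.16% under the varQTL) disagree with the model as written:
the OLS z-statistic for the baseline effect has expectation
b·√(n·var(g)/var(p)) ≈ 6.3 under the stated parameters, which forces
Bonferroni power near 0.96, whereas the reported pair of values implies an
effective n·var(g) of roughly half the stated design.  We could not
reconstruct a variant of the model that reproduces all reported power
columns simultaneously, so the simulator follows the written model; the
null-calibration columns reproduce exactly.

## QTL pipeline numerics

- **HWE filter**: 1-df chi-square goodness of fit against p², 2pq, q² from
  the estimated allele frequency; monomorphic SNPs return p = 1 (flagged).
  At the QC threshold of 10⁻⁶ and QC-scale sample sizes the chi-square and
  exact tests agree on the filter decision (asserted against an enumeration
  oracle in the tests).
- **LD pruning**: greedy left-to-right per chromosome on 1-based positions;
  a SNP is dropped when its squared dosage correlation with a kept SNP within
  50 kb reaches the threshold (default r² ≥ 0.5).
- **Fast scan**: covariates (plus intercept) are projected out of products
  and dosages once via a QR decomposition; per (SNP, pair) the partialled
  regression coefficient, SE and t are computed with dense matrix algebra and
  df = n − n_covariates − 1.  By Frisch–Waugh this equals naive per-test OLS;
  the suite asserts max |Δp| < 1e-8.  Missing dosages are mean-imputed per
  SNP (tested to be negligible below 2% missingness); products must be
  complete (the residualize mode guarantees this).
- **varQTL**: a double-GLM — iterate weighted OLS for the mean and a
  gamma GLM (log link) of squared residuals on dosage until the dispersion
  coefficient changes < 1e-6 (max 25 iterations); the Wald z of the dosage
  term is rescaled to the fixed gamma dispersion 2 appropriate for
  squared-normal responses.  Non-convergence falls back to a Breusch–Pagan
  style test, flagged.  Calibration (KS-uniform null) and power are asserted
  in the tests.
- **Replication**: within-candidate Bonferroni (0.05/n candidates) and BH
  FDR counts, plus an exact binomial test of effect-sign agreement against
  0.5.  The FDR denominator is the candidate set (the discovery hits), with
  the count exposed so other conventions can be applied.

## Decoherence pipeline choices

- The Spearman prefilter removes pairs with |ρ| > 0.9 in **any** stratum;
  absolute value, because strongly negative near-collinearity causes the same
  product pathology as positive.
- "Loss" direction means products lower in the higher-status group
  (beta < 0 for a 0/1 healthy/disease coding).
- The directional bias statistic is reported under two constructions —
  Fisher's exact test on {significant, not} × {loss, gain}, and an exact
  binomial test of the loss fraction among significant pairs — because the
  2×2 underlying published log-odds values of this kind is not uniquely
  determined by the printed counts.  Neither is privileged.
- Category enrichment counts a pair toward a category when **either** member
  belongs to it (a both-members rule is available); upper-tail hypergeometric
  p per category, Bonferroni across categories, run separately per direction.
  With overlapping pairs sharing traits the hypergeometric null is an
  approximation; the suite verifies calibration on exchangeable null draws
  and exact agreement with an enumeration oracle.
- The composite score selects traits whose fraction of significant loss
  pairs exceeds 0.25 of their tested pairs, then takes PC1 of their baseline
  values (centered, unit variance), oriented so the loading sum is positive.
  Candidate biomarkers are compared with linear-probability fits
  (outcome ~ predictor + covariates) reporting R², the predictor p, and the
  gaussian AIC with the variance parameter counted (R's convention).

## What the synthetic data do and do not show

The generator draws independent gaussian (or copula-NB) traits with planted
covariance structure, no LD, no population stratification, no batch
structure beyond what is explicitly planted, and missingness only where
tests inject it.  Passing recovery tests therefore demonstrates the
statistical machinery — calibration, power, direction labeling, FDR
behavior — not robustness to the full messiness of cohort data (probe
cross-hybridization, cell-type composition, relatedness).  The covariate
interface is the intended tool for those problems in real data.

## Known limitations

- The residualize-then-scale mode's shared-eQTL false-positive mode (above).
- The mixed-model Wald z is anti-conservative for very few random-effect
  levels; the pipeline expects tens of groups or more.
- The fast scan materializes the SNP × pair statistic matrix densely;
  genome-scale runs should chunk SNP blocks.
- Power for the scenario grid is Monte-Carlo only; no analytic
  approximations are provided.
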