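# Methods

This note records the statistical model behind each component, the numerical
choices that matter for correctness, and the rationale for every generator
default. Package-internal defaults are the package's own choices; they are
configurable everywhere they appear.

## 1. Relative cell-type proportions (rCTPs)

For a subclass with marker genes $g_1..g_m$ and normalized log expression
$E$ (genes × samples), each marker row is z-scored across samples and the
rCTP is the samples' score on the first principal component (computed by SVD
for determinism), scaled by $1/\sqrt{m}$ so that with $m$ identical markers
the score equals the shared z-scored profile ("average-marker" scale). The
component sign is fixed so the loading sum is positive: a higher score always
means higher average marker expression. Scores are z-scored within dataset
before cross-dataset pooling, which removes dataset-level location/scale and
makes betas comparable.

rCTPs are relative latent scores. They are identifiable up to monotone
transformations of the underlying proportion, which is why recovery is
assessed by Spearman correlation against planted truth.

Markers absent from a dataset are dropped silently (that is what cross-dataset
harmonization means); zero-variance markers are dropped with a warning; fewer
than 3 surviving markers is an explicit failure.

## 2. Marker selection

A gene is a marker for a subclass when its mean CPM there is at least
`fold_threshold` (default 4) times the **maximum** mean CPM over all other
subclasses (+1 CPM pseudocount), and it is detected in ≥ 30% of in-type
nuclei. Using the maximum rather than the mean of the others is robust to one
confusable sibling subclass — the failure mode that matters at subclass
resolution. Genes qualifying for more than one subclass are dropped
everywhere, so gene → subclass assignment is a partial function. Per
subclass, qualifying genes are ranked by fold enrichment and the top 50 kept.

## 3. Bulk QC and normalization

Fixed order, per dataset:

1. **Gene filter**: keep genes with median expected count strictly above 15.
2. **Sample outliers**: classical MDS (principal coordinates of Euclidean
   distances on log2 CPM, equal to PCA scores of the centered matrix,
   computed by SVD); samples more than 3 IQRs from the component median on
   any of the first 5 components are removed.
3. **Winsorization**: per gene, log2(count + 0.5) is clamped into a ±3 IQR
   band around the gene median and transformed back to counts. Quartiles use
   the **inverted-CDF (order-statistic) definition**: with that choice the
   median and both quartiles are fixed points under clamping, so the
   operation is *exactly* idempotent. Interpolated percentiles break this at
   small n (e.g. counts `[0, 0, 0, 100]`, n = 4), because clamping moves the
   interpolated quartile and the band shifts on the second pass. In-band
   values are returned bit-for-bit unchanged.
4. **TMM factors**: trimmed mean of M-values. The reference sample's
   upper-quartile/library ratio is closest to the mean ratio; per sample, M
   (log ratio) and A (log abundance) over genes positive in both sample and
   reference are doubly trimmed (30% on M, 5% on A, rank-based with
   `floor(n·trim)+1` bounds) and the factor is 2^(inverse-variance-weighted
   mean of retained M), with weights from the asymptotic binomial variance;
   factors are rescaled to geometric mean 1. The implementation is verified
   against an independent brute-force oracle (1e-8) in the test suite and
   against edgeR's `calcNormFactors` (agreement ≈ 4e-13 on a 200×6 fixture)
   via `scripts/edger_crosscheck.py`.
5. **Observation weights**: lowess trend of per-gene √(residual SD) on mean
   log2 expression, inverted to precision weights (trend⁻⁴), evaluated at
   each observation.
6. **Technical-covariate removal**: per-gene weighted least squares on batch,
   RIN, PMI, percent mapped/usable bases; categorical covariates use
   sum-to-zero contrasts so the retained intercept is the grand level.
   Collinear designs fail naming the offending columns.

## 4. snCTPs

The percentage of a subject's QC-passing nuclei annotated to each subclass
(rows sum to 100). Subjects with fewer than 100 nuclei are excluded:
percentages from a handful of nuclei are binomially unstable. Within-type
expression models aggregate nuclei to subject-level pseudobulk means before
regression, because nuclei are not independent within subject.

## 5. Phenotype harmonization

Consensus AD diagnosis combines Braak ≥ 4, CERAD ∈ {moderate, frequent} and
cognitive impairment for cases; Braak ≤ 3, CERAD ∈ {none, sparse} and no
impairment for controls; everything else (mixed profiles, missing fields) is
"other" and excluded from case/control contrasts. Cut-points live in a
dataclass so per-study variants (e.g. neuropathology-only) use the same code.

Cognitive composites z-score each test against the **baseline** population
reference, average within domain (a domain counts when ≥ 50% of its tests are
present), then average domains. Per-subject slopes come from a linear mixed
model with correlated random intercepts and slopes (subject slope = fixed +
empirical-Bayes random slope). When trajectories are exactly linear the mixed
fit is degenerate (zero residual variance); the implementation detects this
and uses per-subject least squares, which coincides with the mixed estimate
in that limit. Residual cognition is the OLS residual of late-life cognition
on 11 neuropathology measures plus age, sex and education. Global pathology
is the mean of diffuse plaques, neuritic plaques and tangles.

## 6. Association models

**Mega-analysis** (one model per subclass): linear mixed model of the
z-scored rCTP on AD status with fixed effects of study, age at death and sex
and a random intercept per subject (subjects contribute multiple regional
samples), REML, Wald two-sided p. "Standardized beta" means the outcome is
z-scored, binary predictors stay 0/1 and continuous predictors are z-scored.
Singular fits fall back to OLS with a model tag. Calibration: under a null
generator, 500 replicates give a 5%-level rejection rate within the binomial
band [0.031, 0.069] (verified in the acceptance tests).

**Phenotype battery**: 19 subclasses × (11 pathologies + 3 cognitive
outcomes) = 266 tests. Pathology outcomes covary for age at death, sex, PMI;
cognitive outcomes for sex, education, baseline age. Each test is an exact
multiple regression computed by Frisch–Waugh–Lovell residualization (QR), so
the reported beta/SE/p are identical to the full OLS fit. BH-FDR is applied
across the whole grid; Bonferroni is also reported.

**Variance partitioning**: nested OLS models compared by a likelihood-ratio
test ($n \ln(RSS_0/RSS_1)$, χ² with the parameter difference as df), and a
generalizable R² from the **0.632+ bootstrap**: apparent error and
out-of-bag bootstrap error blended with weight
$w = 0.632 / (1 - 0.368 R)$ where the relative overfit $R$ uses the
no-information error over all (response, prediction) pairs. The same
bootstrap resamples are used for both nested models so the adjusted ΔR² is
paired; rank-deficient resamples are redrawn.

## 7. Mediation

Product-of-coefficients linear mediation: M ~ T + X, Y ~ T + M + X by OLS;
ACME = a·b, ADE = outcome-model T coefficient, total = ACME + ADE (exact
within every draw for linear models without interaction — and equal to the
marginal coefficient of T in Y ~ T + X, which the tests assert to 1e-10).
Confidence intervals are 95% percentile intervals from a nonparametric
row-resampling bootstrap (default 1000 draws), computed vectorized via
batched normal equations; the two-sided bootstrap p is 2·min(frac ≤ 0,
frac ≥ 0). The standard battery runs four configurations: SST and IT rCTPs
each as predictor with global pathology mediating and as mediator with
pathology predicting, cognition proximal to death always the outcome, and
APOE ε4 dose among the covariates. Null-ACME CI coverage is verified at
[92%, 98%] over 500 replicates.

## 8. Synthetic cohort generator

Everything downstream assumes a structure the generator plants explicitly.

**Proportions** follow a logistic-normal model: subject logits = subclass
base logits + N(0, `logit_sd`) + group multiplier × effect sizes
(cases 1, controls 0, "other" ½); proportions are the softmax. Defaults:
`logit_sd = 1.0`, chosen so a planted logit shift of b is approximately a
b-SD standardized group difference on the latent scale — making "planted
−0.5" directly comparable to the estimated standardized beta. Base
proportions span ~0.8% (VLMC, PAX6) to 25% (oligodendrocytes), covering the
regime where rare-type recovery is the hard case.

**Reference**: each subclass owns a disjoint block of `round(0.01 × n_genes)`
marker genes whose signature expression is `fold = 32` times the gene's
log-normal background; nucleus counts are negative binomial (gamma-Poisson,
Var = μ + φμ², φ = 0.2) at ~20k counts/nucleus. The fold default comes from
an a-priori signal-to-noise argument: marker CPM scales with the subclass
proportion, so for a p ≈ 0.8% subclass the marker signal must clear bulk NB
noise (φ = 0.05) and batch noise at realistic library sizes; fold 32 with 20
markers per subclass achieves that with margin, while fold near the selection
threshold (4) would make rare-type recovery dominated by noise rather than by
the method under test.

**Bulk**: expected counts are proportions × signatures scaled to 2M
counts/sample, with per-(gene, batch) log-normal offsets (SD 0.1), log-linear
effects of standardized technical covariates (per-gene coefficient SD 0.02),
and NB sampling (φ = 0.05). Multi-region studies either reuse the subject
pool per region (shared subjects) or partition it.

**Phenotypes**: pathologies are linear in standardized subclass logits via a
loading matrix (by default only SST loads, −0.45, on the six amyloid/tau
measures) plus a direct disease shift and Gaussian noise. Cognition is linear
per subject; intercepts and slopes load on standardized SST and IT logits and
on global pathology. Braak/CERAD/CDR are discretized from the continuous
pathologies, so the consensus-diagnosis code faces realistic mixed profiles.
Raw test scores are affine transforms of the composite on arbitrary scales
(fixed per truth seed) to exercise the composite construction.

**Realism limits** (by design): gene expression signatures are
subclass-constant (no within-type disease regulation unless planted
explicitly), marker blocks are perfectly disjoint, covariate effects are
log-linear, and phenotype couplings are linear-Gaussian. These are the
assumptions of the downstream models; the generator tests the machinery, not
model misspecification.

## 9. Determinism and seeds

A single pipeline seed expands into per-stage seeds through
`SeedSequence([seed, stage_index])`, reduced mod 2³¹ so they are valid
everywhere. Stage streams never collide; reruns with the same config and seed
produce byte-identical output tables (asserted in the tests). The run
manifest records per-stage seeds and a SHA-256 content hash of every output
file.

## 10. Problem sizes

The default validation cohort (400 subjects across three studies, five
datasets, 2000 genes, 19 × 20 markers, 1900 reference nuclei) is sized so
the full suite — including 500-replicate calibration and coverage studies —
runs on one CPU in a few minutes while keeping the rare-subclass regime
(p < 1%) represented. These sizes are this package's choices for desk-scale
validation, not properties of any real cohort.
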