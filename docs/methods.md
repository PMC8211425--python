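# Methods

`tmecausal` implements a biomarker-discovery analysis for bulk tumor
transcriptomes with a binary mortality endpoint: tumor-microenvironment
(TME) scoring, differential expression between score-defined groups,
univariate screening, data-driven confounder selection, and targeted
maximum likelihood estimation (TMLE) of the causal effect of dichotomized
gene expression on 3-year mortality.  This note records the models, the
defaults, and the choices made where the design was genuinely open.

## Cohort and outcome

The binary outcome is death before a fixed follow-up horizon (default 3
years).  Patients dead with overall survival below the horizon are cases
(Y = 1); patients with survival at or beyond the horizon are controls
(Y = 0) regardless of later vital status — the horizon, not the final
status, defines the endpoint.  Patients alive with follow-up shorter than
the horizon carry no information about the endpoint and are excluded, with
the exclusion itemized in the run manifest.  Non-primary (recurrent)
samples and samples missing from either the expression or the clinical
table are dropped before the outcome rule is applied.  Survival times are
accepted in years or days (`os_time_unit`), since public exports differ.

## TME scoring

Each sample is scored against an immune and a stromal gene signature with a
single-sample rank-based running-sum statistic.  Genes are ranked by
expression within the sample, ranks are centered on zero, and the score is

    ES = Σ_i [ P_in^w(i) − P_out(i) ]

walking genes from highest to lowest expression, where `P_in^w` is the
weighted ECDF of in-set genes with weights |centered rank|^τ (default
τ = 0.25, configurable) and `P_out` the flat ECDF of out-of-set genes.
Centering the ranks makes the statistic exactly antisymmetric under rank
reversal, which is a tested invariant.  Only ranks enter, so the score is
invariant to any strictly monotone transform of expression; the documented
normalization is log2(CPM + 1).  The combined score is the exact sum of the
immune and stromal scores (higher = lower tumor purity).  A tumor-purity
calibration is deliberately omitted — nothing downstream uses it.  Samples
are split at the median score; strictly-greater-than-median is "high", so
ties go to "low".

Signatures are supplied as GMT; the package ships none (the original
immune/stromal signature lists are licensed), and the synthetic generator
writes its own.

## Differential expression

Genes where every count is below half the sample number are filtered (the
prefilter wording admits other readings; `total_below_half_n` and
`majority_below_half_n` are available as config options).  Per gene, a
negative-binomial GLM (log link) with median-of-ratios size factors as
offsets is fit; the group coefficient is the log2 fold change (high vs low
score) and is tested by Wald, with Benjamini–Hochberg adjustment across
genes.  Dispersion is NB2 (variance μ + αμ²), estimated per gene by method
of moments within groups and shrunk on the log scale toward a fitted trend
α(μ) = a₀ + a₁/μ (trend weight 0.5, configurable).  This reproduces the
qualitative behavior of empirical-Bayes DE tools; on simulated NB data the
fold-change estimates agree with pyDESeq2 to ~0.01 log2 units (a tested
cross-check), but numerical equality with any specific tool is not claimed.
DEGs require |log2FC| > 1.5 and FDR < 0.05 (the threshold is on the log2
scale); the final DEG list is the direction-concordant intersection of the
immune-split and stromal-split DEGs: (up ∩ up) ∪ (down ∩ down).

## Screening

Every shared DEG is dichotomized at its per-gene median expression (same
tie rule as the score split) and regressed one at a time on the outcome by
maximum-likelihood logistic regression; clinical factors enter the same way
with reference-coded levels.  OR = exp(β̂) with Wald 95% CIs.  A
categorical variable is retained when *any* level is significant at α
(a variable with one significant extreme category is a real candidate even
if intermediate levels are not).  Separation is flagged, never fatal, and
flagged fits cannot qualify a variable.  Continuous age enters untransformed.

## Minimal confounder sets

For candidate gene G_j with covariate pool C (all other candidate genes,
dichotomized, plus the clinical covariates), two nested backward
eliminations are run:

1. V ⊆ C minimal with Y ⊥ C\V | V  (outcome-predictive set), then
2. W ⊆ V minimal with G_j ⊥ V\W | W  (exposure-linked subset).

At each step the covariate with the largest conditional-independence
p-value above the threshold (default 0.10) is dropped; ties break by
p-value then name, so the procedure is deterministic.  W is the adjustment
set passed to TMLE; V is reported for diagnostics.

The conditional-independence engine is pluggable.  The default adapts to
the data: with a binary target and all-discrete candidate/conditioning
columns (≤ 64 strata) it uses the exact stratified G² test — nonparametric
in the conditioning set, hence matching the natural brute-force oracle on
discrete toy graphs; otherwise it uses a likelihood-ratio test of nested
regressions (logistic for binary targets, OLS for continuous).  A
permutation-based machine-learning test was considered and rejected as the
default: on the covariate pools this pipeline produces (binary gene
indicators plus a few clinical columns) it adds orders of magnitude of
compute without changing the selected sets, and the parametric LRT is the
standard default in this setting.  Note the two displayed conditions keep
exposure-linked covariates (instruments) in W when they survive the V
stage; this is a property of the stated contract, not a bug, and is
exercised in the tests.

## TMLE

Estimands for binary exposure G (high expression) and outcome Y, with
Y(g) the potential outcome:

- AE  = E[Y(1) − Y(0)]  (average effect, marginal risk difference)
- IEᵢ = E[Y | G=1, Wᵢ] − E[Y | G=0, Wᵢ]  (individual effect)
- MOR = {E[Y(1)](1−E[Y(0)])} / {(1−E[Y(1)])E[Y(0)]}  (marginal odds ratio)

Initial estimates of Q(G,W) = E[Y|G,W] and g(W) = P(G=1|W) come from a
Super Learner: V-fold (default 10) cross-validated convex stacking over a
library of main-terms logistic regression, all-pairwise-interaction
logistic regression, elastic-net logistic regression (l1_ratio 0.5, C 1.0,
standardized inputs), gradient-boosted trees (100 trees, depth 3, η 0.1,
subsample 0.8) and a random forest (200 trees, min leaf 5).  Weights
minimize the cross-validated negative log-likelihood on the probability
simplex; a failing learner is excluded with weight 0 and a log entry.
Predictions are clipped to (1e-6, 1−1e-6).  The library and fold count are
configurable; simulation studies in the tests use the correctly-specified
main-terms logistic alone, which keeps hundreds of replicates inside
seconds without changing what the estimator is.

The propensity is truncated to (0.025, 0.975) by default — standard
positivity protection; a warning artifact records when more than a
configurable fraction (10%) of samples is truncated, and a single-armed
exposure is a hard error (effects are unidentifiable without positivity).
Targeting is a single two-parameter logistic fluctuation with offset
logit(Q) and clever covariates H₁ = G/g(W), H₀ = −(1−G)/(1−g(W)),
fit to convergence tolerance 1e-12; this solves both arms' efficient-
influence-curve score equations at once, so no iteration is needed (the
empirical mean of the influence curve is checked to ≤ 1e-8 on every fit).
The targeted Q* gives EY1 = mean Q*(1,Wᵢ), EY0 = mean Q*(0,Wᵢ), the
plug-in AE, the IE vector (reported from the targeted fit), and the MOR.
Inference is influence-curve based: Wald SEs and CIs for AE, delta-method
on log(MOR).  The estimator is doubly robust — consistent when either Q or
g is consistent — which the tests verify by deliberate misspecification at
n = 10,000.

Per-gene fits derive their seed as `(global_seed · 1000003 + crc32(gene))
mod 2³¹−1`, so batch order cannot change any gene's result.  One gene's
failure is logged and skipped, never aborting the batch.

## Validation utilities

Per-gene sensitivity/specificity from median-dichotomized expression; AUC
by the rank (Mann–Whitney) formulation, which equals the trapezoidal ROC
area and gives ties half credit.  Multi-gene discrimination uses the
in-sample logistic linear predictor over the dichotomized genes — the
simplest defensible fusion rule, and swappable; the combined operating
point is Youden-optimal.  An alias map substitutes a measured family member
for a gene absent from a platform.

## Synthetic cohorts and what they show

The generator emulates the statistical structure the analysis assumes:

- Latent binary immune state (P = 0.5); the stromal state copies it with a
  5% flip, because immune and stromal infiltration co-vary strongly in bulk
  tumors.  Signature genes (default 100 per signature) have NB means
  multiplied by 8 in latent-high samples.
- NB counts with dispersion α = 0.2 and log2 base means uniform on (3, 10)
  — typical bulk RNA-seq ranges.
- Confounders (default: one binary "advanced stage", Bern(0.4), and one
  standardized continuous "age") affect the exposure (logit coefficients
  0.8, 0.5) and the outcome (1.0, 0.6).
- Exposure G ~ Bernoulli(expit(a₀ + a'Z)); outcome Y ~
  Bernoulli(expit(b₀ + βG + b'Z)) with β = −1.2 — a strongly protective
  gene whose crude (confounded) OR ≈ 0.5, in the range of univariate ORs
  typical of screened prognostic genes; baseline intercept −0.4 gives
  ≈ 40% three-year mortality.
- The designated exposure gene's counts are elevated 6-fold by the latent
  immune state (so it reaches the DE stage, as a TME-related biomarker
  must) and 20-fold under G = 1, so a median split of its expression
  recovers G with ≈ 94% accuracy.
- Survival times are drawn consistently with Y at the horizon; optional
  fractions of recurrent samples and alive-short-follow-up samples exercise
  the cohort filters.

Ground truth is computed from the structural model, not the draws:
IEᵢ = p₁(Zᵢ) − p₀(Zᵢ), AE = mean(IE), MOR from the counterfactual mean
risks — so mean(IE) = AE holds to machine precision by construction — and,
for all-discrete confounders, seed-free by exact enumeration of the
confounder support.

What passing tests do *not* show about real data: the generator has no
batch effects, no library-preparation artifacts, no correlation structure
among non-signature genes, no measurement error in clinical covariates, no
informative censoring, and its outcome model is exactly logistic.  Results
on real cohorts depend on assumptions (no unmeasured confounding,
positivity, correct enough nuisance models) the synthetic checks cannot
establish.

## Problem sizes and numerical choices

Simulation studies in the tests use cohorts of n = 300–500 (n = 10,000 for
the double-robustness checks), 50 replicates for the confounder-selection
oracle comparison and 200 for the TMLE bias/coverage study; these sizes
give Monte-Carlo error well below the effects being measured while keeping
the default suite quick.  Degenerate inputs are errors, not silences:
constant expression cannot be dichotomized, an all-identical score vector
cannot be median-split, a single-armed exposure violates positivity, and a
gene set equal to the whole universe has no enrichment contrast.  BH
adjustment, logistic fits and NB GLMs delegate to statsmodels; stacking
weights use SLSQP on the simplex with ftol 1e-10.

## Known limitations

- The DE dispersion shrinkage is a deliberate simplification of
  empirical-Bayes machinery (no outlier refitting, no independent
  filtering, no LFC shrinkage).
- Backward elimination returns a local minimal set; agreement with
  exhaustive search is a tested statistical property (≥ 90% on discrete toy
  graphs), not a guarantee.
- One fluctuation step, not iterated or cross-validated TMLE; continuous
  exposures and survival outcomes are out of scope.
- The enrichment score is defined up to the documented construction; no
  claim of numerical equality with any published scoring package is made.
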