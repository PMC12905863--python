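# Methods

## Overview

gxekit studies how a worsening air-pollution trend and polygenic
susceptibility jointly relate to type 2 diabetes in a cross-sectional
cohort. The pipeline has five analysis stages — genotype/individual QC,
exposure-trend slopes, clumping-and-thresholding (C+T) polygenic scores,
logistic association models, and additive/multiplicative interaction — plus
a synthetic-data generator that creates all inputs from known parameters.
This note records the models, the defaults and why, the numerical choices,
and what the synthetic validation does and does not establish.

## Synthetic-data generator

The generator is the package's study population; its defaults are the
conditions under which the pipeline is validated.

**Genotypes.** Hard calls in {0,1,2} for `n_blocks × snps_per_block`
variants. Each haplotype is a latent Gaussian AR(1) sequence (correlation
`within_block_rho`, default 0.7) thresholded at Φ⁻¹(MAF), MAF ~
U(0.05, 0.5); a genotype is the sum of two independent haplotypes. Blocks
are independent, span < 250 kb (2-kb spacing) and sit 1 Mb apart, so the
clumping window never straddles blocks. The latent correlation bounds the
realized dosage r², which is what clumping sees; tests assert monotonicity
in rho rather than equality. Calls are set missing completely at random at
`missing_rate` (default 1%). An optional small subpopulation with
logit-shifted MAFs exercises the PC-outlier screen.

**Summary statistics.** `n_causal` variants (default 40) receive true
log-ORs ~ N(0, `causal_beta_sd`); reported effects are
`β̂_j = β_j + N(0, se_j)` with the standard GWAS approximation
`se_j = 1/sqrt(2·MAF_j(1−MAF_j)·n_effective)` (default n_effective
200,000), and two-sided Wald p-values consistent with (β̂_j, se_j). As
n_effective → ∞ the reported effects converge to truth; null variants have
uniform p-values (both tested).

**Exposures.** Per participant and pollutant,
`conc(t) = b_i + s_i·t + N(0, noise_sd)` over five calendar years
(t = 0…4), with `s_i ~ N(slope_mean, slope_sd)` and
`b_i ~ N(baseline_mean, baseline_sd)`. Defaults emulate the Taiwanese
setting the package mirrors: PM₂.₅ slope −1.56 ± 0.88 µg/m³/yr, baseline
26.7 ± 7.64 µg/m³; NO₂ −0.44 ± 0.59; SO₂ −0.13 ± 0.13; O₃ −0.01 ± 0.61.
"Baseline" in the descriptive table is the concentration in the index
(latest) year, so its generated mean is `baseline_mean + 4·slope_mean`
(the intercept is drawn at window start). The Gaussian tails can produce
occasional small negative concentrations (<1% at defaults); they are kept
rather than clipped so that the linear ground truth stays exact — real
panels are non-negative, synthetic ones are a model.

**Cohort.** Covariates (age group, sex, income, BMI class, education,
exercise, smoking, drinking, comorbidities) are drawn from realistic
general-population marginals with the reference levels fixed (age 20–39,
female, income < NT$20k, normal BMI, college, no exercise, never smoker,
occasional drinker, comorbidity-free). The outcome is

    P(T2D=1) = expit( b0 + γ_G·z(PRS_true) + γ_E·s_i + γ_GE·z(PRS_true)·s_i + covariate terms )

where `PRS_true` uses the true causal effects and s_i is the true PM₂.₅
slope. Defaults: b0 = −2.95 (≈5% prevalence), γ_E = 0.035 ≈ ln(1.036) per
µg/m³/yr, γ_GE = 0.05, and γ_G = 0.2. γ_G is set above the target quartile
contrast because the genetic effect at the mean slope is
`γ_G + γ_GE·E[s] = 0.2 − 0.05·1.56 ≈ 0.12`, which yields a marginal
Q4-vs-Q1 odds ratio near 1.4 — the strength of association reported in the
study population this package emulates. Covariate effects default to zero
so crude and adjusted models estimate the same quantity; they are settable
(some tests use strong age/BMI/smoking effects to make the covariate-only
AUC meaningful). Each stage draws from its own RNG stream derived from the
master seed, so regenerating one stage never perturbs another.

**Implied true RERI.** For ground-truth comparisons the generator records
the additive interaction implied by the true model for the binary contrast
high genetic risk (top-quartile true PRS) × adverse exposure (slope > 0):
cell odds are formed from the mean *true* risk in each of the four cells,
odds ratios taken against the (low-G, improving-E) cell, and combined as
OR11 − OR10 − OR01 + 1. A saturated logistic fit on the same two indicators
is consistent for exactly this quantity, which is what the bootstrap
coverage study relies on.

**What the generator does not emulate:** satellite/land-use exposure
modelling (the pipeline starts from annual concentrations), genotype
imputation, fine-scale LD and allele-frequency spectra, population
admixture beyond a single shifted subpopulation, confounding structure
(covariates are independent of exposure by default), and measurement error
in covariates. Passing tests therefore validate the *statistical machinery*
— estimator consistency, test calibration, CI coverage, determinism — not
the field behaviour of any particular real cohort.

## Exposure trends

Years are recoded to 0…(n−1) from the earliest year in the window, making
β₀ the fitted concentration at window start and β₁ unit-identical to µg/m³
per year; β₁ uses the closed-form OLS estimator. Series need ≥ 2 distinct
years; shorter series are excluded from models and logged. Summaries use
the n−1 SD and linear-interpolation quantiles (the scientific-computing
default). Location invariance, time-scale covariance and time-reversal
antisymmetry are property-tested.

## Genotype and individual QC

Variant filters: missingness > 0.02, MAF < 0.05, exact conditional
Hardy–Weinberg test (enumeration over heterozygote counts, log-factorial
arithmetic) with p < 1e-10 in cases and < 1e-6 in controls, each variant's
failure reasons reported. Individual filters: call missingness > 0.02,
heterozygosity outside mean ± 3 SD, relatedness (method-of-moments IBD
pi-hat > 0.2 on pairwise-complete one-hot IBS counts; within a flagged
pair the member with higher missingness is dropped, ties to the larger
index), and ± 6 SD outliers on the top two principal components of the
standardized dosage matrix.

Pi-hat is a ratio-of-moments estimator whose sampling error scales with
the inverse square root of the (effective) marker count; below
`min_ibd_markers` (default 1,000) the 0.2 cutoff would flag large fractions
of unrelated pairs from noise alone, so the relatedness screen is skipped
with a warning at smaller marker counts. Duplicate detection and null
calibration (< 1% of pairs flagged at n=500, m=2,000 i.i.d. markers) are
unit-tested.

## Polygenic score

Allele alignment matches variants by ID (falling back to chrom:pos),
re-orients effects where the summary-statistic effect allele is the
genotype's other allele, and drops strand-ambiguous (A/T, C/G) or
allele-incompatible variants with reasons. Clumping is greedy and
p-ordered (ties broken by position then ID for determinism): each
unassigned variant with p ≤ threshold becomes an index and absorbs
unassigned variants within 250 kb whose in-sample dosage r² ≥ 0.1
(pairwise-complete Pearson). "LD pruning" inside a C+T workflow is
implemented as clumping — the behaviour of the standard tool's --clump —
not MAF-blind pruning. Scoring imputes missing dosages as twice the sample
effect-allele frequency. The threshold grid is
{5e-8, 1e-6, 1e-4, 1e-3, 0.01, 0.05, 0.1, 0.3, 0.5}; the score maximising
ΔAUC (model with covariates + standardized PRS vs covariate-only; 0.5 when
no covariates) wins, ties to the smaller threshold, with Nagelkerke R²
reported alongside. Thresholds yielding no variants, a constant score,
fewer than four distinct scores, or a non-convergent fit are skipped with
a warning. Quartile categories use the cohort 25/50/75 percentiles with
right-closed intervals (a score equal to a cut point goes to the lower
category). Both the raw sum and a per-variant-mean score
(raw / (2 × variant count)) are emitted, the latter because quartile ranges
on a normalized scale appear in some published tables without definition.

## Association models

2×2 odds ratios are cross-products with Wald CIs
(`exp(ln OR ± 1.96·√(1/a+1/b+1/c+1/d))`); a zero cell raises unless the
optional Haldane–Anscombe 0.5 correction is enabled (off by default).
Chi-square tests are Pearson, no continuity correction. Logistic models are
fitted by Newton/IRLS with step-halving; convergence when the largest
coefficient update is below 1e-8 within 50 iterations; covariance is the
inverse observed information, so Wald ORs/CIs follow. statsmodels is the
independent oracle in the tests, never the implementation. Perfect
separation (including constant outcomes) is flagged, not raised, so
bootstrap loops can count failures. Desk-scale cohorts can make rare
covariate levels perfectly predictive (zero cases among carriers, or a
case-free reference group); such indicator columns have infinite MLEs and
are dropped with a warning — the standard collapse-into-reference remedy.
Continuous slope terms enter per 1 µg/m³/yr unstandardized; analyses are
complete-case with dropped rows logged.

## Interaction

The joint model contains the slope main effect, three quartile indicators,
three products and the adjustment covariates; per-quartile slope ORs are
exp(β₁ + β₃(q)) with SEs from the coefficient covariance, and a stratified
mode refits the slope model within each quartile (the two coincide when
the adjustment set is empty, which is tested). RERI defaults to the
standard Rothman form; the `as_printed` variant (omitting −exp(β₁), a form
that circulates in applied work, plausibly a typesetting loss) is
first-class and labelled in every output. Bootstrap: individuals resampled
with replacement (same n, unstratified), model refitted, RERI recomputed;
percentile 2.5/97.5 CI over successful refits, point estimate from the
original fit; refit failures (non-convergence or separated interaction
terms) are dropped, counted, and flag the result unreliable above 5%.
Besides the quartile contrasts, a binary contrast mode (top-quartile PRS ×
slope > 0) matches the generator's implied true RERI for coverage studies.
BCa intervals and attributable-proportion/synergy-index measures are not
implemented.

## Pipeline and reporting

`run_pipeline` executes simulate/ingest → QC → slopes → PRS scan →
association suite → interaction suite and writes five study-shaped TSV
tables (descriptives with level-wise ORs and chi-square p; slope
descriptives; slope models under crude/Model-1/Model-2; PRS-quartile
models; per-quartile slope ORs with RERI and CIs), QC exclusion reports,
the scan report, an analysis-ready cohort, a plain-text log and a JSON
manifest (package and library versions, seed, SHA-256 config hash, stage
timings). Any stage failure names the stage in the manifest, preserves
partial outputs and exits non-zero. Human tables round to 6 significant
digits; identical config + seed reproduces every table byte-for-byte.

## Validation problem sizes

The test suite validates worked odds-ratio arithmetic from printed counts;
logistic-vs-closed-form equivalence on 104,554 expanded rows; clumping
against a brute-force reference on 60 randomized 30-variant instances;
parameter recovery of γ_E, γ_G, γ_GE at n = 50,000 (all within 3 SE);
Wald-test type-I error of the product terms over 1,000 replicates at
n = 50,000 (accept 3.5–6.5% at α = 0.05); and 95% bootstrap-CI coverage of
the implied true RERI over 200 replicates at n = 5,000 with 200 bootstrap
draws (accept 88–99%; observed 94%). The coverage study sets slope_mean = 0
(keeping slope_sd = 0.88) so the worsening/improving split is balanced —
with the Taiwan-like default of −1.56 only ~4% of participants have a
positive slope and the binary contrast degenerates at that n. The
acceptance script reruns the full pipeline at n = 20,000 with a 1,000-draw
bootstrap, the generator defaults above, and reports what it computes.
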