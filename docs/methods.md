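# Methods

## The problem and the estimands

A worldwide barley collection grown at one location for many autumn-sown
seasons separates three sources of variation in days to heading from sowing
(DHS): accession identity (genetics), season (environment), and their
interaction (accession-specific environmental sensitivity). The package
treats four estimands:

1. the share of DHS variance attributable to categorical factor sets,
   via fixed-effect OLS;
2. each accession's Finlay–Wilkinson sensitivity b_i — the slope of its DHS
   on the environment index (per-season mean DHS over all accessions) — and,
   dually, each season's slope on the accessions' multi-season means;
3. between-season similarity of the panel's response (Pearson r and mean
   squared difference over accessions);
4. SNP effects on DHS in flowering-pathway genes: marginal scans, subset
   selection, prediction, standardized partial coefficients.

## Generative model of the synthetic data

    DHS_ij = μ + g_i + b_i·E_j + Σ_k β_k·x_ik + ε_ij

* `E_j` — season effect, Normal(0, season_effect_sd²), centered exactly.
* `g_i` — accession effect, Normal(0, accession_effect_sd²); the total
  accession-level genetic value g_i + Σβ_k x_ik is centered across
  accessions so the noiseless grand mean equals μ exactly.
* `b_i` — sensitivity, Normal(slope_mean, slope_sd²) truncated at zero
  (a genotype cannot respond negatively to a generally late year).
* `x_ik` — accession-constant biallelic SNP codes, Bernoulli with allele
  frequencies Uniform(0.1, 0.5); a random subset of `n_causal_snps` carries
  effects β_k ~ Normal(0, snp_effect_sd²) (or fixed |β| with random sign via
  `snp_effect_fixed`, used by power/selection simulations).
* `ε_ij` — iid Normal(0, noise_sd²).
* Covariates: vernalization requirement and longitude are coupled to b_i by
  a Gaussian copula at correlation `covariate_slope_correlation`;
  vernalization is discretized to an ordinal 0–5 scale (the scale is a
  modelling choice — field scores vary between programmes) and growth habit
  is winter for scores ≥ 3. Origin region (10 areas), country, latitude,
  kernel row and population cluster are uninformative labels.
* Missingness: exactly ⌊f·N⌋ cells masked uniformly at random (MCAR),
  chosen over Bernoulli masking so completeness counts are testable;
  phenotype cells are dropped as records, genotype cells become NA.

All randomness flows from one seed through named `SeedSequence` substreams
(season, slope, genotype, …), so the same config is bit-reproducible and
changing one component's draws never shifts another's.

### Default study conditions

| parameter | default | rationale |
|---|---|---|
| n_accessions × n_seasons | 274 × 20 | collection size and trial length emulated |
| grand_mean | 156 d | centre of the observed seasonal means (150.5–166 d) |
| accession_effect_sd | 8 d | accession means span ≈137–175 d |
| season_effect_sd | 4.5 d | seasonal means span ≈15 d over 20 seasons |
| slope_mean / slope_sd | 1.0 / 0.25 | FW slopes span ≈0.3–1.5 across the panel |
| noise_sd | 2 d | reproduces per-season FW R² ≈ 0.9–0.96 |
| n_snps / n_causal | 84 / 8 | eight-gene flowering panel |
| snp_effect_sd | 2.5 d | few-day allele effects |
| covariate_slope_correlation | −0.4 | stability increases with vernalization requirement and longitude |
| missing fractions | 0.0032 / 0.0011 | attrition ≈ 274 → 257 phenotype-complete → ≈234 genotype-complete |

## Estimation details and numerical choices

* **Factor models** are OLS with treatment-coded dummies (first level
  reference) and an intercept; the reported F is the overall model F. The
  design is rank-checked up front; a deficiency raises an error naming the
  aliased columns (found by pivoted QR). Single-level factors are rejected.
* **Environment index** includes the focal accession (the classical joint
  regression definition); with hundreds of accessions the self-contamination
  of each index point is ≤ 1/N.
* **FW fits** are closed-form simple OLS. A constant response is reported
  with slope 0 and R² defined as 0 rather than dropped — flat responders are
  the interesting stable genotypes. Unit SD uses the n−1 denominator and
  range is max − min over observed seasons. On complete balanced data the
  unweighted mean of per-accession slopes is identically 1 (Σᵢ cov(yᵢ, Ē) =
  N·var(Ē)); the test suite asserts this to 1e-10, and the same identity
  holds in the season direction.
* **Slope–covariate correlations** are Pearson r with two-sided t-test
  p-values, uncorrected; zero-variance covariates are flagged undefined, not
  dropped.
* **Season similarity**: MSE between seasons j and k is the mean over
  accessions of (DHS_ij − DHS_ik)², computed on raw DHS (so a uniform shift
  keeps r = 1 while MSE grows as the squared shift). A zero-variance season
  yields NaN correlations; its MSEs are still defined.
* **Range extrapolation** rounds half-away-from-zero to whole days
  (142.65 → 143, 185.21 → 185) and swaps endpoints for negative slopes.
* **SNP scans** residualize the response and each SNP column on the base
  design (intercept + season dummies) once via QR; this reproduces the joint
  OLS coefficient and t-test exactly (Frisch–Waugh–Lovell) at a fraction of
  the cost. Monomorphic SNPs are flagged untestable; an exact residual fit
  is flagged `separation-limit` with p = 0 rather than an underflowed
  t-value. p-values are raw (no multiple-testing correction), reported as
  −log₁₀(p).
* **Variable selection** defaults to backward elimination on the joint
  model: remove the SNP with the largest coefficient p until all
  p ≤ threshold, ties broken by genomic position (the later position is
  removed). Perfectly collinear duplicates (|r| = 1 at accession level) are
  set aside as aliases first. The L1 alternative projects out season
  dummies, standardizes SNP columns, and takes the nonzero set of a Lasso at
  α = threshold. Both are deterministic; an empty selection is a result, not
  an error.
* **Prediction reports** are in-sample; the regression of predicted on
  observed values has slope and R² equal to the model R², an identity the
  tests assert. Because SNP codes are accession-constant, the accession +
  season design spans every SNPs + season design: the SNP model's R² can
  never exceed the accession model's on the same sample, and the pipeline
  asserts this bound on every run.
* **Standardized coefficients and subset refits** use the per-accession
  mean DHS across seasons as the response: accession-constant predictors
  cannot explain within-accession (seasonal) variance, and regressing the
  season-replicated records would only dilute R² by that constant factor.
  Response and predictors are z-scored with the n−1 SD, so a single
  predictor's standardized beta equals its Pearson r.

## What the generator does and does not emulate

It reproduces the additive G + E + G×E structure, paper-scale dimensions,
accession-constant genotypes, covariate–stability coupling, and staged
attrition. It deliberately omits: population structure and kinship (SNPs are
exchangeable across accessions), linkage disequilibrium between SNPs,
weather-driven season effects (seasons are exchangeable draws), and any
correlation between accession mean and sensitivity. The last omission is
visible in the season-direction FW fits: with mean and slope independent,
per-season slopes concentrate near 1, whereas real panels — where
late-heading accessions tend to be the sensitive ones — show per-season
slopes spreading roughly 0.8–1.3. Passing recovery tests therefore
demonstrate estimator correctness under the additive model, not robustness
to structure, LD or mean–sensitivity coupling.

## Recovery precision of FW slopes

The sampling error of an estimated slope is ≈ noise_sd / (√(n_seasons−1) ·
sd(index)). At the default conditions (noise 2 d, 20 seasons, index SD
≈ 4.5 d) this is ≈ 0.10, so with true slope SD 0.25 the expected
truth–estimate correlation is ≈ 0.92, and individual simulated panels range
roughly 0.86–0.94 as the realized season spread fluctuates. Recovery of the
slope *scale* is tighter: the regression of estimated on true slopes stays
within [0.9, 1.1]. Users comparing slope rankings across panels of ~20
seasons should expect this level of attenuation; it is a property of the
design, not of the estimator.

## Problem sizes used by tests and the acceptance script

Unit and property tests run on grids from hand-checkable toys (4–10
accessions) up to the balanced 257 × 20 panel. The acceptance script runs
the full pipeline at 274 × 20 with 84 SNPs, five recovery replicates at
274 × 20, fifty selection-recovery replicates at 234 × 20 with 25 SNPs, and
one thousand null-calibration replicates at 60 × 2 — sizes chosen so the
whole script completes in well under a minute while keeping every estimate's
Monte-Carlo error small relative to the quantities reported.
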