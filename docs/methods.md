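# Methods

## Score construction and harmonization

The genetic risk score is a weighted sum of effect-allele dosages,
`raw_j = Σ_i w_i d_ij`, standardized within each cohort to zero mean and
unit **sample** standard deviation (n−1 denominator, the default of
mainstream statistical software), so association models report per-SD
effects. Standardization is per cohort, never pooled: per-SD odds ratios
are only comparable within the cohort whose SD defined them.

Dosages are read from VCF (DS FORMAT field preferred; GT hard calls
converted to 0/1/2 otherwise) or from a TSV matrix, and aligned to the
scoring file's effect alleles before scoring: when the file's ALT is the
effect allele the dosage is kept; when REF is the effect allele the
dosage becomes `2 − d`; strand-ambiguous palindromic pairs (A/T, C/G)
are dropped by default rather than resolved by allele-frequency
heuristics — with ~11 SNPs a single silent strand error would materially
corrupt the score, and the loss of one variant is the lesser evil. All
exclusions are reported machine-readably. Harmonization is idempotent
and invariant to ref/alt recoding of the source file (both properties
are tested).

Missing dosages are imputed with the per-variant mean (2 × allele
frequency), the standard PRS practice that keeps every sample scoreable;
the imputed-entry count is carried in the score output. An optional
filter drops variants with imputation r² ≤ 0.30; it is off by default
because scoring files are normally quality-filtered upstream.

CAD case status, where derived from stenosis, uses an inclusive
threshold: case ⇔ max(available LAD/RCA stenosis) ≥ 50 %.

## Logistic association models

Three nested presets: model 1 = score + age + sex + BMI; model 2 = score
+ age + sex + smoking + HDL + total cholesterol + systolic blood
pressure + hypertension treatment (clinical flavor) or score + age + sex
+ BMI + smoking + hypertension treatment (autopsy flavor, where lipids
and blood pressure do not exist), plus the leading genotype principal
components; model 3 = model 2 + a second standardized score. Sex enters
as a male = 1 indicator; statin use is available as an explicit opt-in
covariate (`include_statin`) rather than a default, since reasonable
analysts differ on whether it belongs in a risk-factor adjustment set.

Fitting is maximum likelihood via Newton/IRLS (statsmodels `Logit`).
Inference is Wald throughout: 95 % CI = exp(β ± z₀.₉₇₅·SE), two-sided
normal p-values — symmetric-on-the-log-scale CIs matching how such
tables are conventionally printed, at the cost of poorer behavior near
separation, which is therefore detected and raised explicitly (|β̂| > 30
or non-finite SEs). Rows with any missing model term are dropped
(complete-case); no covariate imputation is attempted, so reported n's
shrink when questionnaire covariates are missing — deliberately mirroring
how reduced analytic samples arise in practice. Rank-deficient designs
and single-class outcomes raise immediately.

Genotype PCs use the Patterson normalization: each variant column is
centered by 2f̂ and scaled by √(2f̂(1−f̂)); scores are the leading left
singular vectors scaled by their singular values, with signs fixed so
each component's largest-magnitude loading is positive (determinism).
Monomorphic variants are dropped before the SVD.

Quantile-interval analysis uses four quartile intervals (five quantile
edges) with the lowest interval as reference. Intervals are
left-open/right-closed except the first; a value equal to an internal
edge goes to the **lower** bin (deterministic tie-break). Binning is
invariant under standardization since quantiles commute with monotone
maps.

## Beta regression of calcified-plaque area

Plaque-area percentages divided by 100 are proportions in [0, 1];
morphometry produces exact 0s and 100s, which lie outside the beta
support. The Smithson–Verkuilen transform `y' = (y(n−1) + 0.5)/n` is
applied to all observations (n = number with a measured outcome), and
the number of boundary observations is reported. The model is
Ferrari–Cribari-Neto: `y ~ Beta(μφ, (1−μ)φ)`, `logit(μ) = x'β`, constant
precision φ estimated on the log scale (hence always positive), ML via
statsmodels `BetaModel`, SEs from the inverse observed information.
Exponentiated coefficients are printed in an OR column for table
compatibility, but they are odds ratios of the expected proportion
`μ/(1−μ)`, not case-control odds ratios. No dispersion covariates and no
zero/one-inflation components are offered: a single OR column is the
target output shape.

## Added predictive value (bootstrap train/test ΔAUC)

Per replicate: draw n rows with replacement, split the resample 70/30
(unstratified simple random split by default, matching the plainest
reading of a "train–test split"; `stratify_split` is available), fit the
reference and augmented logistic models on the training part, compute
both rank-based (Mann–Whitney, midrank ties) AUCs on the held-out part.
Both models share each replicate's resample and split, so the
per-replicate ΔAUC is a paired comparison. The resample is drawn
*before* the split (resample-then-split). Headline AUCs are the means of
the B per-replicate held-out AUCs; the p-value is the proportion of
ΔAUC < 0, with exact zeros counted at half weight (a measure-zero event
for continuous predictors). Replicate RNG streams are spawned from the
seed, so replicate b is reproducible regardless of B; replicates with
degenerate (single-class) resamples or splits are dropped and counted,
and more than 5 % failures aborts.

**Calibration behavior.** Under a null augmentation the p-values
concentrate near 0.5 rather than being uniform: each replicate's ΔAUC is
dominated by evaluation noise on the 30 % held-out set, so the bootstrap
spread is wider than the sampling spread of the dataset-level ΔAUC. The
test is therefore *conservative* — its type-I error at α = 0.05 is well
below 5 % (0/100 null runs in the validation suite) — and p-values just
under 0.05 indicate strong evidence. This is a property of the procedure
itself, documented here because the test suite checks conservativeness,
not uniformity.

The undersampling check subsamples the majority class without
replacement down to the minority count before rerunning the comparison.

## Synthetic cohort generator

The generator defines the study conditions for every validation:

* **Genotypes**: independent SNPs (no LD — the scored variants are
  independent lead SNPs by construction), dosage ~ Binomial(2, f) under
  HWE with f ~ U(0.05, 0.5); optional Gaussian blur clipped to [0, 2]
  mimics imputed expected counts. Weight vectors are Normal draws
  rescaled so the raw score has unit variance in expectation
  (Σ w²·2f(1−f) = 1). On-disk VCFs randomize ref/alt orientation per
  variant so reading a generated cohort exercises real harmonization.
* **Covariates**: age ~ N(62, 10) years clipped to [18, 95]; 72 % male;
  BMI ~ N(27.5, 4) kg/m²; SBP ~ N(140, 20) mmHg; TC ~ N(208, 40) and
  HDL ~ N(38, 12) mg/dL; smoking ~ Bern(0.6); hypertension treatment ~
  Bern(0.58) — marginals typical of high-risk angiography cohorts. The
  autopsy flavor omits blood pressure, lipids and statin entirely and
  masks smoking/hypertension at 65.5 % (postal-questionnaire
  non-response; 34.5 % returned).
* **CAD outcome**: logit P(case) = α + log(OR_sd)·z + covariate effects
  on centered covariates (defaults: 1.05/year age, 2.7 male, 1.83
  smoking, 1.32 hypertension treatment, 0.98/mg·dL HDL; missing entries
  contribute average risk). The intercept α is calibrated by bisection so
  the population case fraction hits its target (default 0.70, the 70/30
  imbalance of the large clinical preset) to 1e-4 — robust to arbitrary
  effect maps, unlike closed-form approximations. The default per-SD OR
  is 1.4. The second (meta) score has no outcome effect unless
  `meta_in_outcome` is set: a second independent cause of CAD would
  attenuate the primary score's marginal per-SD OR through logistic
  non-collapsibility, breaking the stated study condition.
* **Calcification**: logit(μ) = −1.5 + log(1.78)·z + 0.3·z_age, φ = 5;
  LAD and RCA drawn independently. The intercept puts mean calcified
  area near 18 %, the age slope corresponds to roughly a 1.03/year
  proportional-odds effect, and φ = 5 gives the broad, boundary-heavy
  distributions morphometry produces.
* **Stenosis** is a noisy monotone transform of calcification plus a
  case offset, provided solely so threshold-based case definitions are
  exercised; no biological fidelity is claimed.
* **Presets** mirror the three target cohorts' size, imbalance and
  flavor: clinical n = 2742 (70 % cases) and n = 133 (74 %), autopsy
  n = 622 (53 %, lifestyle 65.5 % missing).

Everything derives deterministically from one seed via spawned RNG
streams (weights, genotypes, covariates, outcomes are independent
streams, so changing the meta-panel size does not reshuffle covariates);
generated bundles are byte-identical across runs.

**What passing tests do and do not show.** The generator has no LD, no
population structure (beyond a two-cluster PCA fixture), no
genotype-covariate correlation, and missingness independent of outcome
(MCAR). Recovery and calibration results therefore validate the
*estimators and procedures*, not robustness to confounding,
informative missingness or LD-induced weight misspecification, which
real cohorts may exhibit.

## Validation problem sizes

The validation suite and `scripts/acceptance.py` use: per-SD OR recovery
at n = 3000 with 200 replicates (±10 % on the log-OR, CI coverage in
[92 %, 98 %]); calcification-slope recovery at n = 600 with 200
replicates plus a 200×200 grid-search ML cross-check on one tiny
instance; ΔAUC null calibration with 100 outer runs at n = 1500,
B = 200, and power with 50 runs at n = 3000, per-SD OR 1.5 (also rerun
balanced); quantile-gradient frequency over 200 replicates at n = 1500;
and numerical oracles (brute-force scoring sums, 2×2 closed-form odds
ratios, exhaustive AUC pair counting) at hundreds of random instances.
The full-size demonstration runs use the presets at their native sizes
with B = 1000 bootstraps.

## Known limitations

* Wald inference misbehaves near separation; separation is raised, not
  penalized (no Firth correction).
* The beta model assumes constant precision; heteroskedastic dispersion
  or genuine zero/one inflation would call for richer models that are
  deliberately out of scope.
* The ΔAUC p-value is conservative (see above); DeLong-style analytic
  variance, NRI and IDI are not implemented.
* Palindromic SNPs are dropped, never strand-resolved; scores whose
  files contain many A/T–C/G sites will lose variants.
* No multiple-testing adjustment across cohorts or models; p-values are
  nominal.
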