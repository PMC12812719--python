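# Methods

## Scope and data model

The package analyses longitudinal cohorts of adults followed with biannual
75-g OGTTs over 10 years (visit indices 0–5 ↔ years 0–10). Each visit holds
plasma glucose and insulin at 0/60/120 min, HbA1c, BMI, fat mass, and an
antidiabetic-medication flag; any field may be absent. Missing values are
empty CSV cells end to end — never numeric sentinels — and every undefined
index value propagates as `None`/`NaN` with the reason logged. Rows failing
plausibility ranges (glucose/insulin in (0, 1000), HbA1c in [3, 20]) are
rejected, not clamped: silent correction hides data errors.

Visit timing is indexed, not dated; the analysis uses only the baseline and
year-10 endpoints plus per-visit summaries, so a fixed biannual schedule is
adequate metadata.

## Classification and eligibility

Per-visit glycemic status uses the ADA three-state criteria on whatever
inputs are present (a visit with only FPG = 95 mg/dL is NGT); severity is
monotone in every input, and the medication flag forces diabetes. Visits
with no evaluable criterion are UNKNOWN and are skipped — never imputed —
when deriving a participant's progression group.

Eligibility mirrors a prospective NGT cohort: NGT on baseline labs, no
baseline medication, a fully evaluable baseline OGTT (FPG, 2h-PG and HbA1c
all present, because NGT is defined conjunctively), and an evaluable OGTT
at year 10. Exclusions record the first failing rule in that order.
Baseline NGT is assessed on labs alone so that medication use is reported
as its own exclusion reason rather than disappearing into "not NGT".

Progression defaults to the worst-ever post-baseline status
(`EVER_WORST`); a `FINAL_VISIT` rule is provided because published
incidence tables of such cohorts are sometimes consistent with
last-visit-only classification. `EVER_WORST` severity is always ≥
`FINAL_VISIT` severity, which the suite checks as a property.

## Indices and change statistics

All index formulas are the canonical forms (glucose mg/dL, insulin μU/mL):
Matsuda `10000/√(Ī·Ḡ·I₀·G₀)` with trapezoidal 0/60/120-min means,
HOMA-IS `405/(I₀G₀)` (reciprocal of HOMA-IR), HOMA-β `360·I₀/(G₀−63)`
(undefined at G₀ ≤ 63), IGI60 `ΔI/ΔG` over 0–60 min (undefined when
G₆₀ = G₀), and disposition indices as products. DIS/DBCF are baseline
minus year-10 values, so positive means decline. The
insulin-sensitivity/beta-cell measure pair is selectable: the OGTT
surrogates (Matsuda, IGI60; default) or externally supplied model-derived
values (`msi`/`mbcf` columns merged by participant and visit) — the
package deliberately does not implement any differential-equation model of
glucose–insulin dynamics; that slot is a plug-in.

## Statistical layer

* **Median splits** send elements strictly above the sample median to the
  high ("high BCF" / "large DIS") side; ties and, for odd n, the median
  element go low. The DIS split is computed *within* each baseline-BCF
  stratum: the motivating study's stratum sizes (703/702 in each BCF
  column) are only attainable with within-stratum medians.
* **2×2 chi-square** is uncorrected Pearson `n(ad−bc)²/((a+b)(c+d)(a+c)(b+d))`
  — the default convention at these cell sizes; a zero margin flags the
  statistic undefined rather than raising.
* **Group comparisons**: pooled-variance two-sample t-test for two groups,
  one-way ANOVA for three or more, Bonferroni-multiplied pairwise p-values
  (capped at 1).
* **Logistic models** are ML fits (Newton/IRLS via statsmodels) with Wald
  95 % CIs. Standardization centers and scales *continuous* covariates
  (more than two distinct values) to unit SD and leaves binary covariates
  untouched, since its purpose is unit comparability of predictors; it is
  an affine reparameterization, so standardized and unstandardized fits
  have identical deviance (asserted in tests). The two outcomes are
  separate binary contrasts against non-progressors, excluding the third
  group; non-convergence or diverging coefficients raise a separation
  error rather than returning garbage. Degenerate (constant) covariates
  are dropped with a warning.
* **Little's MCAR test** groups rows by missingness pattern and compares
  pattern-wise observed means with Gaussian-ML grand means and covariance
  estimated by EM under ignorable missingness:
  `d² = Σⱼ nⱼ (ȳⱼ − μ̂ⱼ)' Σ̂ⱼⱼ⁻¹ (ȳⱼ − μ̂ⱼ)`, df = Σⱼ kⱼ − K,
  asymptotically χ² under MCAR. An EM-free shortcut (available-case means
  with complete-case covariance) was measured anti-conservative
  (~15 % rejection at nominal 5 % with correlated variables at n = 1000),
  so the EM-based canonical form is used; its hand-checkable oracle in the
  tests is the closed-form factored-likelihood ML solution for monotone
  bivariate missingness. The test assumes approximate normality: audit
  tables should use near-normal variables (e.g. BMI trajectories) — on
  strongly skewed mixture variables the χ² approximation degrades at small
  pattern sizes.

## Synthetic cohort generator

The generator emulates the structure the analysis assumes, with defaults
frozen to the motivating study's published conditions: n = 2,810; latent
group mixture 824/1803/183 (non-progressors / prediabetes / diabetes
progressors); group-conditional log-normal baselines for latent insulin
sensitivity (means 1.39/1.30/1.28, SDs 0.46/0.53/0.60 on the model-derived
mSI scale) and beta-cell function (0.44/0.36/0.29, SDs 0.26/0.25/0.28 on
the mBCF scale); 10-year fractional declines 16.8/31.0/46.2 % (SI) and
9.4/18.4/43.6 % (BCF), applied log-linearly with per-subject slope jitter
(relative SD 0.25 — the within-subject tracking of such indices is not
published, so this is a documented free parameter).

Observed values are synthesized by inverting the index relations:
`I₀ = 405/(k_SI·SI·G₀)` (HOMA-IS inversion, k_SI = 0.60 converting the mSI
scale to HOMA-IS units), `I₆₀ − I₀ = k_BCF·BCF·(G₆₀ − G₀)` (IGI inversion,
k_BCF = 1.55), `I₁₂₀ − I₀ = 0.72·(I₆₀ − I₀)`; post-load glucose increments
grow as `(D₀/D_t)^γ` with disposition D = SI·BCF and γ = 0.5; HbA1c is a
linear-in-mean-glucose function plus subject and visit noise; fasting
glucose and HbA1c drift upward in proportion to each subject's realized
relative SI decline (no decline ⇒ no drift). Multiplicative observation
noise uses CVs of 4 % (glucose), 12 % (insulin) and 5 % on the exported
model-derived `msi`/`mbcf` columns (model-derived indices are estimates,
not oracles; noiseless export also produces quasi-separated logistic fits
at small n, which real data do not).

Baseline draws are rejection-sampled into the NGT region (FPG < 100,
2h-PG < 140, HbA1c < 5.7) — the cohort's enrolment screen. Published
baseline tables describe the *screened* population, so the pre-screen
group means are set slightly above the printed values such that
post-screen means land on them (e.g. simulated baseline BMI 24.1 (2.9)
kg/m², FPG 80.5 mg/dL at n = 2,810). A consequence used in testing: with
zero observation noise and zero declines, every generated participant is
NGT at every visit.

Follow-up visits (never baseline) are dropped either completely at random
or with BMI-dependent log-odds (`mar_bmi`, slope 1.0 per BMI SD) to
exercise the MCAR test's null and power behaviour.

`inject_effects` replaces threshold-driven progression with labels drawn
from an explicit logistic model on the realized (exported) DIS/DBCF with
user-chosen log-odds coefficients; the intercept is solved numerically for
a target marginal event rate (default 183/2810). Because labels are drawn
from the same covariate values the analysis later uses, the recovery fit
is a textbook consistent MLE — the basis of the parameter-recovery checks.

**What passing tests do and do not show.** The generator reproduces
marginal baseline moments, programmed decline trajectories, and a
threshold-crossing route to dysglycemia, and its classifier-driven
progression mix (~39/56/5 %) is realistic rather than exact. It does not
reproduce the real cohort's correlation structure beyond what the index
inversions imply, its HbA1c–glucose coupling is a simple linear surrogate,
and there is no treatment dynamics after diabetes onset. Consequently,
pipeline results on synthetic data validate the *machinery* (formulas,
classification, stratification, model fitting, calibration of tests), not
the study's numerical effect estimates: baseline-table means, logistic
coefficient values and trajectory percent-declines of the real cohort
require the real data and are deliberately out of scope.

## Numerical choices and problem sizes

Rounding in rendered tables is half-away-from-zero to one decimal (the
convention of printed clinical tables). Logistic fits cap Newton
iterations at 100 and declare separation if |β| > 30 or convergence fails.
EM for the MCAR test iterates to a 1e-10 parameter shift (max 500
iterations) with a 1e-12 ridge for numerical safety. Monte-Carlo test
sizes — 2,000 null tables for chi-square calibration (plus an exact
binomial enumeration of the same rejection probability), 200 replicates of
n = 1,000 cohorts for the MCAR/MAR rates, and 100 replicates of n = 2,810
for parameter recovery — keep the full suite around a minute while leaving
Monte-Carlo error well inside the asserted bands.

## Known limitations

* Percent-decline figures printed in the motivating literature are
  internally inconsistent between sections; outputs here are validated
  against the defining formula only.
* The disposition-index scale of model-derived values is whatever the
  plugged-in model supplies; the package multiplies, it does not rescale.
* The pipeline's odd-n median convention (median element low) makes the
  large-decline side the smaller half; published stratum Ns suggest some
  studies use the opposite convention. The deterministic incidence fixture
  encodes published counts directly and is unaffected.
* No survival/time-to-event modelling, no multiple imputation, no 30/90-min
  OGTT time points, and no IFG/IGT subtyping beyond the three-state scheme.
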