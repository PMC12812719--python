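# glycoprog

Longitudinal OGTT analysis of progression to dysglycemia: who develops
prediabetes or type 2 diabetes over a decade of biannual oral glucose
tolerance tests, and how much of that risk is carried by *declining insulin
sensitivity* as opposed to *declining beta-cell function*.

The package is aimed at epidemiologists and metabolism researchers working
with cohort data of the form *one row per participant-visit* containing
plasma glucose and insulin at 0/60/120 min of a 75-g OGTT, HbA1c, BMI, fat
mass and medication status. It provides a tested, reusable pipeline for:

* **Glycemic classification** per visit (ADA three-state scheme): diabetes
  if FPG ≥ 126 mg/dL, 2h-PG ≥ 200 mg/dL, HbA1c ≥ 6.5 %, or antidiabetic
  medication; prediabetes if FPG ∈ [100, 126), 2h-PG ∈ [140, 200), or
  HbA1c ∈ [5.7, 6.5); otherwise normal glucose tolerance (NGT).
* **Surrogate indices** (glucose mg/dL, insulin μU/mL):
  * Matsuda index `10000 / √(Ī·Ḡ·I₀·G₀)` with Ī, Ḡ the trapezoidal
    0/60/120-min means (AUC/120 min),
  * `HOMA-IS = 405/(I₀·G₀)` and its reciprocal HOMA-IR,
  * `HOMA-β = 360·I₀/(G₀ − 63)`,
  * insulinogenic index `IGI60 = (I₆₀ − I₀)/(G₆₀ − G₀)`,
  * disposition indices as products of an insulin-sensitivity and a
    beta-cell measure (oDI = Matsuda × IGI60; mDI = mSI × mBCF for
    externally plugged-in model-derived values).
* **Change statistics** DIS and DBCF = baseline minus year-10 value of the
  chosen insulin-sensitivity / beta-cell measure (positive = decline).
* **Progression groups** (non-progressor / progressor to prediabetes /
  progressor to diabetes) from post-baseline visit classifications, under a
  worst-ever-status or final-visit rule.
* **Median-stratified incidence**: low/high beta-cell function at baseline
  (cohort median), large/small DIS within each stratum (within-stratum
  median), with uncorrected Pearson 2×2 chi-square tests.
* **Logistic model suite** for each outcome contrast (prediabetes vs
  non-progressors; diabetes vs non-progressors): Model 1 = DIS + DBCF,
  Model 2 = + sex, age, BMI, Model 3 = + baseline IS/BCF median categories;
  unstandardized and standardized coefficients (continuous covariates
  centered/scaled to unit SD) with Wald 95 % CIs, and the DIS:DBCF ratio of
  standardized coefficients as the relative-strength summary.
* **Missing-data audit** with Little's MCAR test (EM-based Gaussian ML).
* **A calibrated synthetic-cohort simulator** that emulates the structure
  of a 10-year Korean NGT cohort (N = 2,810), for testing and power work
  when the real data are not available.

## Worked example

```bash
glycoprog simulate --out cohort.csv --seed 1 --n 2810
glycoprog analyze --in cohort.csv --outdir report --seed 1
```

`report/stratified_incidence.txt` (output of the run above):

```
Low beta-cell function: Large DIS (N=609)  Small DIS (N=609)
  T2D_P         82 (13.5%)       16 (2.6%)   P=<0.001
  PREDM_P      389 (63.9%)     328 (53.9%)   P=<0.001
  NON_P        138 (22.7%)     265 (43.5%)   P=<0.001

High beta-cell function: Large DIS (N=609)  Small DIS (N=609)
  T2D_P          29 (4.8%)       10 (1.6%)   P=0.002
  PREDM_P      386 (63.4%)     270 (44.3%)   P=<0.001
  NON_P        194 (31.9%)     329 (54.0%)   P=<0.001
```

Reading: of the 2,810 simulated participants, 2,436 are eligible (NGT at
baseline, year-10 OGTT present; the run log itemises the 374 exclusions).
Within **both** baseline beta-cell strata, the half of the cohort with the
larger 10-year insulin-sensitivity decline progresses to diabetes and
prediabetes far more often (e.g. 13.5 % vs 2.6 % diabetes incidence in the
low-BCF stratum) — the qualitative signature the pipeline is designed to
quantify. `report/model_suite.txt` then shows the logistic models, e.g.

```
Outcome: progression to preDM | Model 1 (n=2299)
  dis                beta   0.36 (0.31, 0.42)  std   0.65 (0.55, 0.75)
```

with standardized DIS coefficients exceeding the DBCF ones (DIS:DBCF
ratio > 1), i.e. insulin-sensitivity decline carries more of the risk per
SD than beta-cell decline in this simulated cohort.

A deterministic label fixture reproducing the published stratified-incidence
table of the motivating 2,810-participant study ships with the package:

```python
from glycoprog import build_table2_fixture, stratified_incidence
table = stratified_incidence(build_table2_fixture())
print(table.counts.loc["T2D_P", ("LOW", "LARGE")])   # 45
print(round(table.percentages.loc["T2D_P", ("LOW", "LARGE")], 1))  # 6.4
```

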