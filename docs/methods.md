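# Methods

## Problem and scope

After aneurysmal subarachnoid hemorrhage (aSAH), outcome is driven both by
the brain injury of the first ~72 hours (early brain injury, EBI) and by
dysfunction of extracerebral organs. This package implements an early
risk-stratification pipeline around two scores computed from admission data:

* **LODS** (Logistic Organ Dysfunction System): worst first-24-hour values
  across six organ systems, each mapped to 0/1/3/5 points and summed
  (total 0–22). The total is also reported with the neurologic (GCS)
  component removed (0–17) to isolate extracerebral dysfunction.
* **EBI grade** (1–5): one point for persistent loss of consciousness, one
  for global cerebral edema, plus 1–3 points for the categorized total
  intracranial blood burden (Hijdra cisternal 0–30 + Le Roux ventricular
  0–16 + 0–3 points for ABC/2 hematoma volume; maximum 49; bands
  0–19 / 20–29 / 30–49). Grade ≥ 3 is classified severe.

The analysis stage relates LODS to three dichotomous endpoints — severe
EBI, unfavorable 3-month outcome (mRS > 2) and in-hospital death — via ROC
analysis at a fixed cutoff of 7 (test-positive means LODS > 7), 2×2
diagnostic metrics, odds ratios and simple logistic fits, and fits a
multiple linear regression of mRS on age, treatment modality, LODS, EBI
grade and the Charlson Comorbidity Index (CCI).

Imaging grades, consciousness and edema flags are expert-read *inputs*; no
image processing is in scope. No mortality-probability transform of LODS is
computed, and no APACHE II / SAPS II scores.

## Scoring conventions

* **Interval boundaries.** Bands printed with decimal upper edges
  ("10–19.9") are implemented half-open at the next threshold: urea
  [10, 20) → 3, ≥ 20 → 5; SBP [90, 240) → 0; creatinine [1.20, 1.60) → 1;
  and so on. This matches the printed decimals and leaves no gaps.
* **Per-system aggregation.** A system's score is the *maximum* severity
  triggered by any of its variables (the original LODS convention); the
  total sums across the six systems. Within-system summation would exceed
  the documented per-system maxima.
* **Platelets and PT.** Platelet count < 50×10⁹/L scores 1 point, and the
  prothrombin-time criterion is read as seconds above control (> 3 s → 1),
  both per the source scoring system; the commonly circulated typeset table
  misaligns these rows.
* **Worst-value convention.** Scoring uses the most severe value of the
  first 24 h, hence min/max extremes in `OrganObservations`. Urine output
  is deliberately non-monotone (oliguria < 0.5 L → 5, polyuria ≥ 10 L → 3).
* **Missing data.** A missing variable scores 0 (normal) and is recorded in
  `missing_fields`; scoring decisions are logged at debug level. A row with
  *every* field missing is an error.
* **Units.** Creatinine and bilirubin in mg/dL, urea in mmol/L; PaO2/FiO2
  accepts mmHg (threshold 150) or kPa (threshold 19.9) behind an explicit
  unit tag — never a silent conversion.
* **EBI boundary cases.** A hematoma volume of exactly 10 or 30 mL falls in
  the 2-point band (the printed "10–30 ml" read inclusively); no hematoma
  contributes 0 points; a completely blood-free scan still receives burden
  category 1, so the minimum grade is 1.
* **CCI.** Classical non-age-adjusted weights, because age enters the
  multivariate model as its own covariate. Mutually exclusive severity
  pairs (e.g. mild vs. moderate/severe liver disease) are validation errors.

## Statistical choices

* **AUC** is the Mann-Whitney rank statistic with ties counted 1/2
  (identical to the trapezoidal area under the empirical curve). The 95% CI
  uses the Hanley-McNeil normal approximation; the method is recorded in
  the report so a bootstrap/DeLong variant can be swapped in.
* **Cutoff.** The default is the fixed clinical cutoff 7 with strict
  positivity (score > 7); `--cutoff auto` selects the Youden-index
  maximizer, ties broken toward the lower (more sensitive) threshold.
* **Odds ratios** are cross-product ratios with Woolf logit CIs; when any
  cell is empty the Haldane-Anscombe +0.5 correction is applied and
  flagged. A 2×2 with an empty margin is explicitly not estimable.
* **Logistic fits** are maximum likelihood via iteratively reweighted least
  squares (Newton), convergence tolerance 1e-8, at most 100 iterations,
  with Wald SEs; perfect separation is detected up front and raised naming
  the covariate. The endpoint fits are logistic; the multivariate model of
  mRS is ordinary least squares (consistent with an estimate/|t| table on
  an ordinal 0–6 outcome), with t-based CIs from the unbiased residual
  variance. Both fits are executed through statsmodels behind the
  package's interfaces.
* **Median CIs** use the distribution-free order-statistic (binomial)
  method, recorded in the output metadata; no headline quantity depends on
  the CI bounds, only on the median itself.
* **p-values** are printed to four decimals, with anything below 1e-4
  rendered as "<0.0001".
* **Degenerate inputs.** An endpoint with a single outcome class is
  reported as "not estimable" with a reason, and the pipeline still exits
  successfully; undefined diagnostic metrics carry an explicit marker
  rather than NaN.

## Synthetic cohort generator

Patient-level data for the reference cohort were never deposited (only
summary tables), so the pipeline ships a seeded generator whose defaults
reproduce the reference cohort's published anchors: n = 324-shaped
marginals, severe-EBI prevalence 0.38, unfavorable-outcome prevalence 0.27,
in-hospital mortality 0.068, age 55.9 ± 13.6 years, clipping fraction
173/324, and a LODS marginal equal to the published frequency column
renormalized (the published LODS median/range text is internally
inconsistent with that column, so the marginal is documented as
approximate). The published mRS column itself sums to 323 and slightly
disagrees with the stated favorable rate; the generator therefore uses the
mRS *shape* within strata rescaled so that P(mRS > 2) and P(mRS = 6) equal
the configured prevalences exactly.

Mechanics: one latent severity z ~ N(0,1) per patient drives three Gaussian
links (LODS, EBI severity, mRS), each `loading · z + noise`. A
single-factor latent-trait design was chosen over a copula because the
configured AUC is then solvable before simulation: the correlation between
the LODS and EBI links is found by root-finding on the *exact* tie-aware
AUC of the discretized LODS score against the thresholded severity latent,
computed from bivariate-normal orthant probabilities — so discretization
ties are handled analytically, and the realized AUC converges to the
configured 0.78 as n grows (verified within ±0.03 at n = 5,000).

LODS totals are assigned by inverse-CDF on the configured marginal and
converted to raw physiology through deterministic "witness" observation
sets that the scorer maps back to exactly the assigned total — a
constructive proof that every total 0–22 is attainable, and a guarantee
that the scorer itself stays in the loop. EBI grades drawn from the
severity latent are decomposed into (loss-of-consciousness, edema, burden
points), the burden into Hijdra/Le Roux/ICH components, and those into
per-cistern grades, per-ventricle grades and hematoma diameters (volume
bands are drawn with small interior margins so CSV float formatting cannot
move a volume across a band edge); re-scoring the generated raw inputs
reproduces every assigned grade. The mRS link loading defaults to 0.6, a
moderate outcome dependence chosen once as clinically plausible.
Comorbidity flags are independent Bernoullis at prevalences typical of a
middle-aged cohort, with severity pairs drawn hierarchically so flags never
conflict. Identical seed ⇒ byte-identical CSV.

**What the generator does not emulate:** vasospasm/delayed cerebral
ischemia, treatment effects, informative missingness, measurement error in
imaging grades, or any dependence between comorbidities and severity.
Passing calibration/recovery tests therefore demonstrates that the
*estimators and pipeline* are correct under a known generating law — not
that the synthetic cohorts are clinically realistic in every respect, nor
that cohort-level effect sizes from real data are reproduced.

## Problem sizes

Unit and boundary tests run on enumerations and 10,000-observation random
sweeps (seconds). Calibration checks use n = 20,000 (three binomial
standard errors), discrimination recovery n = 5,000 (±0.03), and CI
coverage 500 replicates at n = 1,000 — sizes at which the checked
tolerances are several sampling standard deviations wide. The analysis
drivers use a study-sized cohort (n = 324) plus an n = 5,000 cohort to
show convergence of the AUC to its configured target.

## Known limitations

* The headline cohort-level results of the reference study (AUC 0.78 with
  its CI, OR 6.03, sensitivity 73% / specificity 70% / PPV 60% / NPV 80%,
  and the regression coefficient tables) require the unavailable
  patient-level data and are *not* reproduced; the package instead proves
  its estimators on synthetic cohorts with known truth.
* The order-statistic median CI is one of several defensible choices; the
  reference summaries' CI method is not identifiable from summary data.
* The OLS model treats mRS as interval-scaled, as the reference analysis
  does; an ordinal (proportional-odds) model would be the stricter choice
  and is out of scope here.
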