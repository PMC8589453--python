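# Methods

## The estimation problem

Given a cohort table (one subject per row: chronological age CA, gender, a
group label, biomarker columns), the package estimates each subject's
biological age (BA) and derives dAge = BA − CA and age ratio = BA/CA to
compare groups and to validate against mortality.  All models are
calibrated on *control* subjects only, per gender, and applied
out-of-sample to held-out controls and to disease groups.

## KDM1

Assumptions: BA = CA + R_BA with E[R_BA] = 0 and variance s²_BA, and each
biomarker linear in BA, x_j = q_j + k_j·BA + R_j with R_j zero-mean,
variance s_j².  Calibration regresses each biomarker on CA in training
controls (OLS), storing (q_j, k_j, s_j); s_j is the residual RMS with
denominator n − 2 (this convention matters only for small-fixture
reproducibility — it is negligible at realistic n).  Prediction combines
the stand-alone inversions (x_j − q_j)/k_j weighted by k_j²/s_j²; the
result is exactly the weighted-least-squares minimiser over BA, which the
test suite verifies against an independent gradient-root oracle.

Two numerical choices: s_j is floored at 10⁻¹² when forming weights, so a
noise-free calibration degrades to an equal-weight mean of the per-marker
inversions instead of dividing by zero (the noise-free loop then returns
BA = CA to machine precision); and subjects whose gender has no trained
sub-model are rejected rather than pooled, since male and female
calibration lines differ in general.

The CA-augmented variant of the estimator (which treats CA as an
additional pseudo-biomarker and estimates s²_BA) is deliberately out of
scope; the implemented estimator uses the biomarkers alone.

## MLR

Per-gender OLS of CA on the panel, prediction by the stored linear form.
No shrinkage correction is applied: the point of carrying this estimator
is precisely its regression-to-the-mean behaviour.  With noisy markers its
out-of-sample BA-on-CA slope is bounded by the multiple R² of the
calibration, hence strictly below the KDM1 slope on the same data — a
contrast the acceptance suite asserts.  Rank deficiency of the design is
detected before fitting and reported with the most collinear column pair.

## Phenotypic Age

The linear score is xb = −19.907 − 0.0336·albumin + 0.0095·creatinine +
0.0195·glucose + 0.0954·ln CRP − 0.0120·lymphocyte% + 0.0268·MCV +
0.3356·RDW + 0.00188·ALP + 0.0554·WBC + 0.0804·CA (Levine units:
albumin g/L, creatinine µmol/L, glucose mmol/L, CRP mg/dL, MCV fL, RDW %,
ALP U/L, WBC 10³ cells/µL), and the outer map is
PhAge = 141.50 + ln(−0.0053·ln(1 − xb))/0.09165.

Two caveats are inherent to this printed form and are documented rather
than silently repaired:

1. **Variant of the leading term.**  A widely circulated rendering writes
   the first term as the product "−19.907 × 0.0336 × albumin", which makes
   the score scale-degenerate.  The default variant (`"levine-sign"`)
   reads −19.907 as a stand-alone intercept with albumin coefficient
   −0.0336, the only reading under which xb is a well-formed linear score;
   the literal product reading is retained as `"paper-printed"` for
   fidelity audits.
2. **Domain.**  The outer map needs 0 < xb < 1.  In the original
   construction the quantity inside ln(1 − ·) is a 10-year mortality
   *probability* obtained from xb through a Gompertz CDF; feeding the raw
   linear score in directly, as this form does, puts typical human marker
   profiles (xb ≈ −10) outside the domain.  `compute_phage` is faithful to
   the stated form: it raises a per-subject domain error naming the
   offending term.  Test fixtures therefore use marker values solved to
   place xb inside (0, 1) and are labelled synthetic.  A related numerical
   fact: the point where the outer logarithm vanishes (PhAge = 141.50)
   requires 1 − xb ≈ e^(−189), which is not representable in double
   precision next to 1; the outer constants are instead verified through
   the algebraic identity PhAge − 141.50 = ln(−0.0053·ln(1 − xb))/0.09165.

Unit conversions (albumin g/dL→g/L ×10; creatinine mg/dL→µmol/L ×88.42;
glucose mg/dL→mmol/L ÷18.016) are exact scalars with exact inverses; the
mg/dL-based pairs are specific to creatinine and glucose respectively,
since such conversions depend on molar mass.

## Preprocessing and screening

Order: Box–Cox → standardise → winsorise → gender-adjust, recorded in the
fitted `TransformSpec`.  Every parameter — the Box–Cox λ (profile-
likelihood maximum over [−5, 5], absolute tolerance 10⁻⁶), the
standardisation mean/sd, the winsor clip values, the per-gender offsets —
is fitted on training controls and frozen before application to held-out
or disease data, so the reference transforms cannot leak information from
the groups being compared.  Markers containing non-positive values skip
Box–Cox (they are typically already near-normal); winsor limits default to
the 1st/99th percentiles, computed as order statistics (`method="lower"`),
which makes winsorisation exactly idempotent.

Screening selects markers whose univariate OLS slope on CA has p < 0.05
(threshold configurable); pairs with |Pearson r| strictly above 0.75 are
flagged as redundant, and a marker with univariate R² strictly above 0.32
is flagged for the "CA paradox" (too collinear with CA to add independent
information).  Both flags are advisory — markers are reported, not
dropped, matching the common practice of retaining e.g. creatinine despite
a high R².

## Cohort preparation

Controls with HbA1c ≥ 5.7% are excluded (strict "lower than" inclusion:
a control at exactly 5.7 is removed), as are rows missing required values
or outside the 20–80 age window; counts per rule are always logged.
Case–control matching is greedy nearest-age within gender, without
replacement, inside a 2-year caliper, with seeded tie-breaks — simple,
auditable, and checked against a brute-force assignment oracle on small
fixtures.  The training split is two thirds of controls, stratified by
gender so both per-gender models remain trainable.

## Survival validation

Cox proportional-hazards fits are delegated to lifelines (Efron handling
of tied event times, Newton iteration, Wald intervals on the log-hazard
scale).  The dichotomised analysis cuts at the in-sample median of dAge
with the high arm defined as dAge ≥ median.  An optional interaction term
(dAge term × covariate) is reported with its own hazard ratio and p-value.
Kaplan–Meier curves are product-limit estimates per group.

## The synthetic cohort generator

The generator produces data satisfying the KDM assumptions exactly: CA
uniform over the configured range (default 20–80 — uniform maximises
leverage for the calibration regressions), BA = CA + N(0, s²_BA) with
s_BA = 5 years by default, a constant BA shift in disease groups, and
biomarkers linear in BA with Gaussian noise (log-normal multiplicative
noise for CRP, keeping it positive).  Survival times are exponential with
hazard baseline·exp(log-HR·dAge) and administrative censoring — the
simplest law consistent with a proportional-hazards analysis.
Missingness is completely at random; outliers multiply a random cell by 3
or 5 (configurable), giving winsorisation something to shrink.  The random
stream draws all values before any contamination mask, so raising the
missing or outlier rate never alters unaffected cells.

The default 8-marker panel sets each marker's noise to 8.5·|slope|, i.e.
each marker alone resolves age to about ±8.5 years and the panel jointly
to about ±3 years.  This is deliberately more age-informative than
typical survey chemistry panels (where single-marker resolution is several
decades): it keeps held-out parameter-recovery checks sharp at cohort
sizes of a few thousand.  Two consequences for realism: pairwise marker
correlations in the synthetic default are ≈ 0.8 (real panels sit below
0.75, so the redundancy flag fires on synthetic data by design), and the
synthetic BA-vs-CA R² (≈ 0.9) is higher than real cohorts achieve.
Passing tests therefore demonstrate correctness of the estimators and
pipeline under the model's own assumptions — not that any particular real
panel attains this precision, nor anything about non-linear marker-age
relationships, informative missingness, or cohort selection effects,
none of which the generator emulates.

## Problem sizes and tolerances

The structural checks run at desk scale, chosen so Monte-Carlo error sits
well inside each tolerance: n = 2000 (2/3 train) for the slope ≈ 1.00 ±
0.05 and mean-dAge 0 ± 0.5 checks; n = 2000 per arm for recovering an
injected 12-year shift to ±0.5 years; n = 5000 for recovering a 5%/year
dAge hazard ratio to [1.03, 1.07].  Oracle equivalences (KDM1 vs. WLS
gradient root, MLR vs. normal equations, Cox vs. partial-likelihood
enumeration on a 6-subject fixture) are asserted at 10⁻⁸–10⁻⁶.

## Known limitations

- Reported cohort-specific magnitudes from real diabetes/survey data
  (e.g. a ~12-year T2D acceleration, HR ≈ 1.2 for above-median dAge)
  require restricted clinical data; this package reproduces the
  procedures and their structural properties on synthetic data only.
- The Phenotypic Age printed form is undefined for typical human marker
  values (see above); users wanting population PhAge values need the
  original Gompertz-CDF construction, which is out of scope here.
- Greedy matching is not globally optimal for pathological age
  configurations; it coincides with the optimum on well-separated data
  and is preferred for auditability.
- No imputation: subjects with missing panel values must be excluded (the
  exclusion stage does this) before prediction.
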