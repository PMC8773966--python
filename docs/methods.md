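# Methods

This note documents the models, algorithmic choices and limitations of
`spectsuv`. Nothing here states a number the test suite or
`scripts/acceptance.py` does not itself compute.

## SUV quantification

The pipeline starts from reconstructed, attenuation- and scatter-corrected
activity-concentration volumes in Bq/mL; reconstruction itself (OSEM,
collimator/scanner modelling, CT processing) is out of scope. Conversion
to SUVlbm (g/mL) follows the clinical formula chain:

* **Decay rate.** λ = 0.693 / T½ per hour. The rounded constant 0.693 is
  the default because it is what clinical formula sheets print; an exact
  ln 2 numerator is available (`numerator=math.log(2)`, difference
  < 0.03%). The ⁹⁹ᵐTc half-life default is 6.0067 h and is overridable —
  it is a physical constant, not a tunable of the method.
* **Actual activity.** The syringe assay is decayed to the administration
  time, the residual assay is referred to the same reference, and the net
  injected activity is decayed on to the scan time:
  `actual = decay_scan · decay1 · (A_pre − decay2 · A_post)`, with
  `decay1 = exp(λ(t_meas − t_adm)) ≤ 1`, `decay2 = exp(λ(t_post − t_meas))
  ≥ 1`, `decay_scan = exp(λ(t_adm − t_scan)) ≤ 1`. An algebraically
  independent oracle (net activity at administration time, then a single
  exponential to scan time) agrees to ~1e-16 relative and is kept as a
  test. `actual ≤ 0` (residual exceeding the assay after correction) is a
  domain error naming the patient.
* **Time arithmetic** uses wall-clock timestamps at minute resolution on a
  single clock, differences in hours, no time zones. The scan is treated
  as a single timestamp (no mid-scan vs start-of-scan distinction; vendor
  behaviour here is unspecified in practice).
* **Lean body mass** is the James formula; the female variant is
  1.07·W − 148·(W/H)², the male 1.10·W − 120·(W/H)² (W kg, H cm).
  Non-physical inputs that drive LBM ≤ 0 are domain errors.
* **SUV.** SUV = C · LBM · 1000 / A_actual with activities carried in MBq
  and converted to Bq only at this step. Only SUVmax on lean body mass is
  implemented; SUVbw/SUVpeak variants are non-goals.

## Lesion extraction

Lesions are enumerated by iterated global-maximum selection: the hottest
non-excluded voxel seeds a VOI, the VOI plus an exclusion ball joins the
exclusion set, and the loop repeats until `k_max` (default 5, the
per-category cap used clinically) or until the next maximum falls below a
floor. Choices:

* **VOI growth**: 26-connected component of voxels ≥ 40% of the seed SUV,
  clipped to a 15 mm ball around the seed. Vendor VOI tools are
  proprietary; fixed-fraction thresholding at 40% is standard oncology
  practice, and all three knobs (`frac`, `radius_mm`, connectivity via the
  structuring element) are configuration-exposed.
* **Exclusion**: besides the clipped VOI and the seed ball, the *full*
  unclipped threshold-connected component of the seed is excluded, so an
  extended uniform lesion cannot be re-selected from just beyond the ball
  (with ties broken lexicographically the seed can sit at a lesion's edge,
  where a ball alone does not cover it).
* **Stop floor**: 2× the median of nonzero voxels, a background proxy that
  replaces the operator's judgement with a deterministic rule; overridable.
* **Tie-break**: equal maxima resolve to the smallest (i, j, k) in
  lexicographic order — deterministic and implementation-independent.
* Both lesion categories use the same algorithmic extraction; category
  labels always come from the input (or generator). The visual-assessment
  step used clinically for degenerative lesions is not implementable, and
  CT-based morphological classification is a non-goal.
* Adjacent lesions with merged uptake cannot be split (the disjoint-VOI
  rule is this package's choice); `top_k_per_category` deduplicates equal
  SUVmax values within a patient/category before keeping the top k, so
  the retained values are distinct.

## Cohort statistics

Metastatic is the positive class throughout; the decision rule is strict
("positive if SUVmax > t").

* **Mann–Whitney U** uses midranks for ties; the two-sided p-value comes
  from the normal approximation with tie-corrected variance and continuity
  correction (scipy). An exact-enumeration mode iterates over every group
  assignment on the shared midranks and serves as the small-sample oracle.
  The approximation's worst-case deviation from exact enumeration over all
  tie-free instances with n₁+n₂ ≤ 12 is 0.088 (at n = 4) and shrinks with
  n; at the cohort sizes analysed here (hundreds per group) it is
  negligible. Heavily tied tiny samples can deviate more; exact mode is
  the right tool there.
* **ROC/AUC**: thresholds are the distinct observed scores plus a −∞
  endpoint; the trapezoidal AUC then equals U/(n₁n₂) exactly (midrank
  identity, property-tested to 1e-12).
* **AUC confidence interval**: DeLong placement-value variance with a
  normal-theory interval clipped to [0, 1]; degenerate separation returns
  a point interval with a warning. A 2000-resample bootstrap is kept as a
  test oracle (agreement within 0.01 at moderate n).
* **Youden cut-off**: maximizes J = sens + spec − 1 over the observed
  thresholds; plateau ties resolve to the smallest finite threshold, so
  the reported cut-off is the lowest SUVmax achieving optimal J.
* **Bins and overlap**: the breakdown bins are [min, 20), [20, 27),
  [27, ∞) g/mL with boundary values assigned upward (an SUVmax of exactly
  27.00 counts as "27 or above", the assignment consistent with published
  bin counts); edges are configurable. The overlap interval is
  [min(metastatic), max(degenerative)], closed, with counts of all values
  inside.
* Percentages are rounded to 1–2 decimals only in reports; internal math
  is unrounded. No multiple-testing correction is applied (single
  comparison).

## Synthetic cohort generator

The generator's defaults *are* the study conditions: 70 female patients,
236 metastatic and 179 degenerative lesions allocated 1–5 per patient per
category, region frequencies proportional to the published localization
table, age 59.36 ± 11.45 y, injected activity 673.61 ± 56.64 MBq,
injection-to-scan delay 176.32 ± 34.47 min.

* **SUVmax distribution family**: lognormal truncated to the published
  per-category [min, max], because the real samples are right-skewed and
  reject normality while the printed summaries give only mean, sd and
  range. Calibration solves the two truncated-moment equations for
  (μ, σ) with a hybrid root finder started from the closed-form
  untruncated match μ = ln m − ½ln(1+(s/m)²), σ² = ln(1+(s/m)²);
  convergence is required to 1e-6 relative (verified against a quadrature
  oracle) and sampling is inverse-CDF on the truncated interval.
* **Allocation**: one lesion per patient per category is mandatory; the
  surplus is multinomial across patients, clipped at 5 with deterministic
  rebalancing, so category totals are met exactly.
* **Patient weight/height** (70 ± 12 kg, 163 ± 7 cm, truncated to
  plausible ranges) are invented plumbing for phantom/quantification
  realism — no such distributions are published — and never enter the
  statistics stage.
* **Per-lesion SUVs are i.i.d.**: no within-patient correlation is
  modelled because none is reported. Real cohorts likely correlate lesions
  within patients, which would widen seed-to-seed variability of the
  cohort statistics relative to this generator.
* The true per-lesion distribution shape is unknown beyond its moments
  and range; the calibrated lognormal reproduces those but not
  necessarily tail behaviour, so ROC-derived quantities (AUC ≈ 0.96,
  cut-off ≈ 16 g/mL, and especially the sensitivity/specificity operating
  point) are shape-dependent and treated with wider tolerances; the
  operating point is reported but not gated.

## Digital phantoms

`build_phantom` inverts the SUV mapping: prescribed true-SUV spheres are
converted to concentrations C = SUV · A_actual(Bq)/(LBM·1000) for a given
patient, painted on a low background (default SUV 1), optionally blurred
(Gaussian, FWHM in mm) and degraded with Poisson noise (`gain` counts per
Bq/mL; counts are Poisson(gain·C)/gain). Overlapping spheres are
rejected. Noise-free, blur-free phantoms must round-trip SUVmax exactly;
with Poisson noise the recovered SUVmax is a maximum over many voxels and
carries an upward bias of order z*/√(SUV·gain) (z* the extreme-value
quantile of the sphere's voxel count), which sets the gain needed for a
given accuracy — 1% recovery needs gain ≈ 10⁴ counts per SUV unit.

## Problem sizes

Simulation-based checks use 50 seeds at the study's 236/179 sample sizes
(seconds of runtime); calibration round-trips use 10⁶ draws; phantoms are
48³ grids at 4 mm spacing with 12–20 mm spheres. These sizes keep the
whole suite fast while leaving Monte-Carlo error well inside every
asserted tolerance.

## Known limitations

* No DICOM ingestion, no reconstruction physics, no anatomy: phantoms are
  geometric. Passing tests demonstrate correctness of the quantification
  and statistics chain, not robustness to reconstruction artefacts,
  partial-volume effects or patient motion.
* The camera calibration factor is assumed absorbed into the input Bq/mL
  volumes.
* Region labels are consumed, never inferred from coordinates.
* The report JSON is validated against the pydantic model that also
  generates the shipped `report_schema.json`.
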