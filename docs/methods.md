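# Methods

## Scoring model

Each of 12 thoracic fields carries an aeration pattern in {N, B1, B2, C},
scored 0–3. Regions are fixed sets of four field indices (ventral 1,2,7,8;
intermediate 3,4,9,10; dorsal 5,6,11,12; fields 1–6 right hemithorax, 7–12
left, mirrored). Within a region the anterior/superior ordering of the two
fields per hemithorax is a file-format convention only: every statistic the
package computes is a sum or distribution over a region, hence invariant to
within-region order. Missing or unscorable fields are rejected rather than
imputed; the analysis assumes complete 12-field exams.

## Diagnostic-accuracy conventions

* Positive class: non-focal morphology. Test positive ⇔ score ≥ cutoff.
* The empirical ROC table enumerates cutoff 0, every observed score value,
  and a trailing "greater than max" sentinel (sensitivity 0, specificity
  100). AUC is the trapezoid rule over the (1 − specificity, sensitivity)
  polyline, which under ties equals the tie-corrected Mann–Whitney pair
  statistic (asserted against a brute-force oracle in the tests).
* Youden cut-point: maximizer of J = sens + spec − 1 over table rows, ties
  broken toward the smallest cutoff.
* Likelihood ratios LR+ = sens/(1 − spec) and LR− = (1 − sens)/spec are
  undefined (rendered blank) at specificity 1 and 0 respectively.
* Binomial 95% CIs are exact Clopper–Pearson (via the beta-quantile form).
  PPV/NPV come from the cohort's own confusion matrix, with no external
  prevalence adjustment, and are reported as absent when a predicted class
  is empty.
* Cohen's κ uses chance agreement from marginal products; its CI uses the
  Fleiss–Cohen–Everitt large-sample variance. Identical ratings yield the
  degenerate CI (1, 1).
* Rounding: ROC-table percentages to two decimals, likelihood ratios to
  four; narrative percentages to whole percent, half rounded up
  (`percent-half-up-v1` in report metadata).
* Quantiles: linear interpolation between order statistics (the numpy
  default). Descriptive medians/IQRs in reports use this convention
  throughout; other software's quantile rules can differ by up to one score
  point on 20-patient strata.

## Fixture reconstruction

An empirical ROC table over an integer score determines the per-class score
multisets exactly: between consecutive tabulated cutoffs c_k < c_{k+1}, the
sensitivity drop times the positive-class size is the number of positives
with score in [c_k, c_{k+1}), and absence of an intermediate cutoff row
means no patient held that value, so the whole mass sits at c_k (likewise
for negatives via specificity rises). Implied counts must be integral
within a tolerance of 0.05 patients (printed percentages carry two
decimals); violations are rejected naming the offending row.

The training fixture (25 patients) is the inversion of the published
training operating-point table: non-focal ventral scores
{0, 3, 3, 4, 4, 6×7, 7, 8×4, 9×3}, focal {0, 0, 1, 1, 1}. Recomputing the
ROC from this cohort reprints every table column and gives AUC 0.9600 with
Youden cutoff 3.

The validation fixture (22 patients) encodes the unique confusion matrix at
cutoff 3 compatible with the published whole-percent sensitivity (94% of 16
non-focal ⇒ 15/16) and specificity (100% of 6 focal ⇒ 6/6): TP 15, FN 1,
TN 6, FP 0. Within-stratum values are fixed constants chosen next to the
published stratum quantiles: non-focal {2,3,4,4,4,5,5,6,6,6,7,7,7,8,8,9}
(median 6, quartiles 4–7, matching the published 6 (4–7)); focal
{1,1,2,2,2,2} (median 2 as published; the published focal upper quartile of
3 is unattainable — any focal score of 3 would be a false positive,
contradicting the 100% specificity, so the constraint with patient-level
consequences wins).

## Synthetic cohort generator

The generator emulates the study population, not ultrasound physics. Its
defaults are the calibrated study conditions and are not tuning knobs.

* Morphology first: Bernoulli with non-focal prevalence 0.77 (the observed
  36/47).
* Regional severity: per (patient, region) a latent two-component severity
  class is drawn; given the class, the region's four fields are i.i.d. with
  pattern probabilities Binomial(3, p) over scores 0–3. The latent class
  induces within-patient correlation between fields of a region. This is
  deliberate: the published IQRs are far wider than any sum of four
  independent fields allows (a 4-field i.i.d. regional sum with median 10
  forces a lower quartile of at least 8, against a published 6), so a pure
  i.i.d. design cannot represent the data the study describes. No
  cross-region correlation is modelled (latent classes are independent
  across regions), which understates the correlation between a patient's
  regional scores; total-score dispersion is therefore somewhat narrow.
* CT ROIs: given a field's score s and the morphology, pixel counts over
  the four compartments are multinomial in configured weights w(s); each
  compartment's pixels are drawn from a normal located centrally in its HU
  bin (locations −950, −700, −300, 0; scale 40 HU), truncated to the bin.
  Truncating per-bin rather than merely to [−1000, 100] keeps empirical
  compartment fractions convergent to the weights (a −950 ± 40 component
  truncated only globally would leak ~12% of its mass past −900). The
  weight schedules encode the observed aeration trends: normally-aerated
  weight strictly decreasing and non-aerated strictly increasing in s, with
  the poorly-aerated weight constant across s in focal and increasing in
  non-focal disease. ROI size defaults to 250 pixels.
* Reproducibility: one root seed spawns a child RNG stream per patient, so
  enlarging a cohort never changes earlier patients.

### Calibration

`calibrate_to_table2` grid-searches, per (morphology, region) stratum, the
mixture (w, p_A, p_B) — component weight on a 0.05 grid, severities on a
0.01 grid — minimizing 10·|Δmedian| + |Δq1| + |Δq3| between the theoretical
regional-score distribution's discrete quantiles and the published targets,
preferring solutions whose CDF clears the 0.25/0.5/0.75 levels by ≥ 0.02 so
finite-cohort empirical quantiles are stable. All six published regional
median/IQR triples (focal 1 (0–2), 4 (2–7), 10 (6–12); non-focal 6 (4–8),
8 (5–9), 9 (8–11)) are matched exactly. Because many mixtures match the
ventral targets, the two ventral strata are selected jointly among exact
matches to also reproduce the study's headline operating point — a
theoretical Youden optimum at cutoff 3 with ventral AUC ≥ 0.9 — maximizing
the margin by which that holds. The shipped defaults are the output of this
procedure; a test asserts the round trip.

Under the calibrated defaults the dorsal score is non-discriminative (AUC
near 0.5), consistent with the published finding that dorsal aeration loss
is common to both morphologies; the generator makes no attempt to reproduce
the small-sample dorsal AUC point value.

### What passing synthetic tests does and does not show

The generator reproduces the marginal regional score distributions, the
prevalence, the gravity gradient, and score-conditional aeration trends. It
does not model within-region field correlation beyond the latent class,
cross-region correlation, respiratory-cycle or PEEP-response dynamics, or
anatomically structured CT volumes. Pipeline recovery results on synthetic
cohorts therefore validate the code path and the self-consistency of the
published tables, not clinical performance on new patients.

## Problem sizes

Default test and acceptance runs use cohorts of n = 2000 (quantile and
recovery checks; seed 0, the configuration default), 1000/500 (end-to-end
exam-level study), 10⁵ pixels (ROI convergence), 1000 replicates of n ≤ 50
(AUC oracle equivalence) and 2000 binomial draws per (p, n) cell (CI
coverage). These sizes make the binding Monte-Carlo margins several
standard errors wide.

## Known limitations

* The training-table inversion is exact only because the published table is
  internally consistent; tables with rounding inconsistencies > 0.05
  patients are rejected rather than repaired.
* The κ machinery is exercised on synthetic rater pairs only; reproducing a
  published κ would require the original raters' paired scores.
* AUC standard errors and AUC CIs are out of scope (no method is fixed by
  the conventions above); only the point AUC is computed.
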