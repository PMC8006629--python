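# lusmorph

Bedside lung ultrasound (LUS) can phenotype the morphology of the acute
respiratory distress syndrome (ARDS). Whether aeration loss is **focal**
(lobar/segmental) or **non-focal** (diffuse/patchy) — a distinction normally
made on computed tomography — determines how a patient responds to
recruitment maneuvers and higher PEEP. `lusmorph` implements the
computational chain of a two-phase diagnostic-accuracy study of this
question, for intensivists and biostatisticians who want to score exams,
re-run the analysis, or simulate cohorts with the same statistical
structure.

## What it computes

* **LUS scoring** — each of 12 thoracic fields (6 per hemithorax) carries a
  pattern `N`, `B1`, `B2` or `C`, scored 0/1/2/3 by B-line extent and
  consolidation. The total score LUS_TOT ∈ [0, 36] sums all fields; the
  regional scores LUS_V (ventral, fields 1,2,7,8), LUS_I (intermediate,
  3,4,9,10) and LUS_D (dorsal, 5,6,11,12) each lie in [0, 12].
* **Quantitative CT aeration** — per-field Hounsfield-unit arrays are binned
  into hyperinflated [−1000, −900), normally [−900, −500), poorly
  [−500, −100) and non-aerated [−100, 100] compartments (out-of-range pixels
  tracked as excluded, so fractions sum to one).
* **Diagnostic accuracy** — empirical (non-parametric) ROC tables of each
  score for non-focal morphology (test positive ⇔ score ≥ cutoff),
  trapezoidal AUC, Youden-index cut-point estimation
  (J = sensitivity + specificity − 1), confusion-matrix summaries with exact
  Clopper–Pearson 95% CIs, and Cohen's κ for inter-observer agreement.
* **ROC-table inversion** — an empirical ROC table over an integer score plus
  the class sizes uniquely determines the per-class score multisets; the
  package inverts published operating-point tables into deterministic
  patient-level fixtures (training n = 25: 20 non-focal / 5 focal;
  validation n = 22: 16 / 6).
* **Synthetic cohorts** — a seeded generator calibrated so the simulated
  regional score distributions match the published median/IQR table, with a
  ventro-dorsal aeration gradient and per-field CT mixtures whose
  compartment weights shift with the LUS score.
* **Two-phase pipeline** — Phase 1 estimates the ventral Youden cutoff on a
  training cohort; Phase 2 applies it, frozen, to a validation cohort and
  emits the report tables.

## Worked example

```python
from lusmorph import (build_training_fixture, build_validation_fixture,
                      empirical_roc, youden_cutoff, diagnostic_summary)

train = build_training_fixture()          # 20 non-focal / 5 focal LUS_V values
scores, labels = train.scores_labels()
roc = empirical_roc(scores, labels)
print(roc.to_dataframe(printed=True).to_string(index=False))
print("AUC", f"{roc.auc:.4f}", "Youden cutoff", youden_cutoff(roc))
```

```
cutoff sensitivity_pct specificity_pct correctly_classified_pct lr_plus lr_minus
  >= 0          100.00            0.00                    80.00  1.0000
  >= 1           95.00           40.00                    84.00  1.5833   0.1250
  >= 3           95.00          100.00                    96.00           0.0500
  >= 4           85.00          100.00                    88.00           0.1500
  >= 6           75.00          100.00                    80.00           0.2500
  >= 7           40.00          100.00                    52.00           0.6000
  >= 8           35.00          100.00                    48.00           0.6500
  >= 9           15.00          100.00                    32.00           0.8500
   > 9            0.00          100.00                    20.00           1.0000
AUC 0.9600 Youden cutoff 3
```

A ventral score ≥ 3 is the optimal training cut-point. Applying it frozen to
the validation cohort:

```python
vs, vl = build_validation_fixture().scores_labels()
d = diagnostic_summary(vs, vl, cutoff=3).to_dict()
print(d["sensitivity"]["percent"], d["sensitivity"]["ci95_percent"])  # 94 [70, 100]
print(d["specificity"]["percent"], d["specificity"]["ci95_percent"])  # 100 [54, 100]
print(d["ppv"]["percent"], d["npv"]["percent"])                       # 100 86
```

That is: sensitivity 94% (exact 95% CI 70–100%), specificity 100% (54–100%),
positive predictive value 100% and negative predictive value 86% for
identifying non-focal morphology. The same operations are exposed on the
command line:

```bash
lusmorph fixtures --which training --out train.csv
lusmorph roc --scores train.csv --region ventral --out roc.csv
lusmorph simulate --n 2000 --seed 17 --out cohort/
lusmorph run-study --training train.csv --validation valid.csv --out report/
```

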