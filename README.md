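# utiaudit

Urinalysis-based prediction of urine-culture positivity and an
**intersectional equity audit** of urinary tract infection (UTI) diagnosis —
comparing a machine-learning model against a rule-based proxy for the
treating physician's real-world decision, group by demographic group.

## The problem

UTI is a common emergency-department presentation, but the laboratory gold
standard (the urine culture) does not result during the visit, so clinicians
over- and underdiagnose at substantial rates, and the burden of misdiagnosis
is not distributed evenly across patient groups.  A model trained only on
objective urinalysis results can, in principle, standardise this decision —
but whether it narrows or widens cross-group differences is an empirical
question that requires an intersectional audit.

`utiaudit` is that audit as a tested, reproducible pipeline.  Because real
encounter-level EHR data cannot be shared, the package includes a
first-class synthetic cohort generator with known ground truth, so every
stage — harmonization, labeling, training, auditing — is verifiable end to
end.  It is aimed at clinical-informatics and health-equity researchers who
want to run or adapt the audit methodology on their own data.

## What it computes

* **Outcomes.** Culture positivity (≥10,000 CFU/mL of a pathogenic
  organism); *strict* UTI (culture positivity AND ≥1 sign/symptom, which
  excludes asymptomatic bacteriuria) and *liberal* UTI (culture positivity
  alone); and a composite physician-diagnosis proxy (explicit UTI code, or
  UTI-relevant antibiotic + nonspecific attributable diagnosis with no
  alternative infectious diagnosis).
* **Model.** An XGBoost classifier of culture positivity from the nine
  harmonized urinalysis components plus site — demographics are excluded by
  construction.  Patient-level 80/20 split, class-ratio observation
  weights, seeded random-search tuning scored by 5-fold grouped CV AUROC,
  cohort-wide probabilities by 5-fold cross-fitting, additive (TreeSHAP)
  attributions.
* **Audit.** For every intersectional group (age bin × sex × race ×
  ethnicity with ≥2000 encounters): overdiagnosis FP/(FP+TN),
  underdiagnosis FN/(TP+FN), accuracy and diagnostic odds ratio
  DOR = (TP/FN)/(FP/TN), for the physician proxy and for the model at three
  thresholds — a *policy-constrained* threshold (highest integer percent
  keeping model underdiagnosis below the physician's in **every** group),
  a fixed clinician treatment threshold (42.3%), and the Youden-optimal
  point.  Cross-group variance is summarised by the coefficient of
  variation of accuracy and DOR with normal-approximation 95% CIs, plus a
  decile table of physician diagnosis rates by model-predicted probability.

See `docs/methods.md` for the model, the generator's assumptions, and all
numerical choices.

## Worked example

```python
from utiaudit import (CohortConfig, TrainingProtocol, AuditConfig,
                      generate_cohort, harmonize_table, label_table,
                      split_patient_stratified, tune_and_fit,
                      cross_fit_probabilities, run_full_audit)

cohort = generate_cohort(CohortConfig(n_encounters=8000, n_patients=6800, seed=7))
labeled = label_table(harmonize_table(cohort))

protocol = TrainingProtocol(n_trials=2,
                            search_space={"n_estimators": (60, 150),
                                          "max_depth": (3, 6)}, seed=7)
train, test = split_patient_stratified(labeled, protocol)
model = tune_and_fit(train, protocol)
probs = cross_fit_probabilities(labeled, model.params, protocol)
report = run_full_audit(labeled, probs, AuditConfig(min_group_size=250))
```

printing the headline quantities of `report` gives:

```
encounters: 8000, culture-positive: 14.6%, strict UTI: 13.2%
audit groups: 7
policy threshold: 45%  youden: 35%
model     over 12.2%  under 20.4%  acc 0.867  DOR 28.0
physician over 9.3%  under 35.7%  acc 0.872  DOR 17.5
model DOR CV 0.39 (95% CI 0.00-0.95)
```

Reading: the generated cohort hits its configured prevalences (15.1%
culture positivity, ~13.4% strict UTI, up to sampling noise).  Seven
demographic cells clear the (scaled) audit floor.  Scanning thresholds
downward, 45% is the highest at which the model misses fewer strict-UTI
cases than the simulated physician in every audit group; at that operating
point the model's underdiagnosis (20.4%) is far below the physician's
(35.7%) at a modest overdiagnosis cost, and its diagnostic odds ratio is
higher (28.0 vs 17.5).  The CV line quantifies how variable the model's
DOR is across groups, with its 95% CI.

## Command line

```bash
utiaudit simulate --config cohort.yaml --seed 7 --out cohort.csv
utiaudit harmonize --cohort cohort.csv --out harmonized.csv
utiaudit label     --cohort harmonized.csv --out labeled.csv
utiaudit train     --cohort labeled.csv --out model_out/
utiaudit audit     --cohort labeled.csv --probabilities model_out/probabilities.csv --out report/
utiaudit run-all   --seed 1 --out run/        # full pipeline, demo config
```

`run-all` writes `cohort.csv`, `labeled.csv`, `model_metrics.json`,
`probabilities.csv`, `report.json`, per-group/threshold/decile CSVs and a
`manifest.json` with config hashes and artifact digests.  Identical config
and seed reproduce identical artifacts.

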