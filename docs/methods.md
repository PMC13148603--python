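# Methods

`utiaudit` implements an end-to-end, fully synthetic re-implementation of a
diagnostic-equity analysis for urinary tract infection (UTI) in the emergency
department: predict urine-culture positivity from urinalysis alone, define
UTI outcomes with and without a symptom requirement, proxy the physician's
real-world diagnosis from structured orders and codes, and compare model and
physician over-/underdiagnosis across intersectional demographic groups.

## Outcome definitions

* **Culture positivity** — growth of ≥10,000 CFU/mL of a pathogenic organism.
  The default uropathogen list (E. coli, Klebsiella, Proteus, Enterobacter,
  Citrobacter, Pseudomonas aeruginosa, Enterococcus, S. saprophyticus,
  Serratia, group B Streptococcus) is a documented, overridable default;
  growth of skin/vaginal flora at any count does not qualify.
* **Strict UTI** — culture positivity AND ≥1 UTI sign or symptom.  The
  symptom requirement separates true UTI from asymptomatic bacteriuria,
  which typically is not treated.  Symptom flags are binary inputs here
  (three flags: likely UTI symptom, likely UTI exam finding, systemic
  symptom); free-text symptom extraction is out of scope.
* **Liberal UTI** — culture positivity alone (sensitivity analysis).
* **Physician diagnosis proxy** — explicit UTI diagnosis code, or else
  (UTI-relevant antibiotic) AND (nonspecific UTI-attributable diagnosis) AND
  no alternative infectious diagnosis that would explain the antibiotic.
  Matching is exact on case-folded labels; no fuzzy matching, so the rule is
  deterministic and auditable.

## Urinalysis harmonization

Sites report dipstick and microscopy components on different scales.  The
package reconciles three dialects — qualitative words, semiquantitative
pluses, quantitative bins — onto one ordinal scale per component: 4 levels
for dipstick chemistries (negative / trace / moderate / large) and binned
microscopy counts (none / 0–10 / 11–50 / >50 per hpf).  Nitrites are a
two-level scale (negative/positive): clinical assays report nitrite
qualitatively, and for a tree-based model only the ordering of levels
matters, not their numeric spacing.  The mapping table ships as a versioned
JSON resource and can be overridden per deployment.  Unknown vocabulary
fails loudly; only true missingness (empty value) passes through as missing.
No imputation is performed anywhere.

## Synthetic cohort

No real encounter data are distributable, so the generator is a first-class,
tested module whose defaults encode the study conditions:

* culture positivity 15.1%; P(any symptom | positive) = 0.892 and
  P(any symptom | negative) = 0.863, which makes strict-UTI prevalence
  ≈ 13.4% of encounters;
* urinalysis–culture coupling through a latent infection intensity
  `z = μ·C + N(0,1)` (μ = 2.2): component c observes
  `x_c = s_c·z + √(1−s_c²)·N(0,1)` and bins it through fixed monotone
  cutpoints.  Default signal strengths put bacteria, leukocyte esterase,
  white blood cells and nitrite at the top (s ≈ 0.8–0.85), blood/protein
  weak, glucose/ketones near-null — chosen so the fitted model's
  discrimination and attribution ranking resemble a real urinalysis model
  (AUROC ≈ 0.91–0.93 at the default separation);
* demographics sampled from an explicit list of weighted intersectional
  cells; the default mix is the product of realistic ED marginals (71%
  female; ages 46/26/20/8% across 18–44/45–64/65–84/≥85; 56% White, 22%
  Black; 26% Hispanic), giving unequal cell sizes with a heavy tail of
  small cells;
* a simulated physician who acts on the latent strict truth with
  configurable sensitivity (default 0.634) and false-positive rate (default
  0.091), overridable per demographic cell — this is the knob for injecting
  group-specific over/underdiagnosis — and then *emits* structured data:
  92% of diagnoses as an explicit UTI code, the rest as antibiotic +
  nonspecific diagnosis; undiagnosed visits emit nothing, a nonspecific
  code alone, an antibiotic explained by an alternative diagnosis, or an
  antibiotic alone.  By construction the proxy rule recovers the simulated
  intent exactly, so injected rates are recovered up to Bernoulli noise;
* per-component missingness 2% (realistically low; real reports rarely
  omit panel components), reporting dialect assigned per site, 9 sites.

Four RNG streams (demographics, biology, physician, reporting) derive from
one seed, so the same config+seed is byte-reproducible and perturbing one
block leaves the others unchanged.

What the generator does **not** emulate: correlated race/ethnicity
geography, repeat-visit within-patient correlation of culture status,
contamination-driven mixed flora adjudication, site-specific assay quality,
and any real-world demographic differences in presentation.  Passing tests
therefore demonstrate the *pipeline's* correctness and the audit's ability
to recover known injected effects — not the published real-cohort values,
which require the original data.

## Classifier

XGBoost binary classifier on exactly {blood, glucose, ketones, leukocyte
esterase, nitrites, protein, bacteria, epithelial cells, white blood cells,
site}.  Demographics are excluded by construction and the model-matrix
builder raises if one leaks in.  Site is one-hot encoded (nominal);
components enter as ordinal integers; missing levels flow to the fitter as
NaN.

Training: patients (not encounters) are stratified by outcome into an 80/20
train/test split; observation weights are #neg/#pos for positives and 1 for
negatives; hyperparameters are tuned by seeded random search (default 50
trials; demo runs use 8) over max_depth 2–10, learning rate 0.01–0.3 (log),
estimators 100–1000, subsample/colsample 0.5–1.0, L1/L2 0–5, scoring each
trial by mean 5-fold grouped-stratified CV AUROC; every trial is logged.
Random search was chosen over Bayesian optimisation as a deterministic,
dependency-light optimiser with the same contract (budgeted argmax of CV
AUROC); with the seeded stream, a larger budget can never score worse than
a smaller one on the same folds.  Cohort-wide probabilities for the audit
come from 5-fold cross-fitting on the full table, each fold scored by the
model that did not see its patients.

Attribution uses the ensemble's exact tree-path additive contributions
(TreeSHAP, via the booster's native contribution predictor): per-row
contributions plus the base value equal the margin output to numerical
tolerance, and one-hot site columns are re-aggregated to a single site
feature before ranking by mean |contribution|.

## Equity audit

Intersectional groups are the exhaustive cross of age bin (18–44, 45–64,
65–84, ≥85) × sex × race × ethnicity; cells with ≥2000 encounters (default)
enter the audit, all encounters count in overall metrics.  Unknown/declined
race or ethnicity are ordinary categories.  Per group and overall, at a
given operating point: overdiagnosis = FP/(FP+TN), underdiagnosis =
FN/(TP+FN), accuracy, and diagnostic odds ratio (TP/FN)/(FP/TN) with a
Haldane–Anscombe +0.5 correction (flagged) when any cell is zero.

Thresholds (classification rule: probability ≥ t ⇒ positive):

* **policy-constrained** — the highest integer percent at which the model's
  underdiagnosis is *strictly* below the physician's in every audit group,
  found by scanning downward from 99 (the result is invariant to the
  starting point as long as the scan covers it); infeasibility (e.g. when
  model and physician coincide) raises an explicit error listing the
  violating groups;
* **fixed clinician threshold** 42.3%, applied exactly;
* **Youden-optimal** — argmax of TPR − FPR on the integer grid, ties broken
  toward the lower threshold (favoring sensitivity; noted in the report).

Under the strict definition the model's diagnosis is the culture-positivity
prediction AND the binary symptom rule; this is implemented by zeroing the
probability of asymptomatic encounters before thresholding, which is
equivalent for every threshold ≥ 1%.

Cross-group equity is summarized as the coefficient of variation (sample SD
over mean) of accuracy and DOR across audit groups, with a
normal-approximation 95% CI of half-width `z·√(1/(2(k−1)))` for k groups,
floored at zero.  This interval formula reproduces the published intervals
for all four reported CV values at k = 19 to rounding; it is recorded in the
report metadata and alternative formulas can be substituted.  The decile
table (equal-count bins by predicted-probability rank) reports the physician
diagnosis rate and observed culture positivity per decile, which reads as an
indirect estimate of the physicians' operating threshold.

## Numerical and design choices

* Integer-percent threshold grid 1–99 (stepwise 1-point scan); the external
  42.3% threshold is not rounded.
* CV requires ≥2 groups and positive mean; DOR of an all-zero table is an
  error rather than a number.
* Groups are ordered by size (descending, then key) for deterministic
  reports; report JSON is written with sorted keys and NaN mapped to null,
  so repeated seeded runs are byte-identical.
* Seed fan-out: one master seed generates per-stage seeds (cohort,
  training, evaluation bootstrap) through a seed sequence; all derived
  seeds are below 2³¹.
* Demo problem sizes: the bundled demo configuration simulates 30,000
  encounters with an 8-trial tuning budget and scales the audit floor to
  400 (the 2000-encounter floor, proportional to a cohort of this size),
  which yields ≈20 audit groups with the same structure a full-size cohort
  gives at 2000.  The acceptance script uses 20,000 encounters, 4 trials
  and a floor of 270 for the same reason.

## Known limitations

The physician simulator is intentionally simple (conditionally Bernoulli
given truth and group); it cannot represent physicians reacting to the
urinalysis itself, so model-vs-physician comparisons on synthetic data test
bookkeeping, not clinical behaviour.  The latent-intensity model induces
monotone component–outcome links only; non-monotone biology (e.g. dilute
specimens) is not represented.  Bootstrap CIs for per-group AUROC resample
encounters, ignoring within-patient correlation.  Real-cohort performance
values cannot be reproduced without the original data.
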