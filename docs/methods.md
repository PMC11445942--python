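# Methods

This note documents the models and procedures implemented in `arfpheno`,
the assumptions behind them, the parameters that matter, and the design
decisions taken where the underlying analysis left a choice open.

## Sepsis-3 identification from event streams

Sepsis is operationalized in four steps on each encounter's event stream.

**SOFA scoring.** Six organ subscores (respiration, coagulation, hepatic,
cardiovascular, CNS, renal; 0–4 each) are computed from a rubric table
shipped as a versioned CSV (`resources/sofa_rubric.csv`) encoding the
standard consensus thresholds: P/F bands at 400/300/200/100 mmHg (the two
worst bands requiring ventilatory support), platelet bands at 150/100/50/20
×10³/µL, bilirubin at 1.2/2/6/12 mg/dL, MAP < 70 mmHg plus vasopressor dose
tiers (doses in µg/kg/min), GCS bands at 14/12/9/6, and creatinine at
1.2/2/3.5/5 mg/dL. A component with no available inputs scores 0 — the
assumption of no pre-existing organ dysfunction; an alternative would be
carrying a chronic baseline, which the package does not attempt. Inputs are
carried forward on an hourly grid within a staleness horizon (default 24 h
for labs, 8 h for MAP and vasopressor doses): stale values stop contributing
rather than persisting indefinitely. Windowed aggregation uses the
per-component maximum.

**Suspicion of infection.** The earliest qualifying antibiotic/blood-culture
pair: culture within 24 h after antibiotics, or antibiotics within 72 h
after a culture; suspicion time is the earlier member. The window lengths
follow the canonical EMR operationalization and are exposed as parameters,
not asserted as the only defensible choice.

**Onset.** Onset is the earliest time in [suspicion − 48 h, suspicion +
24 h] at which total SOFA exceeds a baseline by ≥ 2. The baseline is the
minimum total over the 24 h preceding the search window, or 0 when no prior
data exist. Both windows and the baseline convention are configurable.

## Cohort construction

The index event is the first recorded ventilation parameter (PEEP, tidal
volume or plateau pressure); for surgical-ICU encounters, the first such
record at or after surgery end + 48 h. Inclusion rules run in a fixed,
documented order, and the first failure is recorded as the exclusion
reason: age ≥ 18 → sepsis-3 onset present → ICU type → index exists → IMV
≥ 24 h from index → pre-index observations present → not ventilated before
ICU arrival (the field/ED-intubation proxy). The observation window is the
half-open interval (index − 24 h, index], so the record at the index time
itself is the last pre-ventilation observation.

## Preprocessing

Median aggregation per encounter-feature over the window; values outside
closed per-feature physiologic bounds (shipped with the feature dictionary)
become missing; features missing in strictly more than 85 % of encounters
are dropped; the remainder is imputed by chained equations
(scikit-learn's `IterativeImputer`, 10 sweeps, seeded — fitted on the
derivation cohort and applied frozen to any validation cohort); highly
correlated features (|Pearson r| > 0.75) are pruned by a greedy pass in a
deterministic order (features sorted by original missingness then name; the
higher-missingness member of an offending pair is dropped, ties resolved
against the lexicographically later name); finally features are z-scored,
and the fitted scaler is reused verbatim for external cohorts. Zero-variance
features are dropped with a warning.

## Phenotype derivation and model selection

The embedding is UMAP (n_neighbors 15, min_dist 0.1, Euclidean, seeded) or
PCA; clustering is best-of-n-init k-means in embedding space, where the
three internal-validity indices are also computed (consistent with
presenting clusters in the 2-D projection). "A combination of" the three
indices is made precise as a rank vote: each (method, dimension, k)
combination scores one point for holding first place on silhouette (max),
Calinski–Harabasz (max) and Davies–Bouldin (min); the most first places
wins, ties broken by silhouette, then smaller k, then smaller dimension.
The full score table is always emitted so any alternative rule can be
audited. A best silhouette below 0.25 flags weak structure.

Reconstruction error is the mean squared difference between the
inverse-mapped embedding and the scaled input. For PCA this is the exact
linear back-projection; for UMAP the inverse map is an iterative
optimisation per point, so the MSE is estimated on a seeded subsample
(default 200 points) to bound run time.

Cluster indices are made canonical by ordering centroids lexicographically,
which renders the labelling invariant to input row order.

## Naming rubric and characterization

With exactly four clusters, the canonical names formalize the qualitative
clinical reading of the phenotypes: **B** is the cluster with the lowest
median P/F ratio (severe hypoxemic respiratory failure); among the rest
**A** has the highest median creatinine (renal/cardiac multi-organ
dysfunction); of the remainder **D** has the highest median total bilirubin
(hepatic injury/coagulopathy; lowest platelets is logged as a consistency
check); **C** is the residual mild-hypoxia cluster. Each anchor has a
clinical fallback (S/F for P/F, BUN for creatinine, AST for bilirubin) in
case the primary feature was pruned upstream. Identical anchor profiles or
a cluster count other than four leave numeric labels with an explanation.

Summary tables report per-phenotype median/IQR with Kruskal–Wallis tests
for continuous features and Chi-squared for categorical ones; mortality is
aggregated at patient level (a patient counts as dead if any encounter ends
in death within 28 days). Feature attributions come from per-cluster
one-vs-rest gradient-boosted trees whose exact tree-path contributions
decompose each prediction additively; per-phenotype importance is the mean
absolute contribution among that phenotype's members. The additivity
identity (contributions + bias = margin) is exact in exact arithmetic; the
tree library emits single-precision outputs, so the observed residual is
of order 1e-6 and tests bound it at 1e-4. The age-adjusted Charlson index
uses a bundled 17-category ICD-9 prefix mapping with the standard weights,
category deduplication, severity hierarchies (complicated diabetes,
moderate/severe liver disease, metastatic cancer) and one age point per
decade from 50–59, capped at 4.

## Transfer, outcomes and treatment effects

The transfer model is a multinomial logistic regression on the scaled,
pruned features with a stratified 80/20 split, benchmarked against random
forest, SVM and Gaussian naive Bayes; the fitted model, imputer and scaler
are applied frozen to external cohorts, and a schema check rejects
feature-set mismatches.

Survival is measured in days from the index intubation and administratively
censored at 28 days; encounters discharged alive earlier are censored at
discharge (conservative default; `assume_alive_post_discharge` switches to
counting them as alive through day 28). The Kaplan–Meier estimator and the
k-group log-rank test come from `lifelines`; tests verify both against a
hand-computed product-limit oracle and simulation calibration.
Ventilator-free days use the critical-care convention: 0 for anyone dead by
day 28, otherwise 28 minus ventilated days, requiring the final extubation
to be sustained ≥ 48 h.

High-PEEP (median PEEP ≥ 10 cmH₂O over the first 24 h of ventilation —
the exposure window is a package choice, exposed as config) effects are
estimated per phenotype: logistic propensity on the confounders (perfect
separation triggers a warning and a strongly regularized refit), greedy 1:1
nearest-neighbour matching on the logit propensity without replacement
(treated visited in descending propensity order; caliper 0.2 × SD of the
logit scores), standardized mean differences before/after, and the ATE as
the matched risk difference (negative = lower mortality under high PEEP)
with a 95 % CI from 2,000 seeded pair-resampling bootstrap replicates.
Matching without replacement estimates the effect on the matched treated
population; with a constant configured risk difference this coincides with
the ATE.

## The synthetic EHR generator

The generator defines the study conditions for every test. Each encounter
draws one latent phenotype (default prevalences 25.2/20.7/29.7/24.4 % for
A/B/C/D). Within a phenotype, feature levels come from a Gaussian copula:
organ-system blocks (respiratory, renal, hepatic, coagulation, cardiac,
hematologic, metabolic, inflammatory) share a within-block latent
correlation of 0.45, with tighter pairs for near-duplicate measurements
(hemoglobin–hematocrit 0.95, AST–ALT 0.90, MAP–SBP 0.85,
bicarbonate–base-excess 0.90, P/F–S/F 0.60) so the correlation-pruning
stage has realistic work to do. Marginals are log-normal for strictly
positive labs and truncated normal otherwise, calibrated from per-phenotype
(median, Q1, Q3) parameters: the log-normal takes µ = ln median and σ from
the log-IQR; the truncated normal solves numerically for the location that
puts the truncated median exactly on target, which matters for features
pressed against a bound (FiO₂ near 1.0, GCS near 15).

The parameter dictionary (`resources/synthetic_phenotype_params.csv`)
carries the published derivation-cohort medians/IQRs for the summary-table
variables; all other rows are synthetic stand-ins. Those stand-ins were
designed to realize the qualitative organ-injury patterns that define the
phenotypes — renal/cardiac markers elevated in A (potassium, phosphate,
troponin, CK, oliguria, metabolic acidosis), respiratory distress in B
(low SpO₂, high respiratory rate and heart rate), hepatic/coagulopathic
markers in D (transaminases, alkaline phosphatase, INR, PTT, ferritin,
hyponatremia, macrocytosis) — with within-phenotype spreads tight enough
that the four latent classes are well separated in the multivariate space.
That separation is a deliberate construction: passing recovery tests shows
the pipeline finds structure that is present, not that real EMR cohorts
contain structure this clean. Conversely the generator does reproduce
several adversarial features of real data: encounter-level missingness per
feature (2 % for vitals up to 90 % for rarely ordered labs — the latter
exercising the missingness filter), multiplicative ×100 / ×0.01 unit-entry
outliers (rate 0.5 %), repeat patients (3 %), ED-initiated ventilation
(2 %) and encounters with no pre-index vitals (1 %) for the exclusion
rules. It does not simulate free-text, waveforms, informative missingness,
or drift between hospitals beyond prevalence shifts.

Outcomes: high-PEEP assignment follows a per-phenotype logistic model of
within-phenotype z-scored severity (P/F negatively, lactate, creatinine and
age positively), intercept calibrated so the realized treated fraction
matches the configured one (defaults 16.7/49.6/24/16.2 %). The coefficient
magnitudes are chosen to give clear confounding while preserving common
support between arms; with much stronger coefficients the treated tail has
no comparable controls and no matching estimator is identifiable, which
would make treatment-effect recovery a test of overlap rather than of the
machinery. Individual 28-day mortality risk is logistic in the same
severity score, calibrated so untreated mortality equals the configured
per-phenotype value (defaults 40.9/51.2/21.4/49.6 %); treatment adds the
configured risk difference (defaults +0.04/−0.04/+0.07/−0.03). Death times
are truncated-exponential on (0, 28] days with the per-phenotype hazard;
deaths end the ventilation episode (no extubation-alive record), survivors
draw a log-normal ventilation duration.

## Numerical choices and problem sizes

Seeds propagate from a single integer through every stochastic stage
(generation, imputation, UMAP, k-means, splits, bootstraps); reruns are
bit-for-bit identical, which the manifest of artifact SHA-256 hashes makes
checkable. Default analysis sizes used by the test-suite and the
acceptance script — 2,000 encounters for derivation, 5,000 for generator
fidelity, 900 for the external hospital, 3,000 × 10–20 replicates for the
treatment-effect study, 500 replicates for log-rank calibration — are large
enough that Monte-Carlo error is small against every tolerance asserted
(e.g. the fidelity tolerance of 10 % on medians, or ±0.03 on the mean
matched ATE) while keeping a full run on a single CPU in minutes.

## Known limitations

Median aggregation discards within-window temporal dynamics by design.
The SOFA renal component ignores urine-output criteria (creatinine only).
The suspicion rule uses the first qualifying pair, not clinician intent.
Imputation assumes missingness at random given observed features, which the
generator satisfies but real EMR data may not. The treatment-effect module
estimates association under no-unmeasured-confounding within the synthetic
design; it makes no causal claim beyond that. The canonical naming rubric
presumes the four-cluster solution; other k values keep numeric labels.
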