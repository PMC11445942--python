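# arfpheno

Derivation and validation of sepsis-induced acute respiratory failure (ARF)
phenotypes from electronic-medical-record-style data — as a tested, reusable
Python pipeline.

Septic ICU patients who need invasive mechanical ventilation (IMV) for at
least 24 h are clinically heterogeneous: some are dominated by hypoxemic
respiratory failure, others by renal/cardiac or hepatic/coagulopathic
multi-organ dysfunction. `arfpheno` implements the full analysis chain that
turns timestamped clinical events into four named phenotypes (A–D) and their
downstream clinical consequences:

1. **Sepsis-3 detection** — six-organ SOFA scoring from a bundled rubric
   table, infection-suspicion from antibiotic/blood-culture pairing, and
   onset as an acute total-SOFA rise ≥ 2 inside a window around suspicion.
2. **Cohort construction** — index IMV time (first recorded PEEP / tidal
   volume / plateau pressure; for surgical ICU stays, the first such record
   ≥ 48 h after surgery), ordered inclusion rules, and the 24-h
   pre-intubation observation window.
3. **Preprocessing** — per-encounter median aggregation, physiologic-outlier
   screening, > 85 % missingness filter, chained-equation (MICE) imputation,
   |r| > 0.75 correlation pruning and z-scoring, frozen for external reuse.
4. **Phenotype derivation** — UMAP (or PCA) embedding, k-means, and model
   selection over (method, dimension, k) by silhouette, Calinski–Harabasz
   and Davies–Bouldin rank voting, with reconstruction-error reporting.
5. **Characterization** — per-phenotype median/IQR tables with
   Kruskal–Wallis / Chi-squared tests, gradient-boosted-surrogate additive
   attributions, the age-adjusted Charlson comorbidity index, and the
   canonical naming rubric (B = lowest P/F, A = highest creatinine,
   D = highest bilirubin, C = the rest).
6. **Transfer** — a frozen multinomial logistic classifier applied to
   external cohorts, benchmarked against RF/SVM/naive-Bayes.
7. **Outcomes** — 28-day Kaplan–Meier survival from intubation, multi-group
   log-rank tests, and ventilator-free days (VFD).
8. **High-PEEP treatment effects** — per-phenotype propensity-score
   matching (greedy 1:1 on logit propensity, 0.2 SD caliper), standardized
   mean-difference balance diagnostics, and the average treatment effect on
   28-day mortality with a pair-bootstrap CI (negative = benefit).

Because no public EMR extract exists for this problem, the package ships a
first-class **synthetic EHR generator**: a four-phenotype Gaussian-copula
cohort model calibrated to published per-phenotype medians/IQRs, with
encounter-level missingness, unit-entry outliers, phenotype-dependent
survival and confounded high-PEEP assignment. Every downstream stage is
tested end-to-end against this generator's known ground truth.

## Worked example

```python
from arfpheno import CohortConfig, PhenotypeModel, generate_study
from arfpheno import sofa, cohort
from arfpheno.preprocess import Preprocessor
from arfpheno import characterize

stream, latent, levels, truth = generate_study(
    config=CohortConfig(n_encounters=2000, seed=13))
onsets = sofa.detect_cohort_sepsis(stream)
inclusion, window = cohort.build_cohort(stream, onsets)
prep = Preprocessor(seed=13)
scaled = prep.fit_transform(window)

results = PhenotypeModel(scaled, methods=("umap",), dimensions=(2, 3),
                         ks=(2, 3, 4, 5, 6), seed=13).fit()
print(results.summary())
```

```
Phenotype derivation results
============================================================
method: umap  dimension: 2  k: 4
silhouette: 0.665   Calinski-Harabasz: 9525.6   Davies-Bouldin: 0.472
reconstruction MSE: 0.7440
cluster sizes: {0: 373, 1: 610, 2: 475, 3: 421}
```

Four clusters are selected by the three internal-validity indices; the
silhouette of ~0.65 on the 2-D embedding indicates clearly separated
groups, and the reconstruction MSE reports how much of the ~45-dimensional
scaled feature space the embedding retains. Naming the clusters and
checking them against the generator's latent truth:

```python
medians = characterize.cluster_medians(prep.unscaled_, results.assignments)
naming = characterize.canonical_label(medians)
named = results.assignments.map(naming["labels"])

from sklearn.metrics import adjusted_rand_score
print(naming["anchors"])
print("ARI vs latent:", round(adjusted_rand_score(
    latent.loc[named.index], results.assignments), 3))
```

```
{'B_pf_ratio': 121.01156498032074, 'A_creatinine': 3.633256068113984, 'D_bilirubin_total': 1.4459283155817233}
ARI vs latent: 0.919
```

The B cluster sits at a median P/F ratio of ~121 mmHg (severe hypoxemia),
A at creatinine ~3.6 mg/dL (renal dysfunction) and D at elevated bilirubin
— the configured organ-injury patterns — and the adjusted Rand index of
0.92 means the pipeline recovers the generator's latent classes almost
exactly.

The same chain is available from the shell:

```bash
arfpheno run-all --seed 13 --out artifacts/
arfpheno synth --n 500 --seed 1 --out cohort/
```

`run-all` persists every intermediate (onsets, inclusion table, feature
matrix, score table, assignments, survival and ATE summaries) plus a
manifest of SHA-256 hashes so a rerun can be verified bit-for-bit.

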