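# etioscope

Soft-clustering of newly diagnosed type 2 diabetes phenotypes by
archetypal analysis, with the downstream modelling that turns the cluster
scores into clinical statements: β-cell function from mixed-meal tolerance
tests, HbA1c disease progression, and association screens against omics
features and genetic risk scores. A synthetic cohort generator with full
ground truth makes every estimator testable end to end.

The package is for biostatisticians and diabetes researchers who want
continuous, overlapping patient stratification instead of hard clusters:
each subject receives k archetype scores on the probability simplex
(Σ_k a_ik = 1), obtained from the decomposition

    X ≈ A·Z,   Z = B·X,   rows of A and B on the simplex,

fitted by alternating simplex-constrained least squares with a robust
(bisquare-reweighted) variant and multi-restart selection. The number of
archetypes is chosen by an RSS scree plus a subsampling-stability protocol
(refit on 90% subsamples ×100, match archetypes by cosine similarity,
score partition agreement with the adjusted Rand index across membership
thresholds). Subjects with any score > 0.6 form extreme groups A–D; the
rest form the mixed-etiology group, subdivided into 12 ordered
primary/secondary groups.

On top of the scores:

* **β-cell model** (`BetaCellModel` → `BetaCellResults`): insulin secretion
  ISR(t) = P(t)·f(G(t)) + k_r·max(dG/dt, 0), estimated from glucose and
  C-peptide by regularized least squares through a two-exponential
  C-peptide kinetics kernel; the regularization is selected so model
  residuals match the assay errors (~1% glucose, ~4% C-peptide). Yields
  glucose sensitivity, rate sensitivity, potentiation factor ratio, basal
  and total secretion, insulin clearances.
* **Progression model** (`ProgressionModel` → `ProgressionFit`): a
  conditional linear mixed-effects model of HbA1c with random subject
  slopes and sign-constrained effects of BMI (≥0), metformin and other
  glucose-lowering drugs (≤0, as a + b·dose), insulin (≤0) and assay
  delay, under a 30-day medication-effectiveness lag.
* **Association harness**: marginal score–phenotype OLS, Kruskal–Wallis /
  Mann–Whitney extreme-group tests, logistic medication odds ratios,
  vectorized omics screens with Benjamini–Hochberg FDR, and weighted
  (partitioned) genetic risk scores.

## Worked example

```python
import pandas as pd
from etioscope import (ArchetypalAnalysis, CohortConfig, generate_cohort,
                       make_assignments, prepare_clustering_matrix)

config = CohortConfig(n_subjects=700, seed=7)      # 700 x 32 cohort
matrix, truth = generate_cohort(config)
pm = prepare_clustering_matrix(matrix, ["sex_genotype", "center"])

model = ArchetypalAnalysis(pm.values, k=4, column_names=pm.column_names)
result = model.fit_restarts(20, seed=7)
print(result.summary())

scores = pd.DataFrame(result.scores, index=matrix.subject_ids,
                      columns=list("ABCD"))
groups = make_assignments(scores, threshold=0.6, dominance=0.4)
print(groups["extreme_label"].value_counts())
```

prints (abridged):

```
Archetypal analysis results
===========================
archetypes (k):      4
observations:        700
phenotypes:          32
RSS:                 5166.94
iterations:          25
converged:           True
min robust weight:   0.863

extreme_label
MIX    322
D      103
C       98
A       94
B       83
```

Roughly half the cohort sits in the mixed-etiology group; the rest are
extreme on one archetype (score > 0.6). `groups["mixed_label"]` further
splits the mixed subjects into the 12 ordered primary/secondary groups
("AB", "CB", ...), and `stability_by_subsampling` reports how reproducible
the partitions are under 90% subsampling (median adjusted Rand index 0.98
at threshold 0 for this cohort).

The same pipeline is scriptable from a shell:

```bash
etioscope simulate --seed 7 --n-subjects 700 --out cohort/
etioscope preprocess --in cohort/cohort.csv --out matrix.csv
etioscope fit --in matrix.csv --k 4 --restarts 100 --seed 7 --out model.json
etioscope stability --in matrix.csv --k 4 --reps 100 --seed 7
```

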