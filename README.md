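# vnnsurv

Survival modelling from binary gene-alteration profiles with a
**pathway-guided visible neural network**, plus the interpretation and
clinical-translation layers that make such a model useful: Shapley-value
attribution of risk to genes and pathways, an altered-cases-only *impact*
statistic, impact-ranked backward feature elimination, a genetic prognostic
index (GPI) for three-level risk stratification, and marker-based genetic
subtype assignment.

The package targets the setting of targeted-sequencing oncology cohorts
(the motivating disease is diffuse large B-cell lymphoma): each patient is
described by one-hot gene-alteration indicators (SNVs and CNVs), a few
binary clinical covariates (age > 60, R-CHOP treatment, de-novo disease),
a survival time and an event indicator.

## The model

The network is *visible*: every neuron maps to a biological entity and
every connection to a biological relation. Gene inputs connect only to the
pathways they belong to; pathway neurons connect only to their parent
pathways in the hierarchy; parentless pathways feed a root embedding that
is concatenated with the clinical covariates and passed through a two-layer
dense head to produce a scalar risk r̂(X). Because real pathway
hierarchies are not strict (a gene can sit in a deep pathway, an edge can
skip levels), frozen identity *skip-through* channels carry values across
intermediate layers untouched.

Training minimizes the negative Cox log partial likelihood
(Breslow handling of tied times)

    L(θ) = Σ_{i∈D} [ r̂_θ(X_i) − log Σ_{j: t_j ≥ t_i} exp(r̂_θ(X_j)) ]

with AdamW and dropout; performance is measured by the concordance index

    C = (1/N_effect) Σ_{i∈D} Σ_{j∈R(t_i)} 1[ r̂_i > r̂_j ].

Interpretation uses interventional Shapley values s_ij (per patient i and
node j, against a background sample or the all-reference profile), exactly
by coalition enumeration for small player sets and by seeded permutation
sampling otherwise. The impact of feature j averages s_ij only over the
N_j carriers of the alteration, so rare-but-strong alterations are not
drowned out:

    Impact_j = (1/N_j) Σ_{i: f_ij = 1} s_ij.

The GPI score of a patient is score_i = Σ_{j∈F_key} f_ij · Impact_j,
thresholded into risk levels I (score ≤ t1), II (t1 < score ≤ t2) and III
(score > t2).

Everything is exercised end-to-end on synthetic data: the `synthetic`
module generates random pathway DAGs and proportional-hazards cohorts with
known ground truth (planted log-hazard effects, calibrated censoring).

## Worked example

```python
from vnnsurv.synthetic import benchmark_conditions
from vnnsurv.architecture import build_vnn_spec
from vnnsurv.model import cross_validate
from vnnsurv.interpretation import shap_values, feature_impact

cohort, truth = benchmark_conditions(seed=0)   # n=600, 5 signal + 15 noise genes
spec = build_vnn_spec(truth.gene_sets, truth.hierarchy, cohort.feature_names)
report = cross_validate(cohort, spec, k=10, seed=0, head_width=16)
```

prints, after attribution of a model trained with the chosen
hyperparameters:

```
cohort: n=600, events=441, features=20+3 clinical
architecture: 12 pathways, 4 layers, root width 4
10-fold CV mean C-index: 0.733 (folds 0.652-0.768)
  G002: impact -0.698  (true beta -0.693)
  G004: impact -0.547  (true beta -0.693)
  G003: impact +0.481  (true beta +0.693)
  G005: impact +0.466  (true beta +0.693)
  G001: impact +0.355  (true beta +0.693)
  G013: impact -0.093  (true beta +0.000)
```

The held-out concordance essentially reaches the generating model's own
ceiling (the true linear predictor scores 0.734 on this draw), and the
impact ranking separates the five planted effects from the noise features —
with signs recovered, so protective and deleterious alterations are
distinguished.

The same workflow is available from the shell:

```sh
vnnsurv simulate --n 600 --features 20 --out-dir data/
vnnsurv build-arch --gmt data/gene_sets.gmt --hierarchy data/hierarchy.tsv \
        --genes data/genes.txt --out spec.json
vnnsurv cv --cohort data/cohort.tsv --spec spec.json --k 10 --out folds.tsv
vnnsurv train --cohort data/cohort.tsv --spec spec.json --out model.json
vnnsurv explain --model model.json --cohort data/cohort.tsv --out shap.tsv
vnnsurv impact --shap shap.tsv --cohort data/cohort.tsv --out impact.tsv
vnnsurv stratify --cohort data/cohort.tsv --impact impact.tsv --out gpi.tsv
```

or as one resumable pipeline with `vnnsurv run --config run.yaml`.

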