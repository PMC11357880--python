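# Methods

## Architecture compilation

Inputs are a gene-set collection (pathway → member genes), a pathway
hierarchy (child → parent edges) and an ordered input gene panel. The
pathway universe is pruned to the nodes reachable from the panel: direct
membership seeds the set, then the transitive closure toward parents is
taken. Genes belonging to no retained pathway are *orphans*; rather than
being dropped silently they are routed directly to the root embedding
through frozen identity channels, so every input can influence the risk
and receives an attribution.

Layers are assigned by **longest child-chain**: `layer(p) = 1 +` the
length of the longest chain of descendants below `p` within the retained
graph. This guarantees `layer(child) < layer(parent)` for every edge —
a shortest-path layering can invert edges when the hierarchy is not
strict. The number of layers is emergent from the inputs, not configured.

Masks are laid out interface by interface. The targets of layer *k* are
the neuron blocks of pathways assigned to layer *k* (`node_width` neurons
per pathway, default 1) followed by **skip-through channels**: one frozen
identity unit for every value still needed deeper in the network (a gene
whose member pathway sits above layer *k*, a child pathway whose parent is
more than one layer up, and every root-bound value). Skip-through units
have no bias, no activation and no dropout, and their identity weights are
not learnable: a gene entering a deep pathway arrives bit-identical to its
input value, which keeps attributions of deep-entering genes undistorted.

Under the default `concat` root mode the root embedding is simply the full
final interface — root-pathway blocks plus orphan channels — so
`root_width` is emergent (roots × node_width + orphans). A `dense` mode
adds a learnable projection to a user-chosen width for cases where a
specific embedding dimension is wanted; nothing in the package depends on
a particular root width.

## Model and training

The risk network applies `tanh` (configurable) at pathway neurons, then
concatenates the root embedding with the binary clinical covariates and
applies a two-layer dense head (default width 64 in the library API; the
test bench and pipeline default to 16, which is ample for panels of tens
of genes). Weights are Glorot-uniform at masked positions' complement and
exactly zero on masked positions; biases start at zero, so an untrained
network with zeroed weights outputs risk 0.

The loss is the negative Breslow log partial likelihood, computed with
log-sum-exp stabilization; the risk set at an event time includes all
patients with `t_j ≥ t_i` (ties included). Gradients flow through the
frozen identity channels but masked positions receive exactly zero
gradient and zero weight decay, so structural absence is preserved
*exactly* (asserted, not approximate) after any number of AdamW updates.
Mini-batches are drawn by seeded shuffling; risk sets are formed within
each batch, and a batch that happens to contain no events is skipped with
a log notice. The per-epoch history records the full-cohort loss in
evaluation mode (dropout off), which makes convergence monitoring
deterministic.

Cross-validation splits once per call, stratified by event status so no
fold is event-free, and shares the folds across the hyperparameter grid.
The default grid is learning rate {1e-2, 1e-3} × weight decay
{1e-2, 1e-4} × batch size {64, full}, 100 epochs, dropout 0.2. These are
declared package defaults; epochs are deliberately a grid dimension
rather than an early-stopping rule, so a CV report is a pure function of
(cohort, spec, grid, seed).

Two baselines share the training and evaluation contract: a dense network
with the same layer count and per-layer unit counts (hence at least as
many parameters as the masked model) and a linear proportional-hazards
fit (lifelines `CoxPHFitter`; the risk is the linear predictor; constant
columns are dropped with a warning).

## Evaluation

The concordance index follows the event/risk-set pair definition: *i*
ranges over events, *j* over `t_j ≥ t_i` excluding *i*; consequently two
events at the same time contribute a pair in both directions. The default
`strict` tie mode scores tied risks 0, which is the literal indicator
definition; `half` awards ties 0.5 for comparability with other survival
tooling. Kaplan–Meier estimation, the unweighted (Mantel–Haenszel)
log-rank test and the Wilcoxon rank-sum test are delegated to lifelines
and scipy; the rank-sum test uses exact enumeration for small tie-free
samples and the continuity-corrected normal approximation otherwise.
Significance stars follow the ns / * 0.05 / ** 0.01 / *** 0.001 /
**** 0.0001 convention.

## Attribution

Shapley values are interventional: the value of a coalition *S* for
patient *x* is the background-averaged risk when nodes in *S* take *x*'s
values and the rest take the background's. Input-scope players are input
columns; pathway-scope players are whole hidden blocks, intervened at the
block's origin layer (skip-through copies downstream inherit the
replacement automatically, so a pathway is one coherent player). Exact
attribution enumerates all 2^m coalitions and is capped at 15 declared
players; sampling averages marginal contributions over seeded
permutations (~`n_samples` value evaluations per patient). With a single
background row, a binary input equal to its background value is a null
player with attribution exactly zero; the sampling path exploits this to
shrink the player set and switches to exact enumeration when ≤ 13
effective players remain, so attributions against the all-reference
profile are usually exact. Additivity
(base + Σ_j s_ij = risk) holds to numerical precision for exact mode and
is tracked via `ShapMatrix.additivity_gap()`.

The per-patient base value is the expected risk with every player
interveined; for pathway scope (and restricted player sets) it varies per
patient because non-player inputs keep the patient's own values.

Impact ranks use the altered-cases-only mean. Features never altered in
the cohort have an undefined mean (0/0); they are reported as impact 0
with an explicit flag. Backward elimination ranks by |Impact| — both
protective and deleterious features matter — drops the weakest `step`
features, rebuilds the architecture on the reduced panel and re-runs CV,
recording the (feature count → mean held-out C-index) curve and the full
ranking at each stage. Elimination stops cleanly when ≤ `step` features
remain or the panel no longer reaches any pathway.

Sankey node widths are the mean |SHAP| across patients (absolute values
prevent sign cancellation in a width); an edge from source *s* into
target *t* carries `width(t) · width(s) / Σ_sources width`, so incoming
widths sum to the target's width before pruning. A target whose sources
all have zero attribution gets zero-width edges and a flag instead of a
division by zero. Pruning removes edges below the requested quantile of
edge widths.

## Stratification and subtyping

GPI scores are exact dot products of the alteration profile with the
impact weights. Level boundaries are inclusive downward (score ≤ t1 →
level I; score ≤ t2 → level II), so a score exactly at a threshold falls
to the lower level. Threshold search operationalizes "most significant
three-way separation" as: over all ordered grid pairs whose three levels
each hold at least `min_group` patients, minimize the *worst* pairwise
log-rank p-value; ties break toward more balanced level sizes and then
the lexicographically smaller pair, making the search deterministic.

Pairwise interaction testing uses two-sided Fisher exact tests with
Benjamini–Hochberg FDR across all tested pairs (the package applies BH
rather than a dependency-robust variant, the standard choice for this
analysis); labels are co-occurrence (q < α, OR > 1) or exclusivity
(q < α, OR < 1). Degenerate tables keep the ∞/0 odds-ratio convention,
with a Haldane-corrected column for plotting. UpSet-style intersection
counts use exclusive patterns and partition the cohort. An optional
precomputed protein-interaction edge list can annotate reports; no live
database queries are performed.

Subtype assignment is purely marker-based: any high-risk marker → H1, any
low-risk marker → L1, both → an explicit "both" label (reported, never
silently resolved), neither → unclassified. Sub-subtypes split carriers
of an anchor alteration by whether its |SHAP| ranks in the patient's top
five genetic features (competition ranking; ties share the better rank):
rank ≤ 5 → sub-subtype II, the anchor-dominant and worse-prognosis group
by this package's convention, else sub-subtype I.

## Synthetic data

The generator emulates the *shape* of a targeted-sequencing cohort, not
any real mutation spectrum. Features are independent Bernoulli draws with
chosen marginal frequencies; a Gaussian-copula option injects correlation
to plant co-occurrence or exclusivity. Clinical covariates are three
Bernoulli columns (frequencies 0.5 / 0.8 / 0.8) mirroring the age > 60,
R-CHOP and de-novo roles. Event times follow a proportional-hazards
mechanism — hazard `h0 · exp(x·β)`, exponential baseline by default,
Weibull shape as an option — and censoring is an independent exponential
whose rate is calibrated by root-finding so the expected censored
fraction matches the target; for n ≥ 2000 the realized fraction lands
within ±0.05.

The planted-signal benchmark used throughout the test bench fixes n=600,
five signal alterations at |β| = log 2 with alternating signs at carrier
frequency 0.5, fifteen noise alterations at frequency 0.3, clinical
effects (log 2, −log 2, −0.35) reflecting the prognostic strength of age,
treatment and disease origin, and ~30% censoring. Under these conditions
the generating model's own concordance is ≈ 0.72–0.73, so a learner can
realistically be asked to reach 0.70; the benchmark's pathway DAG routes
all genes through pathways so the masked architecture is not handicapped.
What passing these tests shows is that the machinery recovers a planted
additive signal at realistic censoring; it does not certify performance
on real cohorts, whose feature correlations, non-proportional hazards and
cohort shifts the generator deliberately does not model.

## Numerical and design notes

- Partial-likelihood and risk-set computations sort descending in time and
  reuse cumulative log-sum-exp terms; tie groups share one normalizer.
- Result tables serialize to tagged TSV with 17-significant-digit floats
  and round-trip losslessly (`read(write(x)) == x` at 1e-10, typically
  bit-exact); reading uses pandas' round-trip float parser.
- The pipeline tracks SHA-256 digests of every artifact: unchanged stages
  are skipped, a modified intermediate is reported by name, and inputs are
  never mutated.
- Missing features in an external cohort are filled with an explicit
  per-feature default (0 or 1) supplied by the caller; the unmarked state
  (0, no alteration) is the default when unspecified.
- Seeds: every stochastic routine takes an explicit seed; the pipeline
  expands one master seed per stage via SHA-256.

## Problem sizes in the test bench

Unit and property tests run on cohorts of 30–400 patients and panels of
1–20 genes; the planted-signal benchmark uses n=600 with 10-fold CV over
the default 8-point grid, and elimination runs 5 seeded replicates at
3-fold CV with step 5. These sizes were chosen so the full suite
exercises every code path on one CPU in a few minutes while keeping the
statistical assertions (oracle ceilings, type-I control, recovery bands)
well-powered.

## Known limitations

- The attribution's pathway intervention replaces hidden activations with
  background activations; other intervention semantics (e.g. marginalizing
  inputs upstream of a pathway) would give different pathway values.
  The chosen semantics keeps each pathway a single coalition player.
- Sampling attributions are unbiased but noisy for many-player sets with
  multi-row backgrounds; the 0.02 accuracy checked in the tests refers to
  2^14 evaluations on 8-player problems.
- `optimize_thresholds` searches a user-supplied grid; it does not refine
  continuously between grid points.
- No competing risks, time-varying covariates, or transcriptomic input
  modes; the cohort model is strictly binary features + right censoring.
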