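# Methods

## Model

One graph-convolutional module per omics block operates on the
*sample* graph: nodes are patients, edges connect transcriptionally (or
epigenetically) similar patients. Message passing therefore smooths
each patient's representation over their molecular neighbors before
classification — the working assumption is that cancer and non-cancer
samples occupy separable neighborhoods of the similarity graph, so
label information propagates even when any single feature is noisy.

The graph is built per omics block from cosine similarity on the
processed features. The threshold `τ` can be fixed, or chosen as the
largest value whose graph retains a target mean node degree (default
10). The degree-targeted rule makes the graph density — not the raw
similarity scale, which varies across omics — the controlled quantity.
Ties at exactly `τ` are kept; similarities below it are zeroed; the
diagonal of `A` is zero and self-loops enter only through the `A + I`
of the normalization, which also guarantees `D̃_ii ≥ 1` (no division by
zero; isolated nodes reduce to pure self-loops). Negative similarities
surviving a negative `τ` are kept as-is.

Each module stacks two graph-convolution layers (`p → 400 → 400`,
configurable 1–3) and two FC layers (`400 → 200 → 2`), all LeakyReLU
slope 0.25, dropout 0.5 on the FC layers only (a flag extends it to
graph layers). The fusion head consumes, per sample, the concatenated
2-class outputs of the omics modules (4 values) through one affine
layer; a config option fuses the 200-dimensional penultimate
activations instead. Therapy-rule matching on DNA variants is
annotation-only: it attaches candidate agents to predictions and never
enters the loss. The shipped default rule table is a small illustrative
set of targetable NSCLC alterations, meant to be replaced by a curated
clinical table.

## Training

Transductive: graphs and forward passes cover all cohort rows, but
only training-partition samples contribute loss terms, and the label
affinities below only count training-partition neighbors. Losses are
per-sample cross-entropy *sums*, so their magnitude scales with the
partition size; Adam's per-parameter normalization makes optimization
insensitive to that scale, but reported loss curves are sums, not
means.

Two stages: 500 epochs of per-module pretraining (learning rate
`lr_pretrain`), then joint fine-tuning of modules (`lr_train`) plus
fusion head (`lr_terminal`) on the composite loss with `α_l = 1` and
`λ = 1`. All three learning rates live on the grid
{1e-7, 5e-7, …, 1e-3, 5e-3}; `grid_search_learning_rates` selects a
triple by mean validation macro F1 across folds (ties toward the
smaller `lr_train`, then `lr_pretrain`, then `lr_terminal`), with
optional random subsampling of the 1000-triple cube for desk-scale
runs. The package defaults (1e-3 / 5e-4 / 1e-3) are mid-grid values
that converge reliably on the synthetic cohorts.

Two graph-informed preprocessing behaviors are on by default, each
independently disableable:

* **Outlier restraint** — feature values beyond 3 SD from the feature
  mean are clipped to that bound.
* **1-hop label-affinity weighting** — during pretraining, sample k's
  cross-entropy term is weighted by the fraction of its (labeled) 1-hop
  neighbors sharing its class; isolated samples get weight 0.5. This
  softens the influence of samples whose labels disagree with their
  molecular neighborhood. By construction it also *caps training
  accuracy* when the graph is noisy (conflicted samples are never fully
  fitted) — convergence tests that probe pure optimizer/architecture
  capacity disable it.

Training is full-batch and deterministic given the seed (weight
initialization and dropout masks come from one seeded generator; there
is no minibatch ordering). No early stopping or schedulers: fixed
epoch counts only.

## Feature identification

Stage 1 is computed on training-partition samples only: Welch's
t-test per feature (t and the Welch–Satterthwaite df from the explicit
formulas, p from Student's t), plus an effect criterion. For
expression, log2 fold change of linear-scale group means with
pseudocount 1, strict `|log2FC| > 0.5`; for methylation, a log-ratio of
beta values is not meaningful, so the criterion is the absolute
beta-value difference with strict `|Δβ| > 0.2` (configurable). Both
inequalities and `p < 0.05` are strict: boundary features are dropped.
No multiple-testing correction is applied at this stage — the filter
is a screen, not an inference.

Stage 2 scores each surviving feature `G` by
`ΔF1(G) = F1_with(G) − F1_without(G)`, macro F1 on the validation
partition. The default "without" is *mask mode*: the feature's
processed column is replaced by its training-set mean and the trained
model re-run; *retrain mode* (full retraining without the feature,
same seed) is available behind a flag but is quadratic in feature
count. In mask mode the sample graph is kept fixed: a single feature
barely moves 200–300-feature cosine similarities, and a fixed graph
keeps scoring at one forward pass per feature. Ranking is by ΔF1
descending, ties broken by |t| then feature ID; top 200 expression and
300 methylation features are kept by default.

## Evaluation

Cancer (label 1) is the positive class; specificity is the recall of
non-cancer. AUC-ROC uses the Mann–Whitney rank formulation with
midranks. Weighted F1 defaults to the standard prevalence-weighted
form (bounded by 1); a literal variant that divides the count-weighted
sum by 2 — which exceeds 1 whenever n > 2 — is retained behind an
explicit flag with a warning, for comparability with reports using
that convention. Degenerate ratios (zero denominator) return 0 with a
warning rather than failing, so cross-validation folds with an empty
predicted class still aggregate.

Baselines mirror the main model's shared settings (LeakyReLU 0.25,
Adam, cross-entropy, 400 hidden units, 200-d FC, dropout 0.5). The CNN
uses a 1-D convolution (8 channels, kernel 5, 'same' zero padding) and
max pooling with kernel 2, stride 1, zero padding; the logistic
baseline is batch-norm → dropout → affine; the naive-Bayes-structured
network is an FC stack whose standard-normal weight prior is realized
exactly as its negative log-density, a unit-coefficient L2 penalty on
the weights. The comparison harness runs all models on identical
preprocessed inputs and identical stratified folds and reports mean ±
SD (over folds) of all seven metrics.

## Synthetic cohorts

The generator emulates the structure of a two-omics NSCLC case/control
cohort at post-selection scale (defaults: 150 + 150 samples, 200
expression features with 20 informative, 300 methylation features with
30 informative):

* **Expression** — log-normal: `x = exp(μ_f + z)` with feature base
  levels `μ_f ~ U(1, 3)` and `z` standard normal on the log scale, in
  equicorrelated blocks of 10 (shared Gaussian factor, default
  within-block correlation 0.3). Informative features shift the cancer
  class by `effect_size` on the log scale (log-SD is 1, so the effect
  is in within-class SD units), alternating up/down.
* **Methylation** — Beta-distributed with concentration `a + b = 8`.
  Informative CpGs draw base means in [0.35, 0.65] (differentially
  methylated sites are modeled at intermediate methylation, where a
  multi-SD shift stays inside (0, 1)); the cancer-class mean shifts by
  `effect_size` within-class beta SDs, clipped to [0.02, 0.98],
  alternating hyper-/hypomethylation. At the default effect 1.5 this
  yields |Δβ| ≈ 0.24–0.27, above the 0.2 filter threshold by design.
  `effect_size` is thus interpreted in SD units for both omics — a raw
  beta-mean shift cannot represent effects ≥ 1.
* **Variants** — Bernoulli draws per (sample, driver gene) at rates
  0.30 (cancer) vs 0.02 (control) over 10 driver genes, with random
  alteration types.

Everything is deterministic per seed, and the returned manifest lists
the informative feature IDs and directions, so recovery experiments
can score themselves against the truth. What the generator does *not*
model: count noise, probe chemistry, batch effects, cohort
heterogeneity, or realistic correlation between omics blocks. Passing
tests on these cohorts demonstrate that the pipeline recovers planted,
well-behaved signal without leakage — not that it matches performance
on real tumor data.

The pipeline's own preprocessing is log1p on expression, per-feature
z-scoring with training-partition statistics, then the 3-SD clip;
graphs are built on these processed features (on all features by
default; restricting the graph to a selected feature subset is a
matter of subsetting the input matrices).

## Numerical choices and problem sizes

* Cross-entropy clamps probabilities at 1e-12; non-finite training
  loss raises immediately, naming the epoch.
* The 55/15/30 split uses largest-remainder apportionment twice: once
  for the global part sizes (exact to the sample) and once,
  column-constrained, for the per-class allocation (class balance per
  part within one sample of proportional); k-fold splitting is
  stratified with sizes within ±1.
* The normalized adjacency is stored sparse (CSR) when edge density is
  below 25%; Adam updates are computed in place. Neither changes
  semantics.
* End-to-end tests and the acceptance script run the default cohort
  (300 samples, 500 features) with 500 pretraining and 500 fine-tuning
  epochs — sizes chosen so a full multi-seed experiment completes in
  minutes on one CPU core while leaving the signal-recovery and
  null-calibration conclusions unambiguous.

## Known limitations

* Binary classification only; no subtype (LUAD vs LUSC) objective.
* Transductive scoring means test samples influence graph structure
  (never losses); a strictly inductive mode is not provided.
* Mask-mode influence underestimates the contribution of features
  with redundant correlates (their information survives masking);
  retrain mode is exact but expensive.
* The affinity-weighting scheme assumes the graph is at least weakly
  label-informative; on noise graphs it down-weights legitimate
  samples.
* Baselines are fixed architectures for parity comparison, not tuned
  competitors.
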