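# Methods

## Model

The classifier is a feedforward binary network over exon-level expression
features.  Prior splicing knowledge enters through fixed binary
relationship matrices derived from transcript annotation:

* **Exonic parts.**  Within one gene, exons are flattened into maximal
  disjoint intervals over which the covering transcript set is constant
  (a boundary sweep over exon start/end coordinates, merging adjacent
  runs with equal sets).  Coordinates are GTF-style 1-based inclusive.
  Genes are flattened independently, per strand; exons that overlap
  *within* a transcript are treated as malformed but recoverable and
  merged with a warning.  Part ids are `<gene>:NNN` (3-digit, 1-based),
  stable and sortable.
* **Isoform map layer (IML).**  With `R[i, j] = 1` iff part *i* lies in
  isoform *j*, the layer computes `act((R ⊙ W)ᵀ x + b)`.  Masking in the
  forward pass makes the gradient on `R = 0` coordinates identically
  zero — no clamping is needed, and the effective weight is exactly zero
  there at all times.  The gene map layer is the same construction with
  the exon×gene incidence matrix (one 1 per row).
* **Feature selection layer (FSL).**  `y_k = w_k · x_k` with `w_k ≥ 0`,
  no bias or activation, plus an L1 penalty `λ Σ w_k` (λ = 5·10⁻⁴) added
  to the training loss only (not to model-selection scores).
  Non-negativity is enforced by projection (clipping at zero) after each
  optimizer step — the simplest rule satisfying the constraint; a
  multiplicative parametrization would be an alternative.
* **Dense stack.**  ReLU hidden layers with strictly decreasing widths,
  dropout 0.2 after each hidden dense activation (not after the FSL or
  mask layers), and a single output unit.  The output is kept as a
  linear logit internally; the sigmoid lives in the loss and in
  `predict_proba` for numerical stability.

Initialization is seeded Glorot-uniform.  For masked layers the fans are
computed on the masked connectivity graph (each connection uses the
receiving unit's nonzero fan-in and the sending unit's fan-out); using
the full-matrix fans would underscale sparse layers by roughly the square
root of the sparsity.  Biases start at zero and FSL weights at one.

The layers and their backpropagation are implemented directly in numpy;
analytic gradients are verified against central finite differences in the
test suite, including the exact-zero property on masked coordinates.

## Training protocol

Adam (lr 3·10⁻⁴, β₁ = 0.9, β₂ = 0.999, ε = 10⁻⁸), minibatches of 256
shuffled per epoch (the final partial batch is used), at most 40 epochs.
Early stopping monitors validation accuracy (threshold 0.5): training
halts when accuracy has not *strictly* increased for 10 epochs (ties do
not reset patience) and the parameter snapshot of the best epoch is
restored.  Loss is mean binary cross-entropy plus the FSL penalty.

Architecture search is greedy and layer-by-layer: widths
{2, 4, …, 512} are scored by mean 5-fold cross-validated accuracy for
layer 1; each further layer scans grid widths strictly below its
predecessor's chosen width, re-initializing all weights per candidate;
the stack grows while the best score strictly improves.  Ties break
toward the smaller width (parsimony).  At most 9 candidates are evaluated
for layer 1 and strictly fewer per deeper layer.

**Protocol-scale interaction.**  The protocol's learning rate and epoch
budget were designed for cohorts of a few thousand samples (several
minibatches per epoch).  On cohorts of only a few hundred samples the
run comprises ~80 Adam steps, which trains the output layers enough to
classify strong signals but leaves the input layers close to their
random initialization; gradient-based attributions are then
uninformative.  Experiments that interrogate feature importances
(sparse-signal recovery, saliency rank comparisons) are therefore run at
a cohort of 2,400 samples, matching the protocol's design scale; the
smaller default cohort (600 samples) is retained for the
classification-performance contest, where it suffices.

## Preprocessing

* **Filters** (computed on CPM against raw pre-filter library sizes):
  remove features with mean CPM < 0.2 or with CPM > 0.5 in fewer than 50
  samples; additionally remove features with CPM > 50,000 in at least
  one but fewer than 50 samples.
* **TMM.**  Reference sample: 75th-percentile CPM closest to the mean
  75th percentile.  Per sample, M/A values over doubly-nonzero features,
  two-sided rank trimming (30% by M, 5% by A), precision-weighted mean M
  (weights are inverse asymptotic variances), factors rescaled to
  geometric mean 1.  The implementation reproduces edgeR's
  `calcNormFactors(method="TMM")` to printed precision and an
  independently transcribed oracle to 1e-8.  Note that scaling one
  sample's counts by a constant leaves M-values and the reference choice
  invariant but perturbs the precision weights, so factors are only
  approximately invariant to per-sample rescaling (observed ~1e-2).
* **log2-CPM** with prior count 0.5 against effective library sizes
  (column sum × factor + 1), the standard offset convention; the
  doubling-stability bound |Δ| < 10⁻³ holds for counts ≥ 1000.
* **Quantile normalization** maps every column onto the across-sample
  mean of order statistics; ties receive the average of the reference
  values at the tied ranks.  Exact idempotence holds for tie-free
  columns; with ties, tie-averaging perturbs the order statistics seen
  by a second pass, so idempotence is only approximate there.
* **Covariate adjustment** fits, per feature, OLS on
  [intercept | covariates | label] (categoricals one-hot with first-level
  reference) and subtracts only the covariate contribution, retaining
  intercept and class effect.  The operation is a projection.
* **Splits** are label-stratified by largest-remainder apportionment of
  the positive class (per-split prevalence within one sample of the
  global rate), with training samples dealt round-robin into five
  stratified folds of near-equal size.  Networks are trained on
  features standardized with training-split statistics (log2-CPM means
  are far from zero and would saturate the sigmoid at initialization).
* Order of operations: normalize (TMM + log2-CPM + quantile), then
  adjust covariates.

## Evaluation

AUC is the Mann-Whitney statistic with midrank tie handling, computed in
O(n log n); it equals the trapezoidal area under the ROC sweep exactly.
The DeLong test expresses each model's AUC as the mean of structural
components (placement values); the empirical covariance of the
components across models gives the variance of the paired AUC difference,
and a two-sided normal p-value follows (no continuity correction).  A
zero-variance difference yields p = 1 when the AUCs agree and p = 0 with
a warning otherwise.

## Synthetic isoform-switch generator

Each toy gene carries K isoforms (default 2) built from one private exon
per isoform plus `parts_per_isoform − 1` exons shared by all isoforms
(100 bp exons, 50 bp gaps, genes on disjoint blocks), so flattening
yields exactly one part per exon with the expected transcript sets.

Class-0 usage per gene is symmetric Dirichlet(α = 5).  For effect genes,
class 1 moves `switch_delta` of usage mass from isoform 1 to isoform 2
(renormalizing with a warning if insufficient mass is available).  Gene
baseline means are log-normal (log-mean 4, log-sd 1, i.e. typical counts
in the tens); per-sample library scale is log-normal with sd 0.2 and
mean 1.  Isoform means are gene mean × usage × library scale; exon-part
means are the mask-weighted sum of isoform means (part length is ignored
by default; a length-weight flag exists); counts are negative binomial
with variance μ + φμ² (φ = 0.1; a Poisson flag covers the φ → 0 limit).
Gene counts are emitted as the *exact* sum of the gene's isoform counts,
so gene totals carry no usage signal whatsoever — the cleanest
falsifiable version of the hypothesis that splice-aware models detect
signal invisible at gene resolution.  Truth records the effect genes and
the informative exons (parts whose expected mean differs between
classes: the private parts of effect genes).

Defaults — 60 genes, 15 effect genes, switch_delta 0.35, 300 samples per
class — define the classification contest.  The sparse-recovery
experiment uses 9 parts per isoform (600 exonic parts), 8 effect genes
(16 informative exons; the private-part construction makes an odd count
impossible) and 1,200 samples per class, per the protocol-scale note
above.

What the generator does *not* emulate: read-level sampling, positional
or GC bias, length-dependent counting noise, correlated genes,
overlapping genes, batch effects, or isoform-estimation uncertainty.
Passing tests therefore demonstrate the mechanics of the method under
its intended signal regime, not performance on real RNA-seq.

## Numerical choices

* Accuracy threshold 0.5 on the sigmoid output.
* Logistic baseline: L-BFGS with analytic gradients to gradient norm
  < 10⁻⁸; ridge penalty (if any) applies to slopes only.  Perfect
  separation without a penalty warns and returns the current iterate.
* Elastic net: logistic loss + l1‖β‖₁ + l2‖β‖² (slopes only, absolute
  penalty weights, default 5·10⁻⁴ each), solved by proximal gradient
  with backtracking, guaranteeing a monotone objective.
* Relationship matrices require every row to have ≥ 1 nonzero (every
  exonic part belongs to at least one transcript by construction).
* Degenerate inputs (zero library sizes, single-class training sets,
  rank-deficient designs, empty importance maps) raise informative
  errors rather than propagating NaNs.

## Known limitations

* Gradient attributions require the training protocol to operate at its
  design scale (see protocol-scale note); on very small cohorts the FSL
  weights and saliencies reflect initialization more than data.
* The fully connected exon→isoform "comparison" layer can be
  constructed, but tuning it at scale is out of scope.
* No GO/pathway enrichment statistics; selected exons are exported as a
  gene list for external tools.
* Overlapping genes are flattened independently; parts shared by two
  genes appear once per gene.
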