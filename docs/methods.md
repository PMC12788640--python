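# Methods

`histoimmune` chains four statistical components — single-cell quality
control and normalization, reference-based cell-composition deconvolution,
weakly supervised multiple-instance learning (MIL) on slide tile bags, and
survival stratification — together with a synthetic-data generator that
supplies every input with known ground truth. This note documents the models,
their assumptions, the tunable parameters that matter, and the numerical
choices made where the design was genuinely open.

## Synthetic data: what it emulates, and what it does not

The generator stands in for a hepatocellular-carcinoma-style cohort: droplet
single-cell RNA-seq with per-sample batch effects and low-quality cells, bulk
expression as mixtures of cell types, H&E-like slide tiles, and right-censored
overall survival.

**Signature reference.** `make_reference(n_types, n_genes, marker_frac,
seed)` draws log-normal baseline gene means shared across types, multiplies
each type's disjoint marker set (`marker_frac` of genes per type, default 5%)
by a fold change (default 8), and renormalizes rows to unit library size.
Disjoint markers guarantee identifiability of the deconvolution problem;
real references have overlapping programs and correlated types, so recovery
here is easier than on real tissue.

**Single cells.** Counts are negative binomial (gamma–Poisson, gene-level
dispersion θ = 10) around the type signature, scaled by a log-normal library
size (mean 2,000 counts, σ = 0.3) and a per-batch multiplicative gene factor
with geometric SD `batch_effect` (1.0 = no batch effect; 1.2–1.3 makes the
batch-vs-clustering ARI comparisons non-trivial without swamping biology).
A `lowq_frac` share of cells is planted as low quality — mitochondrial
fraction drawn in (0.06, 0.30), or detected genes forced below 250 or above
2,500 — and the generator records both the intent (`planted_lowq`) and the
realized truth under the canonical bounds (`qc_ok`). Downstream tests compare
against this bookkeeping, never against re-derived quantities. The
mitochondrial fraction is planted as a per-cell scalar by default; a
`mito_mode="genes"` option renames a small gene set to `MT-*` and realizes
the fraction through counts, for I/O realism.

**Slides.** A bag is `n_tiles` fixed-size RGB tiles: eosin-pink textured
noise (smoothed Gaussian field plus pixel noise), with dark elliptical
nucleus-like blobs stamped onto a binomial-drawn subset of tiles at the
class's `signal_density`. Density maps must be monotone in the ordinal class,
so mean planted-signal count increases with immune level. No attempt is made
to mimic real H&E color statistics, stain variation, or tissue morphology —
passing the MIL benchmarks shows that the aggregators recover a planted,
linearly separable tile signal, not that they would segment real lymphocyte
infiltrates.

**Survival.** Exponential event times with baseline hazard 1/24 per month
(median ≈ 16.6 months, of the order of published HCC cohorts); the first
half of the cohort ("high") has hazard multiplied by `hazard_ratio`.
Censoring is independent: with probability `censor_rate` a record is censored
at a uniform fraction of its event time.

## Quality control and normalization

A cell is retained iff its detected-gene count lies in the closed interval
[250, 2,500] **and** its mitochondrial fraction is ≤ 5%. The boundary
semantics are deliberate: the feature window is read as a closed range, and
mito removal is strict ("exceeding" 5%), so a cell at exactly 0.05 survives.
Missing mitochondrial information is an error, never silently treated as
zero.

Single-cell normalization is global scaling: `log1p(count · scale_total /
libsize)` with `scale_total` = 10,000 (the common global-scaling convention).
After un-logging, every cell's library sums to `scale_total` — a conservation
property the tests assert. Bulk matrices get upper-quartile normalization,
with the 75th percentile computed over each sample's **nonzero** genes (the
usual convention; computing over all genes would make the quartile degenerate
for sparse samples).

The embedding/clustering step (PCA + k-means by default) exists only to
supply a partition to the ARI evaluation; any clusterer can be plugged in via
`cluster_fn`. Equivalence with any particular graph-clustering tool is a
non-goal.

## Adjusted Rand index

From the r×s contingency table of two partitions,

ARI = (Σᵢⱼ C(nᵢⱼ,2) − E) / (½[Σᵢ C(aᵢ,2) + Σⱼ C(bⱼ,2)] − E),
E = Σᵢ C(aᵢ,2) Σⱼ C(bⱼ,2) / C(n,2).

The three-way report compares annotation–clustering (high is good),
batch–clustering (low is good: clusters should not follow batch), and
annotation–batch (low is good: types spread across batches). Degenerate case:
when both partitions are a single cluster the denominator vanishes with
perfect trivial agreement; we define ARI = 1 there. Negative values (worse
than chance) are reported unclamped. The implementation is verified
exhaustively against an independent pair-counting formulation for all
partition pairs of up to 6 points, and on large random samples at 7–8 points.

## Deconvolution

Training data are pseudo-bulk mixtures: a Dirichlet(1) draw on the
type simplex, a multinomial realization of `n_cells` = 500 cells at those
proportions, summation of the sampled cells' raw counts, then CPM + log1p.
The recorded ground truth is the **realized** multinomial composition — what
the mixture actually contains — not the Dirichlet parameter.

The regressor is an ensemble of three multilayer perceptrons of increasing
capacity — hidden layers (256), (512, 128), (512, 256, 64) with dropout
0.0 / 0.2 / 0.4 — each ending in a softmax over types, so every member's
output is a valid fraction vector. Diversity comes from capacity and
initialization; members see identical data. The combine rule is the member
mean renormalized to the simplex, which can only improve on the worst member
(asserted as a test property). The loss is MSE on fractions (a KL/cross-
entropy option is available behind the `loss="kl"` flag); inputs are
z-scored with statistics frozen at fit time; optimization is AdamW (lr 1e-3)
with cosine annealing for 40 epochs at batch size 128.

At prediction time external bulk profiles are reconciled to the training
gene ids: missing genes are imputed as zero with a warning count, and a gene
overlap below 50% is an error rather than a silent extrapolation.

Benchmark conditions: 8 types × 500 genes, 8,000 training / 2,000 validation
mixtures. The suite requires median per-sample Pearson correlation ≥ 0.90 on
validation; the implementation reaches ≈ 0.99. The per-sample correlation is
computed across types (requires ≥ 3 types), the per-type correlation across
samples; zero-variance vectors yield NaN and are flagged, not hidden.

## Multiple-instance learning

A slide is a bag of 224×224 tiles in production settings; the repository
default is 64 px because the aggregation math is size-agnostic and 64 px
trains on one CPU. Tiling is a non-overlapping row-major grid with 0-based,
half-open [r, r+t)×[c, c+t) windows; partial edge tiles are discarded.
Instance selection takes the `k` = 44 darkest tiles by mean intensity at
training time (dark = tissue-rich on H&E, the "min" sort) and a seeded
uniform subsample at evaluation when a bag exceeds k.

**Ordinal encoding.** Class c of C is encoded as c+1 leading ones in a
length-C binary vector (bits 0..c set), so bit k answers "class ≥ k" and
bit 0 is vacuously 1. The literal "up to the label index" reading fixes the
length-C convention; the alternative C−1 "greater-than" encoding was
considered and rejected for fidelity to that rule. Decoding is
max(0, #(p > 0.5) − 1), monotone in every probability. The loss is mean
element-wise binary cross-entropy on logits against this encoding.

**Aggregators.** Tiles in [0,1] (uint8 inputs are rescaled by 1/255; no
channel standardization) pass through a small convolutional encoder: a fixed
2× average pool, three stride-2 3×3 conv blocks (8/16/32 channels), global
average pooling, and a linear projection to d = 128. The input is centered
by −0.5 before the first convolution; with all-positive inputs a fraction of
initializations otherwise collapses to a constant predictor. A pretrained
backbone can replace the encoder wherever a tile→vector callable is
accepted; it is not used in tests. Three permutation-invariant heads:

- **mean** — unweighted average of instance embeddings (CNN baseline);
- **att** — gated attention: scoreₖ = wᵀ(tanh(V hₖ) ⊙ σ(U hₖ)), softmax
  weights over instances, weighted-sum bag embedding;
- **att_trans** — a pre-norm transformer encoder (1 layer, 4 heads, no
  positional encoding) over the instance set, then gated attention pooling.
  Encoding *before* pooling is the only coherent order: pooling first would
  leave a single vector, making a sequence encoder vacuous.

**Training.** AdamW with cosine annealing, mini-batches of up to 4 bags,
per-tile augmentation (random horizontal/vertical flips and uniform 90°
rotations), early stopping on validation QWK (accuracy for binary labels)
with patience 5 and a 10-epoch floor — the floor matters because a constant
predictor can set an early validation bar that genuine learning only clears
after the loss starts moving. For `att_trans` the transformer parameters
form a separate optimizer group at 1/5 of the base rate with weight decay
0.1; the base rate defaults to 1e-3, which suits the small from-scratch
encoder (with a pretrained deep backbone, rates of order 3e-5 base / 6e-6
transformer are the appropriate regime, and the same grouping machinery
applies).

Benchmark conditions: 200 bags of 44 64-px tiles, binary labels, positive
bags ≈ 50% signal tiles, 70/30 split. Gated attention reaches ≥ 0.9
validation accuracy within 30 epochs (typically ~1.0 in ≤ 15), and its mean
attention weight on planted signal tiles exceeds the background mean in
≥ 90% of positive validation bags. Both attention modes match or beat the
mean-pool baseline (within 2%) averaged over 3 seeds. Note that `att_trans`
need not show attention enrichment: the transformer mixes instance
information before pooling, so localization is not guaranteed even when
classification is perfect.

## Labeling and survival

Patients are stratified per cell type at the median estimated fraction:
strictly above the median is "high", ties at the median go "low" (so the
high group strictly exceeds the threshold). An all-identical fraction vector
is an error — no stratification exists.

The Kaplan–Meier estimator is the standard product limit over distinct event
times with tied events aggregated; it equals the empirical survivor function
when there is no censoring (asserted on random cohorts, and cross-checked
against `lifelines`). The two-group log-rank test accumulates observed-minus-
expected events with the hypergeometric variance; the statistic is χ²(1).
Monte-Carlo calibration at n = 200: type-I error within 0.05 ± 0.02 over
1,000 null replicates; power > 0.8 (measured ≈ 0.99) at hazard ratio 2 over
500 replicates. P-values are reported unadjusted per cell type (a
Benjamini–Hochberg helper exists but is off by default).

Accuracy confidence intervals use the t distribution with n−1 degrees of
freedom over repeated runs/folds; what n indexes (runs, folds) is the
caller's choice and is documented at the call site.

## End-to-end pipeline

`run_pipeline` wires the stages from one YAML config. The synthetic cohort
couples everything to a single per-patient truth: the first half of patients
is immune-"high", which (a) boosts the target cell type in their bulk
mixture, (b) raises their slide's planted signal density, and (c) doubles
their hazard. The deconvolution ensemble estimates fractions, the median
split produces pseudo-labels, the MIL classifier trains on slides under
those (imperfect, ≈ 85–90% agreement) weak labels, and the log-rank test is
run on the MIL-predicted groups with survival times drawn from the *true*
groups. Defaults: 5 types × 400 genes, 2,000/500 deconvolution split, 200
patients, 24 tiles of 32 px per slide — sizes chosen so a full run takes
tens of seconds on one CPU while keeping the log-rank power of the planted
hazard ratio 2 near 0.99. Rerunning a config is byte-identical because every
stage seeds its own generator from the config seed.

## Numerical and engineering choices

- **Autodiff.** Models are built on a compact reverse-mode autodiff engine
  (`histoimmune.nn`) over numpy arrays: broadcasted arithmetic, batched
  matmul, im2col convolution, stable softmax/BCE-on-logits primitives, AdamW
  with parameter groups, cosine annealing. Gradients of every layer are
  verified against central finite differences in the test suite.
- **Determinism.** All randomness flows through `numpy.random.Generator`
  instances seeded from explicit integers; identical seeds give bit-identical
  generator outputs, training trajectories, and pipeline artifacts
  (single-threaded numpy).
- **Degenerate inputs.** All-zero cells, all-zero bulk samples, empty batch
  lists, single-group log-rank, all-identical median splits, <50% gene
  overlap, and out-of-range ordinal labels are explicit errors with the
  offending entity named; ARI and QWK degenerate (zero-denominator) cases are
  defined as 1 exactly when agreement is perfect and trivial.
- **Ties.** Instance selection breaks intensity ties by original tile order
  (stable sort); tied event times are simultaneous deaths; median ties go to
  "low".

## Known limitations

- The synthetic generators are deliberately simple; none of the benchmarks
  here certify performance on real scRNA-seq (ambient RNA, doublets,
  overlapping programs) or real WSIs (stain variation, artifacts, weak or
  diffuse signal).
- The deconvolution benchmark uses the same generator family for training
  and validation mixtures; distribution shift to genuine bulk platforms is
  exercised only through the gene-reconciliation path.
- Cox proportional-hazards modelling and concordance-index evaluation are
  out of scope; stratification is binary by design of the weak labels.
- The MIL contract is CPU-only; there is no GPU or mixed-precision path.
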