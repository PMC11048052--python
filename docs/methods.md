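# Methods

## Problem setting

A spatial transcriptomics (ST) spot measures the pooled expression of the 2–10
cells it covers. Deconvolution infers, for every spot, a probability vector
over k reference cell types. `gtadc` treats this as semi-supervised node
regression on a graph that contains both synthetic "pseudo-spots" (whose
composition is known by construction) and the real spots (whose composition is
the quantity of interest).

## Marker-gene selection

Selection operates on the QC-filtered, counts-per-10k log1p-normalized
reference. "Detection rate" of a gene in a type is the fraction of that type's
cells with a strictly positive raw value; the QC prefilter drops genes below a
20% rate in every type (kept at exactly 20%).

Stages, each only removing genes:

1. **Rate fence.** Per type, genes whose detection rate exceeds
   `Q3 + 1.5·IQR` of that type's rate distribution (quartiles by linear
   interpolation) are kept; the union over types survives. On rate data
   bounded by 1 the fence can be unreachable, so if fewer than `min_genes`
   (default 200) pass, the top `min_genes` genes by maximum rate are kept
   instead. The alternative grouping `0.5·(2·Q3 + 1.5·IQR)` is available as a
   config switch.
2. **Top-mean cut.** The `l` genes (default `min(s, 1000)`) with the largest
   max-over-types mean expression; ties break lexicographically by gene id so
   results are reproducible.
3. **Dispersion ranking.** For gene g and target type t,
   `disp = (a − b) · (c / (d + ε))^e` with `a` the mean in t, `b` the largest
   mean among the other types, `c` the rate in t, `d` the mean rate of the
   other types, `ε = 1e-6`, `e = 1` by default. Only genes with `disp > 0`
   qualify as candidates: a candidate marker must be over-expressed in its
   type, which also guarantees that a gene expressed only in type A never
   enters another type's list. The top `3t` candidates per type proceed.
4. **Silhouette re-ranking.** For each candidate, cells are placed on the 1-D
   axis of that gene's (normalized) expression with the cell types as
   clusters; the score is the mean over the target type's cells of
   `s(i) = (b(i) − a(i)) / max(a(i), b(i))` with `a(i)` the mean intra-type
   distance and `b(i)` the smallest mean distance to another type
   (`|x − y|` distances; singletons and `a = b = 0` score 0). Types are
   subsampled to at most 500 cells (fixed seed) to keep the computation
   O(n²)-tractable. The top `t` (default 20) per type form the marker set;
   the deduplicated union (first-appearance order) feeds every later stage.

The per-gene 1-D silhouette has a known quirk worth stating: a gene *absent*
in the target type but present elsewhere also separates the clusters (the
target sits tightly at zero) and can score close to 1. The positive-dispersion
candidacy rule above is what keeps such inverse markers out.

## Pseudo-spots

Each training spot sums the raw counts of 2–8 cells (member count uniform,
cells drawn uniformly with replacement; a per-type-balanced mode exists behind
a flag). Ground truth is the member-type count vector divided by the member
count. Summation happens on raw counts — real spots aggregate transcripts
before any normalization — and the summed spots then pass through the same
counts-per-10k log1p transform as the real ST matrix. The default number of
training spots is 5× the number of real spots. For benchmarks, the cell pool
is split 50/50 beforehand so benchmark spots share no cells with training
spots.

## Integration

Both spot sets, restricted to the shared marker genes (≥ 10 required), are
standardized per gene with pooled mean/std and projected onto the top d = 30
principal axes of the concatenated matrix (full SVD, deterministic). Anchors
are mutual nearest cross-batch neighbors under cosine similarity
(n_neighbors = 15); each anchor's score is the overlap fraction of the two
endpoints' neighborhoods in the full embedding.

The correction keeps, per real spot, only the highest-scoring anchor per real
endpoint — the full mutual-neighbor list contains many merely-similar pairs
whose displacements are biased along the batch shift, and filtering to best
matches removes most of that bias. Real spot x is then shifted by the
weighted mean of anchor displacements (pseudo − real), with weights
`score · exp(−dist(x, real_endpoint)² / (2σ_x²))` and σ_x the median distance
from x to the anchor endpoints. The pseudo batch never moves: the training
labels live there, so it is the fixed reference frame. With no anchors the
embedding passes through unchanged with a warning.

Node features for the network are the integrated embedding by default; a
config switch (`feature_space: expression`) applies the same anchor
correction in marker-expression space instead.

## Spot graph

Random projection trees split recursively: draw a random unit direction,
project, split at the median projection (ties to the lower half, so duplicate
points can never be separated), recurse until ≤ `leaf_size` (default 40)
points remain. If a node's projections are all identical after three
direction retries it becomes a leaf as-is. Points sharing a leaf are
connected with weight 1; averaging over T = 10 trees (independent RNG streams
spawned from the master seed) yields symmetric weights on the 1/T grid with a
zero diagonal. The matrix is stored sparse.

## Graph attention network

Two layers, pure NumPy, gradients derived by hand and checked against finite
differences in the test suite.

- Raw attention `e_ij = LeakyReLU(aᵀ[W h_i ∥ W h_j])`, negative slope 0.2.
- Modulation: `V = E ⊙ A` with self-loops of weight 1 added to A first — with
  a zero diagonal the modulation would erase each node's own signal. The
  softmax is masked to the neighborhood support, so non-neighbors get exactly
  zero attention; modulating after the softmax is a config switch.
- Hidden layer: 4 heads × 64 units, concatenated, ELU. Output layer: 4 heads
  averaged, then row softmax over the k types.
- Loss: soft-label cross-entropy `−Σ_c y_c log(p_c + 1e-12)` averaged over
  pseudo-spots only (the real spots are unlabeled). Uniform predictions give
  exactly log k, which the tests exploit.
- Optimization: Adam, lr 5e-3, 300 epochs, dropout 0.1 on layer inputs,
  Glorot-uniform init, all seeded. A NaN loss aborts with the epoch number.

Node order is pseudo-spots first, then real spots; the layer operations are
permutation-equivariant, which the tests verify directly.

## Evaluation

JSD(p, q) = sqrt(½ KL(p‖m) + ½ KL(q‖m)), m = (p+q)/2, logs base 2 so the
range is exactly [0, 1] (0·log 0 ≡ 0). Spots are aligned by id and types by
name, never by position. The uniform baseline scores the constant 1/k
prediction per spot analytically with the same formula. Variant comparisons
use the two-sided Wilcoxon rank-sum test (exact enumeration when both samples
have n ≤ 10 without ties, otherwise the normal approximation with tie and
continuity correction).

## Synthetic data

The simulator draws counts from a negative binomial (size r = 4; variance
μ + μ²/r) with per-type means and applies entry-wise Bernoulli dropout
(default rate 0.05). Each type owns `markers_per_type` planted marker genes
with mean `baseline_mean × fold_change` (0.5 × 8 = 4) in the owning type and
a near-zero mean (0.01) elsewhere, so markers are detected in roughly 90% of
their own type's cells and under 5% of the rest — the regime of a curated,
cleanly annotated reference. Setting `marker_off_mean=None` switches to a
pure fold-change model (markers keep baseline expression off-type), which is
markedly harder for silhouette ranking because off-type zeros stop being
informative. Benchmark ST spots are pseudo-spots built from the held-out cell
half, multiplied by a fixed per-gene factor `exp(batch_shift · g)`,
`g ~ N(0,1)` (default shift 0.5) — the simplest mechanism that makes the
integration step's contribution observable.

What the simulator does not emulate: spatial autocorrelation of composition,
lattice geometry, library-size gradients, ambient RNA, doublets, or continuous
cell states. Passing tests therefore demonstrate the machinery is correct and
the pipeline recovers planted structure under realistic noise — not
performance on any particular tissue.

## Default problem sizes

The bundled benchmark scenario is k = 4 types × 150 cells, 2000 genes, 25
markers/type, 400 training pseudo-spots and 100 benchmark spots; one full run
takes ~30 s on a single CPU, and the evaluation suite runs several such
configurations. These sizes were chosen so the whole distribution exercises
the complete method at desk scale while remaining statistically meaningful
(100 spots give a stable mean JSD).

## Numerical choices and edge cases

- ε = 1e-6 guards the dispersion denominator; 1e-12 the log in the loss.
- All-zero rows pass through normalization unchanged with a warning.
- Duplicate gene ids on input are summed, not dropped.
- Ties in gene ranking break lexicographically by id; median-split ties go to
  the lower half; subsampling and tree RNG streams all derive from explicit
  seeds, so every path is reproducible.
- Quartiles use linear interpolation (the common default), stated so the
  fence is reproducible elsewhere.

## Limitations

- The anchor correction is a single-pass rigid local shift; it removes
  location (mean-like) batch differences but not variance or nonlinear
  distortions.
- Per-gene 1-D silhouette ignores gene-gene covariance; a gene pair that
  separates types jointly but not marginally will be missed.
- Full-graph dense attention is O(N²) per layer; comfortable to a few
  thousand spots, not for large arrays without neighbor sampling.
- With `t` markers per type and cross-type duplicates deduplicated, the
  marker union is at most k·t genes; if more planted/true markers exist than
  k·t, complete recovery is impossible by construction.
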