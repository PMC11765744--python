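# Methods

This note documents the models and procedures implemented in `zoocnn`, the
defaults chosen where the design was genuinely open, and what the
desk-scale tests do and do not demonstrate.

## Search space and codec

A configuration Θ = (l, f₁…f_l, η, d) lives in a mixed space: depth
l ∈ [3, 7] (integer), per-layer filter counts with ranges
f₁ ∈ [16, 64], f₂ ∈ [32, 128], f₃ ∈ [64, 256], f₄ ∈ [16, 512],
f₅ ∈ [32, 256] (accepted verbatim, including the non-monotone f₄ range),
learning rate η log-uniform on [10⁻⁵, 10⁻¹], and dropout d ∈ [0.1, 0.7].
Two range repairs were needed: the source material's dropout range is
corrupted (it repeats the depth range) and its printed learning-rate range
excludes its own tuned optimum 1.253981·10⁻⁴, so the defaults here are the
smallest natural intervals containing the tuned point (dropout 0.44 and the
learning rate above); both printed endpoints remain reachable through
configuration.  A further inconsistency is recorded rather than repaired:
the optimized reference network's fifth layer uses 512 filters although the
printed f₅ range tops out at 256; the reference fixture keeps 512, the
search space keeps the printed range.

Vectors use a fixed length-8 codec (depth, five filter slots, η, d) in
natural units; decoding clips to bounds and rounds discrete slots to the
nearest valid integer, making decode a projection.  Slots at index ≥ depth
are carried but inert.  Configurations deeper than five blocks repeat the
fifth slot's filter count, keeping the codec fixed-length while allowing
depths 6–7.  Internally the optimizer works in normalized [0,1]⁸
coordinates with the learning rate on a log scale, so a step size is a
fraction of each interval regardless of units.

## SRACOS

The optimizer is a sequential classification-based (positive/negative set)
search:

1. evaluate a uniform population (default 50);
2. maintain a positive set of the best 1 + population/10 points and a
   negative reservoir (capacity population − positives) filled by random
   replacement, so negatives stay representative of the whole space rather
   than clustering near the incumbent;
3. each iteration, with exploration probability annealed linearly from
   0.6 to 0.3, draw a uniform candidate; otherwise draw from an
   axis-aligned box around a random positive point: initial half-width
   `step_size` (default 0.1) per normalized coordinate, then single
   coordinates are repeatedly shrunk to a random cut between the anchor
   and a violating negative until all retained negatives are excluded
   (the anchor always stays inside).  Two refinements make exploitation
   effective in practice: all but max(2, dim/4) randomly chosen
   coordinates are clamped to the anchor's exact values (randomized
   coordinate shrinking), and the per-iteration step is drawn
   log-uniformly between `step_size` and an annealed floor reaching
   `step_size`/100 at the end of the run, so fine refinement and coarse,
   grid-cell-hopping moves coexist;
4. candidates that decode to an already-evaluated configuration are
   redrawn (up to 10 attempts), so discrete spaces are not burned on
   duplicates;
5. stop at the evaluation budget (default 300, counting failed
   evaluations, which score +∞) or after `patience` (default 30)
   iterations in which no candidate improved on the positive set.  On a
   flat landscape this stops after exactly population + patience
   evaluations; with the budget read as total evaluations, "300
   iterations" of single-candidate refinement matches the published
   schedule (the 300-generations reading is available via configuration).

The "expected loss, averaged over multiple evaluations" reading of the
noisy objective is honoured by `re_evaluations` (default 1).  The
explore/exploit ratio is interpreted as a per-candidate exploration
probability; the source never states the mapping, and a candidate-count
split is equivalent in expectation.

A random embedding option maps a low-dimensional unit box through a fixed
Gaussian matrix (entries i.i.d. N(0,1)) into the normalized space, centred
at 0.5 and clipped, for problems whose objective has low effective
dimension.

## POSS

Layer pruning uses the canonical Pareto-optimization-for-subset-selection
construction: masks of length n (bit 1 = exclude), a start at all-excluded,
uniform parent choice from the archive, independent per-bit flips with
probability 1/n, and an archive kept mutually non-dominated under the
bi-objective (loss, number of *included* layers), both minimized.  The
included-count objective is what makes the single-layer example archive
both masks (the smaller mask survives on size, the better mask on loss).
`select_final` bridges to the depth constraint: lowest loss among masks
with at least `min_layers` included, ties toward fewer layers then
lexicographic order.  On additive losses with n = 8 the archive's best mask
matches exhaustive enumeration over 256 masks well within the theory budget
2·e·n²·ln n.  The undefined expectation in the loss is implemented as the
mean over `re_evaluations` evaluator calls, consistent with the noisy
objective treatment above.  Within the pipeline POSS is a post-hoc
refinement of the incumbent's layer pattern (the interleaving is not
specified by the source; post-hoc is the least intrusive choice).

## ADASYN

For minority class size m_s versus majority m_l and balance level
β ∈ [0, 1]: G = round(β·(m_l − m_s)); per-minority-point difficulty
rᵢ = Δᵢ/k with Δᵢ the count of non-minority points among the k nearest
neighbours in the full dataset (Euclidean, self excluded; k defaults to 5,
the original reference value, as none is stated); normalized ratios
r̂ᵢ (uniform when all rᵢ = 0) are apportioned into integer counts gᵢ by
largest remainder, so Σgᵢ = G exactly — plain rounding does not guarantee
this.  Synthesis interpolates xᵢ + λ(x_z − xᵢ), λ ~ U[0,1], toward a
uniformly chosen one of xᵢ's k nearest *minority* neighbours; pixel-space
outputs are clipped to [0,1].  In the three-class setting Δᵢ counts all
non-minority neighbours, not a single designated majority class.  Images
are balanced on flattened raw pixels (no feature extractor is stated in the
source; an embedding hook would slot in at the `_as_matrix` boundary), and
only the training split is ever balanced — validation and test stay
untouched to prevent leakage (standard practice, though unstated in the
source).

## Architecture accounting

Shape rules: same-padded stride-1 convolution preserves spatial size and
sets channels to the filter count; valid convolution maps n to
⌊(n − K)/S⌋ + 1; 2×2 pooling halves (floor) each spatial dimension.
Parameter counts: conv K²·C_in·n_f + n_f; dense n_in·n_out + n_out; pooling,
flatten and dropout zero.  These conventions are the unique ones consistent
with every printed shape row of the reference tables.  Batch normalization
is a descriptive flag counted as zero parameters — the baseline's printed
totals are only reproducible that way.  Known errata in the source tables,
excluded from assertions: the optimized network's dense cell prints
1,605,695 where the arithmetic gives 25088·64 + 64 = 1,605,696; its printed
total 3,174,891 matches neither the row sum (3,173,890) nor the comparison
table's 3,174,991; its input row prints 226×226 (unreachable from a
224×224 input with same padding); and the baseline is listed with one
input channel although its first conv cell (448 = 3·9·16 + 16) requires
three.  One published improvement figure (2.43 accuracy points) differs
from the printed operands (97.26 − 94.96 = 2.30); the metric engine
computes, it does not replicate arithmetic errors.  The tuned dropout
(0.44) is placed after the first dense layer, a parameter-free position
consistent with all printed counts.

## Trainer backend and surrogate

The trainer contract is pluggable; the shipped backend is a compact NumPy
implementation (im2col convolution, fused ReLU, 2×2 max pooling, dense
layers, inverted dropout, softmax cross-entropy, Adam) that is fully
deterministic under a seed and single-threaded.  It is intended for
desk-scale problems — 16–32 px images, tens of filters — where a candidate
trains in well under a second; it makes no attempt at large-scale
performance.  Early stopping monitors validation loss with configurable
patience and reports the best epoch's metrics.  Requesting any other
backend raises a capability error pointing to the surrogate.

The surrogate evaluator is a deterministic analytic stand-in for validation
loss: accuracy 0.95 − 0.05·(log₁₀η − log₁₀η*)² − 0.4·(d − 0.44)² + 0.004·min(l, 5)
(clipped to [0,1]) with η* the tuned learning rate, fed through the
composite fitness.  It exists to exercise the search loop in milliseconds
and to make pipeline runs byte-reproducible; it encodes the qualitative
landscape (a broad optimum in log-learning-rate and dropout, mild depth
preference) rather than any measured surface.

## Composite fitness and metrics

fitness = accuracy + depth_penalty·l − λ·n_params, with defaults
depth_penalty = −0.01 (a penalty per block) and λ = 10⁻⁸ per parameter.
Magnitudes are not published; these defaults price the observed
12.9M → 3.2M parameter reduction at ≈ 0.1 fitness, commensurate with the
~2-point accuracy differences at stake.  Metrics are one-vs-rest per class
(sensitivity TP/(TP+FN), specificity TN/(TN+FP), precision TP/(TP+FP),
F1 = 2PR/(P+R)) with macro (unweighted) averages — the convention that
treats classes equally after rebalancing; the averaging rule is not stated
in the source.  Zero-denominator cells report 0 and are flagged.

## Synthetic data

All classes share a procedural lung-field background: low-amplitude
sinusoidal rib bands, a smooth off-centre vignette, faint grain.  Class 0
adds 1–3 bright elliptical consolidation blobs (random position,
eccentricity, orientation); class 1 is the clear background; class 2 adds a
diffuse ground-glass haze (uniform lift of 0.10–0.16) plus correlated
Gaussian noise (σ = side/32 smoothing, amplitude 0.10).  The haze component
matters: purely zero-mean independent noise makes same-class pairs *more*
distant in pixel space than cross-class pairs, destroying nearest-neighbour
signal; a systematic diffuse opacity is also the more faithful rendering of
a viral pattern.  Pixels are clipped to [0,1]; each image draws from its
own child of a splittable seed sequence keyed by (class, index), so output
is bit-identical for identical arguments and independent of other classes'
counts.  Default test side is 64 px (the reference pipeline uses 224; all
shape/parameter arithmetic is size-parametric and verified at 224).

What passing tests show: the textures are separable (1-NN accuracy > 70%
at 100 images/class), so the pipeline has signal to find, and every
combinatorial/numeric component behaves correctly.  What they do not show:
anything about real radiographs — no anatomy, no acquisition variability,
no label noise, and pixel-space ADASYN on real CXRs would behave
differently than on these compact textures.  The published full-scale
accuracies (≈97%) are out of reach of, and not claimed by, this package.

## Pipeline and problem sizes

Stages (simulate/ingest → split → balance → search → final evaluation →
summary) each persist an artifact (HDF5 bundle, JSON manifest, CSV trace,
CSV shape table, JSON metrics/summary) and can be resumed; summaries embed
the exact space, weights and seeds used.  Train/validation/test fractions
default to 70/15/15 (the source states no split).  The desk-scale
end-to-end check uses 16×16 images (75/45/40 per class), a reduced space
(depth 1–3, filters 4–16), population 6 with 12 evaluations, 3 training
epochs per candidate, and compares the selected configuration against the
space's mid-range fixed baseline at equal training budget, median over
5 seeds — sizes chosen so a full run takes seconds while leaving the
comparison non-trivial.

## Known limitations

* The NumPy backend routes tied max-pool gradients fractionally and uses
  float32 accumulation; it is a reference implementation, not a performance
  one.
* SRACOS internals beyond the published schedule (positive-set size,
  reservoir capacity, clamping count, step anneal) are this package's
  design choices, exposed in `OptimizerConfig`.
* ADASYN on raw pixels produces blended images (convex combinations); no
  attempt is made at anatomically plausible synthesis.
* The random embedding clips at the box boundary, so mass concentrates on
  faces for large target deviations — inherent to the construction.
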