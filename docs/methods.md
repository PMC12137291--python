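# Methods

## Pipeline model

`plantpatch` treats whole-plant phenotyping as patch classification, not
segmentation or object detection: an image is a grid of 10×10-pixel
tiles, each tile carries exactly one of six labels (background, branch,
leaf, bud, flower, pod), and every downstream quantity — evaluation
metrics, abundance trajectories, first-appearance dates — is a function
of those tile labels. The assumptions this rests on: one plant per image,
a dark uniform background, fixed scale across the series, and a patch
size small enough that a single label per patch is a reasonable
approximation (10 px was chosen as the largest size at which most patches
contain one class only).

### Grid conventions

Tiling starts at the top-left origin; only full patches are kept, so an
H×W image yields ⌊H/10⌋·⌊W/10⌋ patches and right/bottom remainder strips
(2056 and 2454 are not multiples of 10) are excluded rather than padded
or resized — this keeps every training example exactly 10×10×3.
Coordinates are 0-based, row-major, with half-open pixel intervals, so
reassembly arithmetic is exact; the round-trip (slice, then concatenate)
is bit-identical on the covered region, which the tests assert at full
2056×2454 resolution.

### Splitting and weighting

The 60/20/20 stratified split uses a two-level rounding rule: global
validation and test sizes are each round-half-up(0.2·N); per class,
allocations are apportioned against the exact targets 0.2·N_c by largest
remainder (ties by descending class count, then canonical class order),
so every per-class allocation is within one patch of its target while
the global totals are met exactly. This rule reproduces the published
corpus arithmetic (62,303 → 37,381/12,461/12,461, and 3,486 for the
plant-only subsets).

Class weights are `w_c = 10/(0.6·N_c)` with N_c the full class count —
the real-valued 60% training share, not the post-split integer. The
distinction matters: the published plant-subset counts contain an
internal off-by-one (10,458 + 3,486 + 3,486 ≠ 17,431), so integer-based
weights are not uniquely recoverable, while the real-valued form
reproduces all six published weights at 4 decimal places. Under the
weighted with-replacement sampler, `w_c · (0.6·N_c) = 10` for every
class, i.e. expected draws are class-balanced.

### Classifier backbone

The trainable unit is `PatchNetClassifier`, a fully-connected softmax
network (flatten → 64 ReLU units → softmax) trained with mini-batch Adam
(lr 0.001, batch 16) under a step schedule (×0.1 every 10 epochs, 50
epochs by default), deterministic for a fixed seed. A compact dense
network is the deliberate default for 10×10×3 inputs: at this patch size
class identity is carried almost entirely by color and coarse texture,
which a two-layer network on raw pixels separates reliably, and the
pipeline contract (probability vectors over a label subset, confidences,
seeded determinism) is architecture-agnostic — larger pretrained
backbones can be plugged in behind the same estimator interface.
Imbalance is handled by the weighted sampler rather than loss weighting;
the loss is unweighted cross-entropy. The final-epoch model is used (no
early stopping); per-epoch loss and learning rate are recorded on the
estimator so the trajectory is auditable. Pixel values are scaled to
[0, 1]; no further normalization is applied by default.

### Composition strategies

All three strategies are total functions over the input patches and
deterministic; every tie-break uses the canonical class order.

- **multi6**: argmax of the 6-class probability vector; confidence is
  that maximum.
- **chain**: each binary model votes 1 when its positive-class
  probability is ≥ 0.5 (configurable); among positive votes the highest
  probability wins. When *no* model votes positive the class with the
  highest positive probability overall is emitted and the row carries a
  fallback flag — silently defaulting to background would inflate the
  majority class. The rule is patch-wise and model-order independent, so
  the six models may run in any order or concurrently.
- **hierarchical**: patches the binary background model calls positive
  are finalized as background with that confidence and never reach the
  organ model; the rest take the 5-class argmax. No first-stage
  background patch can carry a plant label, by construction.

Raw softmax outputs are used as confidences throughout; no calibration
is applied.

### Metrics

Precision, recall and F1 are computed from per-class TP/FP/FN; micro
aggregation pools the counts (and equals accuracy for single-label
multiclass data), macro averages per-class values without weights,
weighted averages by true-label support in the evaluated set. Empty
denominators yield 0 — this matches published tables where an
untrainable model scores 0.0 on minority classes. Reported values are
percentages at 2 decimals; full-precision values are retained. Model
ranking is by macro F1 (ties: weighted F1, then name) to emphasize the
minority organ classes. The implementation is independent of
scikit-learn; the test suite cross-checks all aggregates against
`precision_recall_fscore_support` on 100 random instances.

### Phenotyping rules

Abundance is an exact tally of final labels per image. "First
appearance" of a class is the earliest date with count ≥ threshold
(default 1 patch) sustained for `persistence` consecutive dates (default
1; 2 is recommended on real predictions to suppress single-date
misclassification blips). The rule is a documented convention — no
quantitative criterion exists to inherit — and the result is invariant
to record order. Multi-view series are kept separate by default; an
optional max-across-views merge is provided as a conservative lower
bound under occlusion.

## Synthetic data: what it emulates, and what it does not

The generator renders a side-view-like plant on a near-black noisy
background (values 0–12, so plant/background binarization is
non-degenerate): a seeded recursive branching skeleton (default depth 3,
2–3 children per node) drawn as thick strokes, leaf ellipses beside the
nodes, and organs at branch tips gated by a developmental schedule —
buds from day 5, flowers from day 8, pods from day 12, with a per-tip
lag (tip *i* lags `i mod 6` days) so organ classes overlap in time the
way a real raceme does. Growth is phenomenological: skeleton extent
scales linearly with day up to maturity (day 15); there is no
biomechanics. Image and label mask are painted by the same strokes, so
ground truth is exact by construction. Patch labels follow the
predominant-organ rule with `min_plant_pixels = 5` of 100: cells with
fewer plant pixels stay background, making explicit the annotator
convention that tiny organ slivers at a patch edge are not labelled as
that organ.

Default organ sizes were fixed once so that a default 3-plant × 15-day
series reproduces the *ordering* of the real corpus's imbalance —
background ≫ leaf > branch > flower > pod ≈ bud, with background above
60% of patches. The default canvas is 600×700 px (not 2056×2454) to keep
test runtimes at seconds scale; full resolution is available by config
and the grid round-trip is tested at full resolution.

Class palette colors are pairwise separable in RGB beyond their jitter
ranges. This is deliberate and is the main idealization: it makes a
learning-free nearest-palette-color classifier an exact oracle
(validating the generator, the predominant-organ rule and the metrics
jointly before any learning is involved), but it also means passing the
end-to-end benchmark does **not** demonstrate robustness to the
color-ambiguous cases that dominate real error (dark leaves vs. black
background, buds/pods against background at patch edges), nor to
lighting variation, occlusion, or camera artifacts. Results on the
synthetic benchmark are evidence that the pipeline — splitting,
weighting, training, composition, scoring, phenotype extraction — is
correct, not that the default backbone matches large pretrained
architectures on real imagery.

## Benchmark problem sizes

The end-to-end benchmark trains on a 3-plant × 15-day series (189,000
patches; 60/20/20 split) with the default optimizer settings at 20
epochs and 20,000 weighted draws per epoch. Held-out macro F1 lands in
the low-to-high 80s depending on seed; the spread is driven almost
entirely by the rare `bud` and `pod` classes, whose test supports are a
dozen-odd patches each, so single misclassifications move their F1 by
several points — mirroring the minority-class behavior seen on real
data.

## Known limitations

- The dense backbone does not exploit spatial context between patches;
  neighboring-patch smoothing is intentionally out of scope.
- The chain strategy uses uncalibrated confidences; classes whose binary
  models are systematically over- or under-confident will be over- or
  under-selected.
- Color-filter candidate rules (HSV ranges for flower/bud/pod) are
  tunable conventions; the default bud/pod range also matches leaves,
  which is acceptable for a candidate-ranking aid but not for automatic
  labelling.
- First-appearance detection with persistence 1 is exact on oracle
  predictions but sensitive to false positives on learned predictions;
  use persistence 2 there.
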