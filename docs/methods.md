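# Methods

## The training objective

A student network is trained on a classification task while one or more of
its internal layers carry an auxiliary error that matches the layer's
representational distance matrix (RDM) to that of a frozen teacher model on
the same mini-batch.  The RDM of a layer over a batch of n inputs is the
n×n matrix of pairwise dissimilarities between the layer's activation
vectors; it characterises the layer's representational geometry
independently of unit ordering and layer width, which is what allows
teacher and student architectures to differ.

The auxiliary error is the mean squared difference between student and
teacher RDM entries over the n(n−1)/2 unordered pairs, with prefactor
2/(n(n−1)).  Its gradient with respect to the activations is implemented
analytically for each supported dissimilarity; for the summed
squared-Euclidean dissimilarity the per-image gradient carries the
constant 8/(n(n−1)).  A pair-subsampled estimator evaluates the same
expression over a uniformly drawn subset of the n(n−1) ordered non-self
pairs, normalising each image's row by |X_P|·|P_{x_i}| where |P_{x_i}| is
the number of sampled pairs containing that image and |X_P| the number of
images covered at all; unsampled images receive an exactly zero row.  With
the exhaustive pair set this estimator coincides with the full gradient to
floating-point accuracy (a test asserts 1e−10), which fixes the
normalisation convention.  Whether the subsampled estimator is exactly
unbiased for the full gradient is not assumed anywhere; it is a measured
property.

Pair counting treats "image pairs" as ordered non-self pairs, n(n−1) in
total, because that convention reproduces the documented sample count
exactly: 2.5 % of the pairs of a 128-image batch is round(0.025·128·127) =
406.  For a 100-image batch, 5 % gives round(0.05·9900) = 495; a
`pair_count` override exists for callers who want a fixed budget such as
500 instead of the rounded fraction.

The combined gradient at an attachment layer is
backprop + α(t)·auxiliary, injected mid-backpropagation so that all
earlier layers receive the combined signal.  α is updated once per epoch:
linearly, α(t) = α₀(1 − t/t_max), for RDM matching (reaching exactly 0 at
t_max), and multiplicatively, α_{t+1} = α_t·0.1·(1 − t/t_max), for the
deep-supervision baseline.  Degenerate batches (n < 2) skip the RDM term
with a logged warning.

## Dissimilarities and their gradients

Four dissimilarities are provided: summed squared Euclidean (the API
default, whose printed gradient constant is exact), its per-unit mean
(scale-stable across layer widths), Euclidean, and correlation distance
(1 − Pearson r across units).  Correlation distance is undefined for
zero-variance vectors and raises a degenerate-input error rather than
returning a value.  Every gradient is validated against central finite
differences of the error itself; for the Euclidean dissimilarity the
subgradient 0 is used at coincident points, and for correlation distance
the centring projector is absorbed analytically (the centred vectors are
fixed points of it).  With exactly two units the correlation is ±1 almost
everywhere and its gradient is identically zero on each branch; gradient
tests therefore draw at least three units.

## Training regimes

* **baseline** — plain softmax/cross-entropy SGD with momentum.
* **finetune** — parameters copied layer-by-layer from the teacher before
  normal training; only the final paired layer (a replaced readout, e.g.
  for a different class count, or an extra appended readout) may disagree
  in shape; any hidden-layer mismatch is an error listing the offending
  layers.  Batch-normalisation running statistics are copied along with
  the parameters.
* **dsn** (deep supervision) — a *linear* softmax companion classifier on
  the flattened output of each attachment layer, trained against the task
  labels; its gradient into the trunk and its own parameter updates are
  both weighted by the multiplicative α schedule.
* **hints** — stage 1 trains a linear adapter from a student layer to the
  corresponding teacher layer's activations by mean squared error, updating
  the adapter jointly with the student layers up to the hint layer; the
  adapter is then discarded and stage 2 is ordinary supervised training.
  Stage-2 distillation variants are deliberately out of scope: hints are
  used here purely as a representational-transfer baseline.
* **rdl** — the RDM-matching attachments described above, teacher targets
  computed on the fly by a frozen teacher forward pass (inference mode) on
  the same images as the student's batch.

Each regime reduces exactly to the baseline when its mechanism is disabled
(α₀ = 0, no copy, skipped pretraining).  This is guaranteed structurally:
the single run seed is split into independent streams for initialisation,
batch shuffling, dropout masks, pair sampling and auxiliary-classifier
initialisation, so the α₀ = 0 run consumes the same randomness in the same
order as the baseline and is bit-identical.

## Network stack

Models are described by an ordered list of block descriptors (conv,
max/avg pool, fully connected, linear/softmax readout) that expand to layer
primitives; a block's name denotes its output *after* the nonlinearity,
which is where activations are extracted (flattened to n×K, inference
mode) and where auxiliary errors attach.  The stack — im2col convolution,
pooling with optional ceil-mode, batch normalisation, inverted dropout,
fan-in-scaled uniform initialisation, SGD with momentum — is NumPy
throughout, and every backward pass is validated against finite
differences in the test suite.  Initialisation is seed-deterministic;
training runs are bit-reproducible on a single worker.

Two full-scale presets mirror published architectures: a 28×28
two-conv/max-pool CNN with a dropout-regularised 200-unit FC layer and
10-way readout, and a 32×32 batch-normalised Network-in-Network with three
5×5-conv + two 1×1-MLPConv stages and a global-average-pool softmax
readout.  The CNN preset infers the FC layer's input width from the shape
chain (valid convolution, floor pooling gives 64·2·2 = 256 features); its
output widths (200 → 10) are as published.  These presets are provided as
configurations; reproducing published error rates on external datasets is
out of scope.

## Synthetic data and the reference experiments

The generator emulates a small image-classification benchmark: each class
is a fixed smoothed-Gaussian prototype image (pixel sd = `prototype_scale`),
samples add i.i.d. pixel noise (`noise_sd`), and optional augmentation
applies integer-pixel translations and smoothed random displacement fields
(amplitude-bounded, in pixels) — seedable stand-ins for the pseudo-random
deformations and translations of extended handwritten-digit corpora.
Generation is a pure function of the spec; teacher and student datasets
share class prototypes through `prototype_seed` while drawing independent
samples.

What the generator does *not* model: object structure, within-class pose
or style variation beyond the smooth deformations, label noise, class
imbalance, or any nontrivial image statistics.  Passing tests therefore
demonstrate that the machinery behaves as specified and that
representational transfer occurs under controlled conditions — not that
the method attains any particular accuracy on natural images.

The reference study conditions (module `rdlearn.experiments`): 5 classes
of 12×12 single-channel images, prototype scale 1.0, noise sd 3.0 — a
noise-dominated task; the student sees 6 training images per class (30
total, 60/class held out for testing) while the teacher is trained on 150
augmented images per class.  Both use the small conv(8@3×3) → max-pool(2) →
fc(32) → softmax architecture, SGD with lr 0.02, momentum 0.9, batch 25,
30 epochs.  RDM matching attaches after the pooling layer and the fully
connected layer.

Two non-default choices matter here and were made as design decisions:

* **Correlation distance at the attachments.**  Matching raw
  squared-Euclidean distances forces a freshly initialised student (tiny
  pairwise distances) to inflate its activation magnitudes toward those of
  a trained teacher; the gradient grows with the activation norm and the
  magnitude-matching dynamic is violently unstable under SGD with momentum
  at desk scale.  Correlation distance is scale-free — the student matches
  the teacher's representational *geometry*, not its activation scale —
  and trains stably at α₀ = 1.
* **Pair fraction 0.25.**  The batch size here (25) is a quarter of the
  batch sizes used at full scale, so a denser fraction keeps the absolute
  number of sampled pairs per update (150 of 600) in the regime the
  subsampled estimator is designed for; 5 % of a 25-image batch would be
  30 pairs, a very sparse gradient.

The two canned experiments are: (1) *convergence* — a student trained with
the RDM-matching objective alone (output-loss weight 0) must reduce the
correlation distance between its layer RDMs and the teacher's on a 50-image
held-out probe, layer by layer; (2) *transfer benefit* — across ≥ 5
independent student draws and initialisations (10 in the acceptance
script), the mean test error of RDM-matched students must not exceed the
baseline's.  Both finish in seconds; the full acceptance script runs in
well under a minute on one CPU.

## Analysis conventions

* RDMs are compared on their vectorised upper triangles (row-major,
  i < j — the fixed ordering used everywhere, including persistence).
* *Correlation distance* between RDMs is 1 − Pearson r of the triangles;
  *normalised Euclidean* is the Euclidean distance between the two
  unit-norm-scaled triangle vectors (one of several reasonable readings of
  that phrase; it is the implemented and documented one).
* Bootstrap aggregation draws probe subsets *without* replacement within a
  draw by default (a "sample of k images" is read as a subset); sampling
  with replacement is selectable.  The element-wise mean over draws is
  returned; with one draw covering the whole probe set it reduces exactly
  to the direct comparison.
* MDS is classical/metric (Torgerson): double-centre the squared distance
  matrix, eigendecompose, keep the top axes with positive eigenvalues
  (tolerance 1e−9 relative to the leading eigenvalue), deterministic sign
  convention (first nonzero loading of each axis positive), zero-padding
  with a warning when the matrix supports fewer dimensions.
* The exact McNemar test doubles the smaller binomial tail,
  p = min(1, 2·P(X ≤ min(n01, n10))), X ~ Binomial(n01+n10, ½), with p = 1
  when there are no discordant items.  No multiple-testing correction is
  applied.
* RDM CSVs carry input identifiers in the first row/column and the full
  symmetric matrix at 17 significant digits; reading uses round-trip float
  parsing, so persistence is lossless for doubles.

## Known limitations

* Matching absolute distance magnitudes (the squared-Euclidean
  dissimilarities) between models of very different activation scales is
  intrinsically stiff; the correlation-distance attachment is the robust
  default for cross-model transfer, and divergence (non-finite loss) is
  detected and aborted with a diagnostic rather than silently logged.
* The subsampled gradient's per-image normalisation is implemented exactly
  as specified; its small-sample bias relative to the full gradient is not
  corrected.
* Single-worker, CPU-only; no distributed training.  Bit-reproducibility
  claims hold on one worker with a fixed BLAS.
* The hint stage's duration and learning rate are task-dependent and
  exposed as configuration; there is no automatic schedule.
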