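# Methods

This note documents the models and procedures histogat implements, the
choices made where the design was genuinely open, and what the synthetic
experiments do and do not demonstrate.

## Pipeline model

An image is represented by the spatial token grid of a (frozen) backbone:
an `n_patches × dim` matrix, one embedding per non-overlapping patch of
the standardised 224 × 224 image, flattened row-major (top-left first).
Class or global tokens emitted by transformer backbones are excluded by
contract; only spatial cells are used. Grid arithmetic is
`rows = cols = floor(image_size / patch_size)` — 14 × 14 = 196 patches
for patch-16 backbones, 16 × 16 = 256 for patch-14, 7 × 7 = 49 for
CNN-style feature maps.

Per image, k-means (k-means++ initialisation, 10 restarts, 300 max
iterations, fixed seed) clusters the patch embeddings into at most
k = 100 groups; the effective k is capped at the patch count, and empty
clusters are dropped. Centroids are ordered by the index of the first
patch assigned to them so the node order is a pure function of input and
seed. Cosine similarity is computed over all centroid pairs; distinct
pairs whose similarity **strictly exceeds** the threshold (default 0.6)
are connected by edges in both directions. Edges are unweighted and
similarity values are not retained. A zero-norm centroid is defined to
have similarity 0 against everything, so it can never gain an edge; it
simply remains isolated. Consequences tested as invariants: edge
symmetry, no self-loops in the stored list, monotone shrinkage of the
edge set as the threshold rises, and scale invariance of the edge set
under positive rescaling of the features.

The classifier is a two-layer graph-attention network. Each layer
follows the standard additive-attention formulation: per head, node
features are projected linearly; the score of edge *j → i* is
`LeakyReLU(a_src·z_j + a_dst·z_i)` with negative slope 0.2; scores are
softmax-normalised over each node's in-neighbourhood; messages are
aggregated with those weights; head outputs are concatenated. The head
split is pinned by the design: 4 × 8 = 32 features per node after layer
1 and 4 × 4 = 16 after layer 2 (enforced at configuration time), each
followed by ReLU, then global mean pooling and a linear map to the
classes. Self-loops are inserted inside the attention layers (default
on): the 0.6 threshold regularly isolates nodes, and attention over an
empty neighbourhood would otherwise be undefined. No dropout, weight
decay or early stopping is used; the final-epoch parameters are kept.

Training: Adam with learning rate 1 × 10⁻⁴, categorical cross-entropy,
mini-batches of 32 graphs, 300 epochs by default, seeded initialisation
and shuffling. Variable-size graphs are batched as disjoint unions with
per-graph mean pooling; batched and one-by-one inference agree to float
precision (asserted at 1e-5 in tests). The whole network — forward and
reverse passes — is plain NumPy/SciPy; the hand-written gradients are
verified against central finite differences in the test suite, and the
logits are checked to be invariant under node permutations.

The baseline is a backbone-plus-linear-head fine-tuning harness under
the same optimisation schedule, with training-time augmentation:
independent horizontal/vertical flips (probability 0.5 each) and one
rotation drawn from {0°, 90°, 180°, 270°}. Right-angle rotations are
exact index remaps; arbitrary angles are available via configuration but
interpolate. Augmentation is never applied at prediction time. All
backbone layers are trainable when the backbone supports it; frozen
feature backbones train only the head, which makes fine-tuning exactly
multinomial logistic regression on the embeddings (tested against an
independent gradient-descent fit).

## Metrics and uncertainty

All metrics derive from the full confusion matrix: per-class precision
`TP/(TP+FP)`, recall `TP/(TP+FN)`, `F1 = 2PR/(P+R)`, macro F1 (the
unweighted class mean), balanced accuracy (mean per-class recall —
identically macro recall), macro specificity `TN/(TN+FP)`, one-vs-rest
macro AUC via the midrank Mann-Whitney statistic (ties averaged, so
label-independent scores give exactly 0.5), and the multiclass Matthews
correlation coefficient (Gorodkin form; zero denominator ⇒ 0). Any 0/0
in precision/recall/F1 is defined as 0. For binary tasks the reported
"F1" is macro F1; a positive-class option exists in the evaluation
module. These implementations are cross-checked against scikit-learn on
random label vectors — scikit-learn is the oracle, never the
implementation path.

Cross-validation is stratified 5-fold by default: each class is
shuffled with the seeded generator and dealt round-robin across folds
through one global rotation, so fold sizes differ by at most one and
class proportions are preserved up to rounding even for classes smaller
than the fold count. Stratification is a choice, not a given — heavily
imbalanced datasets risk folds without a class otherwise — and can be
switched off. Per-fold metrics are summarised as mean, **sample**
standard deviation (divisor n − 1; this convention reproduces the
published-style intervals exactly) and the two-sided Student-t interval
`mean ± t_{(1+γ)/2, n−1} · sd/√n` at γ = 0.95.

## Fusion

Two probability matrices over the same samples are fused as the convex
combination `P_fusion = w·P_A + (1 − w)·P_B`. The weight is selected by
maximising macro F1 (configurable) over the grid {0, 0.1, …, 1.0}; ties
break to the smallest w. Because the grid contains both endpoints, the
selected combination never scores below either single model **on the
selection split**; on a held-out fold the guarantee is only empirical.
Selection data come from an inner 90/10 split of each training fold
(the last tenth of the stratified inner deal), never from the outer
test fold — selecting w on test data would leak. A per-fold weight is
selected; a global weight can be obtained by fusing pooled predictions.
Alternatives implemented: simple averaging (w = 0.5 exactly) and
stacking meta-learners on the concatenated probability rows —
multinomial logistic regression and a one-hidden-layer (16-unit, ReLU)
network trained with Adam, both via scikit-learn.

## Synthetic data: what it emulates, and what it does not

The generator stands in for real histology benchmarks at two levels.
**Feature mode** emulates a frozen backbone's token grid directly: patch
rows are drawn from a Gaussian mixture with `n_components` (default 5)
shared component means; class *c* shifts every mean by
`class_separation` along a class-specific orthonormal direction, and
i.i.d. Gaussian noise (sd 1.0 by default) is added. At separation 0 the
class distributions are *identical* by construction — the shared means
make this exact, which is what lets a null experiment measure chance
behaviour. **Image mode** produces RGB images as an 8 × 8 block-colour
pattern (shared base, class-specific shift scaled 0.06·separation)
upsampled to the image size with pixel noise (0.05·noise_sd), clipped
to [0, 1]; any extractor sensitive to local colour statistics separates
the classes. Labels are dealt `i mod n_classes`, so they are balanced up
to rounding and every class occurs.

What the generator does **not** emulate: H&E stain statistics, nuclei
morphology, spatial correlation between patches, magnification effects,
label noise, or class imbalance. Passing the synthetic recovery tests
therefore shows the pipeline is implemented correctly and can extract a
planted class signal end to end; it says nothing about accuracy on real
histopathology data, which additionally depends on the pretrained
backbone plugged into the adapter contract.

## Problem sizes and numerical choices

The reference synthetic study (`synthetic_study_config`) uses 200
images, 2 classes, a 14 × 14 patch grid (the patch-16 ViT geometry) with
64-dimensional embeddings, mixture noise sd 1.0 and separation 5 —
dimensions chosen so a full 5-fold run completes in minutes of
single-core NumPy while exercising every stage at realistic graph sizes
(100 nodes, hundreds of edges per graph). The graph model trains for
120 epochs in this study (its cross-entropy plateaus near zero well
before that at the separations studied); the mean-pool baseline keeps
the full 300-epoch schedule. The determinism check runs the same
pipeline at 100 images with shortened schedules; determinism is
independent of problem size.

Other numerical choices: float64 throughout; cosine similarities are
clipped to [−1, 1] so thresholds at the boundary behave exactly;
per-destination softmax in the attention layers subtracts the segment
maximum for stability; probability rows are validated to sum to 1
within 1e-6; the grid-search tie comparison uses a 1e-12 margin so
float noise cannot steal a tie from a smaller weight. Stage seeds are
derived from the single global seed by XOR with a CRC-32 of the stage
name (kept below 2³¹), so one integer reproduces a run bit-for-bit;
reruns of an unchanged configuration write byte-identical summary JSON.

## Known limitations

- No pretrained backbone weights are shipped; results on PanNuke-,
  BACH- or BreakHis-style data require plugging real extractors into the
  adapter contract.
- One published grid row lists a 7 × 7 patch grid alongside a 196-row
  clustering input; these are mutually inconsistent, and the
  implementation follows the 196-row reading (14 × 14 grid).
- k-means is a local optimiser: scale invariance of the *edge rule* is
  exact, but re-clustering rescaled data can land in a different local
  optimum on tiny inputs; tests therefore check the invariance at the
  similarity/threshold stage and centroid recovery on well-separated
  data against a brute-force partition oracle.
- The meta-learner fusion variants inherit scikit-learn's optimisers;
  with the conservative learning rate used for comparability the
  two-layer network may stop at its iteration cap rather than full
  convergence.
- Attention-weight visualisation and runtime/GPU benchmarking are out
  of scope.
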