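# histogat

Patch-graph classification of histology images: each image is condensed
into a small graph of clustered patch-embedding centroids, classified by
a lightweight graph-attention network, evaluated under stratified 5-fold
cross-validation, and optionally fused with a fine-tuned image baseline.

## Who this is for

Computational-pathology and biomedical-imaging researchers who want a
self-contained, CPU-friendly implementation of the patch-graph approach:
frozen backbone embeddings in, cross-validated class predictions out.
Real pathology foundation models (CONCH, UNI, UNI2) and ImageNet
backbones plug in through a small adapter contract; none of their weights
are required — a deterministic toy extractor and a synthetic data
generator make every stage runnable and testable offline.

## The method

For one image:

1. **Patch features.** The image is resized to 224 × 224, channel-
   standardised with ImageNet statistics, and embedded as an
   `n_patches × dim` token grid (e.g. 196 × 768 for a patch-16 ViT,
   256 × 1536 for a patch-14 backbone, 7 × 7 cells for CNN feature maps).
2. **Graph construction.** k-means (k = 100 by default, capped at the
   patch count, fixed seed) clusters the patch embeddings; the centroids
   become graph nodes. For every pair of distinct centroids *i*, *j* with
   cosine similarity `⟨cᵢ,cⱼ⟩ / (‖cᵢ‖‖cⱼ‖) > 0.6`, bidirectional edges
   are added; edges are unweighted.
3. **Classification.** A two-layer graph-attention network: 4 heads × 8
   features (32 per node) → ReLU → 4 heads × 4 features (16 per node) →
   ReLU → global mean pooling → linear map to the classes. Training uses
   Adam (lr 1 × 10⁻⁴), categorical cross-entropy, batch size 32,
   seeded shuffling. The attention layers are implemented in NumPy with
   hand-written reverse-mode gradients (verified against finite
   differences in the test suite).
4. **Evaluation.** Macro F1 `(1/C) Σᵢ F1(i)` and balanced accuracy
   `(1/C) Σᵢ TPᵢ/(TPᵢ+FNᵢ)`, plus precision, recall, specificity,
   one-vs-rest macro AUC and multiclass MCC; per-fold values are
   summarised as mean ± sd with the Student-t 95 % interval
   `mean ± t₀.₉₇₅,₄ · sd/√5`.
5. **Fusion.** Two models' probability rows are combined as
   `P_fusion = w·P_A + (1 − w)·P_B`, with w chosen on an inner selection
   split by grid search over {0, 0.1, …, 1} (plus simple averaging and
   logistic / two-layer-NN stacking variants).

## Worked example

```python
from histogat.pipeline import run_cv_experiment, synthetic_study_config
from histogat.evaluation import CVSummary, format_mean_sd

cfg = synthetic_study_config(seed=1)          # 200 images, 2 classes, sep 5
result = run_cv_experiment(cfg)
for model in ("gnn", "baseline", "fused"):
    s = CVSummary(result["per_fold"][model]["macro_f1"])
    print(model, format_mean_sd(s))
print("chosen fusion weights:", result["chosen_weights"])
```

prints

```
gnn 100.00 (±0.00)
baseline 100.00 (±0.00)
fused 100.00 (±0.00)
chosen fusion weights: [0.0, 0.0, 0.0, 0.0, 0.0]
```

At class separation 5 the synthetic task is fully separable, so both the
graph model and the mean-pool baseline reach macro F1 = 1.0 on every
fold and fusion cannot improve further (ties in the weight grid resolve
to the smallest w, hence 0.0). Lower the separation (e.g.
`synthetic_study_config(seed=1, class_separation=1.0)`) to see the
models disagree and the fused row sit at or above the weaker component.

The same experiment runs from the shell:

```bash
histogat run --config experiment.yaml --out results/run1
histogat sweep --config experiment.yaml --parameter similarity_threshold \
    --values 0.2,0.4,0.6,0.8 --out results/sweep
```

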