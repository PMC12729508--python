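"""Fine-tuning harness for a pluggable image backbone with a linear head.

The second model of the fusion pair: a backbone embeds each standardised
224-square image into a fixed-width vector, the original classifier head
is replaced by a single linear layer sized to the number of classes, and
the whole stack is trained with Adam / cross-entropy under the same
schedule as the graph model.  Random horizontal/vertical flips and
rotations are applied during training only.

Real pretrained backbones (VGG19, DenseNet201, EfficientNetV2S, ViT-Base)
are adapter extension points and are not shipped.  Built in instead:

* :class:`TinyConvBackbone` -- a small trainable convolutional stack
  (patch embedding, 1x1 mixing layer, global average pooling) with seeded
  random initialisation, for self-contained image-mode runs;
* :class:`MeanPoolFeatureBackbone` -- mean-pools a patch-feature matrix,
  for feature-mode runs where no pixel data exists;
* :class:`IdentityBackbone` -- passes precomputed vectors through, under
  which fine-tuning reduces to multinomial logistic regression.
"""

from __future__ import annotations

from dataclasses import dataclass
from typing import Optional, Sequence

import numpy as np
from scipy import ndimage

from ._nn import Adam, cross_entropy_grad, glorot, softmax
from .feature_extraction import ImageRecord, PatchFeatureMatrix, _patchify
from .gat_classifier import ProbabilityMatrix, TrainConfig

__all__ = [
    "AugmentConfig",
    "augment",
    "TinyConvBackbone",
    "MeanPoolFeatureBackbone",
    "IdentityBackbone",
    "BaselineModel",
    "finetune",
    "predict_proba",
]


@dataclass(frozen=True)
class AugmentConfig:
    """Training-time augmentation: independent flips plus one rotation
    drawn uniformly from ``rotation_set``.  Right-angle rotations are
    exact (no interpolation); other angles use spline interpolation with
    unchanged output size."""

    horizontal_flip: float = 0.5
    vertical_flip: float = 0.5
    rotation_set: tuple[float, ...] = (0.0, 90.0, 180.0, 270.0)
    seed: int = 0

    def __post_init__(self) -> None:
        for p in (self.horizontal_flip, self.vertical_flip):
            if not 0.0 <= p <= 1.0:
                raise ValueError("flip probabilities must lie in [0, 1]")
        if not self.rotation_set:
            raise ValueError("rotation_set must be nonempty")

    @property
    def is_identity(self) -> bool:
        return (
            self.horizontal_flip == 0.0
            and self.vertical_flip == 0.0
            and all(a % 360 == 0 for a in self.rotation_set)
        )


def augment(image: ImageRecord, cfg: AugmentConfig, rng: np.random.Generator) -> ImageRecord:
    """One random draw of the augmentation pipeline; the label rides along."""
    px = image.pixels
    if rng.random() < cfg.horizontal_flip:
        px = px[:, ::-1, :]
    if rng.random() < cfg.vertical_flip:
        px = px[::-1, :, :]
    angle = float(cfg.rotation_set[rng.integers(len(cfg.rotation_set))])
    if angle % 90 == 0:
        px = np.rot90(px, k=int(angle // 90) % 4, axes=(0, 1))
    elif angle % 360 != 0:
        px = ndimage.rotate(px, angle, axes=(1, 0), reshape=False, mode="nearest")
    return ImageRecord(pixels=np.ascontiguousarray(px), image_id=image.image_id,
                       label=image.label)


# ---------------------------------------------------------------------------
# backbones
# ---------------------------------------------------------------------------

class TinyConvBackbone:
    """Small trainable convolutional stack for tests and synthetic runs.

    Patch-embedding convolution (kernel = stride = ``patch_size``), ReLU,
    a 1x1 mixing convolution, ReLU, then global average pooling over the
    spatial grid.  Both convolutions are stride-aligned matrix products,
    so gradients are exact and cheap.
    """

    trainable = True

    def __init__(self, patch_size: int = 16, hidden: int = 32, feature_dim: int = 32,
                 seed: int = 0) -> None:
        self.name = f"tinyconv-{patch_size}-{feature_dim}"
        self.patch_size = patch_size
        self.hidden = hidden
        self.feature_dim = feature_dim
        self.seed = seed

    def init_params(self) -> dict[str, np.ndarray]:
        rng = np.random.default_rng(self.seed)
        pd = self.patch_size * self.patch_size * 3
        return {
            "bb_W0": glorot(rng, (pd, self.hidden)),
            "bb_b0": np.zeros(self.hidden),
            "bb_W1": glorot(rng, (self.hidden, self.feature_dim)),
            "bb_b1": np.zeros(self.feature_dim),
        }

    def _flatten(self, images: np.ndarray) -> np.ndarray:
        b, s = images.shape[0], images.shape[1]
        g = s // self.patch_size
        flat = np.stack(
            [_patchify(im, self.patch_size).reshape(g * g, -1) for im in images]
        )
        return flat  # (B, G, patch_size^2 * 3)

    def forward(self, params, images: np.ndarray):
        p = self._flatten(images)
        pre1 = p @ params["bb_W0"] + params["bb_b0"]
        h1 = np.maximum(pre1, 0.0)
        pre2 = h1 @ params["bb_W1"] + params["bb_b1"]
        h2 = np.maximum(pre2, 0.0)
        feats = h2.mean(axis=1)
        return feats, (p, pre1, h1, pre2, h2)

    def backward(self, params, cache, dfeats):
        p, pre1, h1, pre2, h2 = cache
        g = p.shape[1]
        dh2 = (dfeats[:, None, :] / g) * (pre2 > 0)
        grads = {
            "bb_W1": np.einsum("bgh,bgo->ho", h1, dh2),
            "bb_b1": dh2.sum(axis=(0, 1)),
        }
        dh1 = (dh2 @ params["bb_W1"].T) * (pre1 > 0)
        grads["bb_W0"] = np.einsum("bgp,bgh->ph", p, dh1)
        grads["bb_b0"] = dh1.sum(axis=(0, 1))
        return grads

    def embed(self, params, images: np.ndarray) -> np.ndarray:
        feats, _ = self.forward(params, images)
        return feats


class MeanPoolFeatureBackbone:
    """Frozen backbone over precomputed patch-feature matrices: the image
    embedding is the mean of its patch rows."""

    trainable = False

    def __init__(self, feature_dim: int) -> None:
        self.name = f"meanpool-{feature_dim}"
        self.feature_dim = feature_dim

    def embed_inputs(self, inputs: Sequence[PatchFeatureMatrix]) -> np.ndarray:
        feats = np.stack([m.features.mean(axis=0) for m in inputs])
        if feats.shape[1] != self.feature_dim:
            raise ValueError("feature dim mismatch")
        return feats


class IdentityBackbone:
    """Passes precomputed embedding vectors straight through."""

    trainable = False

    def __init__(self, feature_dim: int) -> None:
        self.name = f"identity-{feature_dim}"
        self.feature_dim = feature_dim

    def embed_inputs(self, inputs: Sequence[np.ndarray]) -> np.ndarray:
        feats = np.asarray(np.stack([np.asarray(v, dtype=np.float64) for v in inputs]))
        if feats.shape[1] != self.feature_dim:
            raise ValueError("feature dim mismatch")
        return feats


# ---------------------------------------------------------------------------
# training
# ---------------------------------------------------------------------------

def _sample_id(item) -> str:
    return getattr(item, "image_id", None) or ""


@dataclass
class BaselineModel:
    backbone: object
    params: dict[str, np.ndarray]
    n_classes: int
    history: list[float]

    def embed(self, inputs) -> np.ndarray:
        bb = self.backbone
        if bb.trainable:
            images = np.stack([r.pixels for r in inputs])
            return bb.embed(self.params, images)
        return bb.embed_inputs(inputs)

    def predict_proba(self, inputs) -> ProbabilityMatrix:
        feats = self.embed(inputs)
        logits = feats @ self.params["head_W"] + self.params["head_b"]
        ids = [_sample_id(r) or str(i) for i, r in enumerate(inputs)]
        return ProbabilityMatrix(probs=softmax(logits, axis=1), sample_ids=ids)


def finetune(
    records: Sequence[tuple[object, int]],
    backbone,
    n_classes: int,
    train_config: TrainConfig,
    augment_config: Optional[AugmentConfig] = None,
) -> BaselineModel:
    """Train the linear head (and the backbone, when trainable).

    ``records`` pairs inputs with integer labels; inputs are standardised
    :class:`ImageRecord` objects for image backbones, or patch-feature
    matrices / vectors for the frozen feature backbones.  Augmentation is
    applied per epoch during training only, and requires pixel inputs.
    """
    inputs = [r for r, _ in records]
    y = np.asarray([int(l) for _, l in records])
    if y.size == 0:
        raise ValueError("empty training set")
    if y.min() < 0 or y.max() >= n_classes:
        raise ValueError("label out of range for n_classes")
    missing = sorted(set(range(n_classes)) - set(y.tolist()))
    if missing:
        raise ValueError(f"training set lacks examples of class(es) {missing}")

    use_aug = augment_config is not None and not augment_config.is_identity
    if use_aug and not isinstance(inputs[0], ImageRecord):
        raise ValueError("augmentation requires image inputs")

    rng = np.random.default_rng(train_config.seed)
    aug_rng = (
        np.random.default_rng([train_config.seed, augment_config.seed])
        if use_aug
        else None
    )
    params: dict[str, np.ndarray] = {}
    if backbone.trainable:
        params.update(backbone.init_params())
    params["head_W"] = glorot(rng, (backbone.feature_dim, n_classes))
    params["head_b"] = np.zeros(n_classes)
    opt = Adam(params, lr=train_config.learning_rate)

    static_feats = None
    if not backbone.trainable and not use_aug:
        static_feats = backbone.embed_inputs(inputs)

    n = len(inputs)
    bs = train_config.batch_size
    history: list[float] = []
    for _ in range(train_config.epochs):
        perm = rng.permutation(n)
        epoch_loss = 0.0
        for start in range(0, n, bs):
            idx = perm[start : start + bs]
            grads: dict[str, np.ndarray] = {}
            if backbone.trainable:
                batch_imgs = [inputs[i] for i in idx]
                if use_aug:
                    batch_imgs = [augment(im, augment_config, aug_rng) for im in batch_imgs]
                arr = np.stack([im.pixels for im in batch_imgs])
                feats, cache = backbone.forward(params, arr)
            elif static_feats is not None:
                feats, cache = static_feats[idx], None
            else:  # frozen backbone but augmented pixels
                batch_imgs = [augment(inputs[i], augment_config, aug_rng) for i in idx]
                feats, cache = backbone.embed_inputs(batch_imgs), None
            logits = feats @ params["head_W"] + params["head_b"]
            loss, dlogits = cross_entropy_grad(logits, y[idx])
            grads["head_W"] = feats.T @ dlogits
            grads["head_b"] = dlogits.sum(axis=0)
            if backbone.trainable:
                dfeats = dlogits @ params["head_W"].T
                grads.update(backbone.backward(params, cache, dfeats))
            opt.step(grads)
            epoch_loss += loss * len(idx)
        history.append(epoch_loss / n)
    return BaselineModel(backbone=backbone, params=params, n_classes=n_classes,
                         history=history)


def predict_proba(model: BaselineModel, inputs) -> ProbabilityMatrix:
    """Softmax class probabilities in input order (no augmentation)."""
    return model.predict_proba(inputs)
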