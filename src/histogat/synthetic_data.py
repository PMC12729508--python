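"""Synthetic labelled datasets with controllable class separation.

Real histology benchmarks and the gated foundation backbones that embed
them cannot be bundled, so this module generates stand-ins at two levels:

* **feature mode** -- per-image patch-embedding matrices drawn from a
  Gaussian mixture whose component means are shared across classes and
  shifted by a class-specific offset of controllable size.  These emulate
  the token-grid embeddings a frozen backbone would produce (e.g. a
  196 x 768 grid) without any pretrained weights.
* **image mode** -- RGB images made of class-dependent block textures plus
  pixel noise, classifiable by any extractor sensitive to local colour
  statistics.

``class_separation`` is the single knob that moves the task from
impossible (0: the per-class distributions are identical) to easy; the
generator makes no attempt to mimic H&E stain statistics or nuclei
morphology.  Everything is deterministic under the spec's seed.
"""

from __future__ import annotations

import os
from dataclasses import dataclass
from pathlib import Path
from typing import Sequence

import numpy as np
from PIL import Image

from .feature_extraction import (
    ImageRecord,
    PatchFeatureMatrix,
    save_feature_dataset,
)

__all__ = [
    "SyntheticSpec",
    "generate_feature_dataset",
    "generate_image_dataset",
    "write_image_dataset",
    "write_feature_dataset",
]


@dataclass(frozen=True)
class SyntheticSpec:
    """Parameters of one synthetic dataset.

    ``n_components`` latent texture clusters are shared by all classes;
    class ``c`` shifts every component mean by ``class_separation`` along
    a unit direction unique to ``c`` (directions are mutually orthogonal).
    Labels are balanced up to rounding: image ``i`` gets class
    ``i % n_classes``.
    """

    n_images: int
    n_classes: int = 2
    patch_grid: tuple[int, int] = (14, 14)
    feature_dim: int = 64
    n_components: int = 5
    class_separation: float = 1.0
    noise_sd: float = 1.0
    image_size: int = 64
    seed: int = 0

    def __post_init__(self) -> None:
        if self.n_classes not in (2, 4):
            raise ValueError("n_classes must be 2 or 4")
        if self.n_images < self.n_classes:
            raise ValueError("n_images must be at least n_classes")
        if self.patch_grid[0] < 1 or self.patch_grid[1] < 1:
            raise ValueError("patch_grid entries must be positive")
        if self.feature_dim < 1 or self.n_components < 1:
            raise ValueError("feature_dim and n_components must be positive")
        if self.feature_dim < self.n_classes:
            raise ValueError("feature_dim must be >= n_classes (orthogonal class directions)")
        if self.class_separation < 0 or self.noise_sd < 0:
            raise ValueError("class_separation and noise_sd must be nonnegative")

    @property
    def n_patches(self) -> int:
        return self.patch_grid[0] * self.patch_grid[1]

    def labels(self) -> np.ndarray:
        return np.arange(self.n_images) % self.n_classes


def _class_directions(rng: np.random.Generator, n_classes: int, dim: int) -> np.ndarray:
    """Orthonormal class directions, ``n_classes x dim``."""
    g = rng.standard_normal((dim, n_classes))
    q, _ = np.linalg.qr(g)
    return q[:, :n_classes].T


def generate_feature_dataset(
    spec: SyntheticSpec,
) -> list[tuple[PatchFeatureMatrix, int]]:
    """Draw per-image patch-feature matrices from the class-shifted mixture.

    Each patch row is ``base_mean[component] + separation * u_class +
    noise_sd * N(0, I)`` with the component picked uniformly.  At
    ``class_separation=0`` every class samples the identical distribution;
    at ``noise_sd=0, n_components=1`` all patches of a class equal the
    class mean exactly.
    """
    rng = np.random.default_rng(spec.seed)
    base_means = rng.standard_normal((spec.n_components, spec.feature_dim))
    directions = _class_directions(rng, spec.n_classes, spec.feature_dim)
    labels = spec.labels()
    out: list[tuple[PatchFeatureMatrix, int]] = []
    for i in range(spec.n_images):
        c = int(labels[i])
        comp = rng.integers(0, spec.n_components, size=spec.n_patches)
        x = base_means[comp] + spec.class_separation * directions[c]
        if spec.noise_sd > 0:
            x = x + spec.noise_sd * rng.standard_normal(x.shape)
        m = PatchFeatureMatrix(
            features=x,
            grid=spec.patch_grid,
            image_id=f"synth-{i:05d}",
            extractor_name="synthetic",
        )
        out.append((m, c))
    return out


# Block texture layout for image mode: a BLOCKS x BLOCKS colour pattern is
# upsampled to the image size.  The class shift and pixel noise are scaled
# so that pixels stay inside [0, 1] at the default knob values.
_BLOCKS = 8
_PATTERN_SCALE = 0.06
_PIXEL_NOISE_SCALE = 0.05


def generate_image_dataset(spec: SyntheticSpec) -> list[tuple[ImageRecord, int]]:
    """RGB images with class-dependent block textures plus pixel noise."""
    if spec.image_size < 32:
        raise ValueError("image_size must be at least 32")
    rng = np.random.default_rng(spec.seed)
    base = rng.uniform(0.25, 0.75, size=(_BLOCKS, _BLOCKS, 3))
    shifts = rng.standard_normal((spec.n_classes, _BLOCKS, _BLOCKS, 3))
    shifts /= np.sqrt((shifts**2).mean(axis=(1, 2, 3), keepdims=True))
    labels = spec.labels()
    reps = int(np.ceil(spec.image_size / _BLOCKS))
    out: list[tuple[ImageRecord, int]] = []
    for i in range(spec.n_images):
        c = int(labels[i])
        pattern = base + _PATTERN_SCALE * spec.class_separation * shifts[c]
        px = np.repeat(np.repeat(pattern, reps, axis=0), reps, axis=1)
        px = px[: spec.image_size, : spec.image_size]
        if spec.noise_sd > 0:
            px = px + _PIXEL_NOISE_SCALE * spec.noise_sd * rng.standard_normal(px.shape)
        px = np.clip(px, 0.0, 1.0)
        out.append((ImageRecord(pixels=px, image_id=f"synth-{i:05d}", label=c), c))
    return out


def write_image_dataset(
    records: Sequence[tuple[ImageRecord, int]],
    root: str | os.PathLike,
    class_names: Sequence[str] | None = None,
) -> Path:
    """Write a class-subfolder tree of PNG files (readable back with
    :func:`histogat.feature_extraction.load_image_folder`)."""
    root = Path(root)
    labels = sorted({int(y) for _, y in records})
    if class_names is None:
        class_names = [f"class_{y}" for y in labels]
    for name in class_names:
        (root / name).mkdir(parents=True, exist_ok=True)
    for rec, y in records:
        arr = np.clip(rec.pixels * 255.0, 0, 255).round().astype(np.uint8)
        fname = rec.image_id.replace("/", "_") + ".png"
        Image.fromarray(arr).save(root / class_names[int(y)] / fname)
    return root


def write_feature_dataset(
    dataset: Sequence[tuple[PatchFeatureMatrix, int]],
    outdir: str | os.PathLike,
) -> Path:
    """One array container per image plus a CSV manifest."""
    matrices = [m for m, _ in dataset]
    labels = [y for _, y in dataset]
    return save_feature_dataset(matrices, labels, outdir)
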