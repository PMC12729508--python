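"""Image standardisation and per-image patch-feature extraction.

A histology image enters the pipeline as an RGB array, is resized to
224 x 224 and channel-standardised with ImageNet statistics, and leaves as
an ``n_patches x dim`` matrix of local embeddings: one feature vector per
cell of the backbone's spatial token grid (14 x 14 for patch-16 vision
transformers, 16 x 16 for patch-14, 7 x 7 for CNN feature maps).

Pretrained backbones -- pathology foundation models (CONCH, UNI, UNI2) or
ImageNet CNNs/ViTs -- plug in through :class:`ExtractorAdapter`; their
weights are not shipped here.  A deterministic, weight-free toy extractor
(per-patch colour/gradient statistics followed by a seeded random
projection) is built in so the full pipeline runs self-contained.
"""

from __future__ import annotations

import os
from dataclasses import dataclass, field
from pathlib import Path
from typing import Callable, Optional, Sequence

import numpy as np
import pandas as pd
from PIL import Image

__all__ = [
    "IMAGENET_MEAN",
    "IMAGENET_STD",
    "ImageRecord",
    "PatchFeatureMatrix",
    "ExtractorAdapter",
    "preprocess",
    "patch_grid_shape",
    "extract_features",
    "toy_extractor",
    "load_image_folder",
    "save_feature_dataset",
    "load_feature_dataset",
]

# Community-standard ImageNet channel statistics (RGB order).
IMAGENET_MEAN = (0.485, 0.456, 0.406)
IMAGENET_STD = (0.229, 0.224, 0.225)

IMAGE_EXTENSIONS = (".png", ".jpg", ".jpeg", ".tif", ".tiff")


@dataclass
class ImageRecord:
    """One RGB image with an identifier and an optional class label.

    ``pixels`` is an ``H x W x 3`` float array.  Raw images live in
    ``[0, 1]``; after :func:`preprocess` the channels are standardised and
    may take any real value.
    """

    pixels: np.ndarray
    image_id: str
    label: Optional[int] = None

    def __post_init__(self) -> None:
        self.pixels = np.asarray(self.pixels, dtype=np.float64)
        if self.pixels.ndim != 3 or self.pixels.shape[2] != 3:
            raise ValueError(
                f"image {self.image_id!r}: expected H x W x 3 RGB pixels, "
                f"got shape {self.pixels.shape}"
            )
        if self.pixels.shape[0] < 1 or self.pixels.shape[1] < 1:
            raise ValueError(f"image {self.image_id!r}: empty image")


@dataclass
class PatchFeatureMatrix:
    """``n_patches x dim`` local-embedding matrix for one image.

    Rows are ordered row-major over the spatial grid (top-left patch
    first), and ``rows * cols`` must equal the number of rows.
    """

    features: np.ndarray
    grid: tuple[int, int]
    image_id: str
    extractor_name: str = ""

    def __post_init__(self) -> None:
        self.features = np.asarray(self.features, dtype=np.float64)
        rows, cols = self.grid
        if self.features.ndim != 2:
            raise ValueError("features must be a 2-D matrix")
        if self.features.shape[0] != rows * cols:
            raise ValueError(
                f"grid {self.grid} implies {rows * cols} patches but the "
                f"matrix has {self.features.shape[0]} rows"
            )
        if not np.all(np.isfinite(self.features)):
            raise ValueError(f"non-finite entries in features of {self.image_id!r}")

    @property
    def n_patches(self) -> int:
        return self.features.shape[0]

    @property
    def dim(self) -> int:
        return self.features.shape[1]


@dataclass
class ExtractorAdapter:
    """Pluggable patch-feature extractor contract.

    ``apply`` maps a standardised square image (``S x S x 3``) to the
    ``(S // patch_size)**2 x feature_dim`` matrix of its spatial token
    grid, row-major.  Class/global tokens of transformer backbones are
    excluded by contract; only spatial cells count.
    """

    name: str
    patch_size: int
    feature_dim: int
    apply: Callable[[np.ndarray], np.ndarray]


def preprocess(
    image: ImageRecord,
    target_size: int = 224,
    channel_means: Sequence[float] = IMAGENET_MEAN,
    channel_sds: Sequence[float] = IMAGENET_STD,
) -> ImageRecord:
    """Resize to ``target_size`` square and standardise each channel.

    Resizing is bilinear on float channels (no uint8 quantisation); the
    output pixel values are ``(x - mean) / sd`` per channel.
    """
    if target_size < 1:
        raise ValueError("target_size must be positive")
    px = image.pixels
    h, w = px.shape[:2]
    if (h, w) != (target_size, target_size):
        chans = []
        for c in range(3):
            im = Image.fromarray(px[:, :, c].astype(np.float32), mode="F")
            im = im.resize((target_size, target_size), Image.BILINEAR)
            chans.append(np.asarray(im, dtype=np.float64))
        px = np.stack(chans, axis=2)
    means = np.asarray(channel_means, dtype=np.float64).reshape(1, 1, 3)
    sds = np.asarray(channel_sds, dtype=np.float64).reshape(1, 1, 3)
    if np.any(sds <= 0):
        raise ValueError("channel sds must be positive")
    out = (px - means) / sds
    return ImageRecord(pixels=out, image_id=image.image_id, label=image.label)


def patch_grid_shape(image_size: int, patch_size: int) -> tuple[int, int]:
    """Grid of non-overlapping patches: ``floor(image_size / patch_size)``
    rows and columns (224/16 -> 14 x 14 = 196 patches; 224/14 -> 16 x 16 =
    256; 224/32 -> 7 x 7 = 49)."""
    if patch_size <= 0:
        raise ValueError("patch_size must be positive")
    if patch_size > image_size:
        raise ValueError("patch_size cannot exceed image_size")
    n = image_size // patch_size
    return (n, n)


def _patchify(pixels: np.ndarray, patch_size: int) -> np.ndarray:
    """Split a square image into its row-major grid of patches.

    Returns ``(rows * cols, patch_size, patch_size, 3)``.
    """
    size = pixels.shape[0]
    rows, cols = patch_grid_shape(size, patch_size)
    crop = pixels[: rows * patch_size, : cols * patch_size]
    p = crop.reshape(rows, patch_size, cols, patch_size, 3)
    return p.transpose(0, 2, 1, 3, 4).reshape(rows * cols, patch_size, patch_size, 3)


def _patch_statistics(patches: np.ndarray) -> np.ndarray:
    """Per-patch summary: channel means, channel sds, and mean absolute
    horizontal/vertical gradients per channel (12 numbers per patch)."""
    mean = patches.mean(axis=(1, 2))
    sd = patches.std(axis=(1, 2))
    gx = np.abs(np.diff(patches, axis=2)).mean(axis=(1, 2))
    gy = np.abs(np.diff(patches, axis=1)).mean(axis=(1, 2))
    return np.concatenate([mean, sd, gx, gy], axis=1)


def toy_extractor(
    feature_dim: int = 64, patch_size: int = 16, seed: int = 0
) -> ExtractorAdapter:
    """Deterministic weight-free extractor for self-contained runs.

    Each patch is summarised by 12 colour/gradient statistics computed
    purely from its own pixels, then mapped to ``feature_dim`` by a fixed
    seeded random projection.  Purity per patch (editing pixels outside a
    patch never changes its row) makes the extractor easy to reason about
    in tests.
    """
    if feature_dim < 1 or patch_size < 1:
        raise ValueError("feature_dim and patch_size must be positive")
    rng = np.random.default_rng(seed)
    projection = rng.standard_normal((12, feature_dim)) / np.sqrt(12.0)

    def apply(pixels: np.ndarray) -> np.ndarray:
        patches = _patchify(pixels, patch_size)
        return _patch_statistics(patches) @ projection

    return ExtractorAdapter(
        name=f"toy-{patch_size}-{feature_dim}",
        patch_size=patch_size,
        feature_dim=feature_dim,
        apply=apply,
    )


def extract_features(image: ImageRecord, extractor: ExtractorAdapter) -> PatchFeatureMatrix:
    """Run an extractor on a preprocessed square image.

    The adapter's output shape is checked against the grid implied by the
    image size and the extractor's patch size; a mismatch is a contract
    violation.
    """
    px = image.pixels
    if px.shape[0] != px.shape[1]:
        raise ValueError("extract_features expects a square preprocessed image")
    grid = patch_grid_shape(px.shape[0], extractor.patch_size)
    out = np.asarray(extractor.apply(px), dtype=np.float64)
    expected = (grid[0] * grid[1], extractor.feature_dim)
    if out.shape != expected:
        raise ValueError(
            f"extractor {extractor.name!r} violated its contract: expected "
            f"output shape {expected}, got {out.shape}"
        )
    return PatchFeatureMatrix(
        features=out, grid=grid, image_id=image.image_id, extractor_name=extractor.name
    )


# ---------------------------------------------------------------------------
# dataset IO: class-subfolder image trees and per-image feature containers
# ---------------------------------------------------------------------------

def load_image_folder(root: str | os.PathLike) -> tuple[list[ImageRecord], list[str]]:
    """Read a class-subfolder tree of PNG/JPEG/TIFF images.

    Class names are the subfolder names, sorted; labels are their indices.
    Returns the records (labels attached) and the class-name list.
    """
    root = Path(root)
    classes = sorted(d.name for d in root.iterdir() if d.is_dir())
    if not classes:
        raise FileNotFoundError(f"no class subfolders under {root}")
    records: list[ImageRecord] = []
    for label, cls in enumerate(classes):
        for path in sorted((root / cls).iterdir()):
            if path.suffix.lower() not in IMAGE_EXTENSIONS:
                continue
            with Image.open(path) as im:
                px = np.asarray(im.convert("RGB"), dtype=np.float64) / 255.0
            records.append(ImageRecord(pixels=px, image_id=f"{cls}/{path.stem}", label=label))
    return records, classes


def save_feature_dataset(
    matrices: Sequence[PatchFeatureMatrix],
    labels: Sequence[int],
    outdir: str | os.PathLike,
) -> Path:
    """Write one ``.npy`` per image plus a CSV manifest.

    Manifest columns: image_id, label, path, extractor, rows, cols.
    Returns the manifest path.
    """
    outdir = Path(outdir)
    outdir.mkdir(parents=True, exist_ok=True)
    rows = []
    for i, (m, y) in enumerate(zip(matrices, labels)):
        fname = f"features_{i:05d}.npy"
        np.save(outdir / fname, m.features)
        rows.append(
            {
                "image_id": m.image_id,
                "label": int(y),
                "path": fname,
                "extractor": m.extractor_name,
                "rows": m.grid[0],
                "cols": m.grid[1],
            }
        )
    manifest = outdir / "manifest.csv"
    pd.DataFrame(rows).to_csv(manifest, index=False)
    return manifest


def load_feature_dataset(
    indir: str | os.PathLike,
) -> tuple[list[PatchFeatureMatrix], list[int]]:
    indir = Path(indir)
    df = pd.read_csv(indir / "manifest.csv")
    matrices, labels = [], []
    for rec in df.itertuples():
        feats = np.load(indir / rec.path)
        matrices.append(
            PatchFeatureMatrix(
                features=feats,
                grid=(int(rec.rows), int(rec.cols)),
                image_id=str(rec.image_id),
                extractor_name=str(rec.extractor),
            )
        )
        labels.append(int(rec.label))
    return matrices, labels
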