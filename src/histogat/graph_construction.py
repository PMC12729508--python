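"""Per-image graph construction: k-means centroid nodes, cosine edges.

Each image's patch-feature matrix is condensed into a small graph: k-means
(default k = 100, capped at the patch count) clusters the patch embeddings,
the cluster centroids become the nodes, and a bidirectional edge joins two
distinct nodes whenever the cosine similarity of their centroids strictly
exceeds a threshold (default 0.6).  Nodes that clear the threshold with no
partner simply remain isolated; similarity values themselves are not kept.

Clustering is per image and seeded, so a dataset maps to a reproducible
list of graphs.
"""

from __future__ import annotations

import os
from dataclasses import dataclass
from pathlib import Path
from typing import Optional, Sequence

import numpy as np
import pandas as pd
from sklearn.cluster import KMeans

from .feature_extraction import PatchFeatureMatrix

__all__ = [
    "GraphBuildConfig",
    "ImageGraph",
    "cluster_patches",
    "similarity_matrix",
    "build_edges",
    "build_graph",
    "save_graph_dataset",
    "load_graph_dataset",
]


@dataclass(frozen=True)
class GraphBuildConfig:
    """Knobs of the graph-construction stage.

    ``n_clusters`` keeps the graph lightweight (100 by default); the
    effective cluster count is capped at the number of patches.
    ``similarity_threshold`` is the strict lower bound a cosine similarity
    must exceed for an edge; both are the ablation axes exposed to sweeps.
    """

    n_clusters: int = 100
    similarity_threshold: float = 0.6
    kmeans_seed: int = 0
    kmeans_max_iter: int = 300
    kmeans_restarts: int = 10

    def __post_init__(self) -> None:
        if self.n_clusters < 1:
            raise ValueError("n_clusters must be >= 1")
        if not -1.0 <= self.similarity_threshold <= 1.0:
            raise ValueError("similarity_threshold must lie in [-1, 1]")
        if self.kmeans_max_iter < 1 or self.kmeans_restarts < 1:
            raise ValueError("kmeans_max_iter and kmeans_restarts must be >= 1")


@dataclass
class ImageGraph:
    """One image as a graph: centroid node features plus a directed edge
    list.  Edges come in symmetric pairs and never include self-loops."""

    node_features: np.ndarray
    edges: np.ndarray  # (E, 2) int array of ordered (src, dst) pairs
    image_id: str
    label: Optional[int] = None

    def __post_init__(self) -> None:
        self.node_features = np.asarray(self.node_features, dtype=np.float64)
        self.edges = np.asarray(self.edges, dtype=np.int64).reshape(-1, 2)
        n = self.node_features.shape[0]
        if n < 1:
            raise ValueError("graph needs at least one node")
        if self.edges.size:
            if self.edges.min() < 0 or self.edges.max() >= n:
                raise ValueError("edge endpoint out of range")
            if np.any(self.edges[:, 0] == self.edges[:, 1]):
                raise ValueError("self-loops are not stored in the edge list")

    @property
    def n_nodes(self) -> int:
        return self.node_features.shape[0]

    @property
    def n_edges(self) -> int:
        return self.edges.shape[0]


def cluster_patches(
    features: PatchFeatureMatrix, config: GraphBuildConfig
) -> np.ndarray:
    """k-means centroids of one image's patch embeddings.

    The effective k is ``min(n_clusters, n_patches)``; clusters that end
    up empty are dropped, and centroids are returned sorted by the index
    of the first patch assigned to them, which makes the node order a
    deterministic function of the input and the seed.
    """
    x = features.features
    if not np.all(np.isfinite(x)):
        raise ValueError("non-finite patch features")
    k = min(config.n_clusters, features.n_patches)
    if k == features.n_patches:
        # one patch per cluster: clustering is the identity
        return x.copy()
    km = KMeans(
        n_clusters=k,
        init="k-means++",
        n_init=config.kmeans_restarts,
        max_iter=config.kmeans_max_iter,
        random_state=config.kmeans_seed % (2**32),
    )
    assign = km.fit_predict(x)
    present, first_idx = np.unique(assign, return_index=True)
    order = present[np.argsort(first_idx)]
    return km.cluster_centers_[order].astype(np.float64)


def similarity_matrix(centroids: np.ndarray) -> np.ndarray:
    """Pairwise cosine similarities of the centroids.

    A zero-norm centroid has similarity 0 against everything (including
    itself), so it can never gain an edge.
    """
    c = np.asarray(centroids, dtype=np.float64)
    if c.ndim != 2 or c.shape[0] < 1:
        raise ValueError("centroids must be a nonempty 2-D matrix")
    norms = np.linalg.norm(c, axis=1)
    safe = np.where(norms > 0, norms, 1.0)
    unit = c / safe[:, None]
    s = unit @ unit.T
    s[norms == 0, :] = 0.0
    s[:, norms == 0] = 0.0
    # clip tiny float excursions so thresholds at +/-1 behave exactly
    return np.clip(s, -1.0, 1.0)


def build_edges(s: np.ndarray, threshold: float) -> np.ndarray:
    """Ordered (i, j) pairs, i != j, with ``s[i, j] > threshold`` (strict).

    Symmetry of ``s`` makes the list symmetric: whenever (i, j) is
    included so is (j, i).
    """
    s = np.asarray(s)
    mask = s > threshold
    np.fill_diagonal(mask, False)
    src, dst = np.nonzero(mask)
    return np.stack([src, dst], axis=1).astype(np.int64)


def build_graph(features: PatchFeatureMatrix, config: GraphBuildConfig,
                label: Optional[int] = None) -> ImageGraph:
    """Full construction for one image: cluster, similarity, threshold."""
    centroids = cluster_patches(features, config)
    s = similarity_matrix(centroids)
    edges = build_edges(s, config.similarity_threshold)
    return ImageGraph(
        node_features=centroids, edges=edges, image_id=features.image_id, label=label
    )


# ---------------------------------------------------------------------------
# persistence: node features as .npy, edges as two-column CSV, plus manifest
# ---------------------------------------------------------------------------

def save_graph_dataset(graphs: Sequence[ImageGraph], outdir: str | os.PathLike) -> Path:
    outdir = Path(outdir)
    outdir.mkdir(parents=True, exist_ok=True)
    rows = []
    for i, g in enumerate(graphs):
        nodes = f"graph_{i:05d}_nodes.npy"
        edges = f"graph_{i:05d}_edges.csv"
        np.save(outdir / nodes, g.node_features)
        pd.DataFrame(g.edges, columns=["src", "dst"]).to_csv(outdir / edges, index=False)
        rows.append(
            {
                "image_id": g.image_id,
                "label": -1 if g.label is None else int(g.label),
                "nodes_path": nodes,
                "edges_path": edges,
            }
        )
    manifest = outdir / "manifest.csv"
    pd.DataFrame(rows).to_csv(manifest, index=False)
    return manifest


def load_graph_dataset(indir: str | os.PathLike) -> list[ImageGraph]:
    indir = Path(indir)
    df = pd.read_csv(indir / "manifest.csv")
    graphs = []
    for rec in df.itertuples():
        nodes = np.load(indir / rec.nodes_path)
        edges = pd.read_csv(indir / rec.edges_path).to_numpy()
        label = None if int(rec.label) < 0 else int(rec.label)
        graphs.append(
            ImageGraph(node_features=nodes, edges=edges,
                       image_id=str(rec.image_id), label=label)
        )
    return graphs
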