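import numpy as np
import pytest

from histogat import (
    GraphBuildConfig,
    SyntheticSpec,
    build_graph,
    generate_feature_dataset,
)


@pytest.fixture
def rng():
    return np.random.default_rng(12345)


@pytest.fixture(scope="session")
def small_feature_dataset():
    """12 images, 2 classes, 3x3 patch grid, 8-dim features, separable."""
    spec = SyntheticSpec(
        n_images=12,
        n_classes=2,
        patch_grid=(3, 3),
        feature_dim=8,
        n_components=2,
        class_separation=3.0,
        noise_sd=0.5,
        seed=5,
    )
    return generate_feature_dataset(spec)


@pytest.fixture(scope="session")
def small_graphs(small_feature_dataset):
    cfg = GraphBuildConfig(n_clusters=4, kmeans_restarts=2, kmeans_seed=3)
    return [build_graph(m, cfg, label=y) for m, y in small_feature_dataset]


def random_graph(rng, n_nodes=8, dim=6, edge_prob=0.4, label=None):
    """Random symmetric graph for model-level tests."""
    from histogat import ImageGraph

    x = rng.standard_normal((n_nodes, dim))
    edges = []
    for a in range(n_nodes):
        for b in range(a + 1, n_nodes):
            if rng.random() < edge_prob:
                edges += [(a, b), (b, a)]
    return ImageGraph(
        node_features=x,
        edges=np.asarray(edges, dtype=np.int64).reshape(-1, 2),
        image_id=f"rand-{rng.integers(1 << 30)}",
        label=label,
    )
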