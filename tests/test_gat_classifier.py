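"""Graph-attention classifier: gradients, invariances, training contracts."""

import numpy as np
import pytest

from histogat import GATClassifier, GATConfig, ImageGraph, TrainConfig
from histogat._nn import cross_entropy_grad, softmax
from histogat.gat_classifier import (
    ProbabilityMatrix,
    _backward_batch,
    _forward_batch,
    _GraphBatch,
)
from histogat.evaluation import compute_metrics

from conftest import random_graph


def test_config_width_law_enforced():
    GATConfig(in_dim=8)  # 4x8 -> 32, 4x4 -> 16: valid
    with pytest.raises(ValueError):
        GATConfig(in_dim=8, layer1_heads=2, layer1_per_head=8)
    with pytest.raises(ValueError):
        GATConfig(in_dim=8, layer2_heads=8, layer2_per_head=4)


def test_intermediate_widths_and_logit_length(rng):
    g = random_graph(rng, n_nodes=12, dim=6)
    model = GATClassifier(GATConfig(in_dim=6, n_classes=4))
    r1, r2 = model.node_representations(g)
    assert r1.shape == (12, 32)
    assert r2.shape == (12, 16)
    assert model.forward(g).shape == (4,)


def test_node_permutation_invariance(rng):
    model = GATClassifier(GATConfig(in_dim=6, n_classes=3, init_seed=2))
    for _ in range(5):
        g = random_graph(rng, n_nodes=int(rng.integers(2, 12)), dim=6)
        perm = rng.permutation(g.n_nodes)
        inv = np.argsort(perm)
        g_perm = ImageGraph(
            node_features=g.node_features[perm],
            edges=np.stack([inv[g.edges[:, 0]], inv[g.edges[:, 1]]], axis=1)
            if g.edges.size else g.edges,
            image_id="perm",
        )
        np.testing.assert_allclose(model.forward(g), model.forward(g_perm), atol=1e-10)


def test_single_node_graph_pools_its_own_representation(rng):
    g = ImageGraph(node_features=rng.standard_normal((1, 5)),
                   edges=np.zeros((0, 2)), image_id="one")
    model = GATClassifier(GATConfig(in_dim=5, n_classes=2))
    _, r2 = model.node_representations(g)
    expected = r2[0] @ model.params["W_out"] + model.params["b_out"]
    np.testing.assert_allclose(model.forward(g), expected, atol=1e-12)


def test_isolated_nodes_still_give_finite_logits(rng):
    g = ImageGraph(node_features=rng.standard_normal((7, 4)),
                   edges=np.zeros((0, 2)), image_id="iso")
    model = GATClassifier(GATConfig(in_dim=4, n_classes=2))
    assert np.all(np.isfinite(model.forward(g)))


def test_analytic_gradients_match_finite_differences(rng):
    """Spot-check the hand-written backward pass against central
    differences on every parameter tensor."""
    graphs = [random_graph(rng, n_nodes=int(rng.integers(3, 7)), dim=5, label=i % 2)
              for i in range(3)]
    cfg = GATConfig(in_dim=5, n_classes=2, init_seed=1)
    model = GATClassifier(cfg)
    batch = _GraphBatch(graphs, cfg.add_self_loops)
    y = np.array([g.label for g in graphs])

    logits, cache = _forward_batch(model.params, cfg, batch, with_cache=True)
    _, dlogits = cross_entropy_grad(logits, y)
    grads = _backward_batch(dlogits, model.params, cache, batch)

    def loss():
        lg, _ = _forward_batch(model.params, cfg, batch)
        return cross_entropy_grad(lg, y)[0]

    eps = 1e-6
    check_rng = np.random.default_rng(0)
    for name, p in model.params.items():
        flat = p.reshape(-1)
        for idx in check_rng.choice(flat.size, size=min(5, flat.size), replace=False):
            old = flat[idx]
            flat[idx] = old + eps
            lp = loss()
            flat[idx] = old - eps
            lm = loss()
            flat[idx] = old
            numeric = (lp - lm) / (2 * eps)
            analytic = grads[name].reshape(-1)[idx]
            assert analytic == pytest.approx(numeric, abs=1e-6, rel=1e-4), name


def test_batched_and_single_inference_agree(rng):
    graphs = [random_graph(rng, n_nodes=int(rng.integers(2, 10)), dim=6)
              for _ in range(7)]
    model = GATClassifier(GATConfig(in_dim=6, n_classes=3))
    batched = model.predict_proba(graphs).probs
    single = softmax(np.stack([model.forward(g) for g in graphs]), axis=1)
    np.testing.assert_allclose(batched, single, atol=1e-5)


def test_softmax_closed_form():
    np.testing.assert_allclose(softmax(np.array([[0.0, 0.0]])), [[0.5, 0.5]])
    np.testing.assert_allclose(
        softmax(np.array([[np.log(3.0), 0.0]])), [[0.75, 0.25]], atol=1e-12
    )


def test_probability_matrix_invariants(rng):
    with pytest.raises(ValueError):
        ProbabilityMatrix(probs=np.array([[0.6, 0.6]]))
    with pytest.raises(ValueError):
        ProbabilityMatrix(probs=np.array([[1.2, -0.2]]))
    pm = ProbabilityMatrix(probs=np.array([[0.25, 0.75]]), sample_ids=["a"])
    assert pm.argmax().tolist() == [1]


class TestTraining:
    def _separable_graphs(self, rng, n=16):
        graphs = []
        for i in range(n):
            c = i % 2
            x = rng.standard_normal((6, 4)) + (4.0 if c else -4.0)
            graphs.append(ImageGraph(node_features=x, edges=np.zeros((0, 2)),
                                     image_id=f"g{i}", label=c))
        return graphs

    def test_loss_decreases_on_separable_data(self, rng):
        graphs = self._separable_graphs(rng)
        model = GATClassifier(GATConfig(in_dim=4, n_classes=2)).fit(
            graphs, TrainConfig(epochs=40, learning_rate=1e-2, seed=0)
        )
        assert model.history[-1] < model.history[0]

    def test_same_seed_reproduces_parameters(self, rng):
        graphs = self._separable_graphs(rng)
        tc = TrainConfig(epochs=5, seed=3)
        m1 = GATClassifier(GATConfig(in_dim=4, n_classes=2, init_seed=1)).fit(graphs, tc)
        m2 = GATClassifier(GATConfig(in_dim=4, n_classes=2, init_seed=1)).fit(graphs, tc)
        for k in m1.params:
            np.testing.assert_array_equal(m1.params[k], m2.params[k])

    def test_shuffled_labels_give_chance_level_accuracy(self, rng):
        """Permutation null: with labels shuffled, held-out balanced
        accuracy stays near 1/n_classes (3 seeds averaged)."""
        accs = []
        for seed in (1, 2, 3):
            local = np.random.default_rng(seed)
            graphs = self._separable_graphs(local, n=40)
            y = np.array([g.label for g in graphs])
            shuffled = local.permutation(y)
            for g, lab in zip(graphs, shuffled):
                g.label = int(lab)
            train, test = graphs[:30], graphs[30:]
            # guard: both classes present in training
            model = GATClassifier(GATConfig(in_dim=4, n_classes=2, init_seed=seed)).fit(
                train, TrainConfig(epochs=30, learning_rate=1e-3, seed=seed)
            )
            y_test = np.array([g.label for g in test])
            accs.append(
                compute_metrics(y_test, model.predict_proba(test).probs)[
                    "balanced_accuracy"
                ]
            )
        assert abs(float(np.mean(accs)) - 0.5) < 0.15

    def test_unlabeled_graph_rejected(self, rng):
        graphs = self._separable_graphs(rng)
        graphs[3].label = None
        with pytest.raises(ValueError):
            GATClassifier(GATConfig(in_dim=4, n_classes=2)).fit(graphs, TrainConfig(epochs=1))

    def test_missing_class_rejected(self, rng):
        graphs = [g for g in self._separable_graphs(rng) if g.label == 0]
        with pytest.raises(ValueError, match="class"):
            GATClassifier(GATConfig(in_dim=4, n_classes=2)).fit(graphs, TrainConfig(epochs=1))

    def test_dimension_mismatch_rejected(self, rng):
        g = random_graph(rng, n_nodes=4, dim=7)
        with pytest.raises(ValueError):
            GATClassifier(GATConfig(in_dim=6, n_classes=2)).forward(g)


def test_checkpoint_roundtrip(tmp_path, rng):
    graphs = [random_graph(rng, n_nodes=5, dim=4, label=i % 2) for i in range(8)]
    model = GATClassifier(GATConfig(in_dim=4, n_classes=2)).fit(
        graphs, TrainConfig(epochs=3, seed=0)
    )
    path = tmp_path / "model.npz"
    model.save(path)
    loaded = GATClassifier.load(path)
    np.testing.assert_allclose(
        model.predict_proba(graphs).probs, loaded.predict_proba(graphs).probs
    )
    assert loaded.history == model.history
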