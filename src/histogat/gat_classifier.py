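"""Lightweight two-layer graph-attention classifier.

The model that reads an image's centroid graph and predicts its class:

* attention layer 1 -- 4 heads x 8 features, concatenated to 32 per node,
  then ReLU;
* attention layer 2 -- 4 heads x 4 features, concatenated to 16 per node,
  then ReLU;
* global mean pooling over all nodes, then a linear map to the classes.

Each attention layer follows the standard graph-attention formulation:
per head, node features are linearly projected, an additive score
``LeakyReLU(a_src . z_j + a_dst . z_i)`` is computed for every edge
``j -> i``, scores are softmax-normalised over each node's in-neighbours,
and messages are aggregated with those weights.  Self-loops are inserted
inside the layers (configurable) so nodes isolated by the similarity
threshold still have a well-defined neighbourhood.

Everything is plain NumPy with explicit reverse-mode gradients; training
uses Adam on mini-batches of disjoint-union graph batches, and batched
inference agrees with one-graph-at-a-time inference to float precision.
"""

from __future__ import annotations

import json
import os
from dataclasses import dataclass, field, asdict
from typing import Optional, Sequence

import numpy as np
import scipy.sparse as sp

from ._nn import Adam, cross_entropy_grad, glorot, leaky_relu, softmax
from .graph_construction import ImageGraph

__all__ = [
    "GATConfig",
    "TrainConfig",
    "ProbabilityMatrix",
    "GATClassifier",
    "forward",
    "train",
    "predict_proba",
]


@dataclass(frozen=True)
class GATConfig:
    """Architecture of the graph classifier.

    The head/width split is pinned to the printed design: layer 1 must
    concatenate to 32 features per node and layer 2 to 16.
    """

    in_dim: int
    n_classes: int = 2
    layer1_heads: int = 4
    layer1_per_head: int = 8
    layer2_heads: int = 4
    layer2_per_head: int = 4
    add_self_loops: bool = True
    attention_slope: float = 0.2
    init_seed: int = 0

    def __post_init__(self) -> None:
        if self.in_dim < 1 or self.n_classes < 2:
            raise ValueError("in_dim must be >= 1 and n_classes >= 2")
        if self.layer1_heads * self.layer1_per_head != 32:
            raise ValueError("layer 1 must concatenate to 32 features per node")
        if self.layer2_heads * self.layer2_per_head != 16:
            raise ValueError("layer 2 must concatenate to 16 features per node")


@dataclass(frozen=True)
class TrainConfig:
    """Optimisation settings shared by the graph model and the baseline:
    Adam, learning rate 1e-4, 300 epochs, mini-batches of 32, categorical
    cross-entropy, seeded shuffling."""

    learning_rate: float = 1e-4
    epochs: int = 300
    batch_size: int = 32
    seed: int = 0

    def __post_init__(self) -> None:
        if self.learning_rate <= 0:
            raise ValueError("learning_rate must be positive")
        if self.epochs < 1 or self.batch_size < 1:
            raise ValueError("epochs and batch_size must be >= 1")


@dataclass
class ProbabilityMatrix:
    """``n_samples x n_classes`` class probabilities, rows summing to 1."""

    probs: np.ndarray
    sample_ids: list[str] = field(default_factory=list)

    def __post_init__(self) -> None:
        self.probs = np.asarray(self.probs, dtype=np.float64)
        if self.probs.ndim != 2:
            raise ValueError("probs must be 2-D")
        if not self.sample_ids:
            self.sample_ids = [str(i) for i in range(self.probs.shape[0])]
        if len(self.sample_ids) != self.probs.shape[0]:
            raise ValueError("sample_ids length mismatch")
        if np.any(self.probs < -1e-9):
            raise ValueError("negative probabilities")
        if np.any(np.abs(self.probs.sum(axis=1) - 1.0) > 1e-6):
            raise ValueError("probability rows must sum to 1")

    @property
    def n_classes(self) -> int:
        return self.probs.shape[1]

    def argmax(self) -> np.ndarray:
        return self.probs.argmax(axis=1)


# ---------------------------------------------------------------------------
# batching
# ---------------------------------------------------------------------------

class _GraphBatch:
    """Disjoint union of graphs: concatenated nodes, offset edges, and the
    graph id of every node (for per-graph mean pooling)."""

    def __init__(self, graphs: Sequence[ImageGraph], add_self_loops: bool) -> None:
        xs, srcs, dsts, gids = [], [], [], []
        offset = 0
        counts = []
        for g_i, g in enumerate(graphs):
            n = g.n_nodes
            xs.append(g.node_features)
            if g.edges.size:
                srcs.append(g.edges[:, 0] + offset)
                dsts.append(g.edges[:, 1] + offset)
            if add_self_loops:
                loop = np.arange(offset, offset + n)
                srcs.append(loop)
                dsts.append(loop)
            gids.append(np.full(n, g_i))
            counts.append(n)
            offset += n
        self.x = np.concatenate(xs, axis=0)
        self.src = np.concatenate(srcs) if srcs else np.zeros(0, dtype=np.int64)
        self.dst = np.concatenate(dsts) if dsts else np.zeros(0, dtype=np.int64)
        self.graph_id = np.concatenate(gids)
        self.counts = np.asarray(counts, dtype=np.float64)
        self.n_nodes = offset
        self.n_graphs = len(graphs)
        e = self.src.shape[0]
        ones = np.ones(e)
        idx = np.arange(e)
        # scatter matrices: M_dst @ v sums edge values at their destination
        self.m_dst = sp.csr_matrix((ones, (self.dst, idx)), shape=(self.n_nodes, e))
        self.m_src = sp.csr_matrix((ones, (self.src, idx)), shape=(self.n_nodes, e))


# ---------------------------------------------------------------------------
# parameters
# ---------------------------------------------------------------------------

def _init_params(cfg: GATConfig) -> dict[str, np.ndarray]:
    rng = np.random.default_rng(cfg.init_seed)
    h1, f1 = cfg.layer1_heads, cfg.layer1_per_head
    h2, f2 = cfg.layer2_heads, cfg.layer2_per_head
    w1 = h1 * f1
    w2 = h2 * f2
    return {
        "W1": glorot(rng, (cfg.in_dim, w1)),
        "a_src1": glorot(rng, (h1, f1)),
        "a_dst1": glorot(rng, (h1, f1)),
        "b1": np.zeros(w1),
        "W2": glorot(rng, (w1, w2)),
        "a_src2": glorot(rng, (h2, f2)),
        "a_dst2": glorot(rng, (h2, f2)),
        "b2": np.zeros(w2),
        "W_out": glorot(rng, (w2, cfg.n_classes)),
        "b_out": np.zeros(cfg.n_classes),
    }


# ---------------------------------------------------------------------------
# attention layer forward/backward
# ---------------------------------------------------------------------------

def _gat_layer_forward(x, w, a_src, a_dst, b, batch: _GraphBatch, slope: float):
    n = batch.n_nodes
    heads, per_head = a_src.shape
    z = (x @ w).reshape(n, heads, per_head)
    score_src = np.einsum("nhf,hf->nh", z, a_src)
    score_dst = np.einsum("nhf,hf->nh", z, a_dst)
    e_pre = score_src[batch.src] + score_dst[batch.dst]
    e = leaky_relu(e_pre, slope)
    m = np.full((n, heads), -np.inf)
    np.maximum.at(m, batch.dst, e)
    m = np.where(np.isfinite(m), m, 0.0)  # nodes with no incoming edge
    ex = np.exp(e - m[batch.dst])
    denom = batch.m_dst @ ex
    denom = np.where(denom > 0, denom, 1.0)
    alpha = ex / denom[batch.dst]
    msg = (alpha[:, :, None] * z[batch.src]).reshape(-1, heads * per_head)
    out = np.asarray(batch.m_dst @ msg) + b
    cache = (x, w, a_src, a_dst, z, e_pre, alpha, slope, batch)
    return out, cache


def _gat_layer_backward(dout, cache):
    x, w, a_src, a_dst, z, e_pre, alpha, slope, batch = cache
    n = batch.n_nodes
    heads, per_head = a_src.shape
    dout_r = dout.reshape(n, heads, per_head)
    dmsg = dout_r[batch.dst]                         # (E, H, F)
    z_src = z[batch.src]
    dalpha = (dmsg * z_src).sum(axis=2)              # (E, H)
    # through the message product onto the source features
    dz = np.asarray(
        batch.m_src @ (alpha[:, :, None] * dmsg).reshape(-1, heads * per_head)
    ).reshape(n, heads, per_head)
    # softmax over each destination's in-edges
    seg = np.asarray(batch.m_dst @ (alpha * dalpha))  # (N, H)
    de = alpha * (dalpha - seg[batch.dst])
    de_pre = de * np.where(e_pre > 0, 1.0, slope)
    d_score_src = np.asarray(batch.m_src @ de_pre)    # (N, H)
    d_score_dst = np.asarray(batch.m_dst @ de_pre)
    dz += d_score_src[:, :, None] * a_src[None] + d_score_dst[:, :, None] * a_dst[None]
    da_src = np.einsum("nh,nhf->hf", d_score_src, z)
    da_dst = np.einsum("nh,nhf->hf", d_score_dst, z)
    dz_flat = dz.reshape(n, heads * per_head)
    grads = {
        "W": x.T @ dz_flat,
        "a_src": da_src,
        "a_dst": da_dst,
        "b": dout.sum(axis=0),
    }
    dx = dz_flat @ w.T
    return dx, grads


# ---------------------------------------------------------------------------
# full model
# ---------------------------------------------------------------------------

def _forward_batch(params, cfg: GATConfig, batch: _GraphBatch, with_cache=False):
    h1, c1 = _gat_layer_forward(
        batch.x, params["W1"], params["a_src1"], params["a_dst1"], params["b1"],
        batch, cfg.attention_slope,
    )
    r1 = np.maximum(h1, 0.0)
    h2, c2 = _gat_layer_forward(
        r1, params["W2"], params["a_src2"], params["a_dst2"], params["b2"],
        batch, cfg.attention_slope,
    )
    r2 = np.maximum(h2, 0.0)
    pooled = np.zeros((batch.n_graphs, r2.shape[1]))
    np.add.at(pooled, batch.graph_id, r2)
    pooled /= batch.counts[:, None]
    logits = pooled @ params["W_out"] + params["b_out"]
    if not with_cache:
        return logits, None
    return logits, (h1, c1, h2, c2, pooled)


def _backward_batch(dlogits, params, cache, batch: _GraphBatch):
    h1, c1, h2, c2, pooled = cache
    grads = {
        "W_out": pooled.T @ dlogits,
        "b_out": dlogits.sum(axis=0),
    }
    dpooled = dlogits @ params["W_out"].T
    dr2 = dpooled[batch.graph_id] / batch.counts[batch.graph_id][:, None]
    dh2 = dr2 * (h2 > 0)
    dr1, g2 = _gat_layer_backward(dh2, c2)
    grads.update({"W2": g2["W"], "a_src2": g2["a_src"], "a_dst2": g2["a_dst"], "b2": g2["b"]})
    dh1 = dr1 * (h1 > 0)
    _, g1 = _gat_layer_backward(dh1, c1)
    grads.update({"W1": g1["W"], "a_src1": g1["a_src"], "a_dst1": g1["a_dst"], "b1": g1["b"]})
    return grads


class GATClassifier:
    """Trained (or trainable) graph-attention classifier.

    ``fit`` runs seeded mini-batch Adam; ``predict_proba`` returns softmax
    rows in input order.  Instances are deterministic functions of
    (config, training data, train config).
    """

    def __init__(self, config: GATConfig) -> None:
        self.config = config
        self.params = _init_params(config)
        self.history: list[float] = []

    # -- inference ---------------------------------------------------------

    def forward(self, graph: ImageGraph) -> np.ndarray:
        """Logits for one graph (length ``n_classes``)."""
        if graph.node_features.shape[1] != self.config.in_dim:
            raise ValueError(
                f"graph feature dim {graph.node_features.shape[1]} does not "
                f"match model in_dim {self.config.in_dim}"
            )
        batch = _GraphBatch([graph], self.config.add_self_loops)
        logits, _ = _forward_batch(self.params, self.config, batch)
        return logits[0]

    def node_representations(self, graph: ImageGraph) -> tuple[np.ndarray, np.ndarray]:
        """Post-ReLU node features after each attention layer (for shape
        introspection: widths 32 and 16)."""
        batch = _GraphBatch([graph], self.config.add_self_loops)
        logits, cache = _forward_batch(self.params, self.config, batch, with_cache=True)
        h1, _, h2, _, _ = cache
        return np.maximum(h1, 0.0), np.maximum(h2, 0.0)

    def predict_proba(
        self, graphs: Sequence[ImageGraph], chunk_size: int = 256
    ) -> ProbabilityMatrix:
        rows = []
        for start in range(0, len(graphs), chunk_size):
            chunk = graphs[start : start + chunk_size]
            for g in chunk:
                if g.node_features.shape[1] != self.config.in_dim:
                    raise ValueError("graph feature dim does not match model in_dim")
            batch = _GraphBatch(chunk, self.config.add_self_loops)
            logits, _ = _forward_batch(self.params, self.config, batch)
            rows.append(softmax(logits, axis=1))
        probs = np.concatenate(rows, axis=0)
        return ProbabilityMatrix(probs=probs, sample_ids=[g.image_id for g in graphs])

    # -- training ----------------------------------------------------------

    def fit(self, graphs: Sequence[ImageGraph], train_config: TrainConfig) -> "GATClassifier":
        labels = []
        for g in graphs:
            if g.label is None:
                raise ValueError(f"graph {g.image_id!r} has no label")
            labels.append(int(g.label))
        y = np.asarray(labels)
        present = set(y.tolist())
        missing = [c for c in range(self.config.n_classes) if c not in present]
        if missing:
            raise ValueError(f"training set lacks examples of class(es) {missing}")
        rng = np.random.default_rng(train_config.seed)
        opt = Adam(self.params, lr=train_config.learning_rate)
        n = len(graphs)
        bs = train_config.batch_size
        self.history = []
        for _ in range(train_config.epochs):
            perm = rng.permutation(n)
            epoch_loss = 0.0
            for start in range(0, n, bs):
                idx = perm[start : start + bs]
                batch = _GraphBatch([graphs[i] for i in idx], self.config.add_self_loops)
                logits, cache = _forward_batch(self.params, self.config, batch, with_cache=True)
                loss, dlogits = cross_entropy_grad(logits, y[idx])
                grads = _backward_batch(dlogits, self.params, cache, batch)
                opt.step(grads)
                epoch_loss += loss * len(idx)
            self.history.append(epoch_loss / n)
        return self

    # -- persistence -------------------------------------------------------

    def save(self, path: str | os.PathLike) -> None:
        meta = json.dumps({"config": asdict(self.config), "history": self.history})
        np.savez(path, __meta__=np.frombuffer(meta.encode(), dtype=np.uint8), **self.params)

    @classmethod
    def load(cls, path: str | os.PathLike) -> "GATClassifier":
        with np.load(path) as data:
            meta = json.loads(bytes(data["__meta__"]).decode())
            model = cls(GATConfig(**meta["config"]))
            model.history = list(meta["history"])
            model.params = {k: data[k] for k in data.files if k != "__meta__"}
        return model


# -- spec-level convenience functions --------------------------------------

def forward(graph: ImageGraph, model: GATClassifier) -> np.ndarray:
    return model.forward(graph)


def train(
    graphs: Sequence[ImageGraph], gat: GATConfig, tc: TrainConfig
) -> tuple[GATClassifier, list[float]]:
    model = GATClassifier(gat).fit(graphs, tc)
    return model, model.history


def predict_proba(model: GATClassifier, graphs: Sequence[ImageGraph]) -> ProbabilityMatrix:
    return model.predict_proba(graphs)
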