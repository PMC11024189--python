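"""Graph neural classifiers over the EEG channel graph.

Channels are nodes; each node's feature vector is that channel's time
series.  A single adjacency matrix, shared by every segment, is the
absolute Pearson correlation between channels over the (training) dataset
with the self-correlation removed: ``A = |P| − I``.

Three layer families are provided —

* GCN: ``Y = D̂^{-1/2} Â D̂^{-1/2} X W + b`` with self-loops ``Â = A + I``;
* GCS: ``Y = D^{-1/2} A D^{-1/2} X W₁ + X W₂ + b`` (trainable skip, no
  self-loops; isolated nodes get a zero normalized term);
* GIN: ``Y_i = MLP((1+ε)·x_i + Σ_{j∈N(i)} x_j)`` with the unweighted
  neighbourhood ``N(i) = {j : A_ij > 0}`` and learned ε (initialized 0)

— each stacked (ReLU between), aggregated by a global attention-sum pool
``X' = Σ_i α_i X_i, α = softmax(Xa)`` over nodes, then a ReLU hidden layer
and a single sigmoid output unit.
"""

from __future__ import annotations

from dataclasses import dataclass
from typing import Callable

import numpy as np

from ..nn.autograd import Tensor, bce_with_logits
from .csnn import _uniform

__all__ = [
    "Graph",
    "GNNLayerParams",
    "GNNConfig",
    "GNNClassifier",
    "build_adjacency",
    "attention_sum_pool",
    "gcn_layer",
    "gcs_layer",
    "gin_layer",
    "gnn_forward",
]


@dataclass
class Graph:
    """Node features with a nonnegative symmetric zero-diagonal adjacency."""

    node_features: np.ndarray  # (N, n)
    adjacency: np.ndarray  # (N, N)

    def __post_init__(self) -> None:
        X, A = np.asarray(self.node_features, float), np.asarray(self.adjacency, float)
        if X.ndim != 2 or A.shape != (X.shape[0], X.shape[0]):
            raise ValueError("shapes inconsistent: X must be (N, n), A (N, N)")
        if not np.allclose(A, A.T):
            raise ValueError("adjacency must be symmetric")
        if (A < 0).any():
            raise ValueError("adjacency must be nonnegative")
        if not np.allclose(np.diag(A), 0):
            raise ValueError("adjacency must have zero diagonal")
        self.node_features, self.adjacency = X, A

    @property
    def degree(self) -> np.ndarray:
        """Diagonal of the degree matrix, D_ii = Σ_j A_ij."""
        return self.adjacency.sum(axis=1)


@dataclass
class GNNLayerParams:
    """Weights for one graph layer (only the relevant fields are used)."""

    W: np.ndarray | None = None
    b: np.ndarray | float = 0.0
    W1: np.ndarray | None = None
    W2: np.ndarray | None = None
    a: np.ndarray | None = None  # attention weight vector
    epsilon: float = 0.0
    mlp: Callable[[np.ndarray], np.ndarray] | None = None  # None → identity


def build_adjacency(dataset: np.ndarray) -> np.ndarray:
    """``A = |P| − I`` from the Pearson correlation across channels.

    ``dataset``: (n_segments, channels, time) or a single (channels, time)
    array; time axes of all segments are concatenated per channel.  Raises
    for a zero-variance channel (correlation undefined).
    """
    x = np.asarray(dataset, dtype=float)
    if x.ndim == 2:
        x = x[None]
    flat = x.transpose(1, 0, 2).reshape(x.shape[1], -1)
    sd = flat.std(axis=1)
    if (sd == 0).any():
        bad = int(np.flatnonzero(sd == 0)[0])
        raise ValueError(f"zero-variance channel {bad}: correlation undefined")
    A = np.abs(np.corrcoef(flat)) - np.eye(flat.shape[0])
    A = np.clip((A + A.T) / 2.0, 0.0, 1.0)
    np.fill_diagonal(A, 0.0)
    return A


# ---------------------------------------------------------------------------
# functional layer operations (numpy; the trainable network mirrors these)


def attention_sum_pool(X: np.ndarray, a: np.ndarray) -> np.ndarray:
    """Softmax-over-nodes weighted sum of node features."""
    X, a = np.asarray(X, float), np.asarray(a, float).reshape(-1)
    logits = X @ a
    e = np.exp(logits - logits.max())
    alpha = e / e.sum()
    return alpha @ X


def gcn_layer(g: Graph, p: GNNLayerParams) -> np.ndarray:
    """Self-loop-normalized graph convolution."""
    A_hat = g.adjacency + np.eye(g.adjacency.shape[0])
    d = A_hat.sum(axis=1)
    dinv = 1.0 / np.sqrt(d)  # self-loop guarantees d >= 1
    S = dinv[:, None] * A_hat * dinv[None, :]
    return S @ g.node_features @ p.W + p.b


def gcs_layer(g: Graph, p: GNNLayerParams) -> np.ndarray:
    """Normalized propagation (no self-loops) plus a trainable skip path."""
    d = g.degree
    dinv = np.where(d > 0, 1.0 / np.sqrt(np.where(d > 0, d, 1.0)), 0.0)
    S = dinv[:, None] * g.adjacency * dinv[None, :]
    return S @ g.node_features @ p.W1 + g.node_features @ p.W2 + p.b


def gin_layer(g: Graph, p: GNNLayerParams) -> np.ndarray:
    """Isomorphism-style aggregation with unweighted neighbour sum."""
    binA = (g.adjacency > 0).astype(float)
    h = (1.0 + p.epsilon) * g.node_features + binA @ g.node_features
    return h if p.mlp is None else p.mlp(h)


# ---------------------------------------------------------------------------
# trainable classifiers


@dataclass
class GNNConfig:
    """Architecture selection and layer sizes.

    Defaults follow the reference configuration: GCN/GCS stack four layers
    with output sizes (115, 28, 14, 3); GIN stacks three (924, 462, 231)
    with 5×256-hidden MLPs.  The post-pool hidden width is a free choice.
    """

    arch: str = "gcn"  # gcn | gcs | gin
    layer_sizes: tuple[int, ...] | None = None
    gin_mlp_hidden: tuple[int, ...] = (256,) * 5
    hidden: int = 32

    def __post_init__(self) -> None:
        if self.arch not in ("gcn", "gcs", "gin"):
            raise ValueError(f"unknown architecture {self.arch!r}")
        if self.layer_sizes is None:
            self.layer_sizes = (924, 462, 231) if self.arch == "gin" else (115, 28, 14, 3)


def _softmax_nodes(logits: Tensor) -> Tensor:
    shift = Tensor(logits.data.max(axis=1, keepdims=True))
    e = (logits - shift).exp()
    return e / e.sum(axis=1, keepdims=True)


class GNNClassifier:
    """GCN / GCS / GIN stack with attention-sum pooling and sigmoid output."""

    def __init__(
        self,
        input_shape: tuple[int, int],  # (N nodes, n features)
        adjacency: np.ndarray,
        cfg: GNNConfig | None = None,
        seed: int = 0,
    ):
        self.cfg = cfg or GNNConfig()
        self.name = self.cfg.arch.upper()
        self.input_shape = tuple(input_shape)
        N, n = self.input_shape
        if adjacency.shape != (N, N):
            raise ValueError("adjacency shape does not match node count")
        self.adjacency = np.asarray(adjacency, dtype=float)

        # constant propagation operators
        A_hat = self.adjacency + np.eye(N)
        d_hat = A_hat.sum(axis=1)
        self._S_gcn = A_hat / np.sqrt(np.outer(d_hat, d_hat))
        d = self.adjacency.sum(axis=1)
        dinv = np.where(d > 0, 1.0 / np.sqrt(np.where(d > 0, d, 1.0)), 0.0)
        self._S_gcs = dinv[:, None] * self.adjacency * dinv[None, :]
        self._binA = (self.adjacency > 0).astype(float)

        rng = np.random.default_rng(seed)
        self.layers: list[dict] = []
        n_in = n
        for n_out in self.cfg.layer_sizes:
            layer: dict = {}
            if self.cfg.arch == "gcn":
                layer["W"] = Tensor(_uniform(rng, (n_in, n_out), n_in), requires_grad=True)
                layer["b"] = Tensor(np.zeros(n_out), requires_grad=True)
            elif self.cfg.arch == "gcs":
                layer["W1"] = Tensor(_uniform(rng, (n_in, n_out), n_in), requires_grad=True)
                layer["W2"] = Tensor(_uniform(rng, (n_in, n_out), n_in), requires_grad=True)
                layer["b"] = Tensor(np.zeros(n_out), requires_grad=True)
            else:  # gin
                layer["eps"] = Tensor(np.zeros(()), requires_grad=True)
                dims = (n_in, *self.cfg.gin_mlp_hidden, n_out)
                layer["mlp"] = [
                    (
                        Tensor(_uniform(rng, (a, b), a), requires_grad=True),
                        Tensor(np.zeros(b), requires_grad=True),
                    )
                    for a, b in zip(dims[:-1], dims[1:])
                ]
            self.layers.append(layer)
            n_in = n_out

        self.att = Tensor(_uniform(rng, (n_in, 1), n_in), requires_grad=True)
        self.wh = Tensor(_uniform(rng, (n_in, self.cfg.hidden), n_in), requires_grad=True)
        self.bh = Tensor(np.zeros(self.cfg.hidden), requires_grad=True)
        self.wo = Tensor(_uniform(rng, (self.cfg.hidden, 1), self.cfg.hidden), requires_grad=True)
        self.bo = Tensor(np.zeros(1), requires_grad=True)

    def parameters(self) -> list[Tensor]:
        ps: list[Tensor] = []
        for layer in self.layers:
            for v in layer.values():
                if isinstance(v, Tensor):
                    ps.append(v)
                else:  # gin mlp
                    for w, b in v:
                        ps.extend((w, b))
        ps.extend((self.att, self.wh, self.bh, self.wo, self.bo))
        return ps

    def _graph_stack(self, X: Tensor) -> Tensor:
        arch = self.cfg.arch
        for i, layer in enumerate(self.layers):
            if arch == "gcn":
                X = Tensor(self._S_gcn) @ X @ layer["W"] + layer["b"]
            elif arch == "gcs":
                X = Tensor(self._S_gcs) @ X @ layer["W1"] + X @ layer["W2"] + layer["b"]
            else:
                h = X * (layer["eps"] + 1.0) + Tensor(self._binA) @ X
                for j, (w, b) in enumerate(layer["mlp"]):
                    h = h @ w + b
                    if j < len(layer["mlp"]) - 1:
                        h = h.relu()
                X = h
            if i < len(self.layers) - 1:
                X = X.relu()
        return X

    def logits(self, x: np.ndarray) -> Tensor:
        x = np.asarray(x, dtype=np.float64)
        if x.ndim == 2:
            x = x[None]
        if x.shape[1:] != self.input_shape:
            raise ValueError(
                f"input shape {x.shape[1:]} does not match {self.input_shape}"
            )
        B = x.shape[0]
        X = self._graph_stack(Tensor(x))
        alpha = _softmax_nodes(X @ self.att)  # (B, N, 1)
        pooled = (alpha.transpose(0, 2, 1) @ X).reshape(B, -1)
        h = (pooled @ self.wh + self.bh).relu()
        return h @ self.wo + self.bo

    def predict_proba(self, x: np.ndarray) -> np.ndarray:
        return self.logits(x).sigmoid().data.reshape(-1)

    def predict(self, x: np.ndarray) -> np.ndarray:
        return (self.predict_proba(x) > 0.5).astype(int)

    def loss(self, x: np.ndarray, y: np.ndarray, sample_weight=None) -> Tensor:
        return bce_with_logits(self.logits(x), y, sample_weight)


def gnn_forward(x: np.ndarray, model: GNNClassifier) -> np.ndarray:
    """Class-1 probabilities in (0, 1)."""
    return model.predict_proba(x)
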