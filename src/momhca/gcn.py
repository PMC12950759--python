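"""Two-layer graph convolutional classifier on the fused similarity graph.

Layers follow H^(l) = σ(Ã · H^(l−1) · W^(l)) with Ã = D^(−1/2) A D^(−1/2),
ELU activations, dropout regularisation, and a distinct fully connected
output layer producing the class logits. Training is transductive: all
node features and edges are visible, but cross-entropy is evaluated on
train-mask nodes only and test labels are never read.
"""

from __future__ import annotations

from dataclasses import dataclass

import numpy as np

from . import nn

__all__ = ["GraphTask", "GCNConfig", "GCN", "normalize_adjacency",
           "gcn_forward", "train_gcn", "predict"]


@dataclass
class GraphTask:
    """Node-classification instance: adjacency A, node features H, integer
    labels (−1 = unknown), and disjoint train/test masks."""

    A: np.ndarray
    H: np.ndarray
    labels: np.ndarray
    train_mask: np.ndarray
    test_mask: np.ndarray
    n_classes: int

    def __post_init__(self):
        self.A = np.asarray(self.A, dtype=np.float64)
        self.H = np.asarray(self.H, dtype=np.float64)
        self.labels = np.asarray(self.labels, dtype=np.int64)
        self.train_mask = np.asarray(self.train_mask, dtype=bool)
        self.test_mask = np.asarray(self.test_mask, dtype=bool)
        n = self.A.shape[0]
        if self.A.shape != (n, n):
            raise ValueError("adjacency must be square")
        if self.H.shape[0] != n or len(self.labels) != n:
            raise ValueError("features/labels do not match adjacency size")
        if np.any(self.train_mask & self.test_mask):
            raise ValueError("train and test masks overlap")
        if np.any(self.labels[self.train_mask] < 0):
            bad = int(np.flatnonzero(self.train_mask & (self.labels < 0))[0])
            raise ValueError(f"train-mask node {bad} has unknown label")


@dataclass
class GCNConfig:
    hidden_dim: int = 64
    activation: str = "elu"
    dropout: float = 0.5
    lr: float = 0.001
    weight_decay: float = 0.01
    epochs: int = 150
    seed: int = 0

    def __post_init__(self):
        if not 0.0 <= self.dropout < 1.0:
            raise ValueError("dropout must be in [0, 1)")


def normalize_adjacency(A: np.ndarray) -> np.ndarray:
    """Symmetric degree normalisation Ã = D^(−1/2) A D^(−1/2)."""
    A = np.asarray(A, dtype=np.float64)
    if not np.allclose(A, A.T, atol=1e-10):
        raise ValueError("adjacency must be symmetric")
    if np.any(A < 0):
        raise ValueError("adjacency must be nonnegative")
    deg = A.sum(axis=1)
    if np.any(deg <= 0):
        i = int(np.argmax(deg <= 0))
        raise ValueError(f"node {i} has zero degree")
    d_inv_sqrt = 1.0 / np.sqrt(deg)
    return A * d_inv_sqrt[:, None] * d_inv_sqrt[None, :]


class GCN:
    """conv(d→hidden) → ELU → dropout → conv(hidden→hidden) → ELU → linear
    output head (hidden→n_classes)."""

    def __init__(self, in_dim: int, n_classes: int, cfg: GCNConfig,
                 rng: np.random.Generator):
        self.cfg = cfg
        self._act = nn.activation(cfg.activation)
        self.W1 = nn.Linear(in_dim, cfg.hidden_dim, rng)
        self.W2 = nn.Linear(cfg.hidden_dim, cfg.hidden_dim, rng)
        self.head = nn.Linear(cfg.hidden_dim, n_classes, rng)

    def forward(self, A_norm: nn.Tensor, H: nn.Tensor, training: bool,
                rng: np.random.Generator | None = None) -> nn.Tensor:
        X = self._act(A_norm @ self.W1(H))
        if training:
            X = nn.dropout(X, self.cfg.dropout, rng, training=True)
        X = self._act(A_norm @ self.W2(X))
        return self.head(X)

    def parameters(self) -> list[nn.Parameter]:
        return self.W1.parameters() + self.W2.parameters() + self.head.parameters()


def gcn_forward(A_norm: np.ndarray, H: np.ndarray, model: GCN,
                training: bool = False,
                rng: np.random.Generator | None = None) -> np.ndarray:
    """Logits for every node; deterministic when `training` is False."""
    A_norm = np.asarray(A_norm, dtype=np.float64)
    H = np.asarray(H, dtype=np.float64)
    if A_norm.shape[0] != H.shape[0]:
        raise ValueError("adjacency and feature row counts differ")
    return model.forward(nn.Tensor(A_norm), nn.Tensor(H), training, rng).data


def train_gcn(task: GraphTask, cfg: GCNConfig | None = None
              ) -> tuple[GCN, list[float]]:
    """Adam on cross-entropy over train-mask nodes; returns the trained
    model and the per-epoch loss history."""
    cfg = cfg or GCNConfig()
    if task.train_mask.sum() == 0:
        raise ValueError("train mask is empty")
    rng = np.random.default_rng(cfg.seed)
    A_norm = nn.Tensor(normalize_adjacency(task.A))
    H = nn.Tensor(task.H)
    model = GCN(task.H.shape[1], task.n_classes, cfg, rng)
    opt = nn.Adam(model.parameters(), lr=cfg.lr, weight_decay=cfg.weight_decay)
    train_idx = np.flatnonzero(task.train_mask)
    y_train = task.labels[train_idx]
    history: list[float] = []
    for _ in range(cfg.epochs):
        opt.zero_grad()
        logits = model.forward(A_norm, H, training=True, rng=rng)
        loss = nn.cross_entropy(logits.rows(train_idx), y_train)
        loss.backward()
        opt.step()
        history.append(float(loss.data))
    return model, history


def predict(task: GraphTask, model: GCN) -> tuple[np.ndarray, np.ndarray]:
    """Predicted labels and softmax class probabilities for all nodes."""
    logits = gcn_forward(normalize_adjacency(task.A), task.H, model,
                         training=False)
    z = logits - logits.max(axis=1, keepdims=True)
    probs = np.exp(z)
    probs /= probs.sum(axis=1, keepdims=True)
    return probs.argmax(axis=1), probs
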