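"""Sparse auto-encoder compression of integrated similarity rows into node features.

Each row of an integrated similarity matrix (a node's similarity profile) is
compressed to a k-dimensional code ``y = sigma(x W1 + b1)`` and passed through
a second k x k layer ``z = sigma(y W2 + b2)``.  The default training
objective is the mean squared discrepancy between hidden code and output,
``Loss = (1/p) sum ||y - z||^2``, optionally plus an L1 penalty on the hidden
activations (the sparsity term); ``z`` is the per-node feature used
downstream.  A conventional mode that decodes back to the input dimension and
minimises reconstruction error ``||x - z'||^2`` is available for comparison
(its k-dimensional hidden code is then the downstream feature).

Training is plain full-batch gradient descent, seeded, so identical seeds
give bit-identical weights.
"""

from __future__ import annotations

from dataclasses import dataclass, field

import numpy as np

from .data_io import SimilarityMatrix


def _sigmoid(x: np.ndarray) -> np.ndarray:
    out = np.empty_like(x)
    pos = x >= 0
    out[pos] = 1.0 / (1.0 + np.exp(-x[pos]))
    ex = np.exp(x[~pos])
    out[~pos] = ex / (1.0 + ex)
    return out


@dataclass
class AutoEncoderParams:
    W1: np.ndarray
    b1: np.ndarray
    W2: np.ndarray
    b2: np.ndarray
    k: int
    epochs: int
    learning_rate: float
    l1_penalty: float
    seed: int
    mode: str = "hidden_output"
    activation: str = "sigmoid"
    loss_history: list[float] = field(default_factory=list)


def train_autoencoder(
    Xside: SimilarityMatrix | np.ndarray,
    k: int,
    epochs: int = 200,
    lr: float = 1e-3,
    l1_penalty: float = 0.0,
    seed: int = 0,
    mode: str = "hidden_output",
) -> tuple[AutoEncoderParams, np.ndarray]:
    """Train on the p rows of a p x p similarity matrix; return (params, Z).

    Z is p x k: the output-layer activations in the default
    ``hidden_output`` mode, the hidden codes in ``reconstruction`` mode.
    """
    X = Xside.values if isinstance(Xside, SimilarityMatrix) else np.asarray(Xside, float)
    if X.ndim != 2 or X.shape[0] != X.shape[1]:
        raise ValueError("input must be a square similarity matrix")
    p = X.shape[0]
    if k > p:
        raise ValueError(f"hidden width k={k} exceeds input dimension p={p}")
    if k < 1:
        raise ValueError("k must be >= 1")
    if mode not in ("hidden_output", "reconstruction"):
        raise ValueError(f"unknown mode {mode!r}")

    rng = np.random.default_rng(seed)
    out_dim = k if mode == "hidden_output" else p
    W1 = rng.standard_normal((p, k)) / np.sqrt(p)
    b1 = np.zeros(k)
    W2 = rng.standard_normal((k, out_dim)) / np.sqrt(k)
    b2 = np.zeros(out_dim)

    losses: list[float] = []
    for epoch in range(epochs):
        Y = _sigmoid(X @ W1 + b1)
        Z = _sigmoid(Y @ W2 + b2)
        if mode == "hidden_output":
            diff = Y - Z
        else:
            diff = X - Z
        loss = float((diff**2).sum() / p) + l1_penalty * float(np.abs(Y).mean())
        if not np.isfinite(loss):
            raise FloatingPointError(f"non-finite loss at epoch {epoch}")
        losses.append(loss)

        # backprop; dL/dZ = -(2/p) diff in both modes
        dZ = -(2.0 / p) * diff
        d2 = dZ * Z * (1.0 - Z)
        gW2 = Y.T @ d2
        gb2 = d2.sum(axis=0)
        dY = d2 @ W2.T
        if mode == "hidden_output":
            dY = dY + (2.0 / p) * diff  # direct dependence of the loss on Y
        if l1_penalty:
            dY = dY + l1_penalty * np.sign(Y) / Y.size
        d1 = dY * Y * (1.0 - Y)
        gW1 = X.T @ d1
        gb1 = d1.sum(axis=0)

        W1 -= lr * gW1
        b1 -= lr * gb1
        W2 -= lr * gW2
        b2 -= lr * gb2

    Y = _sigmoid(X @ W1 + b1)
    Z = _sigmoid(Y @ W2 + b2)
    features = Z if mode == "hidden_output" else Y
    params = AutoEncoderParams(
        W1, b1, W2, b2, k, epochs, lr, l1_penalty, seed, mode, "sigmoid", losses
    )
    return params, features


@dataclass
class NodeFeatureMatrix:
    """(n + m) x k feature matrix Q: circRNA rows stacked over disease rows."""

    values: np.ndarray
    node_ids: list[str]
    n_circ: int

    def __post_init__(self) -> None:
        self.values = np.asarray(self.values, dtype=float)
        if self.values.shape[0] != len(self.node_ids):
            raise ValueError("row count must match node_ids")
        if not np.isfinite(self.values).all():
            raise ValueError("node features must be finite")


def build_node_features(
    Zc: np.ndarray, Zd: np.ndarray, circ_ids: list[str], disease_ids: list[str]
) -> NodeFeatureMatrix:
    """Row-stack the circRNA feature block over the disease feature block."""
    Zc = np.asarray(Zc, float)
    Zd = np.asarray(Zd, float)
    if Zc.ndim != 2 or Zd.ndim != 2 or Zc.shape[1] != Zd.shape[1]:
        raise ValueError("feature blocks must be 2-D with equal width")
    if Zc.shape[0] < 1 or Zd.shape[0] < 1:
        raise ValueError("both blocks must be non-empty")
    if Zc.shape[0] != len(circ_ids) or Zd.shape[0] != len(disease_ids):
        raise ValueError("block heights must match id lists")
    return NodeFeatureMatrix(
        np.vstack([Zc, Zd]), list(circ_ids) + list(disease_ids), Zc.shape[0]
    )
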