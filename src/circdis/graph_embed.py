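"""Local and global graph embeddings of the heterogeneous network.

Two complementary views of the circRNA-disease network are computed:

* **local**: graph-convolutional propagation of the node features through the
  symmetrically normalised adjacency, ``H^(t+1) = ReLU(A_hat W_t H^(t))``,
  with seeded random (untrained) square weight matrices — a parameter-free
  smoothing of node features over immediate neighbourhoods;
* **global**: second-order biased random walks (return parameter p, in-out
  parameter q) embedded with skip-gram negative sampling, capturing long-range
  community structure that the local view misses on sparse networks.
"""

from __future__ import annotations

from dataclasses import dataclass, field

import numpy as np

from .data_io import HeterogeneousAdjacency
from .features import NodeFeatureMatrix
from .skipgram import train_sgns


@dataclass
class GCNConfig:
    depth: int = 2
    weight_init_seed: int = 0

    def __post_init__(self) -> None:
        if self.depth < 1:
            raise ValueError("depth must be >= 1")


@dataclass
class WalkConfig:
    p: float = 1.0
    q: float = 0.25
    walk_length: int = 80
    num_walks: int = 10
    window: int = 5
    embed_epochs: int = 5
    seed: int = 0

    def __post_init__(self) -> None:
        if self.p <= 0 or self.q <= 0:
            raise ValueError("p and q must be positive")


@dataclass
class EmbeddingMatrix:
    """(n + m) x k node embedding; ``source`` is local, global or fused."""

    values: np.ndarray
    node_ids: list[str]
    source: str

    def __post_init__(self) -> None:
        self.values = np.asarray(self.values, dtype=float)
        if self.values.shape[0] != len(self.node_ids):
            raise ValueError("row count must equal number of nodes")
        if not np.isfinite(self.values).all():
            raise ValueError("embedding entries must be finite")


def normalize_adjacency(X: HeterogeneousAdjacency | np.ndarray) -> np.ndarray:
    """Symmetric normalisation with self-loops: D~^(-1/2) (X + I) D~^(-1/2)."""
    vals = X.values if isinstance(X, HeterogeneousAdjacency) else np.asarray(X, float)
    if vals.ndim != 2 or vals.shape[0] != vals.shape[1]:
        raise ValueError("adjacency must be square")
    Xt = vals + np.eye(vals.shape[0])
    dinv = 1.0 / np.sqrt(Xt.sum(axis=1))  # self-loops make degrees >= 1
    return dinv[:, None] * Xt * dinv[None, :]


def gcn_embed(
    X: HeterogeneousAdjacency, Q: NodeFeatureMatrix, cfg: GCNConfig
) -> EmbeddingMatrix:
    """Depth layers of ReLU(A_hat W H) starting from H^0 = Q; W untrained."""
    if Q.values.shape[0] != X.values.shape[0]:
        raise ValueError("feature rows must match adjacency size")
    A_hat = normalize_adjacency(X)
    nm = A_hat.shape[0]
    rng = np.random.default_rng(cfg.weight_init_seed)
    H = Q.values
    for _ in range(cfg.depth):
        W = rng.standard_normal((nm, nm)) / np.sqrt(nm)
        H = np.maximum(A_hat @ (W @ H), 0.0)
    return EmbeddingMatrix(H, list(X.node_ids), "local")


# ---------------------------------------------------------------------------
# biased second-order walks


def _neighbor_lists(vals: np.ndarray) -> list[np.ndarray]:
    return [np.nonzero(vals[i])[0] for i in range(vals.shape[0])]


def transition_probability(
    X: HeterogeneousAdjacency | np.ndarray,
    t: int,
    v: int,
    x: int,
    p: float,
    q: float,
) -> float:
    """P(next = x | walk came t -> v) under the biased second-order rule.

    The unnormalised weight toward a neighbour x of v is the edge weight
    times 1/p if x == t (distance 0 back to t), 1 if x neighbours t
    (distance 1), and 1/q otherwise (distance 2); non-neighbours of v get 0.
    """
    vals = X.values if isinstance(X, HeterogeneousAdjacency) else np.asarray(X, float)
    if vals[t, v] == 0:
        raise ValueError(f"({t}, {v}) is not an edge")
    nbrs = np.nonzero(vals[v])[0]
    weights = _step_weights(vals, t, v, nbrs, p, q)
    Z = weights.sum()
    hit = np.nonzero(nbrs == x)[0]
    if hit.size == 0:
        return 0.0
    return float(weights[hit[0]] / Z)


def _step_weights(
    vals: np.ndarray, t: int, v: int, nbrs: np.ndarray, p: float, q: float
) -> np.ndarray:
    w = vals[v, nbrs].astype(float)
    alpha = np.full(nbrs.size, 1.0 / q)
    alpha[vals[t, nbrs] > 0] = 1.0
    alpha[nbrs == t] = 1.0 / p
    return w * alpha


def simulate_walks(
    X: HeterogeneousAdjacency | np.ndarray, cfg: WalkConfig
) -> list[list[int]]:
    """Seeded biased walks from every non-isolated node.

    The first step is uniform over neighbours; subsequent steps follow the
    second-order transition rule.  Per-(previous, current) cumulative
    distributions are cached so sampling is a single binary search per step.
    """
    vals = X.values if isinstance(X, HeterogeneousAdjacency) else np.asarray(X, float)
    nbrs = _neighbor_lists(vals)
    starts = [i for i in range(vals.shape[0]) if nbrs[i].size > 0]
    if not starts:
        raise ValueError("graph has no edges")
    rng = np.random.default_rng(cfg.seed)
    cdf_cache: dict[tuple[int, int], np.ndarray] = {}

    def step_cdf(t: int, v: int) -> np.ndarray:
        key = (t, v)
        cdf = cdf_cache.get(key)
        if cdf is None:
            w = _step_weights(vals, t, v, nbrs[v], cfg.p, cfg.q)
            cdf = np.cumsum(w)
            cdf /= cdf[-1]
            cdf_cache[key] = cdf
        return cdf

    walks: list[list[int]] = []
    for _ in range(cfg.num_walks):
        for start in starts:
            walk = [start]
            if cfg.walk_length < 2:
                walks.append(walk)
                continue
            first = nbrs[start]
            cur = int(first[rng.integers(first.size)])
            walk.append(cur)
            prev = start
            while len(walk) < cfg.walk_length:
                cdf = step_cdf(prev, cur)
                nxt = int(nbrs[cur][np.searchsorted(cdf, rng.random())])
                walk.append(nxt)
                prev, cur = cur, nxt
            walks.append(walk)
    return walks


def embed_walks(
    walks: list[list[int]],
    node_ids: list[str],
    k: int = 64,
    window: int = 5,
    epochs: int = 5,
    seed: int = 0,
) -> EmbeddingMatrix:
    """Skip-gram embedding of the walk corpus; isolated nodes get zero rows."""
    vecs = train_sgns(
        walks, n_nodes=len(node_ids), k=k, window=window, epochs=epochs, seed=seed
    )
    return EmbeddingMatrix(vecs, list(node_ids), "global")


def node2vec_embed(
    X: HeterogeneousAdjacency, cfg: WalkConfig, k: int = 64
) -> EmbeddingMatrix:
    walks = simulate_walks(X, cfg)
    return embed_walks(
        walks, list(X.node_ids), k=k, window=cfg.window,
        epochs=cfg.embed_epochs, seed=cfg.seed,
    )
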