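"""Skip-gram with negative sampling (SGNS) over random-walk corpora.

A compact, fully vectorised numpy word2vec: walks are sentences, nodes are
words.  Input vectors are the node embedding; negative contexts are drawn
from the unigram distribution raised to the 3/4 power.  Updates are applied
in seeded, shuffled mini-batches with scatter-add, and the learning rate
decays linearly, so a fixed seed yields bit-identical embeddings.
"""

from __future__ import annotations

import numpy as np


def _sigmoid(x: np.ndarray) -> np.ndarray:
    return 1.0 / (1.0 + np.exp(-np.clip(x, -30.0, 30.0)))


def build_pairs(walks: list[list[int]], window: int) -> tuple[np.ndarray, np.ndarray]:
    """All (center, context) index pairs within ``window`` of each other."""
    centers: list[int] = []
    contexts: list[int] = []
    for walk in walks:
        L = len(walk)
        for pos, node in enumerate(walk):
            lo = max(0, pos - window)
            hi = min(L, pos + window + 1)
            for other in range(lo, hi):
                if other != pos:
                    centers.append(node)
                    contexts.append(walk[other])
    return np.asarray(centers, dtype=np.int64), np.asarray(contexts, dtype=np.int64)


def train_sgns(
    walks: list[list[int]],
    n_nodes: int,
    k: int,
    window: int = 5,
    epochs: int = 5,
    negative: int = 5,
    lr: float = 0.5,
    seed: int = 0,
    batch_size: int = 512,
) -> np.ndarray:
    """Return an (n_nodes, k) embedding; nodes absent from the corpus get zeros."""
    if k < 1:
        raise ValueError("embedding width k must be >= 1")
    if not walks:
        raise ValueError("empty walk corpus")
    centers, contexts = build_pairs(walks, window)
    if centers.size == 0:
        raise ValueError("no skip-gram pairs: walks too short for the window")

    rng = np.random.default_rng(seed)
    W_in = (rng.random((n_nodes, k)) - 0.5) / k
    W_out = np.zeros((n_nodes, k))

    counts = np.bincount(contexts, minlength=n_nodes).astype(float)
    noise = counts**0.75
    noise /= noise.sum()
    noise_cdf = np.cumsum(noise)
    noise_cdf[-1] = 1.0

    n_pairs = centers.size
    total_steps = epochs * n_pairs
    step = 0
    min_lr = lr * 0.05
    for _ in range(epochs):
        order = rng.permutation(n_pairs)
        for start in range(0, n_pairs, batch_size):
            idx = order[start : start + batch_size]
            c = centers[idx]
            o = contexts[idx]
            B = c.size
            neg = np.searchsorted(noise_cdf, rng.random((B, negative)))

            cur_lr = max(min_lr, lr * (1.0 - step / total_steps))
            step += B

            v = W_in[c]  # (B, k)
            u_pos = W_out[o]  # (B, k)
            u_neg = W_out[neg]  # (B, negative, k)

            g_pos = _sigmoid(np.einsum("bk,bk->b", v, u_pos)) - 1.0
            g_neg = _sigmoid(np.einsum("bk,bnk->bn", v, u_neg))

            # a node can occur many times in one batch; average its
            # accumulated gradient so the per-node step stays O(lr)
            cnt_in = np.bincount(c, minlength=n_nodes)[c].astype(float)
            out_idx = np.concatenate([o, neg.reshape(-1)])
            cnt_all = np.bincount(out_idx, minlength=n_nodes)
            grad_v = g_pos[:, None] * u_pos + np.einsum("bn,bnk->bk", g_neg, u_neg)
            np.add.at(W_in, c, -cur_lr * grad_v / cnt_in[:, None])
            np.add.at(
                W_out, o, -cur_lr * (g_pos[:, None] * v) / cnt_all[o, None]
            )
            np.add.at(
                W_out,
                neg.reshape(-1),
                (-cur_lr * (g_neg[..., None] * v[:, None, :])).reshape(-1, k)
                / cnt_all[neg.reshape(-1), None],
            )

    seen = np.zeros(n_nodes, dtype=bool)
    seen[centers] = True
    seen[contexts] = True
    W_in[~seen] = 0.0
    return W_in
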