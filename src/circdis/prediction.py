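"""Embedding fusion, pair feature construction, classifier training and ranking.

The local and global node embeddings are concatenated column-wise into the
fused representation H; a candidate (circRNA, disease) pair is represented by
the concatenation of the two fused node rows and scored by a tree-ensemble
classifier (extremely randomised trees by default) trained on known
associations versus uniformly sampled unknown pairs.
"""

from __future__ import annotations

from dataclasses import dataclass

import numpy as np
from sklearn.ensemble import ExtraTreesClassifier, RandomForestClassifier
from sklearn.linear_model import LogisticRegression
from sklearn.naive_bayes import GaussianNB
from sklearn.neighbors import KNeighborsClassifier

from .data_io import AssociationMatrix
from .graph_embed import EmbeddingMatrix

CLASSIFIERS = ("ET", "RF", "LR", "KNN", "GaussianNB")


def fuse_embeddings(Hl: EmbeddingMatrix, Hg: EmbeddingMatrix) -> EmbeddingMatrix:
    """Column-wise concatenation H = [H_l || H_g], local block first."""
    if Hl.node_ids != Hg.node_ids:
        raise ValueError("embeddings must share node order")
    return EmbeddingMatrix(
        np.hstack([Hl.values, Hg.values]), list(Hl.node_ids), "fused"
    )


def make_pair_features(
    H: EmbeddingMatrix,
    pairs: list[tuple[int, int]],
    n_circ: int,
    mode: str = "concat",
) -> np.ndarray:
    """Feature vector per (circ_index, disease_index) pair.

    ``concat`` stacks the circRNA row and the disease row (width twice the
    embedding); ``hadamard`` takes their elementwise product.
    """
    nm = H.values.shape[0]
    feats = []
    for i, j in pairs:
        if not (0 <= i < n_circ) or not (0 <= n_circ + j < nm):
            raise IndexError(f"pair ({i}, {j}) out of range")
        a, b = H.values[i], H.values[n_circ + j]
        feats.append(np.concatenate([a, b]) if mode == "concat" else a * b)
    return np.asarray(feats)


def sample_negatives(
    A: AssociationMatrix,
    ratio: float = 1.0,
    seed: int = 0,
    exclude: set[tuple[int, int]] | None = None,
    n_positives: int | None = None,
) -> list[tuple[int, int]]:
    """Uniform sample of zero cells of A, without replacement.

    Draws ceil(ratio * n_positives) pairs, excluding ``exclude``.  By default
    n_positives is the number of ones in A.
    """
    exclude = exclude or set()
    if n_positives is None:
        n_positives = int(A.values.sum())
    want = int(np.ceil(ratio * n_positives))
    zi, zj = np.nonzero(A.values == 0)
    candidates = [
        (int(i), int(j)) for i, j in zip(zi, zj) if (int(i), int(j)) not in exclude
    ]
    if len(candidates) < want:
        raise ValueError(
            f"only {len(candidates)} unknown cells available, need {want}"
        )
    rng = np.random.default_rng(seed)
    idx = rng.choice(len(candidates), size=want, replace=False)
    return [candidates[i] for i in sorted(idx)]


@dataclass
class PairDataset:
    pairs: list[tuple[int, int]]
    features: np.ndarray
    labels: np.ndarray

    def __post_init__(self) -> None:
        self.labels = np.asarray(self.labels)
        if len(self.pairs) != self.features.shape[0] or len(self.pairs) != self.labels.size:
            raise ValueError("pairs, features and labels must align")


@dataclass
class TrainedModel:
    kind: str
    estimator: object
    seed: int

    def score_pairs(self, features: np.ndarray) -> np.ndarray:
        """Posterior probability of association, in [0, 1]."""
        proba = self.estimator.predict_proba(features)
        pos = list(self.estimator.classes_).index(1)
        return proba[:, pos]


def _make_estimator(kind: str, seed: int):
    if kind == "ET":
        return ExtraTreesClassifier(random_state=seed, n_jobs=1)
    if kind == "RF":
        return RandomForestClassifier(random_state=seed, n_jobs=1)
    if kind == "LR":
        return LogisticRegression(random_state=seed, max_iter=1000)
    if kind == "KNN":
        return KNeighborsClassifier()
    if kind == "GaussianNB":
        return GaussianNB()
    raise ValueError(f"unknown classifier kind {kind!r}; choose from {CLASSIFIERS}")


def train_classifier(ds: PairDataset, kind: str = "ET", seed: int = 0) -> TrainedModel:
    labels = np.unique(ds.labels)
    if labels.size < 2:
        raise ValueError("training data must contain both classes")
    est = _make_estimator(kind, seed)
    est.fit(ds.features, ds.labels)
    return TrainedModel(kind, est, seed)


def rank_for_disease(
    model: TrainedModel,
    H: EmbeddingMatrix,
    A: AssociationMatrix,
    disease_id: str,
    top_k: int = 10,
    pair_mode: str = "concat",
) -> list[tuple[str, float]]:
    """Top-k candidate circRNAs for a disease, excluding known associations.

    Ties in score break lexicographically on circRNA identifier.
    """
    if disease_id not in A.disease_ids:
        raise KeyError(f"unknown disease {disease_id!r}")
    j = A.disease_ids.index(disease_id)
    candidates = [i for i in range(A.n_circ) if A.values[i, j] == 0]
    if not candidates:
        return []
    feats = make_pair_features(H, [(i, j) for i in candidates], A.n_circ, pair_mode)
    scores = model.score_pairs(feats)
    order = sorted(
        range(len(candidates)), key=lambda k: (-scores[k], A.circ_ids[candidates[k]])
    )
    return [(A.circ_ids[candidates[k]], float(scores[k])) for k in order[:top_k]]
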