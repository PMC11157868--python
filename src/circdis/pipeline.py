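"""End-to-end orchestration: similarities -> features -> embeddings -> classifier.

Every stochastic stage draws its seed from one master seed through
``numpy.random.SeedSequence`` fan-out, so a full run is bit-reproducible, and
all training-side artifacts are computed from the training association
matrix only (test-fold positives zeroed) so cross-validation is leakage-free.
"""

from __future__ import annotations

from dataclasses import dataclass

import numpy as np

from .data_io import AssociationMatrix, DiseaseOntology
from .features import build_node_features, train_autoencoder
from .graph_embed import (
    EmbeddingMatrix,
    GCNConfig,
    WalkConfig,
    gcn_embed,
    node2vec_embed,
)
from .prediction import (
    PairDataset,
    TrainedModel,
    fuse_embeddings,
    make_pair_features,
    sample_negatives,
    train_classifier,
)
from .similarity import build_heterogeneous_adjacency, gip_kernel, integrate_similarity
from .similarity import circrna_functional_similarity, disease_semantic_similarity


@dataclass(frozen=True)
class PipelineConfig:
    """All tunable knobs with the library defaults.

    ``k`` must not exceed min(n_circRNAs, n_diseases) (auto-encoder hidden
    width cannot exceed its input dimension); pick a smaller k for small
    datasets.
    """

    gamma: float = 0.5
    k: int = 64
    ae_epochs: int = 200
    ae_lr: float = 1e-3
    ae_l1: float = 0.0
    ae_mode: str = "hidden_output"
    gcn_depth: int = 2
    p: float = 1.0
    q: float = 0.25
    num_walks: int = 10
    walk_length: int = 80
    window: int = 5
    embed_epochs: int = 5
    neg_ratio: float = 1.0
    classifier: str = "ET"
    pair_mode: str = "concat"
    threshold: float = 0.5
    gip_scope: str = "fold"  # "fold": kernels from training positives only


def fan_out(master_seed: int, n: int) -> list[int]:
    """n reproducible child seeds (each < 2**31) from one master seed."""
    ss = np.random.SeedSequence(master_seed)
    return [int(s % (2**31)) for s in ss.generate_state(n, dtype=np.uint64)]


@dataclass
class FoldArtifacts:
    """Everything derived from the training split of one CV fold."""

    A_train: AssociationMatrix
    Hl: EmbeddingMatrix
    Hg: EmbeddingMatrix
    H: EmbeddingMatrix
    train_pos: list[tuple[int, int]]
    train_neg: list[tuple[int, int]]


def build_embeddings(
    A_train: AssociationMatrix,
    ontology: DiseaseOntology,
    cfg: PipelineConfig,
    seed: int,
    A_gip: AssociationMatrix | None = None,
) -> tuple[EmbeddingMatrix, EmbeddingMatrix, EmbeddingMatrix]:
    """(H_l, H_g, H) from training associations and the disease ontology.

    ``A_gip`` overrides the matrix the GIP kernels are computed from (used
    only for the explicitly leakage-unsafe ``gip_scope="global"`` mode).
    """
    seeds = fan_out(seed, 4)
    if A_gip is None:
        A_gip = A_train
    DS = disease_semantic_similarity(ontology, list(A_train.disease_ids), cfg.gamma)
    FS = circrna_functional_similarity(A_train, DS)
    CK = gip_kernel(A_gip, "circRNA")
    DK = gip_kernel(A_gip, "disease")
    Xc = integrate_similarity(FS, CK)
    Xd = integrate_similarity(DS, DK)

    _, Zc = train_autoencoder(
        Xc, cfg.k, cfg.ae_epochs, cfg.ae_lr, cfg.ae_l1, seeds[0], cfg.ae_mode
    )
    _, Zd = train_autoencoder(
        Xd, cfg.k, cfg.ae_epochs, cfg.ae_lr, cfg.ae_l1, seeds[1], cfg.ae_mode
    )
    Q = build_node_features(Zc, Zd, list(A_train.circ_ids), list(A_train.disease_ids))

    X = build_heterogeneous_adjacency(A_train)
    Hl = gcn_embed(X, Q, GCNConfig(depth=cfg.gcn_depth, weight_init_seed=seeds[2]))
    wcfg = WalkConfig(
        p=cfg.p,
        q=cfg.q,
        walk_length=cfg.walk_length,
        num_walks=cfg.num_walks,
        window=cfg.window,
        embed_epochs=cfg.embed_epochs,
        seed=seeds[3],
    )
    Hg = node2vec_embed(X, wcfg, k=cfg.k)
    return Hl, Hg, fuse_embeddings(Hl, Hg)


def fold_artifacts(
    A: AssociationMatrix,
    ontology: DiseaseOntology,
    test_pairs: list[tuple[int, int]],
    cfg: PipelineConfig,
    seed: int,
) -> FoldArtifacts:
    """Training-side artifacts of one fold; independent of test positives."""
    seeds = fan_out(seed, 2)
    A_train = A.mask_pairs(test_pairs)
    A_gip = A if cfg.gip_scope == "global" else None
    Hl, Hg, H = build_embeddings(A_train, ontology, cfg, seeds[0], A_gip=A_gip)
    train_pos = A_train.positive_pairs()
    # negatives come from the TRAINING matrix's zero cells so that nothing on
    # the training side can depend on which cells hold test positives
    train_neg = sample_negatives(A_train, cfg.neg_ratio, seeds[1])
    return FoldArtifacts(A_train, Hl, Hg, H, train_pos, train_neg)


def embedding_for_scheme(art: FoldArtifacts, scheme: str) -> EmbeddingMatrix:
    try:
        return {"local_only": art.Hl, "global_only": art.Hg, "both": art.H}[scheme]
    except KeyError:
        raise ValueError(f"unknown scheme {scheme!r}") from None


def train_fold_model(
    art: FoldArtifacts, cfg: PipelineConfig, scheme: str, seed: int
) -> TrainedModel:
    emb = embedding_for_scheme(art, scheme)
    n = art.A_train.n_circ
    pairs = art.train_pos + art.train_neg
    feats = make_pair_features(emb, pairs, n, cfg.pair_mode)
    labels = np.r_[np.ones(len(art.train_pos)), np.zeros(len(art.train_neg))]
    ds = PairDataset(pairs, feats, labels)
    return train_classifier(ds, cfg.classifier, seed)


def fit_full(
    A: AssociationMatrix,
    ontology: DiseaseOntology,
    cfg: PipelineConfig,
    master_seed: int = 0,
) -> tuple[TrainedModel, FoldArtifacts]:
    """Train on the complete association matrix (no held-out fold)."""
    seeds = fan_out(master_seed, 2)
    art = fold_artifacts(A, ontology, [], cfg, seeds[0])
    model = train_fold_model(art, cfg, "both", seeds[1])
    return model, art


def score_all_unknown(
    model: TrainedModel,
    art: FoldArtifacts,
    A: AssociationMatrix,
    cfg: PipelineConfig,
    scheme: str = "both",
) -> list[tuple[str, str, float]]:
    """Scores for every unknown (circRNA, disease) cell of A."""
    emb = embedding_for_scheme(art, scheme)
    zi, zj = np.nonzero(A.values == 0)
    pairs = list(zip(zi.tolist(), zj.tolist()))
    feats = make_pair_features(emb, pairs, A.n_circ, cfg.pair_mode)
    scores = model.score_pairs(feats)
    return [
        (A.circ_ids[i], A.disease_ids[j], float(s))
        for (i, j), s in zip(pairs, scores)
    ]
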