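"""Metrics, repeated stratified cross-validation and the ablation harness.

Cross-validation partitions the known positive pairs into disjoint folds;
for each fold every training-side artifact (similarities, heterogeneous
network, embeddings, negative sample, classifier) is rebuilt from the
training positives only, and the held-out positives are scored against an
equal-sized sample of unknown pairs.
"""

from __future__ import annotations

from dataclasses import dataclass, field

import numpy as np
import pandas as pd
from sklearn.metrics import average_precision_score, roc_auc_score

from .data_io import AssociationMatrix, DiseaseOntology
from .pipeline import (
    PipelineConfig,
    embedding_for_scheme,
    fan_out,
    fold_artifacts,
    train_fold_model,
)
from .prediction import make_pair_features, sample_negatives

METRIC_NAMES = ("accuracy", "sensitivity", "specificity", "precision", "mcc", "auroc", "aupr")


@dataclass
class MetricSet:
    accuracy: float
    sensitivity: float
    specificity: float
    precision: float
    mcc: float
    auroc: float
    aupr: float

    def as_array(self) -> np.ndarray:
        return np.array([getattr(self, name) for name in METRIC_NAMES])


def compute_metrics(labels, scores, threshold: float = 0.5) -> MetricSet:
    """Confusion-matrix metrics at ``threshold`` plus AUROC and AUPR.

    AUROC is the probability that a random positive outscores a random
    negative (ties count one half); AUPR integrates the precision-recall
    step curve.  Degenerate ratios (zero denominators, including the MCC
    denominator) resolve to 0 by convention.
    """
    labels = np.asarray(labels)
    scores = np.asarray(scores, dtype=float)
    if labels.shape != scores.shape:
        raise ValueError("labels and scores must have the same length")
    if not np.isin(labels, (0, 1)).all():
        raise ValueError("labels must be binary")
    if labels.min() == labels.max():
        raise ValueError("both classes must be present")
    pred = (scores >= threshold).astype(int)
    tp = int(((pred == 1) & (labels == 1)).sum())
    tn = int(((pred == 0) & (labels == 0)).sum())
    fp = int(((pred == 1) & (labels == 0)).sum())
    fn = int(((pred == 0) & (labels == 1)).sum())

    def ratio(num, den):
        return num / den if den else 0.0

    denom = (tp + fp) * (tp + fn) * (tn + fp) * (tn + fn)
    mcc = (tp * tn - fp * fn) / np.sqrt(denom) if denom else 0.0
    return MetricSet(
        accuracy=ratio(tp + tn, tp + tn + fp + fn),
        sensitivity=ratio(tp, tp + fn),
        specificity=ratio(tn, tn + fp),
        precision=ratio(tp, tp + fp),
        mcc=float(mcc),
        auroc=float(roc_auc_score(labels, scores)),
        aupr=float(average_precision_score(labels, scores)),
    )


@dataclass
class CVReport:
    per_fold: list[MetricSet]
    scheme: str
    classifier: str
    folds: int
    repeats: int
    master_seed: int
    mean: MetricSet = field(init=False)
    std: MetricSet = field(init=False)

    def __post_init__(self) -> None:
        arr = np.array([m.as_array() for m in self.per_fold])
        self.mean = MetricSet(*arr.mean(axis=0))
        self.std = MetricSet(*arr.std(axis=0, ddof=0))

    def to_dataframe(self) -> pd.DataFrame:
        rows = [m.as_array() for m in self.per_fold]
        df = pd.DataFrame(rows, columns=METRIC_NAMES)
        df.index.name = "fold_run"
        return df

    def render_table(self) -> str:
        """Per-fold rows plus a mean +/- std summary row, 4 decimals."""
        df = self.to_dataframe().round(4)
        summary = {
            name: f"{getattr(self.mean, name):.4f} ± {getattr(self.std, name):.4f}"
            for name in METRIC_NAMES
        }
        lines = ["fold_run\t" + "\t".join(METRIC_NAMES)]
        for idx, row in df.iterrows():
            lines.append(str(idx) + "\t" + "\t".join(f"{v:.4f}" for v in row))
        lines.append("mean\t" + "\t".join(summary[n] for n in METRIC_NAMES))
        return "\n".join(lines)

    def write_tsv(self, path) -> None:
        with open(path, "w", encoding="utf-8") as fh:
            fh.write(self.render_table() + "\n")


def _fold_partitions(
    positives: list[tuple[int, int]], folds: int, rng: np.random.Generator
) -> list[list[tuple[int, int]]]:
    order = rng.permutation(len(positives))
    return [
        [positives[i] for i in chunk] for chunk in np.array_split(order, folds)
    ]


def _evaluate_scheme(
    art,
    A: AssociationMatrix,
    test_pairs: list[tuple[int, int]],
    cfg: PipelineConfig,
    scheme: str,
    clf_seed: int,
    test_neg: list[tuple[int, int]],
    threshold: float,
) -> MetricSet:
    model = train_fold_model(art, cfg, scheme, clf_seed)
    emb = embedding_for_scheme(art, scheme)
    pairs = list(test_pairs) + list(test_neg)
    feats = make_pair_features(emb, pairs, A.n_circ, cfg.pair_mode)
    labels = np.r_[np.ones(len(test_pairs)), np.zeros(len(test_neg))]
    return compute_metrics(labels, model.score_pairs(feats), threshold)


def _run_cv(
    A: AssociationMatrix,
    ontology: DiseaseOntology,
    cfg: PipelineConfig,
    folds: int,
    repeats: int,
    schemes: tuple[str, ...],
    master_seed: int,
) -> dict[str, list[MetricSet]]:
    positives = A.positive_pairs()
    if len(positives) < folds:
        raise ValueError(f"need at least {folds} positives, have {len(positives)}")
    results: dict[str, list[MetricSet]] = {s: [] for s in schemes}
    repeat_seeds = fan_out(master_seed, repeats)
    for rep_seed in repeat_seeds:
        seeds = fan_out(rep_seed, 1 + 3 * folds)
        rng = np.random.default_rng(seeds[0])
        parts = _fold_partitions(positives, folds, rng)
        for f, test_pairs in enumerate(parts):
            art_seed, neg_seed, clf_seed = seeds[1 + 3 * f : 4 + 3 * f]
            art = fold_artifacts(A, ontology, test_pairs, cfg, art_seed)
            # held-out negatives: unknown cells of the full matrix, disjoint
            # from the training negatives
            test_neg = sample_negatives(
                A,
                ratio=1.0,
                seed=neg_seed,
                exclude=set(art.train_neg),
                n_positives=len(test_pairs),
            )
            for scheme in schemes:
                results[scheme].append(
                    _evaluate_scheme(
                        art, A, test_pairs, cfg, scheme, clf_seed, test_neg,
                        cfg.threshold,
                    )
                )
    return results


def cross_validate(
    A: AssociationMatrix,
    ontology: DiseaseOntology,
    cfg: PipelineConfig | None = None,
    folds: int = 5,
    repeats: int = 10,
    scheme: str = "both",
    master_seed: int = 0,
) -> CVReport:
    """Repeated k-fold CV over positive pairs; returns per-fold-run metrics."""
    cfg = cfg or PipelineConfig()
    res = _run_cv(A, ontology, cfg, folds, repeats, (scheme,), master_seed)
    return CVReport(res[scheme], scheme, cfg.classifier, folds, repeats, master_seed)


def run_ablation(
    A: AssociationMatrix,
    ontology: DiseaseOntology,
    cfg: PipelineConfig | None = None,
    folds: int = 5,
    repeats: int = 1,
    master_seed: int = 0,
) -> dict[str, CVReport]:
    """Paired comparison of local-only / global-only / fused embeddings.

    All three schemes share identical fold partitions, per-fold embeddings,
    negative samples and classifier seeds, so differences are attributable
    to the embedding alone.
    """
    cfg = cfg or PipelineConfig()
    schemes = ("local_only", "global_only", "both")
    res = _run_cv(A, ontology, cfg, folds, repeats, schemes, master_seed)
    return {
        s: CVReport(res[s], s, cfg.classifier, folds, repeats, master_seed)
        for s in schemes
    }
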