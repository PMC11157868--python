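"""Similarity networks over circRNAs and diseases, and the heterogeneous adjacency.

Four networks feed the pipeline:

* disease semantic similarity ``DS`` from shared-ancestor contributions in the
  disease ontology DAG with decay factor gamma;
* circRNA functional similarity ``FS``: average best-match ``DS`` between the
  disease sets of two circRNAs;
* Gaussian interaction profile (GIP) kernels ``CK``/``DK`` over the rows /
  columns of the binary association matrix, with a bandwidth normalised by the
  mean squared profile norm;
* the integrated networks ``Xc``/``Xd`` that take the semantic/functional value
  where it is non-zero and fall back to the GIP kernel elsewhere.
"""

from __future__ import annotations

import warnings

import numpy as np
from scipy.spatial.distance import squareform, pdist

from .data_io import (
    AssociationMatrix,
    DiseaseOntology,
    HeterogeneousAdjacency,
    SimilarityMatrix,
)


class SemanticContribution:
    """Semantic contribution of every ancestor of a target disease.

    ``contributions[d]`` is 1 for the target itself and otherwise the maximum
    over children of ``d`` inside the ancestor closure of gamma times the
    child's contribution — i.e. gamma raised to the shortest downward DAG
    distance from ``d`` to the target (for gamma <= 1).
    """

    def __init__(self, target: str, contributions: dict[str, float], gamma: float):
        self.target = target
        self.contributions = contributions
        self.gamma = gamma

    def semantic_value(self) -> float:
        """Sum of contributions over the ancestor closure; always >= 1."""
        return float(sum(self.contributions.values()))


def semantic_contribution(
    ontology: DiseaseOntology, d_i: str, gamma: float = 0.5
) -> SemanticContribution:
    if d_i not in ontology.terms:
        raise KeyError(f"unknown disease term {d_i!r}")
    closure = ontology.ancestor_set(d_i)
    memo: dict[str, float] = {d_i: 1.0}

    def sc(d: str) -> float:
        if d in memo:
            return memo[d]
        kids = [c for c in ontology.children(d) if c in closure]
        memo[d] = max(gamma * sc(c) for c in kids)
        return memo[d]

    for d in closure:
        sc(d)
    return SemanticContribution(d_i, memo, gamma)


def semantic_value(sc: SemanticContribution) -> float:
    return sc.semantic_value()


def disease_semantic_similarity(
    ontology: DiseaseOntology, diseases: list[str], gamma: float = 0.5
) -> SimilarityMatrix:
    """Pairwise semantic similarity over ``diseases``.

    DS(d_i, d_j) sums the contributions of shared ancestors from both sides
    and normalises by the two semantic values, giving 1 on the diagonal and 0
    for terms with disjoint ancestor closures.  A disease absent from the
    ontology is treated as an isolated term (closure = itself) with a
    warning; the GIP fallback of the integration step covers such rows.
    """
    scs: dict[str, SemanticContribution] = {}
    for d in diseases:
        if d in ontology.terms:
            scs[d] = semantic_contribution(ontology, d, gamma)
        else:
            warnings.warn(
                f"disease {d!r} missing from ontology; treating as isolated term",
                stacklevel=2,
            )
            scs[d] = SemanticContribution(d, {d: 1.0}, gamma)
    m = len(diseases)
    out = np.zeros((m, m))
    sv = {d: scs[d].semantic_value() for d in diseases}
    for i, di in enumerate(diseases):
        ci = scs[di].contributions
        for j in range(i, m):
            dj = diseases[j]
            cj = scs[dj].contributions
            shared = ci.keys() & cj.keys()
            if shared:
                num = sum(ci[d] + cj[d] for d in shared)
                out[i, j] = out[j, i] = num / (sv[di] + sv[dj])
    return SimilarityMatrix(out, list(diseases), "DS")


def circrna_functional_similarity(
    A: AssociationMatrix, DS: SimilarityMatrix
) -> SimilarityMatrix:
    """Best-match functional similarity between circRNAs' disease sets.

    For circRNAs with disease sets T_i (size r) and T_j (size l), each
    disease in T_i is scored by its best semantic match in T_j and vice
    versa; the score is the grand sum divided by r + l.  Either set empty
    gives 0, identical non-empty sets give 1.
    """
    idx = {d: k for k, d in enumerate(DS.ids)}
    missing = [d for d in A.disease_ids if d not in idx]
    if missing:
        raise ValueError(f"DS does not cover diseases {missing}")
    cols = np.array([idx[d] for d in A.disease_ids])
    ds = DS.values[np.ix_(cols, cols)]
    sets = [np.nonzero(row)[0] for row in A.values]
    n = A.n_circ
    out = np.zeros((n, n))
    for i in range(n):
        ti = sets[i]
        if ti.size == 0:
            continue
        for j in range(i, n):
            tj = sets[j]
            if tj.size == 0:
                continue
            block = ds[np.ix_(ti, tj)]
            score = block.max(axis=1).sum() + block.max(axis=0).sum()
            out[i, j] = out[j, i] = score / (ti.size + tj.size)
    np.clip(out, 0.0, 1.0, out=out)
    return SimilarityMatrix(out, list(A.circ_ids), "FS")


def gip_kernel(A: AssociationMatrix, axis: str = "circRNA") -> SimilarityMatrix:
    """Gaussian interaction profile kernel over rows (circRNAs) or columns.

    K(u, v) = exp(-lam * ||profile_u - profile_v||^2) with the bandwidth
    lam = p / sum_u ||profile_u||^2 for p profiles, so the kernel adapts to
    the overall density of the association matrix.
    """
    if axis == "circRNA":
        profiles = A.values.astype(float)
        ids = list(A.circ_ids)
        kind = "CK"
    elif axis == "disease":
        profiles = A.values.T.astype(float)
        ids = list(A.disease_ids)
        kind = "DK"
    else:
        raise ValueError(f"axis must be 'circRNA' or 'disease', got {axis!r}")
    norm_sum = float((profiles**2).sum())
    if norm_sum == 0.0:
        raise ValueError("all-zero association matrix: GIP bandwidth undefined")
    lam = profiles.shape[0] / norm_sum
    sq = squareform(pdist(profiles, metric="sqeuclidean"))
    K = np.exp(-lam * sq)
    np.fill_diagonal(K, 1.0)
    return SimilarityMatrix(K, ids, kind)


def integrate_similarity(
    primary: SimilarityMatrix, fallback: SimilarityMatrix, kind: str = ""
) -> SimilarityMatrix:
    """Elementwise: primary where non-zero, else fallback."""
    if primary.values.shape != fallback.values.shape:
        raise ValueError("shape mismatch between primary and fallback")
    if primary.ids != fallback.ids:
        raise ValueError("id order mismatch between primary and fallback")
    vals = np.where(primary.values != 0, primary.values, fallback.values)
    if not kind:
        kind = {"FS": "Xc", "DS": "Xd"}.get(primary.kind, "")
    return SimilarityMatrix(vals, list(primary.ids), kind)


def build_heterogeneous_adjacency(A: AssociationMatrix) -> HeterogeneousAdjacency:
    """X = [[0, A], [A^T, 0]] with circRNA nodes first."""
    n, m = A.values.shape
    X = np.zeros((n + m, n + m))
    X[:n, n:] = A.values
    X[n:, :n] = A.values.T
    return HeterogeneousAdjacency(X, list(A.circ_ids) + list(A.disease_ids), n)


def integrated_similarities(
    A: AssociationMatrix, ontology: DiseaseOntology, gamma: float = 0.5
) -> tuple[SimilarityMatrix, SimilarityMatrix]:
    """Convenience: build Xc and Xd from associations and the ontology."""
    DS = disease_semantic_similarity(ontology, list(A.disease_ids), gamma)
    FS = circrna_functional_similarity(A, DS)
    CK = gip_kernel(A, "circRNA")
    DK = gip_kernel(A, "disease")
    return integrate_similarity(FS, CK), integrate_similarity(DS, DK)
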