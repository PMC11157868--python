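"""Core matrix containers, text I/O and the synthetic fixture generator.

All external interchange uses small plain-text formats: two-column TSV/CSV
for association lists and ontology edge lists, dense TSV (with id header
row/column) or MatrixMarket for similarity matrices, three-column TSV for
score rankings.
"""

from __future__ import annotations

import math
from dataclasses import dataclass, field

import networkx as nx
import numpy as np
import pandas as pd
import scipy.io
import scipy.sparse


class ParseError(ValueError):
    """Raised when an input text table cannot be parsed; names the line."""


@dataclass
class AssociationMatrix:
    """Binary circRNA x disease association matrix.

    ``values[i, j] == 1`` means circRNA ``circ_ids[i]`` has a known,
    experimentally validated association with disease ``disease_ids[j]``;
    0 means the pair is unobserved (not a verified negative).
    """

    values: np.ndarray
    circ_ids: list[str]
    disease_ids: list[str]

    def __post_init__(self) -> None:
        self.values = np.asarray(self.values)
        if self.values.ndim != 2:
            raise ValueError("association matrix must be 2-D")
        n, m = self.values.shape
        if n < 1 or m < 1:
            raise ValueError("need at least one circRNA and one disease")
        if len(self.circ_ids) != n or len(self.disease_ids) != m:
            raise ValueError("id lists must match matrix shape")
        if len(set(self.circ_ids)) != n or len(set(self.disease_ids)) != m:
            raise ValueError("duplicate identifiers")
        if not np.isin(self.values, (0, 1)).all():
            raise ValueError("entries must be 0 or 1")
        self.values = self.values.astype(np.int8)

    @property
    def n_circ(self) -> int:
        return self.values.shape[0]

    @property
    def n_disease(self) -> int:
        return self.values.shape[1]

    def positive_pairs(self) -> list[tuple[int, int]]:
        """Index pairs (circ_index, disease_index) of known associations."""
        rows, cols = np.nonzero(self.values)
        return list(zip(rows.tolist(), cols.tolist()))

    def mask_pairs(self, pairs) -> "AssociationMatrix":
        """Copy with the given (circ_index, disease_index) cells zeroed.

        Used to hide test-fold positives from every training-side
        computation during cross-validation.
        """
        vals = self.values.copy()
        for i, j in pairs:
            vals[i, j] = 0
        return AssociationMatrix(vals, list(self.circ_ids), list(self.disease_ids))


@dataclass
class DiseaseOntology:
    """Rooted DAG of disease terms with child -> parent edges."""

    terms: set[str]
    edges: set[tuple[str, str]]
    _graph: nx.DiGraph = field(init=False, repr=False)

    def __post_init__(self) -> None:
        for child, parent in self.edges:
            if child not in self.terms or parent not in self.terms:
                raise ValueError(f"edge endpoint not in terms: ({child}, {parent})")
            if child == parent:
                raise ValueError(f"self-loop on term {child!r}")
        g = nx.DiGraph()
        g.add_nodes_from(self.terms)
        g.add_edges_from(self.edges)  # child -> parent direction
        if not nx.is_directed_acyclic_graph(g):
            cycle = nx.find_cycle(g)
            raise ValueError(f"ontology contains a cycle: {cycle}")
        self._graph = g

    def parents(self, term: str) -> set[str]:
        return set(self._graph.successors(term))

    def children(self, term: str) -> set[str]:
        return set(self._graph.predecessors(term))

    def ancestor_set(self, term: str) -> set[str]:
        """T_d: the term itself plus all of its ancestors."""
        if term not in self.terms:
            raise KeyError(term)
        return {term} | nx.descendants(self._graph, term)


@dataclass
class SimilarityMatrix:
    """Square symmetric similarity matrix with entries in [0, 1].

    ``kind`` records which network the matrix holds: disease semantic (DS),
    circRNA functional (FS), Gaussian interaction profile kernels (CK/DK) or
    the integrated networks (Xc/Xd).
    """

    values: np.ndarray
    ids: list[str]
    kind: str = ""

    _KINDS = {"DS", "FS", "CK", "DK", "Xc", "Xd", ""}

    def __post_init__(self) -> None:
        self.values = np.asarray(self.values, dtype=float)
        p = len(self.ids)
        if self.values.shape != (p, p):
            raise ValueError("similarity matrix must be square and match ids")
        if self.kind not in self._KINDS:
            raise ValueError(f"unknown kind {self.kind!r}")
        if not np.allclose(self.values, self.values.T, atol=1e-12):
            raise ValueError("similarity matrix must be symmetric")
        if self.values.min() < -1e-12 or self.values.max() > 1 + 1e-12:
            raise ValueError("similarity entries must lie in [0, 1]")


@dataclass
class HeterogeneousAdjacency:
    """Block adjacency [[0, A], [A^T, 0]] of the circRNA-disease network.

    Node order is circRNAs first then diseases, so node n+j is disease j.
    """

    values: np.ndarray
    node_ids: list[str]
    n_circ: int

    def __post_init__(self) -> None:
        self.values = np.asarray(self.values, dtype=float)
        nm = len(self.node_ids)
        if self.values.shape != (nm, nm):
            raise ValueError("adjacency must be square and match node_ids")
        n = self.n_circ
        if self.values[:n, :n].any() or self.values[n:, n:].any():
            raise ValueError("within-type blocks must be zero")
        if not np.array_equal(self.values, self.values.T):
            raise ValueError("adjacency must be symmetric")


# ---------------------------------------------------------------------------
# text I/O


def _iter_rows(path, delimiter: str):
    with open(path, encoding="utf-8") as fh:
        for lineno, line in enumerate(fh, start=1):
            line = line.rstrip("\n").rstrip("\r")
            if not line.strip():
                continue
            yield lineno, [f.strip() for f in line.split(delimiter)]


def load_association_list(
    path, dialect: str = "tsv", header: bool = False
) -> AssociationMatrix:
    """Read a two-column (circRNA, disease) table into an AssociationMatrix.

    Duplicate rows collapse to a single association.  Identifiers are sorted
    lexicographically so that matrix layout is deterministic regardless of
    file order.
    """
    delim = {"tsv": "\t", "csv": ","}[dialect]
    pairs: set[tuple[str, str]] = set()
    first = header
    n_rows = 0
    for lineno, fields in _iter_rows(path, delim):
        if first:
            first = False
            continue
        fields = [f for f in fields if f]
        if len(fields) < 2:
            raise ParseError(f"{path}: line {lineno}: expected two columns")
        pairs.add((fields[0], fields[1]))
        n_rows += 1
    if n_rows == 0:
        raise ParseError(f"{path}: no data rows")
    circ_ids = sorted({c for c, _ in pairs})
    disease_ids = sorted({d for _, d in pairs})
    ci = {c: i for i, c in enumerate(circ_ids)}
    di = {d: j for j, d in enumerate(disease_ids)}
    values = np.zeros((len(circ_ids), len(disease_ids)), dtype=np.int8)
    for c, d in pairs:
        values[ci[c], di[d]] = 1
    return AssociationMatrix(values, circ_ids, disease_ids)


def write_association_list(assoc: AssociationMatrix, path, dialect: str = "tsv") -> None:
    """Write one (circRNA, disease) row per known association, sorted."""
    delim = {"tsv": "\t", "csv": ","}[dialect]
    with open(path, "w", encoding="utf-8") as fh:
        for i, j in sorted(assoc.positive_pairs()):
            fh.write(f"{assoc.circ_ids[i]}{delim}{assoc.disease_ids[j]}\n")


def load_disease_ontology(path) -> DiseaseOntology:
    """Read a child<TAB>parent edge list; single-field rows declare isolated terms."""
    terms: set[str] = set()
    edges: set[tuple[str, str]] = set()
    for lineno, fields in _iter_rows(path, "\t"):
        fields = [f for f in fields if f]
        if len(fields) == 1:
            terms.add(fields[0])
        elif len(fields) >= 2:
            child, parent = fields[0], fields[1]
            if child == parent:
                raise ParseError(f"{path}: line {lineno}: self-loop on {child!r}")
            terms.update((child, parent))
            edges.add((child, parent))
        else:
            raise ParseError(f"{path}: line {lineno}: empty row")
    return DiseaseOntology(terms, edges)


def write_disease_ontology(ontology: DiseaseOntology, path) -> None:
    with open(path, "w", encoding="utf-8") as fh:
        attached = {c for c, _ in ontology.edges} | {p for _, p in ontology.edges}
        for child, parent in sorted(ontology.edges):
            fh.write(f"{child}\t{parent}\n")
        for term in sorted(ontology.terms - attached):
            fh.write(f"{term}\n")


def write_similarity(sim: SimilarityMatrix, path, fmt: str = "tsv") -> None:
    """Dense TSV (ids as header row and column) or MatrixMarket."""
    if fmt == "tsv":
        pd.DataFrame(sim.values, index=sim.ids, columns=sim.ids).to_csv(path, sep="\t")
    elif fmt == "mtx":
        scipy.io.mmwrite(str(path), scipy.sparse.coo_matrix(sim.values))
    else:
        raise ValueError(f"unknown format {fmt!r}")


def load_similarity(path, kind: str = "", fmt: str = "tsv", ids=None) -> SimilarityMatrix:
    if fmt == "tsv":
        df = pd.read_csv(path, sep="\t", index_col=0)
        return SimilarityMatrix(df.to_numpy(float), [str(c) for c in df.columns], kind)
    if fmt == "mtx":
        vals = np.asarray(scipy.io.mmread(str(path)).todense(), dtype=float)
        if ids is None:
            ids = [str(i) for i in range(vals.shape[0])]
        return SimilarityMatrix(vals, list(ids), kind)
    raise ValueError(f"unknown format {fmt!r}")


def write_scores(pairs, path) -> None:
    """Serialize (circ_id, disease_id, score) triples as a ranked TSV.

    Rows are sorted by descending score; ties break lexicographically on
    (circ_id, disease_id) so output is reproducible.
    """
    for c, d, s in pairs:
        if not (0.0 <= s <= 1.0):
            raise ValueError(f"score out of [0, 1] for ({c}, {d}): {s}")
    ordered = sorted(pairs, key=lambda r: (-r[2], r[0], r[1]))
    with open(path, "w", encoding="utf-8") as fh:
        fh.write("circRNA\tdisease\tscore\n")
        for c, d, s in ordered:
            fh.write(f"{c}\t{d}\t{s:.17g}\n")


# ---------------------------------------------------------------------------
# synthetic fixtures


def generate_synthetic_dataset(
    n: int,
    m: int,
    n_pos: int,
    latent_rank: int = 3,
    dag_depth: int = 4,
    seed: int = 0,
    extra_edge_fraction: float = 0.15,
) -> tuple[AssociationMatrix, DiseaseOntology]:
    """Planted low-rank association matrix plus a random rooted disease DAG.

    Latent scores are the product of two non-negative random factor matrices
    of rank ``latent_rank``; the ``n_pos`` highest-scoring cells become the
    known positives, so the positive set carries learnable block structure
    (the regime the similarity-fusion pipeline assumes).  The ontology is a
    random recursive tree of the m disease terms, depth-capped at
    ``dag_depth``, plus a small fraction of extra child -> ancestor edges so
    multi-parent terms exercise the max rule of the semantic recursion.
    Everything is drawn from a single seeded generator, so a fixed seed gives
    bit-identical output.
    """
    if n_pos > n * m:
        raise ValueError(f"n_pos={n_pos} exceeds matrix size {n * m}")
    if latent_rank < 1:
        raise ValueError("latent_rank must be >= 1")
    rng = np.random.default_rng(seed)

    U = rng.gamma(shape=2.0, scale=1.0, size=(n, latent_rank))
    V = rng.gamma(shape=2.0, scale=1.0, size=(m, latent_rank))
    scores = U @ V.T
    # jitter breaks exact ties so the top-n_pos cut is unambiguous
    scores += rng.normal(scale=1e-9, size=scores.shape)
    flat = np.argsort(scores, axis=None)[::-1][:n_pos]
    values = np.zeros((n, m), dtype=np.int8)
    values[np.unravel_index(flat, scores.shape)] = 1

    circ_ids = [f"circ{i:04d}" for i in range(n)]
    disease_ids = [f"dis{j:04d}" for j in range(m)]

    # random recursive tree over the disease terms, root = disease 0
    depth = {disease_ids[0]: 0}
    edges: set[tuple[str, str]] = set()
    for j in range(1, m):
        term = disease_ids[j]
        candidates = [t for t, dep in depth.items() if dep < dag_depth]
        parent = candidates[rng.integers(len(candidates))]
        edges.add((term, parent))
        depth[term] = depth[parent] + 1
    # extra child -> strict-ancestor edges make it a proper (non-tree) DAG
    onto = DiseaseOntology(set(disease_ids), set(edges))
    n_extra = math.ceil(extra_edge_fraction * (m - 1))
    added = 0
    order = rng.permutation(m)
    for j in order:
        if added >= n_extra:
            break
        term = disease_ids[j]
        strict = onto.ancestor_set(term) - {term} - onto.parents(term)
        if strict:
            anc = sorted(strict)[rng.integers(len(strict))]
            edges.add((term, anc))
            added += 1
    return (
        AssociationMatrix(values, circ_ids, disease_ids),
        DiseaseOntology(set(disease_ids), edges),
    )
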