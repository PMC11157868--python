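"""Independent brute-force oracles used by the test suite.

These deliberately avoid the library's own code paths: semantic
contributions come from exhaustive downward-path enumeration, Gaussian
kernels from per-pair scalar arithmetic, walk transition probabilities from
explicit breadth-first distances, and classification metrics from direct
pair counting.
"""

from __future__ import annotations

import itertools

import numpy as np

from circdis import DiseaseOntology


def paths_down(onto: DiseaseOntology, src: str, dst: str) -> list[int]:
    """Lengths of every downward (via-children) path from src to dst."""
    out: list[int] = []

    def walk(node: str, length: int) -> None:
        if node == dst:
            out.append(length)
            return
        for child in onto.children(node):
            walk(child, length + 1)

    walk(src, 0)
    return out


def sc_bruteforce(onto: DiseaseOntology, target: str, gamma: float) -> dict[str, float]:
    """SC via max over enumerated downward paths of gamma^length."""
    contrib = {}
    for anc in onto.ancestor_set(target):
        lengths = paths_down(onto, anc, target)
        contrib[anc] = max(gamma**length for length in lengths)
    return contrib


def ds_bruteforce(onto: DiseaseOntology, d_i: str, d_j: str, gamma: float) -> float:
    ci = sc_bruteforce(onto, d_i, gamma)
    cj = sc_bruteforce(onto, d_j, gamma)
    shared = ci.keys() & cj.keys()
    num = sum(ci[d] + cj[d] for d in shared)
    return num / (sum(ci.values()) + sum(cj.values()))


def gip_bruteforce(A: np.ndarray, axis: str) -> np.ndarray:
    profiles = A if axis == "circRNA" else A.T
    p = profiles.shape[0]
    lam = p / sum(float(np.dot(row, row)) for row in profiles)
    K = np.empty((p, p))
    for i in range(p):
        for j in range(p):
            d2 = float(np.sum((profiles[i] - profiles[j]) ** 2))
            K[i, j] = np.exp(-lam * d2)
    return K


def transition_bruteforce(
    adj: np.ndarray, t: int, v: int, x: int, p: float, q: float
) -> float:
    """Second-order transition probability from explicit BFS distances."""

    def bfs_dist(src: int, dst: int) -> int:
        if src == dst:
            return 0
        frontier, seen, d = {src}, {src}, 0
        while frontier:
            d += 1
            nxt = set()
            for u in frontier:
                for w in np.nonzero(adj[u])[0]:
                    if w == dst:
                        return d
                    if w not in seen:
                        seen.add(int(w))
                        nxt.add(int(w))
            frontier = nxt
        return -1

    def alpha(dist: int) -> float:
        return {0: 1.0 / p, 1: 1.0}.get(dist, 1.0 / q)

    nbrs = np.nonzero(adj[v])[0]
    weights = {int(n): alpha(bfs_dist(t, int(n))) * adj[v, n] for n in nbrs}
    Z = sum(weights.values())
    return weights.get(x, 0.0) / Z


def metrics_bruteforce(labels, scores, threshold: float) -> dict[str, float]:
    labels = list(labels)
    scores = list(scores)
    tp = sum(1 for y, s in zip(labels, scores) if y == 1 and s >= threshold)
    fn = sum(1 for y, s in zip(labels, scores) if y == 1 and s < threshold)
    fp = sum(1 for y, s in zip(labels, scores) if y == 0 and s >= threshold)
    tn = sum(1 for y, s in zip(labels, scores) if y == 0 and s < threshold)

    def ratio(a, b):
        return a / b if b else 0.0

    den = (tp + fp) * (tp + fn) * (tn + fp) * (tn + fn)
    pos = [s for y, s in zip(labels, scores) if y == 1]
    neg = [s for y, s in zip(labels, scores) if y == 0]
    wins = sum(
        1.0 if sp > sn else (0.5 if sp == sn else 0.0)
        for sp, sn in itertools.product(pos, neg)
    )
    # average precision: sum over positives, in score order, of
    # precision-at-that-rank times the recall increment
    order = sorted(range(len(labels)), key=lambda i: -scores[i])
    ap, seen_pos = 0.0, 0
    i = 0
    while i < len(order):
        # process score ties as one threshold step
        j = i
        while j < len(order) and scores[order[j]] == scores[order[i]]:
            j += 1
        block_pos = sum(labels[order[kk]] for kk in range(i, j))
        seen_pos += block_pos
        prec = seen_pos / j
        ap += prec * (block_pos / len(pos))
        i = j
    return {
        "accuracy": ratio(tp + tn, len(labels)),
        "sensitivity": ratio(tp, tp + fn),
        "specificity": ratio(tn, tn + fp),
        "precision": ratio(tp, tp + fp),
        "mcc": (tp * tn - fp * fn) / np.sqrt(den) if den else 0.0,
        "auroc": wins / (len(pos) * len(neg)),
        "aupr": ap,
    }
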