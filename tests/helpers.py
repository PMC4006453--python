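"""Independent oracles used across the test suite.

Everything here is deliberately naive — dense matrices, exhaustive
enumeration, direct loops — so it cannot share a defect with the
implementations it checks.
"""

from __future__ import annotations

import itertools

import numpy as np

from netpropel import WeightedGraph


def random_graph(
    rng: np.random.Generator, n: int, density: float = 0.05
) -> WeightedGraph:
    """Erdos-Renyi weighted graph with accessions P0..P{n-1}."""
    iu, ju = np.triu_indices(n, k=1)
    keep = rng.random(iu.size) < density
    w = 0.1 + rng.random(iu.size)
    return WeightedGraph(
        n=n,
        src=iu[keep],
        dst=ju[keep],
        weight=w[keep],
        accessions=[f"P{i}" for i in range(n)],
    )


def dense_adjacency(graph: WeightedGraph) -> np.ndarray:
    W = np.zeros((graph.n, graph.n))
    for i, j, w in zip(graph.src, graph.dst, graph.weight):
        W[i, j] = w
        W[j, i] = w
    return W


def dense_rw(graph: WeightedGraph, p0: np.ndarray, steps: int) -> np.ndarray:
    """Direct dense iteration p <- Q^T p with Q = D^-1 W."""
    W = dense_adjacency(graph)
    deg = W.sum(axis=1)
    inv = np.divide(1.0, deg, out=np.zeros_like(deg), where=deg > 0)
    Q = inv[:, None] * W
    p = p0.copy()
    for _ in range(steps):
        p = Q.T @ p
    return p


def brute_auc(scores: np.ndarray, labels: np.ndarray) -> float:
    """Pair counting: (wins + ties/2) / (P * N)."""
    pos = scores[np.asarray(labels, dtype=bool)]
    neg = scores[~np.asarray(labels, dtype=bool)]
    wins = sum(1.0 for p in pos for q in neg if p > q)
    ties = sum(1.0 for p in pos for q in neg if p == q)
    return (wins + ties / 2.0) / (len(pos) * len(neg))


def brute_precision_at_recall(
    scores: np.ndarray, labels: np.ndarray, recall: float
) -> float:
    """Enumerate every cutoff of the (score desc, id asc) ranking."""
    labels = np.asarray(labels, dtype=bool)
    order = sorted(range(len(scores)), key=lambda i: (-scores[i], i))
    n_pos = labels.sum()
    tp = 0
    for k, idx in enumerate(order, start=1):
        tp += bool(labels[idx])
        if tp / n_pos >= recall - 1e-12:
            return tp / k
    raise AssertionError("recall level unreachable")


def brute_wilcoxon_p(diffs: np.ndarray) -> float:
    """Exhaustive two-sided signed-rank p over all 2^m sign patterns."""
    d = np.asarray(diffs, dtype=float)
    d = d[d != 0]
    m = d.size
    if m == 0:
        return 1.0
    absd = np.abs(d)
    # midranks by direct counting
    ranks = np.array(
        [1 + np.sum(absd < a) + (np.sum(absd == a) - 1) / 2.0 for a in absd]
    )
    w_plus = ranks[d > 0].sum()
    total = ranks.sum()
    lower = min(w_plus, total - w_plus)
    count = 0
    n_patterns = 2 ** m
    for bits in itertools.product((0, 1), repeat=m):
        wp = sum(r for r, b in zip(ranks, bits) if b)
        if wp <= lower + 1e-9 or wp >= total - lower - 1e-9:
            count += 1
    return min(1.0, count / n_patterns)


def clique_union_edges(nogs: dict[str, set]) -> set[tuple[str, str]]:
    """All unordered member pairs across clusters, brute force."""
    pairs: set[tuple[str, str]] = set()
    for members in nogs.values():
        for a, b in itertools.combinations(sorted(members), 2):
            pairs.add((a, b) if a < b else (b, a))
    return pairs
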