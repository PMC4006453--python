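"""Cross-validated evaluation of walk-based function prediction.

Each Gene Ontology term is treated as a binary ranking task: annotated
proteins are positives, all other vertices negatives.  A stratified F-fold
split hides one fold at a time; the walk is seeded with the training-fold
positives and the held-out vertices' scores are pooled across folds before
computing the area under the ROC curve (Mann-Whitney form with midranks)
and precision at fixed recall levels.  Two methods are compared over terms
with a paired two-sided Wilcoxon signed-rank test.
"""

from __future__ import annotations

from dataclasses import dataclass, field
from typing import Iterable, Mapping, Optional, Sequence, Union

import numpy as np
from scipy.stats import norm, rankdata

from .graph_store import ShardedGraph, WeightedGraph
from .random_walk import run_rw

GraphLike = Union[WeightedGraph, ShardedGraph]


# ---------------------------------------------------------------------------
# Folds
# ---------------------------------------------------------------------------

def stratified_kfold(labels: np.ndarray, F: int, rng_seed: int) -> np.ndarray:
    """Deterministic stratified fold assignment.

    Positives and negatives are shuffled separately and dealt round-robin,
    so per-fold class counts differ by at most one.
    """
    labels = np.asarray(labels).astype(bool)
    n_pos = int(labels.sum())
    n_neg = int(labels.size - n_pos)
    if F < 2:
        raise ValueError("F must be >= 2")
    if n_pos < F or n_neg < F:
        raise ValueError(
            f"need at least F={F} positives and negatives "
            f"(got {n_pos} / {n_neg})"
        )
    rng = np.random.default_rng(rng_seed)
    folds = np.empty(labels.size, dtype=np.int64)
    for cls in (True, False):
        idx = np.flatnonzero(labels == cls)
        rng.shuffle(idx)
        folds[idx] = np.arange(idx.size) % F
    return folds


# ---------------------------------------------------------------------------
# Ranking metrics
# ---------------------------------------------------------------------------

def auc(scores: np.ndarray, labels: np.ndarray) -> float:
    """Area under the ROC curve, Mann-Whitney form with midranks for ties."""
    scores = np.asarray(scores, dtype=np.float64)
    labels = np.asarray(labels).astype(bool)
    n_pos = int(labels.sum())
    n_neg = int(labels.size - n_pos)
    if n_pos == 0 or n_neg == 0:
        raise ValueError("AUC needs at least one positive and one negative")
    ranks = rankdata(scores)  # midranks
    u = ranks[labels].sum() - n_pos * (n_pos + 1) / 2.0
    return float(u / (n_pos * n_neg))


def precision_at_recall(
    scores: np.ndarray, labels: np.ndarray, recall: float
) -> float:
    """Precision at the smallest cutoff whose recall reaches ``recall``.

    Vertices are ranked by descending score with ties broken by ascending
    vertex id (a fixed, reproducible ordering).
    """
    if not 0.0 < recall <= 1.0:
        raise ValueError("recall level must be in (0, 1]")
    scores = np.asarray(scores, dtype=np.float64)
    labels = np.asarray(labels).astype(bool)
    n_pos = int(labels.sum())
    if n_pos == 0:
        raise ValueError("no positives")
    ids = np.arange(scores.size)
    order = np.lexsort((ids, -scores))
    cum_pos = np.cumsum(labels[order])
    k = int(np.searchsorted(cum_pos, recall * n_pos - 1e-12) + 1)
    return float(cum_pos[k - 1] / k)


# ---------------------------------------------------------------------------
# Paired comparison
# ---------------------------------------------------------------------------

EXACT_WILCOXON_LIMIT = 25


def _exact_signed_rank_p(ranks: np.ndarray, w_plus: float) -> float:
    """Two-sided exact p over all sign assignments of the given midranks.

    The null distribution of W+ is built by convolving the per-pair
    generating functions (1 + x^{2r}) / 2 over doubled ranks — identical to
    enumerating all 2^m sign patterns.
    """
    doubled = np.rint(2 * ranks).astype(np.int64)
    dist = np.zeros(int(doubled.sum()) + 1)
    dist[0] = 1.0
    for r in doubled:
        shifted = np.zeros_like(dist)
        shifted[r:] = dist[: dist.size - r]
        dist = 0.5 * (dist + shifted)
    total = doubled.sum()
    w2 = int(np.rint(2 * w_plus))
    lower = min(w2, total - w2)
    p = dist[: lower + 1].sum() + dist[total - lower:].sum()
    return float(min(1.0, p))


def compare_paired(
    metric_a: Sequence[float],
    metric_b: Sequence[float],
    alpha: float = 0.01,
) -> tuple[float, float, bool]:
    """Two-sided Wilcoxon signed-rank test on paired per-term metrics.

    Zero differences are dropped.  For at most ``EXACT_WILCOXON_LIMIT``
    non-zero pairs the exact sign-enumeration null is used; beyond that a
    normal approximation with continuity correction and a tie-corrected
    variance.  Returns (W = min(W+, W-), p, p <= alpha).
    """
    a = np.asarray(metric_a, dtype=np.float64)
    b = np.asarray(metric_b, dtype=np.float64)
    if a.shape != b.shape:
        raise ValueError("paired vectors must have equal length")
    d = b - a
    d = d[d != 0]
    m = d.size
    if m == 0:
        return 0.0, 1.0, False
    ranks = rankdata(np.abs(d))
    w_plus = float(ranks[d > 0].sum())
    w_minus = float(ranks[d < 0].sum())
    stat = min(w_plus, w_minus)
    if m <= EXACT_WILCOXON_LIMIT:
        p = _exact_signed_rank_p(ranks, w_plus)
    else:
        mu = ranks.sum() / 2.0
        sigma = np.sqrt(np.square(ranks).sum() / 4.0)
        z = (stat - mu + 0.5) / sigma  # continuity-corrected lower tail
        p = float(min(1.0, 2.0 * norm.cdf(z)))
    return stat, p, bool(p <= alpha)


# ---------------------------------------------------------------------------
# Cross-validation driver
# ---------------------------------------------------------------------------

@dataclass
class TermEvaluation:
    """Pooled cross-validated results for one functional class."""

    term: str
    auc: float
    precision_at: dict[float, float]
    n_pos: int
    fold_seeds: list[list[str]] = field(default_factory=list)


def cross_validate_term(
    graph: GraphLike,
    annotations: Mapping[str, set],
    term: str,
    folds: int = 5,
    steps: int = 1,
    rng_seed: int = 0,
    recall_levels: Iterable[float] = (0.2, 0.4),
    tol: Optional[float] = None,
    renormalize: bool = False,
    per_fold: bool = False,
    eval_vertices: Optional[Iterable[int]] = None,
) -> TermEvaluation:
    """Stratified F-fold cross-validation of the t-step walk for one term.

    Per fold, the walk is seeded with the training-fold positives and only
    the held-out vertices' scores are recorded; metrics are computed on the
    pooled held-out score vector (or averaged across folds with
    ``per_fold=True``).

    ``eval_vertices`` restricts both the fold split and the metrics to a
    vertex subset (e.g. one species of a multi-species network); positives
    outside the subset then act as seeds in every fold, which is the
    cross-species annotation-transfer setting.
    """
    n = graph.n
    labels = np.zeros(n, dtype=bool)
    for acc, terms in annotations.items():
        if term in terms and acc in graph.id_map:
            labels[graph.id_map[acc]] = True
    if eval_vertices is None:
        eval_mask = np.ones(n, dtype=bool)
    else:
        eval_mask = np.zeros(n, dtype=bool)
        eval_mask[np.asarray(sorted(set(int(v) for v in eval_vertices)))] = True
    n_pos = int(labels[eval_mask].sum())
    if n_pos == 0:
        raise ValueError(f"term {term!r} has no annotated vertices to evaluate")
    if n_pos == int(eval_mask.sum()):
        raise ValueError(f"term {term!r} annotates every vertex: no negatives")
    sub_assignment = stratified_kfold(labels[eval_mask], folds, rng_seed)
    assignment = np.full(n, -1, dtype=np.int64)
    assignment[eval_mask] = sub_assignment

    recall_levels = tuple(recall_levels)
    pooled = np.zeros(n)
    fold_seeds: list[list[str]] = []
    fold_metrics: list[tuple[float, dict[float, float]]] = []
    for f in range(folds):
        held = assignment == f
        seeds = np.flatnonzero(labels & ~held)
        scores = run_rw(graph, seeds, steps, tol=tol, renormalize=renormalize)
        pooled[held] = scores[held]
        fold_seeds.append(sorted(graph.accessions[i] for i in seeds))
        if per_fold:
            fold_metrics.append(
                (
                    auc(scores[held], labels[held]),
                    {
                        r: precision_at_recall(scores[held], labels[held], r)
                        for r in recall_levels
                    },
                )
            )
    pooled_eval = pooled[eval_mask]
    labels_eval = labels[eval_mask]

    if per_fold:
        return TermEvaluation(
            term=term,
            auc=float(np.mean([m[0] for m in fold_metrics])),
            precision_at={
                r: float(np.mean([m[1][r] for m in fold_metrics]))
                for r in recall_levels
            },
            n_pos=n_pos,
            fold_seeds=fold_seeds,
        )
    return TermEvaluation(
        term=term,
        auc=auc(pooled_eval, labels_eval),
        precision_at={
            r: precision_at_recall(pooled_eval, labels_eval, r)
            for r in recall_levels
        },
        n_pos=n_pos,
        fold_seeds=fold_seeds,
    )
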