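"""t-step random walk for function prediction, local (vertex-centric) form.

The walk starts from the proteins annotated to a functional class (the seed
set ``C``) with probability ``1/|C|`` each and iterates

    p_i(t+1) = sum_{j in N(i)} d_jj^-1 * w_ji * p_j(t)

which is exactly the global update ``p(t+1) = Q^T p(t)`` with ``Q = D^-1 W``.
After ``t`` steps the probabilities rank every protein by its relevance to
the class.  Two execution paths are provided: an in-memory sparse-matrix
path for graphs that fit in RAM, and the out-of-core vertex-centric path via
the engine — both compute the same synchronous iteration.

Zero-degree (dangling) vertices get ``inv_degree = 0``, so any probability
mass they hold vanishes at the next step; pass ``renormalize=True`` to
rescale the vector to unit mass after every step instead.
"""

from __future__ import annotations

from typing import Iterable, Optional, Sequence, Union

import numpy as np
import scipy.sparse as sp

from .engine import VertexState, run_program
from .graph_store import ShardedGraph, WeightedGraph

GraphLike = Union[WeightedGraph, ShardedGraph]

DEFAULT_CONVERGENCE_TOL = 1e-6
MAX_CONVERGENCE_STEPS = 1000


def compute_inverse_degrees(graph: GraphLike) -> np.ndarray:
    """Per-vertex 1 / (sum of incident edge weights); 0 for isolated vertices.

    Computed once as preprocessing: the update rule only ever needs the
    inverse, and the convention for dangling vertices keeps it finite.
    """
    if isinstance(graph, ShardedGraph):
        deg = graph.in_weight_sums()
    else:
        deg = graph.weighted_degrees()
    inv = np.zeros_like(deg)
    nz = deg > 0
    inv[nz] = 1.0 / deg[nz]
    return inv


def init_probabilities(n: int, seeds: Iterable[int]) -> np.ndarray:
    """Uniform start vector: 1/|C| on the seed set, 0 elsewhere."""
    seed_ids = np.asarray(sorted(set(int(s) for s in seeds)), dtype=np.int64)
    if seed_ids.size == 0:
        raise ValueError("seed set must be non-empty")
    if seed_ids.min() < 0 or seed_ids.max() >= n:
        raise ValueError("seed vertex id out of range")
    p = np.zeros(n)
    p[seed_ids] = 1.0 / seed_ids.size
    return p


def _adjacency(graph: WeightedGraph) -> sp.csr_matrix:
    """Symmetric CSR adjacency, cached on the graph object."""
    cached = getattr(graph, "_csr_cache", None)
    if cached is None:
        a_src, a_dst, a_w = graph.directed_arcs()
        cached = sp.csr_matrix(
            (a_w, (a_dst, a_src)), shape=(graph.n, graph.n)
        )
        graph._csr_cache = cached
    return cached


def rw_step(
    graph: WeightedGraph,
    p: np.ndarray,
    inv_degree: Optional[np.ndarray] = None,
) -> np.ndarray:
    """One synchronous walk step on an in-memory graph: ``Q^T p``."""
    if inv_degree is None:
        inv_degree = compute_inverse_degrees(graph)
    return _adjacency(graph) @ (p * inv_degree)


class RandomWalkProgram:
    """Vertex program computing the local walk update of the engine."""

    def __init__(self, inv_degree: np.ndarray, p0: np.ndarray):
        self.inv_degree = inv_degree
        self.p0 = p0

    def start(self, vertex: int, state: VertexState) -> None:
        state.inv_degree[vertex] = self.inv_degree[vertex]
        state.p_prev[vertex] = self.p0[vertex]

    def update(
        self,
        vertex: int,
        in_src: np.ndarray,
        in_weight: np.ndarray,
        state: VertexState,
    ) -> None:
        state.p_curr[vertex] = np.dot(
            in_weight, state.p_prev[in_src] * state.inv_degree[in_src]
        )


def run_rw(
    graph: GraphLike,
    seeds: Iterable[int],
    steps: int,
    tol: Optional[float] = None,
    renormalize: bool = False,
) -> np.ndarray:
    """Run the walk for ``steps`` steps (or to ``tol`` convergence).

    ``steps=0`` returns the initial probability vector.  On a
    ``WeightedGraph`` the sparse in-memory iteration is used; on a
    ``ShardedGraph`` the out-of-core vertex-centric engine — the two paths
    agree to floating-point rounding.
    """
    if steps < 0:
        raise ValueError("steps must be >= 0")
    n = graph.n
    p0 = init_probabilities(n, seeds)
    if steps == 0:
        return p0
    inv_degree = compute_inverse_degrees(graph)

    def maybe_renorm(p: np.ndarray) -> None:
        total = p.sum()
        if renormalize and total > 0:
            p /= total

    if isinstance(graph, ShardedGraph):
        program = RandomWalkProgram(inv_degree, p0)
        state = run_program(
            graph, program, steps, tol=tol, post_iteration=maybe_renorm
        )
        return state.p_prev.copy()

    p = p0
    for _ in range(steps):
        p_next = rw_step(graph, p, inv_degree)
        maybe_renorm(p_next)
        delta = float(np.max(np.abs(p_next - p)))
        p = p_next
        if tol is not None and delta < tol:
            break
    return p


def run_rw_to_convergence(
    graph: GraphLike,
    seeds: Iterable[int],
    tol: float = DEFAULT_CONVERGENCE_TOL,
    max_steps: int = MAX_CONVERGENCE_STEPS,
    renormalize: bool = False,
) -> np.ndarray:
    """Iterate until the max-norm change drops below ``tol``."""
    return run_rw(graph, seeds, max_steps, tol=tol, renormalize=renormalize)


def rank_vertices(
    scores: np.ndarray,
    exclude: Optional[Iterable[int]] = None,
) -> list[tuple[int, float]]:
    """Order vertices by descending score, ties broken by ascending id."""
    scores = np.asarray(scores, dtype=np.float64)
    ids = np.arange(scores.size)
    if exclude is not None:
        keep = np.ones(scores.size, dtype=bool)
        keep[np.asarray(sorted(set(int(e) for e in exclude)), dtype=np.int64)] = False
        ids = ids[keep]
    order = ids[np.lexsort((ids, -scores[ids]))]
    return [(int(i), float(scores[i])) for i in order]


def write_scores(
    scores: np.ndarray, accessions: Sequence[str], path
) -> None:
    """Write an ``accession<TAB>score`` TSV at full precision."""
    with open(path, "w") as fh:
        fh.write("#accession\tscore\n")
        for acc, s in zip(accessions, scores):
            fh.write(f"{acc}\t{s:.17g}\n")
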