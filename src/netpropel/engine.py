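"""Synchronous vertex-centric execution over a sharded graph.

Per-vertex state (inverse weighted degree plus double-buffered probabilities)
lives in an in-RAM global vector while edges stream from disk; an update may
read only its neighbours' *previous*-step values and write only its own
current value, giving strictly synchronous (Jacobi) semantics whose result is
independent of the number of shards.
"""

from __future__ import annotations

from dataclasses import dataclass, field
from typing import Callable, Optional, Protocol

import numpy as np

from .graph_store import PassStats, ShardedGraph


@dataclass
class VertexState:
    """Global per-vertex vectors: d^-1 and the two probability buffers."""

    inv_degree: np.ndarray
    p_prev: np.ndarray
    p_curr: np.ndarray
    #: accumulated sliding-window statistics, one entry per pass
    pass_stats: list[PassStats] = field(default_factory=list)

    @classmethod
    def zeros(cls, n: int) -> "VertexState":
        return cls(
            inv_degree=np.zeros(n),
            p_prev=np.zeros(n),
            p_curr=np.zeros(n),
        )

    def swap_buffers(self) -> None:
        """Promote the just-written step: p_curr becomes p_prev."""
        self.p_prev, self.p_curr = self.p_curr, self.p_prev


class VertexProgram(Protocol):
    """A vertex-centric computation given by ``start`` and ``update``.

    ``update`` receives the vertex's in-arcs (source ids and arc weights) and
    the global state; the contract is that it reads only ``p_prev`` /
    ``inv_degree`` of the sources and assigns only ``p_curr[vertex]``.
    """

    def start(self, vertex: int, state: VertexState) -> None: ...

    def update(
        self,
        vertex: int,
        in_src: np.ndarray,
        in_weight: np.ndarray,
        state: VertexState,
    ) -> None: ...


def run_program(
    sharded: ShardedGraph,
    program: VertexProgram,
    iterations: int,
    tol: Optional[float] = None,
    post_iteration: Optional[Callable[[np.ndarray], None]] = None,
) -> VertexState:
    """Apply ``start`` once per vertex, then run synchronized update passes.

    Each iteration is one full sliding-window pass invoking ``update`` on
    every vertex; buffers are swapped at iteration end.  With ``tol`` set,
    iteration stops early once the max-norm change falls below it.
    ``post_iteration`` (if given) may rewrite the freshly computed buffer
    before the swap — e.g. to renormalize leaked probability mass.

    Returns the final state with ``p_prev`` holding the last computed step.
    """
    if iterations < 0:
        raise ValueError("iterations must be >= 0")
    state = VertexState.zeros(sharded.n)
    for v in range(sharded.n):
        program.start(v, state)
    for _ in range(iterations):
        def visit(v: int, in_src: np.ndarray, in_w: np.ndarray) -> None:
            program.update(v, in_src, in_w, state)

        stats = sharded.sliding_window_pass(visit)
        state.pass_stats.append(stats)
        if post_iteration is not None:
            post_iteration(state.p_curr)
        delta = float(np.max(np.abs(state.p_curr - state.p_prev))) if sharded.n else 0.0
        state.swap_buffers()
        if tol is not None and delta < tol:
            break
    return state
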