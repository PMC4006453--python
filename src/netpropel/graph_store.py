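"""On-disk sharded representation of a weighted undirected protein network.

A logical network (``WeightedGraph``) is split into ``K`` contiguous vertex
intervals; each interval owns a *shard* file holding every directed in-arc of
its vertices, sorted by source vertex.  A full pass over the graph loads one
"memory shard" at a time and advances one read window per other shard
(parallel sliding windows), so a pass needs at most ``K`` non-sequential disk
reads per interval and ``K**2`` per full pass.
"""

from __future__ import annotations

import hashlib
import json
import struct
from dataclasses import dataclass, field
from pathlib import Path
from typing import Callable, Iterator, Sequence

import numpy as np

FORMAT_VERSION = 1
ENDIANNESS = "little"
#: fixed-size arc record: src (u32), dst (u32), weight (f64)
RECORD = struct.Struct("<IId")
RECORD_SIZE = RECORD.size


class GraphFormatError(ValueError):
    """Raised for malformed edge lists or inconsistent shard stores."""


# ---------------------------------------------------------------------------
# Logical graph
# ---------------------------------------------------------------------------

@dataclass
class WeightedGraph:
    """Undirected weighted simple graph with a protein accession <-> id map.

    Each unordered edge is stored once, with ``src < dst``.  Vertex ids are
    dense 0-based integers; ``accessions[i]`` is the protein name of vertex
    ``i`` and ``id_map`` the inverse mapping.
    """

    n: int
    src: np.ndarray
    dst: np.ndarray
    weight: np.ndarray
    accessions: list[str] = field(default_factory=list)

    def __post_init__(self) -> None:
        self.src = np.asarray(self.src, dtype=np.int64)
        self.dst = np.asarray(self.dst, dtype=np.int64)
        self.weight = np.asarray(self.weight, dtype=np.float64)
        if not self.accessions:
            self.accessions = [str(i) for i in range(self.n)]
        if len(self.accessions) != self.n:
            raise GraphFormatError("accession list length does not match n")
        if self.src.size:
            lo = np.minimum(self.src, self.dst)
            hi = np.maximum(self.src, self.dst)
            self.src, self.dst = lo, hi
            if np.any(self.src == self.dst):
                raise GraphFormatError("self-loops are not allowed")
            if self.dst.max() >= self.n or self.src.min() < 0:
                raise GraphFormatError("vertex id out of range")
            if not np.all(np.isfinite(self.weight)) or np.any(self.weight <= 0):
                raise GraphFormatError("edge weights must be finite and > 0")
            keys = self.src * self.n + self.dst
            if np.unique(keys).size != keys.size:
                raise GraphFormatError("duplicate edges are not allowed")
        self.id_map = {a: i for i, a in enumerate(self.accessions)}

    @property
    def n_edges(self) -> int:
        return int(self.src.size)

    def weighted_degrees(self) -> np.ndarray:
        """Sum of incident edge weights per vertex (d_jj of the walk)."""
        deg = np.zeros(self.n, dtype=np.float64)
        np.add.at(deg, self.src, self.weight)
        np.add.at(deg, self.dst, self.weight)
        return deg

    def directed_arcs(self) -> tuple[np.ndarray, np.ndarray, np.ndarray]:
        """Symmetrize: every undirected edge as two directed arcs."""
        a_src = np.concatenate([self.src, self.dst])
        a_dst = np.concatenate([self.dst, self.src])
        a_w = np.concatenate([self.weight, self.weight])
        return a_src, a_dst, a_w

    @classmethod
    def from_named_edges(
        cls, edges: Sequence[tuple[str, str, float]]
    ) -> "WeightedGraph":
        """Build from (accession, accession, weight) triples.

        Ids are assigned in first-appearance order.  Duplicate unordered pairs
        with equal weight are deduplicated; conflicting duplicates, self-loops
        and non-positive weights are rejected.
        """
        id_map: dict[str, int] = {}
        accessions: list[str] = []
        seen: dict[tuple[int, int], float] = {}
        for a, b, w in edges:
            w = float(w)
            if a == b:
                raise GraphFormatError(f"self-loop on {a!r}")
            if not np.isfinite(w) or w <= 0:
                raise GraphFormatError(f"invalid weight {w!r} on edge {a!r}-{b!r}")
            for acc in (a, b):
                if acc not in id_map:
                    id_map[acc] = len(accessions)
                    accessions.append(acc)
            i, j = id_map[a], id_map[b]
            key = (min(i, j), max(i, j))
            if key in seen:
                if seen[key] != w:
                    raise GraphFormatError(
                        f"conflicting weights for edge {a!r}-{b!r}: "
                        f"{seen[key]} vs {w}"
                    )
                continue
            seen[key] = w
        n = len(accessions)
        if seen:
            src, dst = (np.array(x, dtype=np.int64) for x in zip(*seen))
            weight = np.array([seen[k] for k in zip(src.tolist(), dst.tolist())])
        else:
            src = dst = np.empty(0, dtype=np.int64)
            weight = np.empty(0, dtype=np.float64)
        return cls(n=n, src=src, dst=dst, weight=weight, accessions=accessions)


def load_edge_list(path: str | Path) -> WeightedGraph:
    """Read a TSV edge list ``src<TAB>dst<TAB>weight`` (``#`` lines ignored)."""
    path = Path(path)
    edges: list[tuple[str, str, float]] = []
    with path.open() as fh:
        for lineno, line in enumerate(fh, 1):
            line = line.strip()
            if not line or line.startswith("#"):
                continue
            parts = line.split("\t")
            if len(parts) == 1:  # tolerate space-separated files
                parts = line.split()
            if len(parts) != 3:
                raise GraphFormatError(f"{path}:{lineno}: expected 3 columns")
            try:
                w = float(parts[2])
            except ValueError as exc:
                raise GraphFormatError(f"{path}:{lineno}: bad weight") from exc
            edges.append((parts[0], parts[1], w))
    return WeightedGraph.from_named_edges(edges)


def write_edge_list(graph: WeightedGraph, path: str | Path) -> None:
    path = Path(path)
    with path.open("w") as fh:
        fh.write("#src\tdst\tweight\n")
        for i, j, w in zip(graph.src, graph.dst, graph.weight):
            fh.write(
                f"{graph.accessions[i]}\t{graph.accessions[j]}\t{w:.17g}\n"
            )


# ---------------------------------------------------------------------------
# Sharding
# ---------------------------------------------------------------------------

def _interval_boundaries(in_arc_counts: np.ndarray, K: int) -> list[tuple[int, int]]:
    """Greedy arc-balanced contiguous intervals covering [0, n).

    Grows each interval until it holds at least ``total_arcs / K`` arcs, while
    keeping enough vertices for the remaining intervals to be non-empty.
    """
    n = in_arc_counts.size
    total = int(in_arc_counts.sum())
    target = total / K
    bounds: list[tuple[int, int]] = []
    start = 0
    for k in range(K):
        remaining_intervals = K - k - 1
        if k == K - 1:
            end = n
        else:
            end = start + 1
            acc = int(in_arc_counts[start])
            while (
                end < n - remaining_intervals
                and acc < target
            ):
                acc += int(in_arc_counts[end])
                end += 1
        bounds.append((start, end))
        start = end
    return bounds


def _checksum(path: Path) -> str:
    h = hashlib.sha256()
    with path.open("rb") as fh:
        for chunk in iter(lambda: fh.read(1 << 20), b""):
            h.update(chunk)
    return h.hexdigest()


@dataclass
class PassStats:
    """Instrumentation of one full parallel-sliding-windows pass."""

    non_sequential_reads: int = 0
    per_interval_reads: list[int] = field(default_factory=list)
    vertices_visited: int = 0


class ShardedGraph:
    """Handle to an on-disk shard store described by a JSON manifest."""

    def __init__(self, manifest_path: str | Path, verify: bool = True):
        self.manifest_path = Path(manifest_path)
        with self.manifest_path.open() as fh:
            self.manifest = json.load(fh)
        if self.manifest.get("format_version") != FORMAT_VERSION:
            raise GraphFormatError("unsupported shard format version")
        self.directory = self.manifest_path.parent
        self.n: int = self.manifest["n"]
        self.K: int = self.manifest["K"]
        self.intervals: list[tuple[int, int]] = [
            tuple(b) for b in self.manifest["intervals"]
        ]
        self.shard_paths = [
            self.directory / s["file"] for s in self.manifest["shards"]
        ]
        idmap_path = self.directory / self.manifest["idmap_file"]
        self.accessions = _read_idmap(idmap_path, self.n)
        self.id_map = {a: i for i, a in enumerate(self.accessions)}
        if verify:
            self.verify_checksums()

    def verify_checksums(self) -> None:
        for meta, path in zip(self.manifest["shards"], self.shard_paths):
            if not path.exists():
                raise GraphFormatError(f"missing shard file {path}")
            if _checksum(path) != meta["checksum"]:
                raise GraphFormatError(f"checksum mismatch for {path}")

    # -- reading -----------------------------------------------------------

    def read_shard(self, k: int) -> tuple[np.ndarray, np.ndarray, np.ndarray]:
        """Load shard ``k`` fully (src, dst, weight arrays sorted by src)."""
        raw = np.fromfile(self.shard_paths[k], dtype=_record_dtype())
        return (
            raw["src"].astype(np.int64),
            raw["dst"].astype(np.int64),
            raw["w"].astype(np.float64),
        )

    def iter_arcs(self) -> Iterator[tuple[int, int, float]]:
        for k in range(self.K):
            src, dst, w = self.read_shard(k)
            yield from zip(src.tolist(), dst.tolist(), w.tolist())

    def in_weight_sums(self) -> np.ndarray:
        """Per-vertex sum of in-arc weights (equals the weighted degree)."""
        sums = np.zeros(self.n, dtype=np.float64)
        for k in range(self.K):
            _, dst, w = self.read_shard(k)
            np.add.at(sums, dst, w)
        return sums

    def sliding_window_pass(
        self,
        visitor: Callable[[int, np.ndarray, np.ndarray], None],
    ) -> PassStats:
        """Visit every vertex once, giving it its in-arcs.

        For each interval the owning shard is loaded in full (one
        non-sequential read); the out-arc blocks of the interval's vertices
        are then pulled from every other shard by advancing one read window
        each (one non-sequential read per shard).  ``visitor(v, in_src,
        in_weight)`` is called exactly once per vertex, in ascending vertex
        order, with that vertex's in-arcs (sources ascending).
        """
        stats = PassStats()
        offsets = [s["window_offsets"] for s in self.manifest["shards"]]
        n_arcs = [s["n_arcs"] for s in self.manifest["shards"]]
        handles = [p.open("rb") for p in self.shard_paths]
        try:
            for ell, (lo, hi) in enumerate(self.intervals):
                reads = 0
                # memory shard: all in-arcs of this interval's vertices
                handles[ell].seek(0)
                raw = np.frombuffer(
                    handles[ell].read(n_arcs[ell] * RECORD_SIZE),
                    dtype=_record_dtype(),
                )
                reads += 1
                # sliding windows: out-arcs of this interval stored elsewhere
                for s in range(self.K):
                    if s == ell:
                        continue
                    w0, w1 = offsets[s][ell], offsets[s][ell + 1]
                    handles[s].seek(w0 * RECORD_SIZE)
                    handles[s].read((w1 - w0) * RECORD_SIZE)
                    reads += 1
                stats.non_sequential_reads += reads
                stats.per_interval_reads.append(reads)

                src = raw["src"].astype(np.int64)
                dst = raw["dst"].astype(np.int64)
                wgt = raw["w"].astype(np.float64)
                order = np.argsort(dst, kind="stable")
                dst_sorted = dst[order]
                starts = np.searchsorted(dst_sorted, np.arange(lo, hi + 1))
                for v in range(lo, hi):
                    sel = order[starts[v - lo]: starts[v - lo + 1]]
                    visitor(v, src[sel], wgt[sel])
                    stats.vertices_visited += 1
        finally:
            for h in handles:
                h.close()
        return stats


def _record_dtype() -> np.dtype:
    return np.dtype([("src", "<u4"), ("dst", "<u4"), ("w", "<f8")])


def _read_idmap(path: Path, n: int) -> list[str]:
    accessions = [""] * n
    with path.open() as fh:
        for line in fh:
            line = line.rstrip("\n")
            if not line or line.startswith("#"):
                continue
            acc, idx = line.split("\t")
            accessions[int(idx)] = acc
    return accessions


def build_shards(
    graph: WeightedGraph,
    K: int,
    directory: str | Path,
    name: str = "graph",
) -> ShardedGraph:
    """Write the shard store for ``graph`` split into ``K`` intervals.

    Every undirected edge is emitted as two directed arcs; an arc lives in
    the shard owning its destination and shards are sorted by (src, dst).
    Interval boundaries balance in-arc counts.  Returns an opened handle.
    """
    if K < 1:
        raise ValueError("K must be >= 1")
    if graph.n == 0:
        raise ValueError("cannot shard an empty graph")
    if K > graph.n:
        raise ValueError(f"K={K} exceeds vertex count n={graph.n}")
    directory = Path(directory)
    directory.mkdir(parents=True, exist_ok=True)

    a_src, a_dst, a_w = graph.directed_arcs()
    in_counts = np.bincount(a_dst, minlength=graph.n)
    intervals = _interval_boundaries(in_counts, K)
    interval_starts = [lo for lo, _ in intervals] + [graph.n]

    shard_meta = []
    for k, (lo, hi) in enumerate(intervals):
        mask = (a_dst >= lo) & (a_dst < hi)
        s_src, s_dst, s_w = a_src[mask], a_dst[mask], a_w[mask]
        order = np.lexsort((s_dst, s_src))
        s_src, s_dst, s_w = s_src[order], s_dst[order], s_w[order]
        rec = np.empty(s_src.size, dtype=_record_dtype())
        rec["src"], rec["dst"], rec["w"] = s_src, s_dst, s_w
        fname = f"{name}.shard.{k}.bin"
        rec.tofile(directory / fname)
        # window offsets: first record with src >= each interval start
        offsets = np.searchsorted(s_src, interval_starts).tolist()
        shard_meta.append(
            {
                "file": fname,
                "n_arcs": int(s_src.size),
                "window_offsets": offsets,
                "checksum": _checksum(directory / fname),
            }
        )

    idmap_file = f"{name}.idmap.tsv"
    with (directory / idmap_file).open("w") as fh:
        fh.write("#accession\tvertex_id\n")
        for i, acc in enumerate(graph.accessions):
            fh.write(f"{acc}\t{i}\n")

    manifest = {
        "format_version": FORMAT_VERSION,
        "endianness": ENDIANNESS,
        "name": name,
        "n": graph.n,
        "arc_count": int(a_src.size),
        "K": K,
        "intervals": [list(b) for b in intervals],
        "shards": shard_meta,
        "idmap_file": idmap_file,
    }
    manifest_path = directory / f"{name}.manifest.json"
    with manifest_path.open("w") as fh:
        json.dump(manifest, fh, indent=1)
    return ShardedGraph(manifest_path)
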