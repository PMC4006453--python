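"""Similarity-network construction and integration.

Data-type-specific protein networks are built from sparse binary profiles:
the classical Jaccard coefficient for feature profiles (domains, motifs,
keywords, ...) and a hierarchical, depth-weighted Jaccard for Gene Ontology
annotation profiles, where a term at distance ``d`` above the leaves weighs
``1/(d+1)`` so that shared specific annotations count more than shared
generic ones.  Networks over the same proteins are merged by unweighted
averaging, with a pair missing from a network contributing weight 0.
"""

from __future__ import annotations

from collections import defaultdict, deque
from dataclasses import dataclass, field
from pathlib import Path
from typing import Iterable, Mapping, Optional

#: protein accession -> set of feature / term identifiers
ProfileTable = Mapping[str, frozenset | set]


# ---------------------------------------------------------------------------
# Ontology and depth weights
# ---------------------------------------------------------------------------

@dataclass
class Ontology:
    """A DAG of terms given as child -> parent edges."""

    terms: set[str]
    edges: list[tuple[str, str]]

    def __post_init__(self) -> None:
        for c, p in self.edges:
            if c not in self.terms or p not in self.terms:
                raise ValueError(f"edge ({c!r}, {p!r}) references unknown term")

    def children_of(self) -> dict[str, set[str]]:
        kids: dict[str, set[str]] = {t: set() for t in self.terms}
        for c, p in self.edges:
            kids[p].add(c)
        return kids

    def parents_of(self) -> dict[str, set[str]]:
        pars: dict[str, set[str]] = {t: set() for t in self.terms}
        for c, p in self.edges:
            pars[c].add(p)
        return pars

    def assert_acyclic(self) -> None:
        # Kahn's algorithm along child->parent edges
        parents = self.parents_of()
        indeg = {t: 0 for t in self.terms}
        for c in self.terms:
            for p in parents[c]:
                indeg[p] += 1
        queue = deque(t for t, d in indeg.items() if d == 0)
        seen = 0
        while queue:
            t = queue.popleft()
            seen += 1
            for p in parents[t]:
                indeg[p] -= 1
                if indeg[p] == 0:
                    queue.append(p)
        if seen != len(self.terms):
            raise ValueError("ontology contains a cycle")


def read_ontology(path: str | Path) -> Ontology:
    """Read a ``child<TAB>parent`` TSV."""
    edges: list[tuple[str, str]] = []
    terms: set[str] = set()
    with Path(path).open() as fh:
        for line in fh:
            line = line.strip()
            if not line or line.startswith("#"):
                continue
            child, parent = line.split("\t")[:2]
            edges.append((child, parent))
            terms.update((child, parent))
    return Ontology(terms=terms, edges=edges)


def leaf_distance_weights(ontology: Ontology) -> dict[str, float]:
    """Term weight 1/(d+1), d = minimum edge distance down to a leaf.

    Leaves (terms with no children) have d = 0 and weight 1.  Distances are
    found by a multi-source breadth-first search upward from the leaves along
    the child -> parent edges, which yields for every term the minimum number
    of child-edges to any descendant leaf.
    """
    ontology.assert_acyclic()
    kids = ontology.children_of()
    parents = ontology.parents_of()
    dist: dict[str, int] = {t: 0 for t in ontology.terms if not kids[t]}
    queue = deque(dist)
    while queue:
        t = queue.popleft()
        for p in parents[t]:
            if p not in dist:
                dist[p] = dist[t] + 1
                queue.append(p)
    return {t: 1.0 / (dist[t] + 1) for t in ontology.terms}


def propagate_ancestors(
    annotations: Mapping[str, set], ontology: Ontology
) -> dict[str, set]:
    """True-path closure: extend each term set with all its ancestors."""
    parents = ontology.parents_of()
    closure: dict[str, frozenset] = {}

    def ancestors(term: str) -> frozenset:
        if term not in closure:
            acc = {term}
            for p in parents.get(term, ()):
                acc |= ancestors(p)
            closure[term] = frozenset(acc)
        return closure[term]

    out: dict[str, set] = {}
    for protein, terms in annotations.items():
        full: set = set()
        for t in terms:
            full |= ancestors(t) if t in ontology.terms else {t}
        out[protein] = full
    return out


# ---------------------------------------------------------------------------
# Similarity measures
# ---------------------------------------------------------------------------

def jaccard(a: Iterable, b: Iterable) -> float:
    """|A∩B| / |A∪B|; two empty sets score 0 by convention."""
    a, b = set(a), set(b)
    union = len(a | b)
    if union == 0:
        return 0.0
    return len(a & b) / union


def hierarchical_jaccard(
    a: Iterable, b: Iterable, weights: Mapping[str, float]
) -> float:
    """Depth-weighted Jaccard: sum of weights over A∩B / sum over A∪B."""
    a, b = set(a), set(b)
    unknown = (a | b) - weights.keys()
    if unknown:
        raise KeyError(f"unweighted terms: {sorted(unknown)[:5]}")
    # summation in sorted term order keeps the value deterministic and
    # makes identical sets score exactly 1
    union_w = sum(weights[t] for t in sorted(a | b))
    if union_w == 0:
        return 0.0
    return sum(weights[t] for t in sorted(a & b)) / union_w


# ---------------------------------------------------------------------------
# Networks
# ---------------------------------------------------------------------------

@dataclass
class SimilarityNetwork:
    """Sparse symmetric similarity map over named proteins.

    Edges are stored once under the lexicographically sorted accession pair;
    zero-weight pairs are omitted.
    """

    nodes: set[str] = field(default_factory=set)
    edges: dict[tuple[str, str], float] = field(default_factory=dict)

    @staticmethod
    def _key(a: str, b: str) -> tuple[str, str]:
        if a == b:
            raise ValueError(f"self-pair {a!r}")
        return (a, b) if a < b else (b, a)

    def set_edge(self, a: str, b: str, w: float) -> None:
        self.nodes.update((a, b))
        if w != 0.0:
            self.edges[self._key(a, b)] = float(w)

    def get(self, a: str, b: str, default: float = 0.0) -> float:
        return self.edges.get(self._key(a, b), default)

    @property
    def n_edges(self) -> int:
        return len(self.edges)

    def copy(self) -> "SimilarityNetwork":
        return SimilarityNetwork(nodes=set(self.nodes), edges=dict(self.edges))

    @classmethod
    def from_weighted_graph(cls, graph) -> "SimilarityNetwork":
        """View a dense-id weighted graph as an accession-keyed network."""
        net = cls(nodes=set(graph.accessions))
        for i, j, w in zip(graph.src, graph.dst, graph.weight):
            net.set_edge(graph.accessions[i], graph.accessions[j], float(w))
        return net

    def to_weighted_graph(self):
        """Materialize as a dense-id graph; isolated nodes are kept.

        Accessions are sorted so the id assignment is reproducible.
        """
        from .graph_store import WeightedGraph
        import numpy as np

        accessions = sorted(self.nodes)
        id_map = {a: i for i, a in enumerate(accessions)}
        items = sorted(self.edges.items())
        src = np.array([id_map[a] for (a, _), _ in items], dtype=np.int64)
        dst = np.array([id_map[b] for (_, b), _ in items], dtype=np.int64)
        w = np.array([v for _, v in items], dtype=np.float64)
        return WeightedGraph(
            n=len(accessions), src=src, dst=dst, weight=w,
            accessions=accessions,
        )

    def write_tsv(self, path: str | Path) -> None:
        with Path(path).open("w") as fh:
            fh.write("#src\tdst\tweight\n")
            for (a, b), w in sorted(self.edges.items()):
                fh.write(f"{a}\t{b}\t{w:.17g}\n")

    @classmethod
    def read_tsv(cls, path: str | Path) -> "SimilarityNetwork":
        net = cls()
        with Path(path).open() as fh:
            for line in fh:
                line = line.strip()
                if not line or line.startswith("#"):
                    continue
                a, b, w = line.split("\t")[:3]
                net.set_edge(a, b, float(w))
        return net


def build_similarity_network(
    profiles: ProfileTable,
    measure: str = "jaccard",
    weights: Optional[Mapping[str, float]] = None,
    min_weight: float = 0.0,
) -> SimilarityNetwork:
    """Score every unordered protein pair; keep non-zero similarities.

    ``measure`` is ``"jaccard"`` for plain binary profiles or
    ``"hierarchical"`` for term profiles with depth ``weights``.
    ``min_weight`` optionally sparsifies the result.
    """
    if len(profiles) < 2:
        raise ValueError("need at least 2 protein profiles")
    if measure == "jaccard":
        score = lambda x, y: jaccard(x, y)
    elif measure in ("hierarchical", "hier"):
        if weights is None:
            raise ValueError("hierarchical measure requires term weights")
        score = lambda x, y: hierarchical_jaccard(x, y, weights)
    else:
        raise ValueError(f"unknown measure {measure!r}")
    net = SimilarityNetwork()
    names = list(profiles)
    net.nodes.update(names)
    for idx, a in enumerate(names):
        pa = profiles[a]
        for b in names[idx + 1:]:
            s = score(pa, profiles[b])
            if s > 0.0 and s >= min_weight:
                net.set_edge(a, b, s)
    return net


def ua_integrate(
    networks: list[SimilarityNetwork],
    n_override: Optional[int] = None,
) -> SimilarityNetwork:
    """Unweighted-average consensus network.

    The integrated weight of a pair is the mean of its weights across the
    ``n`` input networks, a pair absent from a network contributing 0;
    ``n_override`` replaces the divisor (e.g. when integrating a subset).
    """
    if not networks:
        raise ValueError("need at least one network")
    n = n_override if n_override is not None else len(networks)
    if n < 1:
        raise ValueError("divisor must be >= 1")
    sums: dict[tuple[str, str], float] = defaultdict(float)
    out = SimilarityNetwork()
    for net in networks:
        out.nodes.update(net.nodes)
        for key, w in net.edges.items():
            sums[key] += w
    for (a, b), total in sums.items():
        out.set_edge(a, b, total / n)
    return out


# ---------------------------------------------------------------------------
# Annotations
# ---------------------------------------------------------------------------

def read_profiles(path: str | Path) -> dict[str, set]:
    """Read ``accession<TAB>comma-separated-feature-ids`` TSV."""
    table: dict[str, set] = {}
    with Path(path).open() as fh:
        for line in fh:
            line = line.rstrip("\n")
            if not line or line.startswith("#"):
                continue
            parts = line.split("\t")
            acc = parts[0]
            feats = parts[1] if len(parts) > 1 else ""
            table[acc] = {f for f in feats.split(",") if f}
    return table


def write_profiles(table: Mapping[str, set], path: str | Path) -> None:
    with Path(path).open("w") as fh:
        fh.write("#accession\tfeatures\n")
        for acc in sorted(table):
            fh.write(f"{acc}\t{','.join(sorted(table[acc]))}\n")


def read_annotations(
    path: str | Path, min_confidence: Optional[float] = None
) -> dict[str, set]:
    """Read ``accession<TAB>term[<TAB>confidence]`` rows into term sets.

    With ``min_confidence`` set, rows whose third column falls below it are
    dropped (rows without a confidence column always pass).
    """
    table: dict[str, set] = defaultdict(set)
    with Path(path).open() as fh:
        for line in fh:
            line = line.strip()
            if not line or line.startswith("#"):
                continue
            parts = line.split("\t")
            acc, term = parts[0], parts[1]
            if (
                min_confidence is not None
                and len(parts) > 2
                and float(parts[2]) < min_confidence
            ):
                continue
            table[acc].add(term)
    return dict(table)


def write_annotations(table: Mapping[str, set], path: str | Path) -> None:
    with Path(path).open("w") as fh:
        fh.write("#accession\tterm\n")
        for acc in sorted(table):
            for term in sorted(table[acc]):
                fh.write(f"{acc}\t{term}\n")


def filter_classes(
    annotations: Mapping[str, set],
    min_positives: int,
    max_positives: Optional[int] = None,
) -> list[str]:
    """Terms with at least ``min_positives`` (and at most ``max_positives``)
    annotated proteins, sorted for determinism."""
    if min_positives < 1:
        raise ValueError("min_positives must be >= 1")
    counts: dict[str, int] = defaultdict(int)
    for terms in annotations.values():
        for t in set(terms):
            counts[t] += 1
    kept = [
        t
        for t, c in counts.items()
        if c >= min_positives and (max_positives is None or c <= max_positives)
    ]
    return sorted(kept)
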