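"""Multi-species network assembly via orthology cliques.

Per-species protein networks form disconnected blocks of one big graph; to
let annotations propagate across species, clusters of orthologous genes
(NOGs) are filtered to a chosen core species set, reduced to the
species-consistent ones (exactly one protein per represented species) and
turned into cliques of edges joining their members.  A connected-components
analysis quantifies how much the augmentation stitches the blocks together.
"""

from __future__ import annotations

from collections import defaultdict, deque
from pathlib import Path
from typing import Iterable, Mapping

from .netbuild import SimilarityNetwork

#: cluster id -> member protein accessions
NogTable = dict[str, set]
#: protein accession -> species identifier
SpeciesMap = Mapping[str, str]


def read_nogs(path: str | Path) -> NogTable:
    """Read ``nog_id<TAB>accession`` rows."""
    nogs: NogTable = defaultdict(set)
    with Path(path).open() as fh:
        for line in fh:
            line = line.strip()
            if not line or line.startswith("#"):
                continue
            nog_id, acc = line.split("\t")[:2]
            nogs[nog_id].add(acc)
    return dict(nogs)


def write_nogs(nogs: NogTable, path: str | Path) -> None:
    with Path(path).open("w") as fh:
        fh.write("#nog_id\taccession\n")
        for nog_id in sorted(nogs):
            for acc in sorted(nogs[nog_id]):
                fh.write(f"{nog_id}\t{acc}\n")


def read_species_map(path: str | Path) -> dict[str, str]:
    """Read ``accession<TAB>species_id`` rows."""
    table: dict[str, str] = {}
    with Path(path).open() as fh:
        for line in fh:
            line = line.strip()
            if not line or line.startswith("#"):
                continue
            acc, sp = line.split("\t")[:2]
            table[acc] = sp
    return table


def write_species_map(table: SpeciesMap, path: str | Path) -> None:
    with Path(path).open("w") as fh:
        fh.write("#accession\tspecies_id\n")
        for acc in sorted(table):
            fh.write(f"{acc}\t{table[acc]}\n")


def filter_nog_members(
    nogs: NogTable,
    core_species: Iterable[str],
    species_map: SpeciesMap,
) -> NogTable:
    """Restrict every cluster to proteins of the core species; drop empties."""
    core = set(core_species)
    out: NogTable = {}
    for nog_id, members in nogs.items():
        kept = set()
        for acc in members:
            if acc not in species_map:
                raise KeyError(f"protein {acc!r} has no species mapping")
            if species_map[acc] in core:
                kept.add(acc)
        if kept:
            out[nog_id] = kept
    return out


def select_consistent_nogs(nogs: NogTable, species_map: SpeciesMap) -> NogTable:
    """Keep clusters whose member count equals their distinct-species count,
    i.e. exactly one protein per represented species."""
    out: NogTable = {}
    for nog_id, members in nogs.items():
        species = {species_map[acc] for acc in members}
        if len(members) == len(species):
            out[nog_id] = set(members)
    return out


def add_ortholog_edges(
    network: SimilarityNetwork,
    nogs: NogTable,
    weight: float = 1.0,
) -> tuple[SimilarityNetwork, int]:
    """Add the full clique over each cluster's members.

    A cluster of size ``s`` contributes all ``s*(s-1)/2`` unordered pairs.
    A pair already in the network keeps ``max(existing, weight)`` and does
    not count as added.  Returns the augmented copy and the added-edge count.
    """
    if weight <= 0:
        raise ValueError("orthology edge weight must be > 0")
    out = network.copy()
    added = 0
    for members in nogs.values():
        mm = sorted(members)
        for i, a in enumerate(mm):
            for b in mm[i + 1:]:
                existing = out.edges.get(out._key(a, b))
                if existing is None:
                    out.set_edge(a, b, weight)
                    added += 1
                else:
                    out.set_edge(a, b, max(existing, weight))
    return out, added


def connected_components(
    network: SimilarityNetwork,
) -> tuple[dict[str, int], list[int], float]:
    """Label components by breadth-first traversal.

    Returns (node -> component label, component sizes in descending order,
    edge density 2|E| / (n (n-1))).  Labels are assigned in order of first
    discovery over the sorted node list.
    """
    adj: dict[str, list[str]] = {node: [] for node in network.nodes}
    for (a, b) in network.edges:
        adj[a].append(b)
        adj[b].append(a)
    labels: dict[str, int] = {}
    sizes: list[int] = []
    for start in sorted(network.nodes):
        if start in labels:
            continue
        label = len(sizes)
        queue = deque([start])
        labels[start] = label
        size = 0
        while queue:
            node = queue.popleft()
            size += 1
            for nb in adj[node]:
                if nb not in labels:
                    labels[nb] = label
                    queue.append(nb)
        sizes.append(size)
    n = len(network.nodes)
    density = 2.0 * network.n_edges / (n * (n - 1)) if n > 1 else 0.0
    return labels, sorted(sizes, reverse=True), density
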