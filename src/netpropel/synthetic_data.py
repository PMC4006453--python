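"""Synthetic multi-species fixtures with planted functional modules.

The generators emulate the structure the method assumes in real data:
per-species protein networks made of dense functional modules with sparse
background edges (strong intra-module weights, weak inter-module ones),
binary feature profiles aligned with the modules, a small tree-shaped
ontology for depth-weight checks, and a multi-species setting where species
blocks are mutually disconnected and joined only by species-consistent
orthology clusters, with annotations emitted for a subset of species (the
annotation-transfer scenario).

All randomness derives from a single master seed; every sub-generator draws
from its own fixed-offset stream so adding one generator never perturbs the
output of another.
"""

from __future__ import annotations

from dataclasses import dataclass, field
from pathlib import Path

import numpy as np

from .graph_store import WeightedGraph, write_edge_list
from .netbuild import Ontology, write_annotations, write_profiles
from .multispecies import write_nogs, write_species_map

# fixed stream offsets for sub-generators
_STREAM_GRAPH = 1
_STREAM_PROFILES = 2
_STREAM_NOGS = 3
_STREAM_ANNOTATIONS = 4


@dataclass
class SyntheticSpec:
    """Parameters of the planted-module multi-species generator.

    Defaults describe a small but structured setting: four species of 60
    proteins each, three functional modules of 20 proteins per species,
    dense strong edges inside modules (p_in = 0.3, weights uniform on
    [0.5, 1]) and sparse weak background edges between modules (p_out =
    0.02, weights uniform on [0.05, 0.3]); half of the aligned orthologous
    protein slots carry a species-consistent NOG; annotations cover every
    module member of the annotated species.
    """

    n_per_species: int = 60
    n_species: int = 4
    n_modules: int = 3
    p_in: float = 0.3
    p_out: float = 0.02
    w_intra: tuple[float, float] = (0.5, 1.0)
    w_inter: tuple[float, float] = (0.05, 0.3)
    annotation_sparsity: float = 1.0
    annotated_species_fraction: float = 0.5
    nog_rate: float = 0.5
    seed: int = 42

    def validate(self) -> None:
        if not (0.0 <= self.p_out < self.p_in <= 1.0):
            raise ValueError("need 0 <= p_out < p_in <= 1")
        if not 0.0 < self.annotation_sparsity <= 1.0:
            raise ValueError("annotation_sparsity must be in (0, 1]")
        if not 0.0 <= self.nog_rate <= 1.0:
            raise ValueError("nog_rate must be in [0, 1]")


def _module_labels(n: int, n_modules: int) -> np.ndarray:
    """Contiguous near-equal module blocks over [0, n)."""
    return (np.arange(n) * n_modules // n).astype(np.int64)


def gen_planted_partition(
    spec: SyntheticSpec,
    species: int = 0,
    accession_prefix: str | None = None,
) -> tuple[WeightedGraph, np.ndarray]:
    """One species' planted-partition network and its module labels.

    Pairs inside a module are joined with probability ``p_in`` and weight
    uniform on ``w_intra``; pairs across modules with probability ``p_out``
    and weight uniform on ``w_inter``, so expected intra-degree exceeds
    inter-degree and module membership is recoverable from the topology.
    """
    spec.validate()
    n = spec.n_per_species
    labels = _module_labels(n, spec.n_modules)
    rng = np.random.default_rng((spec.seed, _STREAM_GRAPH, species))
    iu, ju = np.triu_indices(n, k=1)
    same = labels[iu] == labels[ju]
    p = np.where(same, spec.p_in, spec.p_out)
    keep = rng.random(iu.size) < p
    lo = np.where(same, spec.w_intra[0], spec.w_inter[0])
    hi = np.where(same, spec.w_intra[1], spec.w_inter[1])
    w = lo + (hi - lo) * rng.random(iu.size)
    prefix = accession_prefix if accession_prefix is not None else "p"
    accessions = [f"{prefix}{i:04d}" for i in range(n)]
    graph = WeightedGraph(
        n=n,
        src=iu[keep],
        dst=ju[keep],
        weight=w[keep],
        accessions=accessions,
    )
    return graph, labels


def gen_profiles(
    module_labels: np.ndarray,
    n_features: int,
    noise_flip_prob: float,
    seed: int,
    accessions: list[str] | None = None,
) -> dict[str, set]:
    """Module-block binary profiles with independent bit flips.

    The feature universe is split evenly across modules; a protein's clean
    profile is its module's block, then every (protein, feature) bit flips
    with probability ``noise_flip_prob``.  With zero noise, within-module
    Jaccard is 1 and cross-module Jaccard is 0.
    """
    if not 0.0 <= noise_flip_prob < 0.5:
        raise ValueError("noise_flip_prob must be in [0, 0.5)")
    module_labels = np.asarray(module_labels)
    n = module_labels.size
    n_modules = int(module_labels.max()) + 1 if n else 0
    if accessions is None:
        accessions = [f"p{i:04d}" for i in range(n)]
    rng = np.random.default_rng((seed, _STREAM_PROFILES))
    feature_module = _module_labels(n_features, n_modules)
    clean = feature_module[None, :] == module_labels[:, None]
    flips = rng.random((n, n_features)) < noise_flip_prob
    bits = clean ^ flips
    return {
        accessions[i]: {f"f{k}" for k in np.flatnonzero(bits[i])}
        for i in range(n)
    }


def gen_toy_ontology(
    depth: int, branching: int
) -> tuple[Ontology, dict[str, float]]:
    """Complete tree ontology plus the expected depth weights.

    A term ``branching**level`` wide at level ``level`` (root = 0, leaves =
    ``depth``) sits ``depth - level`` child-edges above the nearest leaf, so
    its expected weight is ``1 / (depth - level + 1)``.
    """
    if depth < 0 or branching < 1:
        raise ValueError("need depth >= 0 and branching >= 1")
    terms: set[str] = set()
    edges: list[tuple[str, str]] = []
    expected: dict[str, float] = {}
    level_terms = ["T"]
    for level in range(depth + 1):
        for t in level_terms:
            terms.add(t)
            expected[t] = 1.0 / (depth - level + 1)
        if level < depth:
            next_level = []
            for t in level_terms:
                for b in range(branching):
                    child = f"{t}.{b}"
                    edges.append((child, t))
                    next_level.append(child)
            level_terms = next_level
    return Ontology(terms=terms, edges=edges), expected


@dataclass
class MultiSpeciesData:
    """Everything the multi-species pipeline consumes, from one seed."""

    spec: SyntheticSpec
    species_ids: list[str]
    per_species: dict[str, WeightedGraph]
    merged: WeightedGraph
    module_labels: np.ndarray  # over merged vertex ids
    species_map: dict[str, str]
    nogs: dict[str, set]
    annotations: dict[str, set]
    annotated_species: list[str] = field(default_factory=list)

    def term_for_module(self, module: int) -> str:
        return f"GO:MOD{module}"


def gen_multispecies(spec: SyntheticSpec) -> MultiSpeciesData:
    """Disconnected per-species planted networks plus NOGs and annotations.

    Modules are aligned across species (module ``m`` of every species is one
    orthologous functional group).  For a ``nog_rate`` fraction of the
    within-module protein slots, a species-consistent NOG links the slot's
    protein in every species.  Annotations (one term per module, covering an
    ``annotation_sparsity`` fraction of its members) are emitted only for
    the first ``ceil(annotated_species_fraction * n_species)`` species.
    """
    spec.validate()
    species_ids = [f"sp{s}" for s in range(spec.n_species)]
    per_species: dict[str, WeightedGraph] = {}
    labels_per_species: dict[str, np.ndarray] = {}
    for s, sp_id in enumerate(species_ids):
        g, labels = gen_planted_partition(
            spec, species=s, accession_prefix=f"{sp_id}_p"
        )
        per_species[sp_id] = g
        labels_per_species[sp_id] = labels

    # merged graph: disjoint union, species blocks in order
    accessions: list[str] = []
    merged_labels: list[int] = []
    species_map: dict[str, str] = {}
    src_all, dst_all, w_all = [], [], []
    offset = 0
    for sp_id in species_ids:
        g = per_species[sp_id]
        accessions.extend(g.accessions)
        merged_labels.extend(labels_per_species[sp_id].tolist())
        for acc in g.accessions:
            species_map[acc] = sp_id
        src_all.append(g.src + offset)
        dst_all.append(g.dst + offset)
        w_all.append(g.weight)
        offset += g.n
    merged = WeightedGraph(
        n=offset,
        src=np.concatenate(src_all),
        dst=np.concatenate(dst_all),
        weight=np.concatenate(w_all),
        accessions=accessions,
    )

    # species-consistent NOGs over aligned protein slots
    rng = np.random.default_rng((spec.seed, _STREAM_NOGS))
    nogs: dict[str, set] = {}
    slot_selected = rng.random(spec.n_per_species) < spec.nog_rate
    for slot in np.flatnonzero(slot_selected):
        members = {f"{sp_id}_p{slot:04d}" for sp_id in species_ids}
        nogs[f"NOG{int(slot):04d}"] = members

    # annotations only in a subset of species
    n_annotated = int(np.ceil(spec.annotated_species_fraction * spec.n_species))
    annotated_species = species_ids[:max(1, n_annotated)]
    rng_ann = np.random.default_rng((spec.seed, _STREAM_ANNOTATIONS))
    annotations: dict[str, set] = {}
    for sp_id in annotated_species:
        labels = labels_per_species[sp_id]
        keep = rng_ann.random(labels.size) < spec.annotation_sparsity
        for i in np.flatnonzero(keep):
            acc = f"{sp_id}_p{int(i):04d}"
            annotations.setdefault(acc, set()).add(f"GO:MOD{int(labels[i])}")

    return MultiSpeciesData(
        spec=spec,
        species_ids=species_ids,
        per_species=per_species,
        merged=merged,
        module_labels=np.asarray(merged_labels),
        species_map=species_map,
        nogs=nogs,
        annotations=annotations,
        annotated_species=annotated_species,
    )


def write_fixture_dir(data: MultiSpeciesData, directory: str | Path) -> None:
    """Write every fixture file as TSV, byte-reproducible from the seed."""
    directory = Path(directory)
    directory.mkdir(parents=True, exist_ok=True)
    write_edge_list(data.merged, directory / "merged.edges.tsv")
    for sp_id, g in data.per_species.items():
        write_edge_list(g, directory / f"{sp_id}.edges.tsv")
    write_species_map(data.species_map, directory / "species.tsv")
    write_nogs(data.nogs, directory / "nogs.tsv")
    write_annotations(data.annotations, directory / "annotations.tsv")
    profiles = gen_profiles(
        data.module_labels,
        n_features=30 * data.spec.n_modules,
        noise_flip_prob=0.05,
        seed=data.spec.seed,
        accessions=data.merged.accessions,
    )
    write_profiles(profiles, directory / "profiles.tsv")
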