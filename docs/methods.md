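# Methods

## The walk and its local form

The scorer is the "vanilla" random walk on a weighted undirected functional
network: with transition matrix `Q = D⁻¹W` (`D` the diagonal of weighted
degrees), start probability `1/|C|` on the class's annotated proteins and
`p^{t+1} = Qᵀ p^t`. Because `W` is symmetric, the update resolved at one
vertex needs only that vertex's incident edge weights, the neighbours'
previous probabilities and their precomputed inverse degrees — an in-RAM
vector of three doubles per vertex. Per-step cost is proportional to the
arc count, so sparse graphs iterate in O(n).

Assumptions: the network is a simple graph (no self-loops, no parallel
edges) with finite positive weights; classes are binary (every protein not
annotated to the class is treated as a negative); the walk runs a small
fixed number of steps (1–3 in practice) rather than to stationarity, since
short walks preserve locality of functional signal.

### Dangling vertices

A zero-degree vertex gets `inv_degree = 0`, so probability mass placed on
it vanishes at the next step. We keep the update rule literal and document
the leak rather than renormalizing; `renormalize=True` (CLI
`--renormalize`) rescales the vector to unit mass after each step for users
who prefer a proper distribution. Convergence mode uses the max-norm
change with default tolerance 1e-6 and a 1000-step cap.

## Out-of-core execution

Vertices are split into `K` contiguous intervals; each interval owns one
shard file holding every directed in-arc of its vertices (both directions
of every undirected edge are stored, which doubles disk but keeps the
loader uniform), as fixed-size little-endian records (u32 src, u32 dst,
f64 weight) sorted by (src, dst). Interval boundaries are chosen greedily
to balance *arc* counts — the quantity that determines shard memory — not
vertex counts; `K` is exposed as a parameter since the right value depends
on available RAM. A JSON manifest records sizes, boundaries, per-shard
window offsets and SHA-256 checksums (verified on open); the
accession↔id map is a TSV beside it.

A full pass loads each interval's shard entirely (one non-sequential read)
and advances one read window per other shard to touch the interval's
out-arc blocks (one non-sequential read each, their offsets precomputed in
the manifest) — at most `K` non-sequential reads per interval and `K²` per
pass, which the pass instruments and the tests assert.

Execution is strictly synchronous (Jacobi): updates read only
previous-step values; the two probability buffers physically swap roles at
iteration end (observationally equivalent to alternating reads by
iteration parity). Synchrony makes the result exactly independent of `K`
— the per-vertex in-arc sequence is identical under any interval layout,
so floating-point summation order is too, and K=1 versus K=5 agree
bitwise. The in-memory sparse-matrix path agrees with the sharded path to
~1e-12 (summation-order rounding only). Asynchronous execution is
deliberately out of scope: it would trade determinism for speed.

## Network construction

- **Classical Jaccard** between binary profiles; the empty∩empty pair
  scores 0 (not NaN), keeping networks sparse.
- **Hierarchical Jaccard** weighs each GO term `1/(d+1)`, `d` its minimum
  child-edge distance down to a leaf of the ontology *as supplied* (the
  caller may first restrict the ontology to the annotation corpus). The
  minimum over descendant leaves is used where several paths exist.
  Annotation profiles are not ancestor-closed by default;
  `propagate_ancestors` / `--propagate-ancestors` applies the true-path
  closure first.
- **UA integration** averages edge weights across networks with missing
  pairs as 0; it is idempotent on a single network and bounded by the
  largest input weight. No sparsification is applied by default; a
  `min_weight` cutoff is available.
- **Class filtering** keeps terms with at least `min_positives` annotated
  proteins (boundary inclusive: a term with exactly the threshold is
  kept), with an optional upper bound for the 20–100 regime used on
  large networks.

## Multi-species assembly

NOG clusters are restricted to the chosen core species (an unmapped
protein is an error, not silently dropped), then only species-consistent
clusters — exactly one protein per represented species — are kept, and
each surviving cluster contributes its full clique of edges. Orthology
edges default to weight 1.0 (the natural ceiling of Jaccard-scaled
networks) and a pre-existing edge keeps `max(existing, new)`, making the
augmentation monotone and idempotent; the added-edge count excludes
pre-existing pairs. Components are labelled by breadth-first traversal;
density is `2|E|/(n(n−1))`.

## Evaluation protocol

Stratified 5-fold cross-validation per term: folds are dealt round-robin
after a seeded shuffle, so per-fold class counts differ by at most one and
the split is reproducible from the seed. Per fold the walk is seeded with
the training positives only, and only held-out vertices' scores are
recorded; metrics are computed on the pooled held-out vector (one AUC per
term), with `per_fold=True` switching to fold-averaged metrics. AUC uses
the Mann–Whitney form with midranks (tie-robust); precision-at-recall
ranks by descending score with ascending-id tie-break and reports
precision at the smallest cutoff reaching the recall level.

`eval_vertices` restricts the fold split and the metrics to a vertex
subset, e.g. the proteins of one species in a multi-species network;
positives outside the subset then act as seeds in every fold. This is the
annotation-transfer comparison: the single- and multi-species settings are
scored on the same vertices, so their AUCs are directly comparable.

The paired Wilcoxon signed-rank test drops zero differences, uses midranks
of |d|, and computes the two-sided p exactly for ≤ 25 non-zero pairs by
convolving the per-pair sign generating functions (identical to exhaustive
sign enumeration, but polynomial-time); larger samples use the normal
approximation with continuity correction and tie-corrected variance
`Σr²/4`. All-zero differences report p = 1, not significant.

## Synthetic data

The generators produce the structure the method assumes, not a calibrated
imitation of any real proteome. Defaults (chosen once): 4 species × 60
proteins, 3 functional modules of 20, intra-module edge probability 0.3
with weights uniform on [0.5, 1], inter-module probability 0.02 with
weights on [0.05, 0.3] — a clear but noisy community structure in which
direct neighbours separate the classes, mirroring how Jaccard-built
networks concentrate weight inside functional groups. Modules are aligned
across species; half of the aligned protein slots carry a
species-consistent NOG; annotations (one term per module, 20 positives —
exactly the class-filter threshold) are emitted for the first half of the
species, giving the transfer scenario where the remaining species are
entirely unannotated. A single master seed feeds fixed-offset
sub-streams, so adding a generator never perturbs another's output and
fixture files are byte-reproducible.

What passing tests on these fixtures does *not* show: real networks have
heavy-tailed degree distributions, classes that straddle modules, and
annotation noise; recovery numbers near 1.0 here say the machinery is
correct, not that real-data AUCs will be high.

## Problem sizes and numerics

Test and acceptance runs use graphs of n ≤ 240 (dozens to low hundreds of
vertices), 50–100 replicate graphs for oracle comparisons and 20 seeded
replicates for the multi- vs single-species direction — sizes at which
dense oracles are exact and the full suite completes in seconds.
Tolerances: sharded-vs-dense walk 1e-10 (observed ~1e-16), in-memory vs
sharded 1e-12, mass conservation 1e-12, metric oracles exact to float
round-off. Ties everywhere break by ascending vertex id so every ranking
is deterministic.

## Known limitations

No random walk with restart, PageRank damping, or kernelized variants; no
asynchronous or multi-threaded execution; shards are immutable after
construction (no graph mutation); OBO parsing is left to the caller (the
ontology arrives as a child→parent TSV); the STRING/eggNOG download and
confidence pipeline is out of scope beyond a generic confidence-column
filter in the annotations reader.
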