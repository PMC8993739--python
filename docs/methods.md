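# Methods

`musclegrn` implements an in-silico workflow for judging how closely the
transcriptome of a reprogrammed (trans-differentiated) skeletal-muscle cell
population resembles mature, functional skeletal muscle. It has two halves:
the *reference-building* half derives comparator objects from public-style
inputs (a co-expression network of normal muscle, a functional gene list, an
interaction network, a multi-tissue expression atlas, stage-ordered
differentiation profiles), and the *scoring* half measures how much of each
comparator a candidate transcriptome recapitulates.

## Reference construction

### Co-expression modules (WGCNA-style)

Given a genes × samples matrix of log2(FPKM + 1) values, the pipeline is the
classical weighted co-expression recipe:

1. **Sample outliers.** Each sample's connectivity is its summed Pearson
   correlation to all other samples; samples with a connectivity z-score
   below −2.5 are dropped in one pass. The threshold is the conventional
   one for bulk tissue panels and is configurable.
2. **Soft threshold.** For each candidate power β (default 1–20) the
   unsigned adjacency `a_ij = |cor(x_i, x_j)|^β` is formed and node
   connectivity `k_i = Σ_j a_ij` computed. Connectivities are binned into
   `n_bins = 10` equal-width bins; log10(bin frequency) is regressed on
   log10(mean bin connectivity) and the fit R² is signed by the negated
   slope, so distributions where frequency *rises* with connectivity score
   negatively. β is the smallest power with signed R² ≥ 0.8 **and** mean
   connectivity ≥ 1. The connectivity floor exists because a power that
   drives nearly all adjacencies to zero produces a degenerate, spuriously
   power-law-like histogram: without it, pure-noise matrices "qualify" at
   high powers even though the resulting network is empty. If no power
   qualifies the best power is returned with a flag. Equal-width binning is
   used because equal-count binning makes the bin frequency constant by
   construction, leaving nothing to regress.
3. **Topological overlap.** `TOM_ij = (ℓ_ij + a_ij) / (min(k_i,k_j) + 1 −
   a_ij)` with `ℓ_ij = Σ_u a_iu a_uj`, `TOM_ii = 1`. TOM rewards shared
   neighbourhoods and damps one-off spurious correlations.
4. **Modules.** Average-linkage hierarchical clustering on `1 − TOM`, cut
   statically at 0.99 × the maximum merge height. This is the simple "tree"
   variant of dendrogram cutting; the dynamic hybrid variant needs
   additional unpublished parameters, and on block-structured data the
   static cut recovers planted modules exactly (verified by the adjusted
   Rand index property below). Clusters smaller than `min_module_size = 30`
   are labelled 0 (unassigned); modules are numbered 1..M by decreasing
   size, ties broken by lowest gene index.
5. **Eigengenes and merging.** A module eigengene is the first right
   singular vector of the module's gene-standardised submatrix (unit norm
   across samples, sign oriented so its correlation with the module's mean
   standardised profile is ≥ 0; the fraction of variance explained is
   reported). Modules whose eigengenes correlate above 0.75 are merged
   iteratively — always the closest pair first, eigengenes recomputed after
   every merge — until all pairwise eigengene correlations are ≤ 0.75
   (merge cut height 0.25). The operation is idempotent.

The network is unsigned (`|cor|^β`), switchable to signed
(`((1+cor)/2)^β`); unsigned matches the convention of converting
correlation coefficients directly into connection strengths.

### Functional gene list and interaction hubs

GO annotations are mined by case-insensitive substring match of curated
keywords against term text (no stemming — "Z disk" does not match "Z disc";
keyword curation is deliberately the user's input). The matched genes are
mapped to human symbols through a table-driven one-to-one ortholog map;
unmapped sources and many-to-one collapses are logged.

The candidate set for the core gene regulatory network (GRN) is the
intersection of the co-expressed genes and the functional list. The
interaction graph over these candidates (STRING-style scored edge list,
scores on [0,1], with a reader option for 0–1000 integer exports) is
filtered at combined confidence ≥ 0.9 (inclusive), and hubs are selected by
three criteria:

1. degree ≥ 3 in the filtered graph ("more than 2 connections"),
2. rank within `top_k` under at least `min_methods` of twelve topological
   centralities (dense descending ranks, ties share a rank), and
3. membership in, or direct adjacency to, a set of seed marker genes
   (fiber-type I/II markers in the intended use).

Defaults `top_k = |candidates|`, `min_methods = 1` reproduce the permissive
reading of an unquantified multi-centrality ranking; both are exposed in
configuration, as is the seed-association rule (distance ≤ 1). Per-node
provenance (degree, all ranks, seed adjacency, per-criterion pass flags) is
recorded.

The twelve centralities follow their operational definitions: degree;
harmonic closeness (Σ 1/d, robust to disconnection); eccentricity
centrality (1/eccentricity within the node's component); radiality
(Σ (Δ_C + 1 − d)/(n_C − 1) per component with diameter Δ_C); betweenness
(Σ σ_st(v)/σ_st over unordered pairs); stress (count of shortest paths
through v); clustering coefficient; MNC (order of the largest connected
component of the open neighbourhood); DMNC (|E|/|V|^1.7 of that component);
MCC (Σ (|C|−1)! over maximal cliques of size ≥ 2 containing v, 0 for
isolated nodes); bottleneck (over shortest-path trees from every root,
+1 whenever a node's strict descendant count exceeds a quarter of the tree;
trees are made deterministic by parenting each node to its
lexicographically smallest neighbour on the shallower level); and EPC, the
edge-percolation component score — the mean number of nodes reachable from
v across `n_reductions = 1000` random subgraphs keeping each edge with
probability 0.5, seeded and reproducible. Isolated nodes score 0 under
every method. Each deterministic centrality is verified against exhaustive
enumeration (path enumeration, subset/clique enumeration, full percolation
expectation) on hundreds of small random graphs.

### Muscle-restricted signature

From a consensus multi-tissue atlas of NX (consensus normalised expression)
values, a gene is muscle-restricted iff NX > 1 (strict) in skeletal muscle
and NX ≤ 1 in every other tissue. The same "expressed ⇔ value > 1"
convention is used everywhere a binary expression call is needed; the
threshold is configurable because the convention, while standard for NX,
is a choice for FPKM-scale data.

### Stage-onset and maintenance genes

Stage profiles are gene × ordered-stage mean-expression tables over the
myogenic axis (pluripotent → presomite → myogenic progenitor → myoblast →
myotube). A gene has *onset* at stage k iff it is ≤ threshold at every
stage before k and > threshold at k and all later stages; genes whose
expression lapses after onset, or that are never expressed, are excluded.
The onset sets are a disjoint partition by construction (asserted on every
run). *Maintenance* genes are onset genes whose stage means increase
strictly from onset to the final stage, each step exceeding
`min_rel_increase` × the previous value (default 0, i.e. any strict
increase). A maintenance gene must have at least one increasing step, so
final-stage-onset genes never qualify — a vacuous "monotone" call on a
single point would be meaningless.

## Scoring

DEG tables (gene, signed linear fold change, p-value; a reader flag accepts
log2 folds) are filtered at p < 0.05 (strict) and |fold| ≥ 2 (inclusive).
Per cell type the report contains: overlap counts/percentages of
up/downregulated genes with the hub reference; stage composition of the
upregulated genes (percentage relative to each stage set's size); the
number of signature genes expressed; and maintenance-gene coverage. Across
cell types, the up/down intersections are reported; a gene up in one cell
type and down in another cannot be common to either direction and is listed
as a conflict rather than raising an error.

Percentages are rounded **half away from zero** (2 decimals by default,
0 for maintenance coverage), computed on exact decimal rationals. This is
the convention that reproduces figures like 42/116 → 36.21 % and
61/71 → 86 %; it is verified against an exact `Fraction`-based oracle for
every k/n with n ≤ 500.

The report is emitted as canonical JSON (sorted keys) plus a flat
(cell type, metric, value) TSV, and records every threshold and an SHA-256
hash of every input file, so identical inputs give byte-identical reports.

## Synthetic data

Every input the workflow consumes has a generator that plants known
structure at desk scale:

- **Consensus atlas** — restricted genes are expressed (> threshold, with
  0.5 headroom so text round-trips never flip a call) only in muscle;
  distractors are either broadly expressed (muscle + ≥ 1 other tissue) or
  silent in muscle.
- **Stage profiles** — onset genes silent before / expressed from their
  onset stage; maintenance-planted genes get cumulative positive steps;
  the remaining onset genes get a forced late decrease (while staying
  expressed) so they cannot be mistaken for maintenance genes; distractors
  lapse after expression or never express.
- **Co-expression matrix** — gene g in module m is
  `baseline + loading·f_m + ε`, one standard-normal latent factor per
  module per sample, ε ~ N(0, noise_sd); background genes are unit-variance
  noise. The baseline (8.0) keeps values on a non-negative
  log2(FPKM+1)-like scale without touching correlations. Defaults used in
  the recovery tests are module sizes (50, 40, 30), 100 samples, loading
  0.9, noise SD 0.4 and 200 background genes.
- **Interaction graph** — planted hubs reach exactly their target degree by
  attaching to spoke nodes that never exceed degree 2, so a degree ≥ 3 hub
  caller recovers exactly the planted set; edge scores are uniform in a
  requested range. Infeasible degree demands are rejected.
- **DEG tables** — exactly the requested number of reference genes up
  (fold ∈ [2, 8], p < 0.05) and down, plus non-reference extras; every row
  passes the significance filter so the table is invariant under it.

Each generator draws from an independent substream of the master seed, so
one fixture never perturbs another and identical configurations produce
byte-identical files.

What the synthetic data does *not* emulate: mean–variance relationships of
real RNA-seq counts, correlated (batch) noise, overlapping or hierarchical
co-expression modules, scale-free interaction topology beyond the planted
hubs, or annotation incompleteness. Passing the recovery suites therefore
demonstrates that the classifiers invert the generative assumptions
exactly — not that those assumptions hold in any particular dataset.

## Numerical choices and degenerate inputs

- Constant genes are rejected by all correlation-based steps (with a
  tolerance of 1e-12 relative to the row magnitude, so exactly-repeated
  values are caught despite floating-point mean round-off); the iterative
  `good_samples_genes` filter removes them, and missing values, to a fixed
  point first.
- Library size for FPKM conversion is the column sum of counts over the
  genes present in the matrix; the conversion conserves column totals to
  1e-9 relative tolerance (tested).
- Linkage ties and module-label ties are broken by lowest gene index;
  all graph iterations sort nodes lexicographically. Fixed seeds make EPC
  and every generator exactly reproducible.
- TOM entries are clipped to [0, 1] after division only to absorb
  float round-off; the formula itself is verified unclipped against a
  brute-force oracle on random instances.

## Known limitations

- The dynamic hybrid dendrogram cut is not implemented; block-structured
  fixtures do not need it, but diffuse real-data modules may be split or
  absorbed differently than the reference toolchain would.
- Desk-scale exact computation only: all-pairs correlation/TOM is O(n²)
  memory, sensible up to a few thousand genes, and the clique-based MCC is
  exponential in the worst case (fine on confidence-filtered interaction
  graphs, which are sparse).
- Keyword-based GO mining matches flat term text only; no ontology-graph
  propagation.
- Ortholog mapping is table-driven; no sequence-based discovery.
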