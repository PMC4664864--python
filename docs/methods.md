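# Methods

## The model

`metmod` treats a metabolome as a two-layer object: an undirected compound
multigraph (nodes are compounds, edges are reactions; two compounds joined
by several reactions carry parallel edges) and a collection of named
pathway sets, optionally with internal pathway graphs. The analysis asks
three questions: which compounds differ between two biological groups,
how the compound network decomposes into modules, and how those modules
align with the pathway layer.

## Screening

Fold change is the ratio of case-group mean to control-group mean
abundance, reported to 2 decimals; a direction (up/down) is attached only
to records that survive testing. The univariate test is Welch's unequal-
variance *t*-test per metabolite with Benjamini–Hochberg adjustment across
metabolites — standard conservative defaults for metabolomics
concentration data, both configurable. A metabolite with zero variance in
both groups is reported with p = 1 and a warning rather than an error.
Mass annotation converts a measured m/z to a neutral mass via the adduct
(M+H subtracts, M−H adds, the monoisotopic proton mass 1.007276 Da) and
matches references when |ppm error| is strictly below the tolerance
(default 5 ppm, typical Q-TOF accuracy). A |t| ordering is offered as an
explicitly labelled effect-strength ranking; no external separation-score
method is reimplemented.

## Markov clustering

MCL is implemented directly on dense numpy arrays. The flow matrix is the
collapsed (parallel edges merged), unweighted adjacency plus a self-loop
weight on the diagonal, column-normalised. Each iteration applies
expansion (matrix power, default 2), inflation (entrywise power, the
granularity dial), pruning (entries below 1e−6 zeroed) and
renormalisation; convergence is declared when the maximum entry change
drops below 1e−8, with a hard cap of 200 iterations and an honest
`converged` flag. Clusters are read from the limit matrix: attractors are
nodes with return flow on the diagonal; attractors exchanging flow form an
attractor system; every node joins the system receiving most of its flow,
exact ties broken toward the system containing the lexicographically
smallest attractor id. Singleton modules are retained (a minimum-size
filter is available but off by default).

Numerical caveat: on graphs with an exact mirror symmetry whose centre
node is equidistant between two attractor systems (an odd path is the
smallest case), the true MCL limit is an even split and the implemented
boundary is decided by floating-point rounding during the iteration. Any
dense MCL implementation shares this behaviour; such graphs are excluded
from the cross-implementation equality battery in the tests, which instead
uses structured motifs plus seeded random graphs (asymmetric almost
surely).

## Module-number selection

The inflation grid (default 1.2–5.0 in steps of 0.2) is scanned; each
converged partition is scored with Newman–Girvan modularity on the
collapsed simple graph, Q = Σ_c [L_c/m − (d_c/2m)²], and with the Shannon
entropy of module-size proportions, H = −Σ (n_c/n) ln(n_c/n) (nats). If a
single inflation maximises both, it is chosen. Otherwise selection follows
modularity, with entropy breaking exact modularity ties (preferring
balanced module sizes) and remaining ties resolved toward the lower
inflation, i.e. coarser modules. Entropy cannot act as a co-equal
objective in this fallback: H increases with fragmentation, so over any
grid wide enough to shatter the network its maximum sits at the finest
partition, and a scalarised Q+H compromise is systematically pulled past
the modularity peak — measurably losing planted block structure that the
modularity-first rule recovers exactly. "Modularity" and "entropy" here
are the standard readings of those terms for partitions; entropy over
module sizes is a documented choice, as is the Newman–Girvan form.

## Module topology

Statistics follow Cytoscape NetworkAnalyzer conventions on the induced
subgraph of each module: degrees on the collapsed simple subgraph, density
2E/(n(n−1)), average neighbours 2E/n, and heterogeneity
sqrt(population variance of degree)/mean degree (population, not sample,
variance — the convention that reproduces the closed forms for path and
star motifs exactly). Multi-edge node pairs are counted from parallel-edge
multiplicities before collapsing. Degenerate conventions: single-node
modules have density 0 and heterogeneity 0; zero mean degree yields
heterogeneity 0. All reported values are rounded to 3 decimals.

## Similarity and enrichment

Module–pathway similarity uses binary membership vectors: the cosine
("vectorial-angle") similarity reduces to 100·k/√(mp) for sets of sizes m
and p sharing k members (2 decimals), and the identical ratio is the
Jaccard index in integer percent. Both are symmetric, invariant to
padding the compound universe, and strictly increasing in the overlap at
fixed sizes.

Enrichment scores every pathway with at least one query hit. The
over-representation p-value is the hypergeometric upper tail
P(X ≥ hits) over a configurable reference-universe size, BH-adjusted and
reported, but significance is driven by the topology impact alone: raw
betweenness centrality (endpoints excluded) within the pathway graph,
normalised so each pathway's importances sum to 1, summed over hit
compounds (2 decimals), with a default significance threshold of
impact > 0.10. On pathway graphs where all betweenness is zero (complete
graphs, 2-node paths) the importance falls back to uniform 1/n. The
expected-hit baseline is pathway size × query fraction, default 0.02 (the
fraction of a reference metabolome a typical biomarker panel occupies),
deliberately independent of any specific database universe. A degree-based
importance is intentionally not the default; betweenness is the measure
under which a linear pathway's interior compound carries exactly half the
pathway's importance.

## Cross-talk

A pathway *converges* on a module when it overlaps it by at least
`min_overlap` compounds (default 1, the most permissive reading, and
configurable because stricter definitions are equally defensible); it
*diverges* when its members land in two or more modules. Inter-module edge
counts include parallel-edge multiplicity, and intra- plus inter-module
edges always sum to the network's edge total. Per-compound pathway
multiplicity (how many pathways claim a compound) and a descriptive
top-betweenness hub per module complete the map.

## Synthetic data

The generator emulates the statistical structure the analysis assumes,
not any real measurement process. Networks are built from planted motifs
— path, star, clique, ring, and Erdős–Rényi blocks (stitched connected) —
joined by bridge edges with specified counts and optionally carrying
parallel edges; the planted partition is returned as ground truth.
Pathway sets share an exact specified overlap with a target module, the
remainder drawn from other modules or fresh identifiers. Abundance tables
are log-normal with sigma² = ln(1+CV²) and the mean set so that the
expected case/control group-mean ratio equals the designated fold — an
unbiased, strictly positive, multiplicative-noise model matching
ratio-type fold effects. Defaults mirror the emulated study design: two
groups, fold effects around 1.2–2.5 as in typical significant metabolite
panels, CV 0.1, and planted-block benchmarks with blocks of 10 at
intra-edge probability 0.6 and two bridges per block pair (the expected
count at an inter-edge probability of 0.02).

What the generator does not emulate: raw spectra, retention times,
heteroscedastic batch effects, correlated metabolites, or the biological
realism of database-curated reaction networks. Passing tests therefore
demonstrate correctness of the algorithms under the stated statistical
model, not performance on any particular real metabolome.

## Problem sizes and determinism

All randomness flows from explicit integer seeds; identical spec + seed
gives byte-identical outputs, and the orchestrated pipeline writes a
manifest recording inputs, parameters and seed. Tests run the MCL
cross-implementation battery on graphs of ≤ 8 nodes at three inflations,
planted-block recovery on 30-node networks (100 replicates in the
acceptance-style checks), and screening operating characteristics on 500
null replicates of 10 metabolites at n = 20 per group — sizes chosen so
the full suite exercises every claim in well under a minute of compute
while keeping binomial error on the measured rates small.

## Known limitations

- Dense-matrix MCL: memory and time are O(n²)–O(n³); intended for
  desk-scale compound networks (hundreds of nodes), not genome-scale
  graphs.
- The symmetric-tie caveat above: cluster boundaries on exactly
  symmetric graphs are rounding-determined.
- Impact scores depend on the pathway graph supplied; when only a member
  set is available the CLI falls back to a deterministic linear topology
  over sorted members, which is a structural assumption, not knowledge.
- The enrichment universe size and query fraction are user inputs; no
  reference metabolome ships with the package.
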