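# metmod

Modular analysis of metabolic compound networks, built for metabolomics
studies that screen two-group abundance data for biomarkers and then ask
how the perturbed compounds organise into network modules and known
pathways.

Disease states such as ischemic stroke perturb dozens of metabolites at
once. A compound–reaction network over those metabolites can be decomposed
into *modules* — densely connected subnetworks acting as functional units —
and each module compared against curated pathway definitions to see where
the two organisational views converge, diverge and cross-talk. `metmod`
implements that pipeline end to end:

1. **Biomarker screening** — per-metabolite fold change
   (case mean / control mean) with direction arrows, Welch's *t*-test with
   Benjamini–Hochberg correction, and precise-mass annotation at a ppm
   tolerance (default 5 ppm).
2. **Network construction** — undirected compound multigraphs from TSV/SIF
   edge lists; parallel edges (multiple reactions between the same
   compounds) are kept.
3. **Markov clustering (MCL)** — from-scratch flow simulation: expansion
   (matrix power) alternating with inflation (entrywise power + column
   renormalisation) until the flow matrix is idempotent; modules are read
   off the attractor structure.
4. **Module selection** — the inflation parameter is scanned; each
   partition is scored with Newman–Girvan modularity
   *Q* = Σ_c [L_c/m − (d_c/2m)²] and the Shannon entropy
   *H* = −Σ_c (n_c/n) ln(n_c/n) of module-size proportions, and the
   partition where both peak is chosen.
5. **Module topology** — per-module node/edge counts, mean degree, density
   2E/(n(n−1)), and degree heterogeneity (coefficient of variation of the
   degree sequence), plus multi-edge node-pair counts.
6. **Module–pathway similarity** — the vectorial-angle (cosine) similarity
   100·|A∩B|/√(|A||B|) and the identical ratio (Jaccard)
   100·|A∩B|/|A∪B|.
7. **Pathway enrichment** — hypergeometric over-representation plus a
   topology *impact* score: the summed relative betweenness centrality of
   hit compounds within the pathway graph, with significance at
   impact > 0.10.
8. **Cross-talk mapping** — convergent pathways per module, divergent
   pathways spanning multiple modules, and inter-module edge counts.

A synthetic-data generator produces planted-module networks (path, star,
clique, ring and random-block motifs), pathway sets with exact controlled
overlap, connected pathway graphs, and two-group log-normal abundance
tables with designated fold effects — so the entire pipeline is testable
without any database download.

## Worked example

```python
import metmod as mm

# A network with two planted modules: a 3-compound path and a 37-compound
# star (one hub metabolite connected to 36 neighbours).
spec = mm.NetworkSpec(modules=(mm.MotifSpec("path", 3), mm.MotifSpec("star", 37)), seed=0)
net, truth = mm.generate_network(spec)
print(mm.summarize(net))
for s in mm.stats_table(net, truth):
    print(s)
```

```
{'nodes': 40, 'edges': 38, 'distinct_pairs': 38, 'components': 2, 'largest_component': 37}
ModuleStats(module=1, n=37, edges=36, avg_neighbors=1.946, density=0.054, heterogeneity=2.917, multi_edge_pairs=0, components=1)
ModuleStats(module=0, n=3, edges=2, avg_neighbors=1.333, density=0.667, heterogeneity=0.354, multi_edge_pairs=0, components=1)
```

The star module is sparse (density 0.054) but extremely hub-dominated
(heterogeneity 2.917); the path module is dense for its size (0.667) and
nearly regular (0.354). Comparing the star module against a 32-compound
pathway sharing 22 compounds with it:

```python
pw, = mm.generate_pathways(truth, [(1, 32, 22, "GST_metab")], seed=1)
mod = truth.modules()[1]
print(mm.cosine_similarity(mod, pw.members), mm.identical_ratio(mod, pw.members))
```

```
63.94 47
```

i.e. a 63.94 % vectorial-angle similarity and a 47 % identical ratio. And
scoring a linear 4-compound pathway in which one interior compound is a
screened biomarker:

```python
pg = mm.generate_pathway_graph(4, "path")
print(mm.impact(pg, {"C2"}), mm.expected_hits(67, 0.02))
```

```
0.5 1.34
```

— the interior hit carries half the pathway's betweenness importance
(impact 0.50), and a 67-compound pathway queried at a 2 % metabolome
fraction expects 1.34 hits.

## Command line

```sh
metmod run-all --demo --seed 1 --out out/        # full pipeline on synthetic data
metmod simulate --seed 1 --out sim/              # write network.tsv / pathways.gmt / abundance.csv
metmod screen --abundance sim/abundance.csv --alpha 0.01 --out biomarkers.csv
metmod select --edges sim/network.tsv --grid 1.2:5.0:0.2 --out selection.json
metmod topology --edges sim/network.tsv --partition partition.json --out stats.csv
```

`run-all` writes every stage artifact plus a `manifest.json` recording
inputs, parameters and the seed; identical configs give byte-identical
outputs.

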