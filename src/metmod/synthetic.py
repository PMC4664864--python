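"""Synthetic data with the statistical structure the pipeline assumes.

Real compound networks of this kind come from curated reaction databases
and two-group abundance tables from mass-spectrometry runs; neither is
redistributable, so this module generates stand-ins with controlled
structure:

* planted-module networks whose modules are path, star, clique, ring or
  Erdős–Rényi-block motifs, optionally joined by bridge edges and carrying
  parallel (multi-)edges — with the planted partition returned as ground
  truth;
* pathway sets with an exact, specified overlap against a chosen module;
* connected pathway graphs (path / star / ring / ER) for impact scoring;
* two-group log-normal abundance tables with designated fold effects.

Everything is deterministic under its seed.
"""

from __future__ import annotations

import math
from dataclasses import dataclass, field
from typing import Sequence

import networkx as nx
import numpy as np
import pandas as pd

from .enrichment import PathwayGraph
from .io import AbundanceTable, PathwaySet
from .mcl import ModulePartition
from .network import CompoundNetwork

MOTIFS = ("path", "star", "clique", "ring", "er_block")
PATHWAY_TOPOLOGIES = ("path", "star", "ring", "er")


@dataclass(frozen=True)
class MotifSpec:
    """One planted module: a motif name, its size, and (for er_block) the
    intra-module edge probability."""

    motif: str
    size: int
    intra_edge_prob: float = 0.3

    def __post_init__(self) -> None:
        if self.motif not in MOTIFS:
            raise ValueError(f"unknown motif {self.motif!r}; choose from {MOTIFS}")
        if self.size < 1:
            raise ValueError("module size must be >= 1")
        if self.motif == "ring" and self.size < 3:
            raise ValueError("ring motif needs >= 3 nodes")
        if not 0.0 <= self.intra_edge_prob <= 1.0:
            raise ValueError("intra_edge_prob must be in [0, 1]")


@dataclass(frozen=True)
class NetworkSpec:
    modules: tuple[MotifSpec, ...]
    bridges: tuple[tuple[int, int, int], ...] = ()  # (module_i, module_j, count)
    multi_edge_pairs: tuple[tuple[int, int], ...] = ()  # (module, extra parallel edges)
    seed: int = 0

    def __post_init__(self) -> None:
        n = len(self.modules)
        for i, j, count in self.bridges:
            if not (0 <= i < n and 0 <= j < n) or i == j:
                raise ValueError(f"bridge ({i},{j}) references nonexistent module pair")
            if count < 0:
                raise ValueError("bridge count must be >= 0")
        for m, count in self.multi_edge_pairs:
            if not 0 <= m < n:
                raise ValueError(f"multi-edge spec references nonexistent module {m}")
            if count < 0:
                raise ValueError("multi-edge count must be >= 0")


def _motif_edges(spec: MotifSpec, nodes: list[str], rng: np.random.Generator) -> list[tuple[str, str]]:
    n = len(nodes)
    if spec.motif == "path":
        return [(nodes[i], nodes[i + 1]) for i in range(n - 1)]
    if spec.motif == "star":
        return [(nodes[0], nodes[i]) for i in range(1, n)]
    if spec.motif == "clique":
        return [(nodes[i], nodes[j]) for i in range(n) for j in range(i + 1, n)]
    if spec.motif == "ring":
        return [(nodes[i], nodes[(i + 1) % n]) for i in range(n)]
    # er_block: G(n, p), then stitch components together so the planted
    # module is a connected induced subgraph.
    edges = [
        (nodes[i], nodes[j])
        for i in range(n)
        for j in range(i + 1, n)
        if rng.random() < spec.intra_edge_prob
    ]
    g = nx.Graph(edges)
    g.add_nodes_from(nodes)
    comps = [sorted(c) for c in nx.connected_components(g)]
    comps.sort(key=lambda c: c[0])
    for a, b in zip(comps, comps[1:]):
        u = a[int(rng.integers(len(a)))]
        v = b[int(rng.integers(len(b)))]
        edges.append((u, v))
    return edges


def generate_network(spec: NetworkSpec) -> tuple[CompoundNetwork, ModulePartition]:
    """Build the planted-module multigraph and its ground-truth partition."""
    rng = np.random.default_rng(spec.seed)
    g = nx.MultiGraph()
    assignment: dict[str, int] = {}
    module_nodes: list[list[str]] = []
    for idx, ms in enumerate(spec.modules):
        nodes = [f"m{idx:02d}c{j:03d}" for j in range(ms.size)]
        module_nodes.append(nodes)
        g.add_nodes_from(nodes)
        for u, v in _motif_edges(ms, nodes, rng):
            g.add_edge(u, v)
        for node in nodes:
            assignment[node] = idx
    for i, j, count in spec.bridges:
        for _ in range(count):
            u = module_nodes[i][int(rng.integers(len(module_nodes[i])))]
            v = module_nodes[j][int(rng.integers(len(module_nodes[j])))]
            g.add_edge(u, v)
    for m, count in spec.multi_edge_pairs:
        intra = [
            (u, v)
            for u, v in {tuple(sorted(e)) for e in g.subgraph(module_nodes[m]).edges()}
        ]
        if not intra:
            raise ValueError(f"module {m} has no edges to duplicate")
        intra.sort()
        chosen = rng.choice(len(intra), size=min(count, len(intra)), replace=False)
        for k in sorted(chosen):
            u, v = intra[k]
            g.add_edge(u, v)
    net = CompoundNetwork(graph=g)
    truth = ModulePartition(assignment=assignment, inflation=None, converged=True)
    return net, truth


def generate_pathways(
    partition: ModulePartition,
    overlap_spec: Sequence[tuple[int, int, int, str]],
    seed: int = 0,
) -> list[PathwaySet]:
    """Pathway sets sharing exactly ``overlap_k`` members with a module.

    Each spec entry is ``(module_id, pathway_size, overlap_k, name)``.  The
    k overlapping members are drawn from the module; the rest come from
    other modules' nodes, topped up with fresh identifiers when the network
    runs out.
    """
    rng = np.random.default_rng(seed)
    modules = partition.modules()
    pathways = []
    for module_id, size, k, name in overlap_spec:
        if module_id not in modules:
            raise ValueError(f"unknown module {module_id}")
        members = sorted(modules[module_id])
        if k > min(size, len(members)):
            raise ValueError(f"{name}: overlap {k} exceeds pathway ({size}) or module ({len(members)}) size")
        inside = [members[i] for i in sorted(rng.choice(len(members), size=k, replace=False))]
        outside_pool = sorted(
            n for n, m in partition.assignment.items() if m != module_id
        )
        need = size - k
        take = [
            outside_pool[i]
            for i in sorted(rng.choice(len(outside_pool), size=min(need, len(outside_pool)), replace=False))
        ] if outside_pool and need else []
        fresh = [f"x_{name}_{i:03d}" for i in range(need - len(take))]
        pathways.append(
            PathwaySet(name=name, description=f"synthetic overlap k={k}", members=frozenset(inside + take + fresh))
        )
    return pathways


def generate_pathway_graph(
    size: int, topology: str, seed: int = 0, name: str = "pathway"
) -> PathwayGraph:
    """Connected pathway graph on ``size`` compound nodes C1..Cn."""
    if size < 2:
        raise ValueError("pathway graph needs >= 2 nodes")
    if topology not in PATHWAY_TOPOLOGIES:
        raise ValueError(f"unknown topology {topology!r}; choose from {PATHWAY_TOPOLOGIES}")
    nodes = [f"C{i + 1}" for i in range(size)]
    rng = np.random.default_rng(seed)
    if topology == "er":
        ms = MotifSpec(motif="er_block", size=size, intra_edge_prob=0.4)
        edges = _motif_edges(ms, nodes, rng)
    else:
        if topology == "ring" and size < 3:
            raise ValueError("ring needs >= 3 nodes")
        edges = _motif_edges(MotifSpec(motif=topology, size=size), nodes, rng)
    g = nx.Graph()
    g.add_nodes_from(nodes)
    g.add_edges_from(edges)
    return PathwayGraph(name=name, graph=g)


@dataclass(frozen=True)
class AbundanceSpec:
    """Two-group log-normal abundance design.

    ``folds`` maps each metabolite to its true case/control mean ratio;
    ``cv`` is the within-group coefficient of variation of concentrations
    (multiplicative noise); ``n_per_group`` samples per group.
    """

    folds: dict[str, float] = field(default_factory=dict)
    n_per_group: int = 10
    cv: float = 0.1
    seed: int = 0
    base_mean: float = 1.0
    groups: tuple[str, str] = ("sham", "ischemia")

    def __post_init__(self) -> None:
        if not self.folds:
            raise ValueError("at least one metabolite required")
        if any(f <= 0 for f in self.folds.values()):
            raise ValueError("fold effects must be positive")
        if self.n_per_group < 2:
            raise ValueError("need n >= 2 per group")
        if self.cv <= 0:
            raise ValueError("CV must be positive")


def generate_abundance(spec: AbundanceSpec) -> AbundanceTable:
    """Log-normal samples whose expected group-mean ratio is the fold.

    With sigma^2 = ln(1 + CV^2) and mu = ln(mean) − sigma^2/2 the
    log-normal mean equals the designated group mean exactly, so the
    estimated fold is unbiased for the specified one.
    """
    rng = np.random.default_rng(spec.seed)
    sigma = math.sqrt(math.log(1.0 + spec.cv**2))
    control, case = spec.groups
    n = spec.n_per_group
    columns = [f"{control}{i + 1:02d}" for i in range(n)] + [f"{case}{i + 1:02d}" for i in range(n)]
    groups = pd.Series([control] * n + [case] * n, index=columns)
    rows = {}
    for met, fold in spec.folds.items():
        mu_control = math.log(spec.base_mean) - sigma**2 / 2.0
        mu_case = mu_control + math.log(fold)
        vals = np.concatenate(
            [
                rng.lognormal(mean=mu_control, sigma=sigma, size=n),
                rng.lognormal(mean=mu_case, sigma=sigma, size=n),
            ]
        )
        rows[met] = vals
    data = pd.DataFrame.from_dict(rows, orient="index", columns=columns)
    data.index.name = "metabolite"
    return AbundanceTable(data=data, groups=groups)
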