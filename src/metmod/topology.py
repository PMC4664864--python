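"""Per-module topology statistics (NetworkAnalyzer conventions).

For each module the induced subgraph of the compound multigraph is
summarised by node/edge counts, mean degree ("average neighbors"),
density, degree heterogeneity and the number of multi-edge node pairs.
Degrees are taken on the collapsed simple subgraph; parallel-edge
multiplicity feeds only the multi-edge pair count.  Heterogeneity is the
coefficient of variation of the degree sequence —
sqrt(population variance)/mean — high for hub-dominated (star-like)
modules, zero for regular ones.
"""

from __future__ import annotations

import math
from dataclasses import dataclass
from typing import Iterable, Sequence

import networkx as nx
from scipy import stats as sps

from .mcl import ModulePartition
from .network import CompoundNetwork

ROUND = 3  # print precision of all reported statistics


@dataclass(frozen=True)
class ModuleStats:
    """Topology record of one module (values rounded to 3 decimals)."""

    module: int | str
    n: int
    edges: int
    avg_neighbors: float
    density: float
    heterogeneity: float
    multi_edge_pairs: int
    components: int

    @classmethod
    def columns(cls) -> list[str]:
        return [
            "module",
            "n",
            "edges",
            "avg_neighbors",
            "density",
            "heterogeneity",
            "multi_edge_pairs",
            "components",
        ]

    def to_row(self) -> dict:
        return {k: getattr(self, k) for k in self.columns()}


def module_stats(net: CompoundNetwork, members: Iterable[str], module_id: int | str = 0) -> ModuleStats:
    """Induced-subgraph statistics for one module.

    Degenerate conventions: a single node has density 0 and heterogeneity 0;
    a zero mean degree likewise yields heterogeneity 0.
    """
    members = set(members)
    if not members:
        raise ValueError("empty member set")
    unknown = members - set(net.graph.nodes)
    if unknown:
        raise ValueError(f"members not in network: {sorted(unknown)[:5]}")
    multi = net.graph.subgraph(members)
    simple = nx.Graph(multi)
    n = len(members)
    edges = simple.number_of_edges()
    degrees = [d for _, d in simple.degree()]
    mean_deg = sum(degrees) / n
    if n >= 2:
        density = 2.0 * edges / (n * (n - 1))
    else:
        density = 0.0
    if mean_deg > 0:
        var = sum((d - mean_deg) ** 2 for d in degrees) / n  # population variance
        heterogeneity = math.sqrt(var) / mean_deg
    else:
        heterogeneity = 0.0
    multi_pairs = 0
    seen: dict[tuple[str, str], int] = {}
    for u, v in multi.edges():
        key = tuple(sorted((u, v)))
        seen[key] = seen.get(key, 0) + 1
    multi_pairs = sum(1 for c in seen.values() if c > 1)
    components = nx.number_connected_components(simple)
    return ModuleStats(
        module=module_id,
        n=n,
        edges=edges,
        avg_neighbors=round(mean_deg, ROUND),
        density=round(density, ROUND),
        heterogeneity=round(heterogeneity, ROUND),
        multi_edge_pairs=multi_pairs,
        components=components,
    )


def stats_table(net: CompoundNetwork, partition: ModulePartition) -> list[ModuleStats]:
    """One record per module, largest first (ties by module id)."""
    records = [
        module_stats(net, members, module_id=mod)
        for mod, members in partition.modules().items()
    ]
    records.sort(key=lambda r: (-r.n, str(r.module)))
    return records


def heterogeneity_size_correlation(stats: Sequence[ModuleStats]) -> float:
    """Pearson correlation between module size and degree heterogeneity."""
    if len(stats) < 3:
        raise ValueError("need at least 3 modules")
    ns = [s.n for s in stats]
    hs = [s.heterogeneity for s in stats]
    if len(set(ns)) == 1 or len(set(hs)) == 1:
        raise ValueError("correlation undefined for constant input")
    r, _ = sps.pearsonr(ns, hs)
    return float(r)
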