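"""Hierarchical module↔pathway cross-talk mapping.

Three linked views of how modules and pathways interlock:

* inter-module edge counts — how many network edges (with multiplicity)
  run between each pair of modules;
* convergent pathways — for a module, the pathways overlapping it by at
  least ``min_overlap`` compounds;
* divergent modules — for a pathway, the modules its members are spread
  across; a pathway touching two or more modules is *divergent*.

The assembled map also records, per compound, how many pathways claim it
(the multi-coloured nodes of a crosstalk diagram) and the most central
compound of each module as a descriptive bottleneck/hub candidate.
"""

from __future__ import annotations

from dataclasses import dataclass, field
from typing import Sequence

import networkx as nx

from .io import PathwaySet
from .mcl import ModulePartition
from .network import CompoundNetwork


@dataclass
class CrosstalkMap:
    convergent: dict[str, list[str]] = field(default_factory=dict)  # module -> pathways
    divergent: dict[str, list[str]] = field(default_factory=dict)  # pathway -> modules (>=2)
    inter_module_edges: dict[tuple[str, str], int] = field(default_factory=dict)
    node_pathway_multiplicity: dict[str, int] = field(default_factory=dict)
    module_hubs: dict[str, str] = field(default_factory=dict)

    def to_dict(self) -> dict:
        return {
            "convergent": self.convergent,
            "divergent": self.divergent,
            "inter_module_edges": {
                f"{a}|{b}": c for (a, b), c in sorted(self.inter_module_edges.items())
            },
            "node_pathway_multiplicity": self.node_pathway_multiplicity,
            "module_hubs": self.module_hubs,
        }

    @classmethod
    def from_dict(cls, d: dict) -> "CrosstalkMap":
        edges = {}
        for key, c in d.get("inter_module_edges", {}).items():
            a, b = key.split("|")
            edges[(a, b)] = c
        return cls(
            convergent=d.get("convergent", {}),
            divergent=d.get("divergent", {}),
            inter_module_edges=edges,
            node_pathway_multiplicity=d.get("node_pathway_multiplicity", {}),
            module_hubs=d.get("module_hubs", {}),
        )


def inter_module_edges(
    net: CompoundNetwork, partition: ModulePartition
) -> dict[tuple[str, str], int]:
    """Count edges (with multiplicity) crossing each module pair.

    Keys are unordered module-id pairs rendered as sorted strings; pairs
    with zero crossing edges are omitted.
    """
    counts: dict[tuple[str, str], int] = {}
    assign = partition.assignment
    for u, v in net.graph.edges():
        mu, mv = assign.get(u), assign.get(v)
        if mu is None or mv is None or mu == mv:
            continue
        key = tuple(sorted((str(mu), str(mv))))
        counts[key] = counts.get(key, 0) + 1
    return counts


def convergent_pathways(
    module_members: frozenset[str] | set[str],
    pathways: Sequence[PathwaySet],
    min_overlap: int = 1,
) -> list[str]:
    """Pathways overlapping the module by >= min_overlap, largest overlap first."""
    if min_overlap < 1:
        raise ValueError("min_overlap must be >= 1")
    module_members = set(module_members)
    hits = [
        (len(module_members & pw.members), pw.name)
        for pw in pathways
        if len(module_members & pw.members) >= min_overlap
    ]
    hits.sort(key=lambda t: (-t[0], t[1]))
    return [name for _, name in hits]


def divergent_modules(pathway: PathwaySet, partition: ModulePartition) -> list[str]:
    """Modules containing at least one pathway member, sorted by id."""
    mods = {
        str(partition.assignment[m]) for m in pathway.members if m in partition.assignment
    }
    return sorted(mods)


def build_crosstalk(
    net: CompoundNetwork,
    partition: ModulePartition,
    pathways: Sequence[PathwaySet],
    min_overlap: int = 1,
) -> CrosstalkMap:
    """Assemble the convergence, divergence and inter-module edge views."""
    cmap = CrosstalkMap()
    modules = partition.modules()
    for mod, members in sorted(modules.items(), key=lambda kv: str(kv[0])):
        conv = convergent_pathways(members, pathways, min_overlap=min_overlap)
        if conv:
            cmap.convergent[str(mod)] = conv
    for pw in pathways:
        mods = divergent_modules(pw, partition)
        if len(mods) >= 2:
            cmap.divergent[pw.name] = mods
    cmap.inter_module_edges = inter_module_edges(net, partition)
    multiplicity: dict[str, int] = {}
    for pw in pathways:
        for node in pw.members:
            multiplicity[node] = multiplicity.get(node, 0) + 1
    cmap.node_pathway_multiplicity = {
        n: c for n, c in sorted(multiplicity.items()) if c >= 1
    }
    simple = net.simple_graph()
    bc = nx.betweenness_centrality(simple, normalized=True)
    for mod, members in modules.items():
        hub = max(sorted(members), key=lambda n: bc.get(n, 0.0))
        cmap.module_hubs[str(mod)] = hub
    return cmap
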