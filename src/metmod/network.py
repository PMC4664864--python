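"""Compound-network construction and whole-network summaries.

The network is an undirected multigraph: nodes are compounds, parallel
edges are distinct reactions between the same compound pair.  Parallel
edges are kept in the data model (they feed the multi-edge node-pair
statistic) but degree-based statistics downstream operate on the collapsed
simple graph.
"""

from __future__ import annotations

import logging
from dataclasses import dataclass, field
from typing import Iterable, Sequence

import networkx as nx

from .io import EdgeRecord

logger = logging.getLogger(__name__)


@dataclass
class CompoundNetwork:
    """Undirected compound multigraph; self-loop free after default cleaning."""

    graph: nx.MultiGraph = field(default_factory=nx.MultiGraph)

    @property
    def n_nodes(self) -> int:
        return self.graph.number_of_nodes()

    @property
    def n_edges(self) -> int:
        """Total edges counting multiplicity."""
        return self.graph.number_of_edges()

    @property
    def nodes(self) -> list[str]:
        return sorted(self.graph.nodes)

    def simple_graph(self) -> nx.Graph:
        """Collapse parallel edges; used for clustering and degree stats."""
        return nx.Graph(self.graph)

    def multiplicities(self) -> dict[tuple[str, str], int]:
        """Edge multiplicity keyed by sorted endpoint pair."""
        mult: dict[tuple[str, str], int] = {}
        for u, v in self.graph.edges():
            key = tuple(sorted((u, v)))
            mult[key] = mult.get(key, 0) + 1
        return mult


def build_network(
    edges: Iterable[EdgeRecord],
    drop_self_loops: bool = True,
    extra_nodes: Sequence[str] = (),
) -> CompoundNetwork:
    """Assemble the multigraph from edge records.

    Self-loops are dropped by default (degree statistics downstream assume
    loop-free graphs); isolated nodes enter only through ``extra_nodes``.
    Raises ``ValueError`` on an empty edge list with no extra nodes.
    """
    g = nx.MultiGraph()
    n_edges = 0
    n_loops = 0
    for rec in edges:
        if rec.is_self_loop and drop_self_loops:
            g.add_node(rec.source)
            n_loops += 1
            continue
        g.add_edge(rec.source, rec.target, interaction=rec.interaction)
        n_edges += 1
    g.add_nodes_from(extra_nodes)
    if g.number_of_nodes() == 0:
        raise ValueError("empty edge list and no explicit nodes")
    if n_loops:
        logger.info("dropped %d self-loop(s)", n_loops)
    logger.info("built network: %d nodes, %d edges", g.number_of_nodes(), n_edges)
    return CompoundNetwork(graph=g)


def summarize(net: CompoundNetwork) -> dict:
    """Node/edge counts plus component structure of the collapsed graph."""
    simple = net.simple_graph()
    components = list(nx.connected_components(simple)) if simple.number_of_nodes() else []
    return {
        "nodes": net.n_nodes,
        "edges": net.n_edges,
        "distinct_pairs": simple.number_of_edges(),
        "components": len(components),
        "largest_component": max((len(c) for c in components), default=0),
    }
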