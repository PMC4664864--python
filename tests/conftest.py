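from __future__ import annotations

import networkx as nx
import pytest

from metmod.io import EdgeRecord
from metmod.mcl import ModulePartition
from metmod.network import CompoundNetwork, build_network


def mk_net(edges, nodes=()) -> CompoundNetwork:
    """Build a compound network from plain (u, v) tuples."""
    return build_network([EdgeRecord(str(u), str(v)) for u, v in edges],
                         extra_nodes=[str(n) for n in nodes])


@pytest.fixture
def two_triangles() -> tuple[CompoundNetwork, ModulePartition]:
    net = mk_net([("a", "b"), ("b", "c"), ("a", "c"),
                  ("x", "y"), ("y", "z"), ("x", "z")])
    part = ModulePartition(assignment={"a": 0, "b": 0, "c": 0, "x": 1, "y": 1, "z": 1})
    return net, part


@pytest.fixture
def bridged_cliques() -> tuple[CompoundNetwork, set[frozenset[str]]]:
    """Two 5-cliques joined by a single bridge edge."""
    g = nx.complete_graph(5)
    edges = [(f"a{u}", f"a{v}") for u, v in g.edges()]
    edges += [(f"b{u}", f"b{v}") for u, v in g.edges()]
    edges.append(("a0", "b0"))
    truth = {frozenset(f"a{i}" for i in range(5)), frozenset(f"b{i}" for i in range(5))}
    return mk_net(edges), truth


_GNP7_EDGES = sorted(nx.gnp_random_graph(7, 0.4, seed=1).edges())
_GNP8A_EDGES = sorted(nx.gnp_random_graph(8, 0.4, seed=2).edges())
_GNP8B_EDGES = sorted(nx.gnp_random_graph(8, 0.4, seed=3).edges())

#: Small graphs (<=8 nodes) as integer edge lists, for oracle comparisons.
#: Graphs with a node exactly equidistant between two attractor systems
#: (e.g. an odd path) are excluded: there the cluster boundary is a pure
#: tie and any MCL implementation resolves it by rounding noise.
SMALL_BATTERY: dict[str, tuple[int, list[tuple[int, int]]]] = {
    "path3": (3, [(0, 1), (1, 2)]),
    "path4": (4, [(0, 1), (1, 2), (2, 3)]),
    "star5": (5, [(0, i) for i in range(1, 5)]),
    "triangle": (3, [(0, 1), (1, 2), (0, 2)]),
    "two_triangles": (6, [(0, 1), (1, 2), (0, 2), (3, 4), (4, 5), (3, 5)]),
    "k4": (4, [(0, 1), (0, 2), (0, 3), (1, 2), (1, 3), (2, 3)]),
    "bridged_k3": (6, [(0, 1), (1, 2), (0, 2), (3, 4), (4, 5), (3, 5), (2, 3)]),
    "ring6": (6, [(i, (i + 1) % 6) for i in range(6)]),
    "lollipop": (7, [(0, 1), (0, 2), (1, 2), (2, 3), (3, 4), (4, 5), (5, 6)]),
    "k3_plus_isolated_edge": (5, [(0, 1), (1, 2), (0, 2), (3, 4)]),
    "gnp7": (7, _GNP7_EDGES),
    "gnp8a": (8, _GNP8A_EDGES),
    "gnp8b": (8, _GNP8B_EDGES),
}


def battery_net(name: str) -> tuple[CompoundNetwork, int, list[tuple[int, int]]]:
    n, edges = SMALL_BATTERY[name]
    net = mk_net([(str(u), str(v)) for u, v in edges],
                 nodes=[str(i) for i in range(n)])
    return net, n, edges
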