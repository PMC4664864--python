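"""Markov clustering (MCL) of compound networks.

MCL simulates flow on the graph: the column-stochastic flow matrix is
alternately *expanded* (matrix power — flow spreads along paths) and
*inflated* (entrywise power + column renormalisation — strong flow is
rewarded, weak flow starved) until the matrix is (numerically) idempotent.
Clusters are read off the attractor structure of the limit: attractors are
nodes that retain flow to themselves; nodes attracted to the same attractor
system share a module.  The inflation exponent sets granularity: larger
values give more, smaller modules.
"""

from __future__ import annotations

import logging
from dataclasses import dataclass, field

import numpy as np

from .network import CompoundNetwork

logger = logging.getLogger(__name__)

#: Defaults in the spirit of the reference mcl implementation.
DEFAULT_EXPANSION = 2
DEFAULT_SELF_LOOP = 1.0
DEFAULT_PRUNE_EPS = 1e-6
DEFAULT_CONV_TOL = 1e-8
DEFAULT_MAX_ITER = 200


@dataclass
class FlowMatrix:
    """Column-stochastic flow matrix over an ordered node list."""

    matrix: np.ndarray
    nodes: tuple[str, ...]

    def __post_init__(self) -> None:
        m = self.matrix
        if m.ndim != 2 or m.shape[0] != m.shape[1] or m.shape[0] != len(self.nodes):
            raise ValueError("matrix must be square and match the node list")
        if (m < 0).any():
            raise ValueError("flow entries must be non-negative")
        colsums = m.sum(axis=0)
        if not np.allclose(colsums, 1.0, atol=1e-12):
            raise ValueError("columns must sum to 1")


@dataclass
class ModulePartition:
    """Disjoint assignment of every network node to a module id."""

    assignment: dict[str, int]
    inflation: float | None = None
    converged: bool = True
    iterations: int = 0

    @property
    def n_modules(self) -> int:
        return len(set(self.assignment.values()))

    def modules(self) -> dict[int, frozenset[str]]:
        out: dict[int, set[str]] = {}
        for node, mod in self.assignment.items():
            out.setdefault(mod, set()).add(node)
        return {k: frozenset(v) for k, v in out.items()}

    def sizes(self) -> list[int]:
        return sorted((len(m) for m in self.modules().values()), reverse=True)

    def as_sets(self) -> set[frozenset[str]]:
        """Partition as a set of member sets (label-free comparison)."""
        return set(self.modules().values())


def _normalize_columns(m: np.ndarray) -> np.ndarray:
    colsums = m.sum(axis=0)
    if (colsums == 0).any():
        raise ValueError("zero column: all flow pruned away")
    return m / colsums


def to_flow_matrix(net: CompoundNetwork, self_loop_weight: float = DEFAULT_SELF_LOOP) -> FlowMatrix:
    """Collapsed unweighted adjacency + self-loop weight, column-normalised.

    The self loop keeps flow from oscillating on bipartite-ish structures
    and guarantees a strictly positive diagonal.
    """
    nodes = tuple(sorted(net.graph.nodes))
    if not nodes:
        raise ValueError("empty network")
    index = {n: i for i, n in enumerate(nodes)}
    a = np.zeros((len(nodes), len(nodes)))
    for u, v in net.simple_graph().edges():
        i, j = index[u], index[v]
        a[i, j] = a[j, i] = 1.0
    a[np.diag_indices_from(a)] += self_loop_weight
    return FlowMatrix(matrix=_normalize_columns(a), nodes=nodes)


def expand(fm: FlowMatrix, e: int = DEFAULT_EXPANSION) -> FlowMatrix:
    """Flow expansion: matrix power ``e`` (stays column-stochastic)."""
    if int(e) != e or e < 2:
        raise ValueError("expansion must be an integer >= 2")
    return FlowMatrix(matrix=np.linalg.matrix_power(fm.matrix, int(e)), nodes=fm.nodes)


def inflate(fm: FlowMatrix, r: float) -> FlowMatrix:
    """Inflation: entrywise power ``r`` then column renormalisation."""
    if r <= 0:
        raise ValueError("inflation must be positive")
    return FlowMatrix(matrix=_normalize_columns(fm.matrix**r), nodes=fm.nodes)


def prune(fm: FlowMatrix, eps: float = DEFAULT_PRUNE_EPS) -> FlowMatrix:
    """Zero entries below ``eps`` and renormalise; errors on a dead column."""
    m = fm.matrix.copy()
    m[m < eps] = 0.0
    return FlowMatrix(matrix=_normalize_columns(m), nodes=fm.nodes)


def _read_clusters(m: np.ndarray, nodes: tuple[str, ...], eps: float) -> dict[str, int]:
    """Read modules from an (approximately) idempotent flow matrix.

    Attractors are nodes with positive return flow (diagonal >= eps).
    Attractors mutually reachable through the limit flow form an attractor
    system; every other node joins the system it sends the most flow to,
    exact ties broken toward the system containing the lexicographically
    smallest attractor id.
    """
    n = len(nodes)
    attractors = [i for i in range(n) if m[i, i] >= eps]
    if not attractors:
        # Degenerate non-converged state: every node its own module.
        return {node: i for i, node in enumerate(nodes)}

    # Union attractors that exchange flow in the limit matrix.
    parent = list(range(len(attractors)))

    def find(x: int) -> int:
        while parent[x] != x:
            parent[x] = parent[parent[x]]
            x = parent[x]
        return x

    pos = {a: k for k, a in enumerate(attractors)}
    for a in attractors:
        for b in attractors:
            if a < b and (m[a, b] >= eps or m[b, a] >= eps):
                ra, rb = find(pos[a]), find(pos[b])
                if ra != rb:
                    parent[rb] = ra

    system_of = {a: find(pos[a]) for a in attractors}
    # Deterministic system label: lexicographically smallest attractor id.
    label: dict[int, str] = {}
    for a in attractors:
        root = system_of[a]
        name = nodes[a]
        if root not in label or name < label[root]:
            label[root] = name

    assignment_name: dict[str, str] = {}
    for j in range(n):
        flow: dict[int, float] = {}
        for a in attractors:
            if m[a, j] > 0:
                flow[system_of[a]] = flow.get(system_of[a], 0.0) + m[a, j]
        if not flow:
            assignment_name[nodes[j]] = nodes[j]  # orphan: own singleton
            continue
        best = max(flow.values())
        candidates = [root for root, f in flow.items() if f == best]
        chosen = min(candidates, key=lambda root: label[root])
        assignment_name[nodes[j]] = label[chosen]

    # Re-index module labels to dense integers, ordered by smallest member.
    by_label: dict[str, list[str]] = {}
    for node, lab in assignment_name.items():
        by_label.setdefault(lab, []).append(node)
    ordered = sorted(by_label, key=lambda lab: min(by_label[lab]))
    module_id = {lab: i for i, lab in enumerate(ordered)}
    return {node: module_id[lab] for node, lab in assignment_name.items()}


def mcl_cluster(
    net: CompoundNetwork,
    inflation: float = 2.0,
    expansion: int = DEFAULT_EXPANSION,
    self_loop_weight: float = DEFAULT_SELF_LOOP,
    prune_eps: float = DEFAULT_PRUNE_EPS,
    max_iter: int = DEFAULT_MAX_ITER,
    conv_tol: float = DEFAULT_CONV_TOL,
) -> ModulePartition:
    """Run MCL to (near-)idempotence and read off the module partition.

    Disconnected inputs are fine — flow never crosses components, so no
    module can span two of them.  If ``max_iter`` is hit first, the best
    current partition is returned with ``converged=False``.
    """
    fm = to_flow_matrix(net, self_loop_weight)
    converged = False
    iterations = 0
    for iterations in range(1, max_iter + 1):
        nxt = prune(inflate(expand(fm, expansion), inflation), prune_eps)
        delta = float(np.abs(nxt.matrix - fm.matrix).max())
        fm = nxt
        if delta < conv_tol:
            converged = True
            break
    if not converged:
        logger.warning("MCL did not converge in %d iterations (inflation=%s)", max_iter, inflation)
    assignment = _read_clusters(fm.matrix, fm.nodes, prune_eps)
    return ModulePartition(
        assignment=assignment,
        inflation=inflation,
        converged=converged,
        iterations=iterations,
    )


def filter_min_size(partition: ModulePartition, min_module_size: int = 1) -> ModulePartition:
    """Drop modules below ``min_module_size`` (their nodes are removed).

    Singletons are valid modules; this filter exists because tiny modules
    (below the smallest biologically reported size) are often noise, but
    nothing is discarded by default.
    """
    keep = {m for m, members in partition.modules().items() if len(members) >= min_module_size}
    assignment = {n: m for n, m in partition.assignment.items() if m in keep}
    return ModulePartition(
        assignment=assignment,
        inflation=partition.inflation,
        converged=partition.converged,
        iterations=partition.iterations,
    )
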