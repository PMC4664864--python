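"""Independent brute-force oracles used to check the implementation.

Everything here is written in plain Python loops against the bare
definitions (no numpy linear algebra, no networkx algorithms) so that it
cannot share a code path with the package.
"""

from __future__ import annotations

import itertools
from math import comb


def naive_mcl_partition(
    edges: list[tuple[int, int]],
    n: int,
    inflation: float,
    expansion: int = 2,
    self_loop: float = 1.0,
    max_iter: int = 200,
    tol: float = 1e-10,
    thr: float = 1e-6,
) -> set[frozenset[int]]:
    """Literal dense-matrix MCL on an integer-labelled graph.

    Pure-Python matrix loops, no pruning; clusters are read from the limit
    matrix: attractors are nodes with positive return flow, attractors
    exchanging flow share a system, and every node joins the system it
    sends the most flow to (ties toward the system with the smallest
    attractor index).
    """
    m = [[0.0] * n for _ in range(n)]
    for u, v in edges:
        if u != v:
            m[u][v] = m[v][u] = 1.0
    for i in range(n):
        m[i][i] += self_loop

    def norm(mat: list[list[float]]) -> list[list[float]]:
        for j in range(n):
            s = sum(mat[i][j] for i in range(n))
            for i in range(n):
                mat[i][j] /= s
        return mat

    def matmul(a: list[list[float]], b: list[list[float]]) -> list[list[float]]:
        return [
            [sum(a[i][k] * b[k][j] for k in range(n)) for j in range(n)]
            for i in range(n)
        ]

    m = norm(m)
    for _ in range(max_iter):
        p = m
        for _ in range(expansion - 1):
            p = matmul(p, m)
        q = norm([[p[i][j] ** inflation for j in range(n)] for i in range(n)])
        delta = max(abs(q[i][j] - m[i][j]) for i in range(n) for j in range(n))
        m = q
        if delta < tol:
            break

    attractors = [i for i in range(n) if m[i][i] > thr]
    system = {a: a for a in attractors}
    changed = True
    while changed:
        changed = False
        for a in attractors:
            for b in attractors:
                if (m[a][b] > thr or m[b][a] > thr) and system[a] != system[b]:
                    lo = min(system[a], system[b])
                    for c in attractors:
                        if system[c] in (system[a], system[b]):
                            system[c] = lo
                    changed = True
    clusters: dict[int, set[int]] = {}
    for j in range(n):
        flow: dict[int, float] = {}
        for a in attractors:
            if m[a][j] > thr:
                flow[system[a]] = flow.get(system[a], 0.0) + m[a][j]
        if not flow:
            clusters.setdefault(-j - 1, set()).add(j)
            continue
        best = max(flow.values())
        root = min(r for r, f in flow.items() if f == best)
        clusters.setdefault(root, set()).add(j)
    return {frozenset(c) for c in clusters.values()}


def brute_betweenness(edges: list[tuple[int, int]], n: int) -> dict[int, float]:
    """Raw betweenness (endpoints excluded) by exhaustive path enumeration."""
    adj: dict[int, set[int]] = {i: set() for i in range(n)}
    for u, v in edges:
        adj[u].add(v)
        adj[v].add(u)

    def all_paths(s: int, t: int) -> list[list[int]]:
        out: list[list[int]] = []
        stack = [(s, [s])]
        while stack:
            node, path = stack.pop()
            if node == t:
                out.append(path)
                continue
            for nb in adj[node]:
                if nb not in path:
                    stack.append((nb, path + [nb]))
        return out

    bc = {i: 0.0 for i in range(n)}
    for s, t in itertools.combinations(range(n), 2):
        paths = all_paths(s, t)
        if not paths:
            continue
        shortest = min(len(p) for p in paths)
        sp = [p for p in paths if len(p) == shortest]
        for node in range(n):
            if node in (s, t):
                continue
            through = sum(1 for p in sp if node in p)
            bc[node] += through / len(sp)
    return bc


def hypergeom_upper_tail(universe: int, pathway: int, query: int, hits: int) -> float:
    """P(X >= hits) by exhaustive enumeration of all query draws."""
    count = 0
    items = list(range(universe))
    for draw in itertools.combinations(items, query):
        if sum(1 for x in draw if x < pathway) >= hits:
            count += 1
    return count / comb(universe, query)
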