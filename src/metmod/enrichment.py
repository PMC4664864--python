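"""Pathway over-representation and topology-impact scoring (MetPA style).

Each pathway contributes two signals: an over-representation tail
probability (hypergeometric: how surprising is the number of query
compounds that land in the pathway) and a *topology impact* — the summed
relative betweenness centrality of the hit compounds within the pathway's
own graph.  A pathway is flagged significant when its impact exceeds the
configured threshold (default 0.10); the hypergeometric p-values are
Benjamini–Hochberg adjusted and reported alongside but do not drive the
flag.

The expected-hit baseline is ``Total × query_fraction`` where
``query_fraction`` is the fraction of the reference metabolome present in
the query list (default 0.02).
"""

from __future__ import annotations

from dataclasses import dataclass, field
from typing import Iterable, Mapping, Sequence

import networkx as nx
from scipy import stats as sps
from statsmodels.stats.multitest import multipletests

DEFAULT_IMPACT_THRESHOLD = 0.10
DEFAULT_QUERY_FRACTION = 0.02


@dataclass
class PathwayGraph:
    """A pathway's compound set plus its internal reaction graph."""

    name: str
    graph: nx.Graph = field(default_factory=nx.Graph)

    @property
    def members(self) -> frozenset[str]:
        return frozenset(self.graph.nodes)

    @property
    def size(self) -> int:
        return self.graph.number_of_nodes()


@dataclass(frozen=True)
class EnrichmentResult:
    pathway: str
    total: int
    expected: float  # 2 decimals
    hits: int
    p_value: float
    p_adjusted: float
    impact: float  # 2 decimals
    significant: bool

    @classmethod
    def columns(cls) -> list[str]:
        return ["pathway", "total", "expected", "hits", "p_value", "p_adjusted", "impact", "significant"]

    def to_row(self) -> dict:
        return {k: getattr(self, k) for k in self.columns()}


def expected_hits(total: int, query_fraction: float) -> float:
    """Expected hit count: pathway size × query fraction, 2 decimals."""
    if not 0.0 <= query_fraction <= 1.0:
        raise ValueError("query_fraction must be in [0, 1]")
    return round(total * query_fraction, 2)


def hypergeom_pvalue(universe: int, pathway: int, query: int, hits: int) -> float:
    """Upper-tail P(X >= hits) for hypergeometric(universe, pathway, query)."""
    if hits > min(pathway, query) or pathway > universe or query > universe or hits < 0:
        raise ValueError("inconsistent hypergeometric counts")
    return float(sps.hypergeom.sf(hits - 1, universe, pathway, query))


def relative_betweenness(pg: PathwayGraph) -> dict[str, float]:
    """Per-compound importance: betweenness normalised to sum to 1.

    Raw shortest-path betweenness (endpoints excluded) is computed on the
    pathway graph and divided by its total so importances sum to one.  On
    graphs where every node has zero betweenness (complete graphs, 2-node
    paths) the importance falls back to uniform 1/n.
    """
    if pg.size < 2:
        raise ValueError("pathway graph needs at least 2 nodes")
    raw = nx.betweenness_centrality(pg.graph, normalized=False)
    total = sum(raw.values())
    if total == 0:
        return {node: 1.0 / pg.size for node in pg.graph.nodes}
    return {node: val / total for node, val in raw.items()}


def impact(pg: PathwayGraph, hit_compounds: Iterable[str]) -> float:
    """Topology impact: summed importance of the hit compounds, 2 decimals."""
    hits = set(hit_compounds)
    outside = hits - pg.members
    if outside:
        raise ValueError(f"hit compounds not in pathway: {sorted(outside)[:5]}")
    importance = relative_betweenness(pg)
    return round(sum(importance[h] for h in hits), 2)


def enrich(
    query: Iterable[str],
    pathways: Sequence[PathwayGraph],
    universe_size: int,
    threshold: float = DEFAULT_IMPACT_THRESHOLD,
    query_fraction: float = DEFAULT_QUERY_FRACTION,
) -> list[EnrichmentResult]:
    """Score every pathway with at least one query hit.

    Results are sorted by impact descending (ties by p-value, then name);
    ``significant`` means impact strictly above ``threshold``.
    """
    query = set(query)
    if not query:
        raise ValueError("empty query")
    if universe_size < len(query):
        raise ValueError("universe smaller than query")
    partial: list[tuple[PathwayGraph, set[str], float]] = []
    for pg in pathways:
        hit_set = query & pg.members
        if not hit_set:
            continue
        p = hypergeom_pvalue(universe_size, pg.size, len(query), len(hit_set))
        partial.append((pg, hit_set, p))
    if not partial:
        return []
    adjusted = multipletests([p for _, _, p in partial], method="fdr_bh")[1]
    results = []
    for (pg, hit_set, p), p_adj in zip(partial, adjusted):
        imp = impact(pg, hit_set)
        results.append(
            EnrichmentResult(
                pathway=pg.name,
                total=pg.size,
                expected=expected_hits(pg.size, query_fraction),
                hits=len(hit_set),
                p_value=p,
                p_adjusted=float(p_adj),
                impact=imp,
                significant=imp > threshold,
            )
        )
    results.sort(key=lambda r: (-r.impact, r.p_value, r.pathway))
    return results
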