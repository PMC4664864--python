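"""Module–pathway similarity: vectorial angle and identical ratio.

Two compound sets are compared as binary membership vectors over their
union universe.  The *vectorial-angle* similarity is the cosine of the
angle between those vectors, which for sets reduces to
``|A∩B| / sqrt(|A|·|B|)``; the *identical ratio* is the Jaccard index
``|A∩B| / |A∪B|``.  Both are reported as percentages at the print
precision used throughout (similarity to 2 decimals, identical ratio to
the nearest integer percent).
"""

from __future__ import annotations

import math
from dataclasses import dataclass
from typing import Iterable, Sequence

from .io import PathwaySet
from .mcl import ModulePartition


@dataclass(frozen=True)
class SimilarityRecord:
    module: int | str
    pathway: str
    overlap: int
    module_size: int
    pathway_size: int
    similarity: float  # percent, 2 decimals
    identical_ratio: int  # percent, nearest integer

    @classmethod
    def columns(cls) -> list[str]:
        return [
            "module",
            "pathway",
            "overlap",
            "module_size",
            "pathway_size",
            "similarity",
            "identical_ratio",
        ]

    def to_row(self) -> dict:
        return {k: getattr(self, k) for k in self.columns()}


def cosine_similarity(a: Iterable[str], b: Iterable[str]) -> float:
    """Vectorial-angle similarity of two compound sets, in percent."""
    a, b = set(a), set(b)
    if not a or not b:
        raise ValueError("cosine similarity undefined for an empty set")
    k = len(a & b)
    return round(100.0 * k / math.sqrt(len(a) * len(b)), 2)


def identical_ratio(a: Iterable[str], b: Iterable[str]) -> int:
    """Jaccard index of two compound sets, in integer percent."""
    a, b = set(a), set(b)
    union = a | b
    if not union:
        raise ValueError("identical ratio undefined for two empty sets")
    return round(100.0 * len(a & b) / len(union))


def rank_pathways(
    partition: ModulePartition,
    pathways: Sequence[PathwaySet],
) -> list[SimilarityRecord]:
    """Score every (module, pathway) pair with at least one shared compound.

    Records are grouped by module; within a module they are sorted by
    similarity descending, ties by larger overlap, then pathway name.
    """
    records: list[SimilarityRecord] = []
    for mod, members in sorted(partition.modules().items(), key=lambda kv: str(kv[0])):
        scored = []
        for pw in pathways:
            k = len(members & pw.members)
            if k == 0:
                continue
            scored.append(
                SimilarityRecord(
                    module=mod,
                    pathway=pw.name,
                    overlap=k,
                    module_size=len(members),
                    pathway_size=pw.size,
                    similarity=cosine_similarity(members, pw.members),
                    identical_ratio=identical_ratio(members, pw.members),
                )
            )
        scored.sort(key=lambda r: (-r.similarity, -r.overlap, r.pathway))
        records.extend(scored)
    return records
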