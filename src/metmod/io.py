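"""Readers and writers for the plain-text formats the pipeline touches.

All other modules do file I/O only through this module.  Supported formats:
TSV edge lists and Cytoscape SIF for networks, GMT for compound sets,
two-header CSV for abundance tables, and CSV/JSON for result records.
Everything is UTF-8.
"""

from __future__ import annotations

import csv
import json
import logging
from dataclasses import dataclass
from pathlib import Path
from typing import Iterable, Sequence

import numpy as np
import pandas as pd

logger = logging.getLogger(__name__)


class FormatError(ValueError):
    """Raised when an input file violates its format contract."""


@dataclass(frozen=True)
class EdgeRecord:
    """One undirected edge; A–B and B–A are the same edge.

    Parallel edges are represented by repeated records.  ``interaction``
    carries the SIF relation label (e.g. a reaction id) when present.
    """

    source: str
    target: str
    interaction: str | None = None

    def __post_init__(self) -> None:
        if not self.source or not self.target:
            raise ValueError("edge endpoints must be non-empty ids")

    @property
    def is_self_loop(self) -> bool:
        return self.source == self.target

    @property
    def key(self) -> tuple[str, str]:
        """Canonical unordered endpoint pair (sorted)."""
        return tuple(sorted((self.source, self.target)))  # type: ignore[return-value]


@dataclass(frozen=True)
class PathwaySet:
    """A named compound set (one GMT line)."""

    name: str
    description: str
    members: frozenset[str]

    @property
    def size(self) -> int:
        return len(self.members)


@dataclass
class AbundanceTable:
    """Metabolite × sample concentration matrix with two group labels.

    ``data`` rows are metabolites, columns are samples; missing values are
    NaN and stay out of all means.  ``groups`` maps each sample column to
    one of exactly two group labels (e.g. sham / ischemia).
    """

    data: pd.DataFrame
    groups: pd.Series

    def __post_init__(self) -> None:
        if list(self.data.columns) != list(self.groups.index):
            raise ValueError("groups index must equal data columns")
        labels = self.groups.unique()
        if len(labels) != 2:
            raise ValueError(f"exactly two groups required, got {list(labels)}")
        counts = self.groups.value_counts()
        if (counts < 2).any():
            raise ValueError("each group needs at least 2 samples")

    @property
    def group_labels(self) -> tuple[str, str]:
        seen: list[str] = []
        for g in self.groups:
            if g not in seen:
                seen.append(g)
        return seen[0], seen[1]

    def samples_of(self, group: str) -> list[str]:
        return [s for s, g in self.groups.items() if g == group]

    @property
    def metabolites(self) -> list[str]:
        return list(self.data.index)


def read_edge_list(path: str | Path, dialect: str = "tsv") -> list[EdgeRecord]:
    """Read an undirected edge list in ``tsv`` or ``sif`` dialect.

    One record per input line; repeated pairs are preserved as parallel
    edges; self-loops are parsed (and flagged on the record) but filtering
    is left to the network builder.  A malformed line raises
    :class:`FormatError` naming the line number.
    """
    path = Path(path)
    records: list[EdgeRecord] = []
    with path.open(encoding="utf-8") as fh:
        for lineno, raw in enumerate(fh, start=1):
            line = raw.rstrip("\n")
            if not line.strip():
                continue
            if dialect == "tsv":
                fields = line.split("\t")
                if len(fields) < 2 or not fields[0].strip() or not fields[1].strip():
                    raise FormatError(f"{path}:{lineno}: malformed TSV edge line {line!r}")
                label = fields[2].strip() if len(fields) > 2 and fields[2].strip() else None
                records.append(EdgeRecord(fields[0].strip(), fields[1].strip(), label))
            elif dialect == "sif":
                fields = line.split()
                if len(fields) < 3:
                    raise FormatError(
                        f"{path}:{lineno}: malformed SIF line {line!r} "
                        "(need source, interaction, >=1 target)"
                    )
                src, rel = fields[0], fields[1]
                for tgt in fields[2:]:
                    records.append(EdgeRecord(src, tgt, rel))
            else:
                raise ValueError(f"unknown dialect {dialect!r}")
    logger.info("read %d edge records from %s (%s)", len(records), path, dialect)
    return records


def write_edge_list(records: Iterable[EdgeRecord], path: str | Path, dialect: str = "tsv") -> None:
    path = Path(path)
    with path.open("w", encoding="utf-8") as fh:
        for rec in records:
            if dialect == "tsv":
                if rec.interaction:
                    fh.write(f"{rec.source}\t{rec.target}\t{rec.interaction}\n")
                else:
                    fh.write(f"{rec.source}\t{rec.target}\n")
            elif dialect == "sif":
                fh.write(f"{rec.source} {rec.interaction or 'rx'} {rec.target}\n")
            else:
                raise ValueError(f"unknown dialect {dialect!r}")


def read_node_list(path: str | Path) -> list[str]:
    """Read one node id per line (explicit isolated-node injection)."""
    path = Path(path)
    with path.open(encoding="utf-8") as fh:
        return [line.strip() for line in fh if line.strip()]


def read_gmt(path: str | Path) -> list[PathwaySet]:
    """Read GMT: name, description, then tab-separated member ids per line."""
    path = Path(path)
    pathways: list[PathwaySet] = []
    seen: set[str] = set()
    with path.open(encoding="utf-8") as fh:
        for lineno, raw in enumerate(fh, start=1):
            line = raw.rstrip("\n")
            if not line.strip():
                continue
            fields = line.split("\t")
            if len(fields) < 3:
                raise FormatError(f"{path}:{lineno}: GMT line needs >=3 tab-separated fields")
            name, desc = fields[0], fields[1]
            if name in seen:
                raise FormatError(f"{path}:{lineno}: duplicate pathway name {name!r}")
            seen.add(name)
            members = frozenset(m for m in fields[2:] if m)
            pathways.append(PathwaySet(name=name, description=desc, members=members))
    logger.info("read %d pathway sets from %s", len(pathways), path)
    return pathways


def write_gmt(pathways: Iterable[PathwaySet], path: str | Path) -> None:
    path = Path(path)
    with path.open("w", encoding="utf-8") as fh:
        for pw in pathways:
            members = "\t".join(sorted(pw.members))
            fh.write(f"{pw.name}\t{pw.description}\t{members}\n")


def read_abundance_csv(path: str | Path) -> AbundanceTable:
    """Read an abundance CSV: sample-id header row, then a ``group`` row.

    Layout::

        metabolite,S1,S2,S3,S4
        group,sham,sham,ischemia,ischemia
        L-Valine,1.2,1.1,1.9,2.0

    Blank cells become missing (NaN); a non-numeric cell is an error.
    """
    path = Path(path)
    raw = pd.read_csv(path, header=0, index_col=0, dtype=str, keep_default_na=False)
    if raw.shape[0] < 1 or "group" not in raw.index:
        raise FormatError(f"{path}: expected a 'group' row under the sample header")
    groups = raw.loc["group"].astype(str)
    body = raw.drop(index="group")
    data = body.mask(body == "")
    try:
        data = data.astype(float)
    except ValueError as exc:
        raise FormatError(f"{path}: non-numeric abundance cell ({exc})") from exc
    data.index.name = "metabolite"
    return AbundanceTable(data=data, groups=groups)


def write_abundance_csv(table: AbundanceTable, path: str | Path) -> None:
    path = Path(path)
    with path.open("w", encoding="utf-8", newline="") as fh:
        writer = csv.writer(fh)
        writer.writerow(["metabolite", *table.data.columns])
        writer.writerow(["group", *table.groups.tolist()])
        for name, row in table.data.iterrows():
            writer.writerow([name, *["" if pd.isna(v) else repr(float(v)) for v in row]])


def write_json(obj: object, path: str | Path) -> None:
    """Write JSON with sorted keys (stable output for identical inputs)."""
    path = Path(path)
    with path.open("w", encoding="utf-8") as fh:
        json.dump(obj, fh, sort_keys=True, indent=2)
        fh.write("\n")


def read_json(path: str | Path) -> object:
    with Path(path).open(encoding="utf-8") as fh:
        return json.load(fh)


def write_records_csv(rows: Sequence[dict], path: str | Path, columns: Sequence[str]) -> None:
    """Write homogeneous record dicts as CSV with a fixed column order."""
    path = Path(path)
    with path.open("w", encoding="utf-8", newline="") as fh:
        writer = csv.DictWriter(fh, fieldnames=list(columns))
        writer.writeheader()
        for row in rows:
            writer.writerow({k: row.get(k, "") for k in columns})


def read_records_csv(path: str | Path) -> list[dict]:
    with Path(path).open(encoding="utf-8", newline="") as fh:
        return list(csv.DictReader(fh))


def write_results(obj: object, path: str | Path, format: str = "json") -> None:
    """Write a result object (record list or mapping-like) to CSV or JSON.

    Record dataclasses expose ``to_row()`` (flat dict) and their class a
    ``columns()`` order; mapping-like results expose ``to_dict()``.  CSV is
    for record lists, JSON for anything ``to_dict``/plain-JSON shaped.
    """
    if format == "csv":
        if not isinstance(obj, Sequence) or not obj or not hasattr(obj[0], "to_row"):
            raise TypeError("CSV output needs a non-empty sequence of row records")
        write_records_csv([r.to_row() for r in obj], path, type(obj[0]).columns())
    elif format == "json":
        if hasattr(obj, "to_dict"):
            obj = obj.to_dict()  # type: ignore[union-attr]
        elif isinstance(obj, Sequence) and obj and hasattr(obj[0], "to_row"):
            obj = [r.to_row() for r in obj]
        write_json(obj, path)
    else:
        raise ValueError(f"unknown result format {format!r}")
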