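"""Multimedia feature graphs (MMFGs) and their structured-text readers.

An MMFG is the per-asset graph of detected feature vocabulary terms and
typed relationships that a multimedia analysis pipeline emits before
indexing.  Three textual sources are supported: a JSON node/edge document,
DICOM-header-like ``Tag: value`` lines, and tabular rows with a header
(the SQL-result-set mapping).
"""

from __future__ import annotations

import json
import logging
import re
from dataclasses import dataclass, field
from numbers import Real
from typing import Iterable, Sequence

import networkx as nx
import pandas as pd

from .graph_code import Discrete

__all__ = [
    "FeatureVocabularyTerm",
    "FeatureRelationship",
    "MultimediaFeatureGraph",
    "normalize_label",
    "read_mmfg",
    "write_mmfg",
    "mmfg_from_keyvalue",
    "mmfg_from_table",
    "mmfg_from_csv_row",
]

log = logging.getLogger(__name__)


class MMFGError(ValueError):
    """Raised for malformed feature-graph documents."""


_WS = re.compile(r"\s+")


def normalize_label(label: str) -> str:
    """Trim surrounding whitespace and collapse internal runs to one space.

    Case is preserved: terms like "BMI" vs "Eye Distance" are case-meaningful.
    Idempotent by construction.
    """
    return _WS.sub(" ", str(label).strip())


@dataclass(frozen=True)
class FeatureVocabularyTerm:
    """One dictionary entry: a normalized label plus an optional semantic
    concept annotation (SKOS-style)."""

    label: str
    concept_tag: str | None = None


@dataclass(frozen=True)
class FeatureRelationship:
    """Directed edge between two terms, carrying either a relationship-type
    code (> 1) or a discrete payload (number or text), never both."""

    source: str
    target: str
    rel_type: int | None = None
    value: Discrete | None = None

    def __post_init__(self) -> None:
        if (self.rel_type is None) == (self.value is None):
            raise MMFGError(
                f"edge {self.source!r}->{self.target!r} needs exactly one of "
                "rel_type or a discrete value"
            )
        if self.rel_type is not None and self.rel_type <= 1:
            raise MMFGError("relationship-type codes must be > 1")


@dataclass
class MultimediaFeatureGraph:
    asset_id: str = ""
    timestamp: str | None = None
    nodes: list[FeatureVocabularyTerm] = field(default_factory=list)
    edges: list[FeatureRelationship] = field(default_factory=list)

    def __post_init__(self) -> None:
        self._labels = {n.label for n in self.nodes}
        self._validate()

    def _validate(self) -> None:
        if len(self._labels) != len(self.nodes):
            raise MMFGError("duplicate node labels after normalization")
        seen_pairs = set()
        for e in self.edges:
            if e.source not in self._labels:
                raise MMFGError(f"dangling edge source {e.source!r}")
            if e.target not in self._labels:
                raise MMFGError(f"dangling edge target {e.target!r}")
            if (e.source, e.target) in seen_pairs:
                raise MMFGError(f"duplicate edge ({e.source!r}, {e.target!r})")
            seen_pairs.add((e.source, e.target))

    # -- construction -------------------------------------------------------
    def add_node(self, label: str, concept_tag: str | None = None) -> FeatureVocabularyTerm:
        label = normalize_label(label)
        if not label:
            raise MMFGError("empty node label")
        if label in self._labels:
            raise MMFGError(f"duplicate node label {label!r}")
        term = FeatureVocabularyTerm(label=label, concept_tag=concept_tag)
        self.nodes.append(term)
        self._labels.add(label)
        return term

    def has_node(self, label: str) -> bool:
        return normalize_label(label) in self._labels

    def add_edge(
        self,
        source: str,
        target: str,
        rel_type: int | None = None,
        value: Discrete | None = None,
    ) -> FeatureRelationship:
        source, target = normalize_label(source), normalize_label(target)
        edge = FeatureRelationship(source=source, target=target, rel_type=rel_type, value=value)
        if source not in self._labels:
            raise MMFGError(f"dangling edge source {source!r}")
        if target not in self._labels:
            raise MMFGError(f"dangling edge target {target!r}")
        if any(e.source == source and e.target == target for e in self.edges):
            raise MMFGError(f"duplicate edge ({source!r}, {target!r})")
        self.edges.append(edge)
        return edge

    # -- comparison -----------------------------------------------------------
    def structurally_equal(self, other: "MultimediaFeatureGraph") -> bool:
        """Same asset, node set (with concept tags) and edge set; order-free."""
        return (
            self.asset_id == other.asset_id
            and set(self.nodes) == set(other.nodes)
            and set(self.edges) == set(other.edges)
        )

    # -- interop ---------------------------------------------------------------
    def to_networkx(self) -> nx.DiGraph:
        g = nx.DiGraph(asset_id=self.asset_id, timestamp=self.timestamp)
        for n in self.nodes:
            g.add_node(n.label, concept_tag=n.concept_tag)
        for e in self.edges:
            g.add_edge(e.source, e.target, rel_type=e.rel_type, value=e.value)
        return g

    @classmethod
    def from_networkx(cls, g: nx.DiGraph) -> "MultimediaFeatureGraph":
        mmfg = cls(asset_id=g.graph.get("asset_id", ""), timestamp=g.graph.get("timestamp"))
        for n, data in g.nodes(data=True):
            mmfg.add_node(str(n), concept_tag=data.get("concept_tag"))
        for u, v, data in g.edges(data=True):
            mmfg.add_edge(str(u), str(v), rel_type=data.get("rel_type"), value=data.get("value"))
        return mmfg

    # -- JSON document ------------------------------------------------------------
    def to_dict(self) -> dict:
        nodes = []
        for n in self.nodes:
            d: dict = {"label": n.label}
            if n.concept_tag is not None:
                d["concept_tag"] = n.concept_tag
            nodes.append(d)
        edges = []
        for e in self.edges:
            d = {"source": e.source, "target": e.target}
            if e.rel_type is not None:
                d["type"] = e.rel_type
            else:
                d["value"] = e.value
            edges.append(d)
        out = {"asset_id": self.asset_id, "nodes": nodes, "edges": edges}
        if self.timestamp is not None:
            out["timestamp"] = self.timestamp
        return out

    def to_json(self, **kwargs) -> str:
        return json.dumps(self.to_dict(), **kwargs)


def _mmfg_from_dict(data: dict) -> MultimediaFeatureGraph:
    if "nodes" not in data or "edges" not in data:
        raise MMFGError("document must contain 'nodes' and 'edges' sections")
    graph = MultimediaFeatureGraph(
        asset_id=data.get("asset_id", ""), timestamp=data.get("timestamp")
    )
    for n in data["nodes"]:
        if "label" not in n:
            raise MMFGError(f"node without a label: {n!r}")
        graph.add_node(n["label"], concept_tag=n.get("concept_tag"))
    for e in data["edges"]:
        try:
            source, target = e["source"], e["target"]
        except (KeyError, TypeError):
            raise MMFGError(f"edge without source/target: {e!r}") from None
        graph.add_edge(source, target, rel_type=e.get("type"), value=e.get("value"))
    return graph


def read_mmfg(source) -> MultimediaFeatureGraph:
    """Read an MMFG JSON document from a path, file object, JSON text or dict."""
    if isinstance(source, dict):
        return _mmfg_from_dict(source)
    if hasattr(source, "read"):
        text = source.read()
    else:
        source = str(source)
        if source.lstrip().startswith("{"):
            text = source
        else:
            with open(source, "r", encoding="utf-8") as fh:
                text = fh.read()
    try:
        data = json.loads(text)
    except json.JSONDecodeError as exc:
        raise MMFGError(f"not a JSON feature-graph document: {exc}") from exc
    return _mmfg_from_dict(data)


def write_mmfg(graph: MultimediaFeatureGraph, path_or_buf) -> None:
    text = graph.to_json(indent=2)
    if hasattr(path_or_buf, "write"):
        path_or_buf.write(text)
    else:
        with open(str(path_or_buf), "w", encoding="utf-8") as fh:
            fh.write(text)


def _parse_scalar(text: str) -> Discrete:
    text = text.strip()
    try:
        return int(text)
    except ValueError:
        pass
    try:
        return float(text)
    except ValueError:
        return text


def mmfg_from_keyvalue(
    lines: Iterable[str], asset_id: str, separator: str = ":"
) -> MultimediaFeatureGraph:
    """Build an MMFG from ``Tag: value`` metadata lines (DICOM-header dialect).

    One node per tag, plus a root node named after the asset; each value is
    stored as a discrete payload on the edge tag -> root, which keeps values
    queryable by term name.  Numeric values are coerced to numbers; anything
    else stays text.  Lines without a separator are skipped with a warning.
    """
    graph = MultimediaFeatureGraph(asset_id=asset_id)
    root = graph.add_node(asset_id).label
    for lineno, raw in enumerate(lines, start=1):
        line = raw.rstrip("\n")
        if not line.strip():
            continue
        if separator not in line:
            log.warning("line %d has no %r separator, skipped: %r", lineno, separator, line)
            continue
        tag, value = line.split(separator, 1)
        tag = normalize_label(tag)
        if not tag:
            log.warning("line %d has an empty tag, skipped: %r", lineno, line)
            continue
        if not graph.has_node(tag):
            graph.add_node(tag)
        if any(e.source == tag and e.target == root for e in graph.edges):
            log.warning("line %d repeats tag %r, keeping the first value", lineno, tag)
            continue
        graph.add_edge(tag, root, value=_parse_scalar(value))
    return graph


def mmfg_from_table(
    columns: Sequence[str], row: Sequence[Discrete], asset_id: str
) -> MultimediaFeatureGraph:
    """Build an MMFG from one tabular row (the SQL-result-set mapping).

    Columns become dictionary terms; each value is carried as a discrete
    payload on the term itself (a self edge, i.e. diagonal placement when
    encoded), so a d-column row encodes to d diagonal discrete cells and no
    off-diagonal content.
    """
    if len(columns) != len(row):
        raise MMFGError(f"{len(columns)} columns but {len(row)} values")
    graph = MultimediaFeatureGraph(asset_id=asset_id)
    for col, value in zip(columns, row):
        label = graph.add_node(col).label
        graph.add_edge(label, label, value=value)
    return graph


def mmfg_from_csv_row(path_or_buf, row_index: int = 0, asset_id: str | None = None):
    """Read a CSV with a header row and map one row through :func:`mmfg_from_table`."""
    frame = pd.read_csv(path_or_buf)
    row = frame.iloc[row_index]
    values = [v.item() if hasattr(v, "item") else v for v in row]
    return mmfg_from_table(
        [str(c) for c in frame.columns],
        values,
        asset_id=asset_id if asset_id is not None else f"row-{row_index}",
    )
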