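"""Graph Codes: adjacency-matrix feature indexes.

A Graph Code is a 2D projection of a multimedia feature graph: an ordered
dictionary of feature vocabulary terms plus a square matrix whose cell
(i, j) describes the directed relationship row-term -> column-term.  Cells
are tagged values: presence of a term (diagonal), a relationship-type code,
a discrete payload (a measured number or a text attribute), or — in query
codes only — an inclusive numeric range.

Matrix operations over these codes scale linearly with the dictionary,
which is what makes them attractive as a retrieval index compared to graph
traversal.
"""

from __future__ import annotations

import json
import re
from dataclasses import dataclass, field, replace
from numbers import Real
from typing import Iterable, Iterator, Mapping, Union

import numpy as np
import pandas as pd

__all__ = [
    "CellValue",
    "DiscreteRange",
    "GraphCode",
    "EMPTY",
    "PRESENCE",
    "RELATIONSHIP_TYPES",
    "register_relationship_type",
    "encode",
    "decode",
    "parse_range_literal",
    "format_discrete_literal",
    "cell_matches",
    "read_graph_code",
    "write_graph_code",
]

Discrete = Union[int, float, str]

#: Registered relationship-type codes.  Code 1 is reserved for term presence
#: on the diagonal; code 0 / the empty cell means "no relationship".
RELATIONSHIP_TYPES: dict[int, str] = {
    1: "presence",
    2: "associated with",
    3: "belongs to",
    4: "is a",
    5: "above",
}


def register_relationship_type(code: int, name: str) -> None:
    """Register an additional relationship-type code (must be > 1)."""
    if code <= 1:
        raise ValueError("relationship-type codes must be > 1 (1 is presence)")
    RELATIONSHIP_TYPES[int(code)] = name


class GraphCodeError(ValueError):
    """Raised for invalid Graph Code structures or literals."""


@dataclass(frozen=True)
class DiscreteRange:
    """Inclusive numeric range carried by a query cell, e.g. D(27.10-27.25)."""

    low: float
    high: float

    def __post_init__(self) -> None:
        if not (isinstance(self.low, Real) and isinstance(self.high, Real)):
            raise GraphCodeError("range bounds must be numeric")
        if self.low > self.high:
            raise GraphCodeError(f"empty range: low {self.low} > high {self.high}")

    def contains(self, value: object) -> bool:
        return isinstance(value, Real) and not isinstance(value, bool) and (
            self.low <= value <= self.high
        )


@dataclass(frozen=True)
class CellValue:
    """Tagged content of one matrix cell.

    Exactly one payload is populated, selected by ``tag``:

    ==========  =====================================================
    tag         payload
    ==========  =====================================================
    empty       none — no relationship
    presence    none — diagonal marker that the term exists (code 1)
    rel_type    ``code`` — a registered relationship-type integer > 1
    discrete    ``value`` — a number or text attribute value
    range       ``low``/``high`` — inclusive numeric bounds, query only
    ==========  =====================================================
    """

    tag: str
    code: int | None = None
    value: Discrete | None = None
    low: float | None = None
    high: float | None = None

    _TAGS = ("empty", "presence", "rel_type", "discrete", "range")

    def __post_init__(self) -> None:
        if self.tag not in self._TAGS:
            raise GraphCodeError(f"unknown cell tag {self.tag!r}")
        if self.tag == "rel_type" and (self.code is None or self.code <= 1):
            raise GraphCodeError("rel_type cells need a type code > 1")
        if self.tag == "discrete" and self.value is None:
            raise GraphCodeError("discrete cells need a value")
        if self.tag == "range" and (self.low is None or self.high is None):
            raise GraphCodeError("range cells need low and high bounds")
        if self.tag == "range" and self.low > self.high:
            raise GraphCodeError(f"empty range: low {self.low} > high {self.high}")

    # -- constructors ------------------------------------------------------
    @classmethod
    def empty(cls) -> "CellValue":
        return EMPTY

    @classmethod
    def presence(cls) -> "CellValue":
        return PRESENCE

    @classmethod
    def rel(cls, code: int) -> "CellValue":
        return cls(tag="rel_type", code=int(code))

    @classmethod
    def discrete(cls, value: Discrete) -> "CellValue":
        return cls(tag="discrete", value=value)

    @classmethod
    def range(cls, low: float, high: float) -> "CellValue":
        return cls(tag="range", low=float(low), high=float(high))

    # -- predicates --------------------------------------------------------
    @property
    def is_empty(self) -> bool:
        return self.tag == "empty"

    @property
    def is_numeric(self) -> bool:
        return self.tag == "discrete" and isinstance(self.value, Real) and not isinstance(
            self.value, bool
        )

    def as_range(self) -> DiscreteRange:
        if self.tag != "range":
            raise GraphCodeError("not a range cell")
        return DiscreteRange(self.low, self.high)

    def __str__(self) -> str:  # matrix-table rendering
        if self.tag == "empty":
            return "0"
        if self.tag == "presence":
            return "1"
        if self.tag == "rel_type":
            return str(self.code)
        if self.tag == "discrete":
            return f"D({self.value})"
        return f"D({self.low}–{self.high})"


EMPTY = CellValue(tag="empty")
PRESENCE = CellValue(tag="presence")

# D(a–b) with en dash or hyphen; D(x) for a single discrete literal.
_NUM = r"[+]?\d+(?:\.\d+)?(?:[eE][+-]?\d+)?"
_RANGE_RE = re.compile(rf"^\s*D\(\s*({_NUM})\s*[–—-]\s*({_NUM})\s*\)\s*$")
_DISCRETE_RE = re.compile(r"^\s*D\(\s*(.*?)\s*\)\s*$")


def parse_range_literal(text: str) -> DiscreteRange:
    """Parse a discrete-range query literal such as ``D(27.10–27.25)``.

    Both the en dash and the plain hyphen are accepted as the separator;
    bounds are inclusive at both ends.  A literal whose lower bound exceeds
    its upper bound is rejected.
    """
    m = _RANGE_RE.match(text)
    if not m:
        raise GraphCodeError(f"malformed range literal: {text!r}")
    low, high = float(m.group(1)), float(m.group(2))
    if low > high:
        raise GraphCodeError(f"range literal out of order: {text!r}")
    return DiscreteRange(low, high)


def _coerce_number(text: str) -> Discrete:
    try:
        i = int(text)
        return i
    except ValueError:
        pass
    try:
        return float(text)
    except ValueError:
        return text


def parse_cell_literal(text: str) -> CellValue:
    """Parse one matrix-table cell: ``0``, ``1``, a type code, ``D(x)`` or ``D(a–b)``."""
    text = str(text).strip()
    if text in ("", "0"):
        return EMPTY
    if text == "1":
        return PRESENCE
    m = _RANGE_RE.match(text)
    if m:
        r = parse_range_literal(text)
        return CellValue.range(r.low, r.high)
    m = _DISCRETE_RE.match(text)
    if m:
        return CellValue.discrete(_coerce_number(m.group(1)))
    try:
        return CellValue.rel(int(text))
    except (ValueError, GraphCodeError):
        raise GraphCodeError(f"unparseable cell literal: {text!r}") from None


def format_discrete_literal(value: Discrete) -> str:
    return f"D({value})"


def cell_matches(query_cell: CellValue, candidate_cell: CellValue) -> bool:
    """Does a candidate cell satisfy a query cell?

    Empty query cells are wildcards.  Relationship-type and discrete query
    cells demand equality.  A range query cell matches a numeric discrete
    candidate lying inside its inclusive bounds; against a non-numeric or
    non-discrete candidate it simply does not match (never an error), so
    ``EQUALS x`` on numeric x is extensionally the degenerate range [x, x].
    """
    if query_cell.is_empty:
        return True
    if query_cell.tag == "presence":
        return candidate_cell.tag == "presence"
    if query_cell.tag == "rel_type":
        return candidate_cell.tag == "rel_type" and candidate_cell.code == query_cell.code
    if query_cell.tag == "discrete":
        if candidate_cell.tag != "discrete":
            return False
        if query_cell.is_numeric and candidate_cell.is_numeric:
            return float(query_cell.value) == float(candidate_cell.value)
        return candidate_cell.value == query_cell.value
    # range
    return candidate_cell.tag == "discrete" and query_cell.as_range().contains(
        candidate_cell.value
    )


@dataclass
class GraphCode:
    """Ordered term dictionary plus a square matrix of tagged cells.

    The matrix is stored sparsely as a mapping ``(row_term, column_term) ->
    CellValue``; absent keys are empty cells.  ``is_query`` marks codes that
    may legally carry range cells (query by example).
    """

    dictionary: list[str]
    cells: dict[tuple[str, str], CellValue] = field(default_factory=dict)
    asset_id: str = ""
    timestamp: str | None = None
    is_query: bool = False

    def __post_init__(self) -> None:
        self.validate()

    # -- validation --------------------------------------------------------
    def validate(self) -> None:
        seen = set()
        for term in self.dictionary:
            if not term:
                raise GraphCodeError("empty dictionary term")
            if term in seen:
                raise GraphCodeError(f"duplicate dictionary term {term!r}")
            seen.add(term)
        for (r, c), cell in list(self.cells.items()):
            if r not in seen or c not in seen:
                raise GraphCodeError(f"cell ({r!r}, {c!r}) outside the dictionary")
            if cell.is_empty:
                del self.cells[(r, c)]
                continue
            if cell.tag == "range" and not self.is_query:
                raise GraphCodeError("range cells are only legal in query codes")
            if cell.tag == "presence" and r != c:
                raise GraphCodeError("presence cells are only legal on the diagonal")

    # -- basic accessors ----------------------------------------------------
    def __len__(self) -> int:
        return len(self.dictionary)

    @property
    def n_cells(self) -> int:
        """Total number of matrix cells, |dict|^2."""
        return len(self.dictionary) ** 2

    def cell(self, row: str, col: str) -> CellValue:
        return self.cells.get((row, col), EMPTY)

    def set_cell(self, row: str, col: str, value: CellValue) -> None:
        if row not in self.term_set or col not in self.term_set:
            raise GraphCodeError(f"cell ({row!r}, {col!r}) outside the dictionary")
        if value.is_empty:
            self.cells.pop((row, col), None)
        else:
            self.cells[(row, col)] = value

    @property
    def term_set(self) -> frozenset[str]:
        return frozenset(self.dictionary)

    def nonempty_cells(self) -> Iterator[tuple[str, str, CellValue]]:
        """Non-empty cells in row-major dictionary order (deterministic)."""
        index = {t: i for i, t in enumerate(self.dictionary)}
        for (r, c), v in sorted(
            self.cells.items(), key=lambda kv: (index[kv[0][0]], index[kv[0][1]])
        ):
            yield r, c, v

    def off_diagonal_cells(self) -> Iterator[tuple[str, str, CellValue]]:
        for r, c, v in self.nonempty_cells():
            if r != c:
                yield r, c, v

    def structurally_equal(self, other: "GraphCode") -> bool:
        """Equality up to dictionary order: same term set, same cell map."""
        return self.term_set == other.term_set and self.cells == other.cells

    def copy(self) -> "GraphCode":
        return GraphCode(
            dictionary=list(self.dictionary),
            cells=dict(self.cells),
            asset_id=self.asset_id,
            timestamp=self.timestamp,
            is_query=self.is_query,
        )

    def with_diagonal_presence(self) -> "GraphCode":
        out = self.copy()
        for t in out.dictionary:
            if out.cell(t, t).is_empty:
                out.set_cell(t, t, PRESENCE)
        return out

    # -- dense views --------------------------------------------------------
    def matrix(self) -> np.ndarray:
        """Dense object-dtype matrix of CellValues, dictionary order."""
        n = len(self.dictionary)
        m = np.full((n, n), EMPTY, dtype=object)
        index = {t: i for i, t in enumerate(self.dictionary)}
        for (r, c), v in self.cells.items():
            m[index[r], index[c]] = v
        return m

    def to_frame(self) -> pd.DataFrame:
        """Matrix-table view: rows/columns labeled by the dictionary."""
        m = self.matrix()
        return pd.DataFrame(
            [[str(v) for v in row] for row in m],
            index=self.dictionary,
            columns=self.dictionary,
        )

    # -- JSON serialization --------------------------------------------------
    def to_dict(self) -> dict:
        index = {t: i for i, t in enumerate(self.dictionary)}
        cells = []
        for r, c, v in self.nonempty_cells():
            if v.tag == "presence":
                payload: dict = {"type": 1}
            elif v.tag == "rel_type":
                payload = {"type": v.code}
            elif v.tag == "discrete":
                payload = {"value": v.value}
            else:
                payload = {"range": [v.low, v.high]}
            cells.append([index[r], index[c], payload])
        out = {
            "dictionary": list(self.dictionary),
            "cells": cells,
            "asset_id": self.asset_id,
            "is_query": self.is_query,
        }
        if self.timestamp is not None:
            out["timestamp"] = self.timestamp
        return out

    def to_json(self, **kwargs) -> str:
        return json.dumps(self.to_dict(), **kwargs)

    @classmethod
    def from_dict(cls, data: Mapping) -> "GraphCode":
        dictionary = list(data["dictionary"])
        gc = cls(
            dictionary=dictionary,
            asset_id=data.get("asset_id", ""),
            timestamp=data.get("timestamp"),
            is_query=bool(data.get("is_query", False)),
        )
        for entry in data.get("cells", []):
            i, j, payload = entry
            r, c = dictionary[i], dictionary[j]
            if "range" in payload:
                low, high = payload["range"]
                cell = CellValue.range(low, high)
            elif "value" in payload:
                cell = CellValue.discrete(payload["value"])
            elif payload.get("type") == 1:
                cell = PRESENCE
            else:
                cell = CellValue.rel(payload["type"])
            gc.set_cell(r, c, cell)
        gc.validate()
        return gc

    @classmethod
    def from_json(cls, text: str) -> "GraphCode":
        return cls.from_dict(json.loads(text))

    # -- CSV matrix table ------------------------------------------------------
    def to_csv(self, path_or_buf=None):
        """Write the matrix-table form (header row = dictionary, one labeled row
        per term, cells as integers or D(...) literals)."""
        return self.to_frame().to_csv(path_or_buf)

    @classmethod
    def from_csv(cls, path_or_buf, asset_id: str = "", is_query: bool = False) -> "GraphCode":
        frame = pd.read_csv(path_or_buf, index_col=0, dtype=str).fillna("0")
        dictionary = [str(c) for c in frame.columns]
        if [str(i) for i in frame.index] != dictionary:
            raise GraphCodeError("matrix table is not square: row labels != column labels")
        gc = cls(dictionary=dictionary, asset_id=asset_id, is_query=is_query)
        for r in dictionary:
            for c in dictionary:
                cell = parse_cell_literal(frame.loc[r, c])
                if not cell.is_empty:
                    gc.set_cell(r, c, cell)
        gc.validate()
        return gc


# -- encode / decode ------------------------------------------------------------


def encode(graph) -> GraphCode:
    """Project a multimedia feature graph onto its Graph Code.

    The dictionary keeps node insertion order; every term's diagonal cell is
    a presence marker; each edge writes its relationship-type code or its
    discrete payload at (source, target).  A self edge with a discrete
    payload produces a diagonal discrete cell (the tabular-row convention),
    replacing the presence marker.
    """
    dictionary = [n.label for n in graph.nodes]
    gc = GraphCode(
        dictionary=dictionary, asset_id=graph.asset_id, timestamp=graph.timestamp
    )
    for t in dictionary:
        gc.set_cell(t, t, PRESENCE)
    for e in graph.edges:
        if e.value is not None:
            gc.set_cell(e.source, e.target, CellValue.discrete(e.value))
        else:
            gc.set_cell(e.source, e.target, CellValue.rel(e.rel_type))
    return gc


def decode(gc: GraphCode):
    """Rebuild the feature graph from a non-query Graph Code (inverse of
    :func:`encode` up to node order)."""
    from . import feature_model as fm

    if gc.is_query:
        raise GraphCodeError("query codes carry ranges, not graph content")
    graph = fm.MultimediaFeatureGraph(asset_id=gc.asset_id, timestamp=gc.timestamp)
    for term in gc.dictionary:
        graph.add_node(term)
    for r, c, v in gc.nonempty_cells():
        if v.tag == "presence":
            continue
        if v.tag == "discrete":
            graph.add_edge(r, c, value=v.value)
        else:
            graph.add_edge(r, c, rel_type=v.code)
    return graph


# -- file helpers -----------------------------------------------------------------


def read_graph_code(path) -> GraphCode:
    """Read a Graph Code from a ``.json`` or ``.csv`` file."""
    path = str(path)
    with open(path, "r", encoding="utf-8") as fh:
        if path.endswith(".csv"):
            return GraphCode.from_csv(fh)
        return GraphCode.from_json(fh.read())


def write_graph_code(gc: GraphCode, path) -> None:
    path = str(path)
    with open(path, "w", encoding="utf-8") as fh:
        if path.endswith(".csv"):
            gc.to_csv(fh)
        else:
            fh.write(gc.to_json(indent=2))
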