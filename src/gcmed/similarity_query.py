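"""Similarity metric triple and query-by-example over Graph Codes.

Retrieval compares a query code against each collection element with three
containment-style measures:

* ``m_f``  — vocabulary overlap: |dict_Q ∩ dict_C| / |dict_Q|;
* ``m_fr`` — fraction of the query's queried cells (non-presence cells,
  i.e. typed relationships, discrete values or ranges) that land on a
  non-empty position of the candidate;
* ``m_rt`` — fraction of queried cells whose candidate value also matches
  (equal type code, equal discrete value, or a numeric value inside the
  query's inclusive range).

Value matching implies position matching, so m_rt <= m_fr always, and a
code's similarity to itself is (1, 1, 1).

Value predicates may name a single term ("Eye Distance IN (27.10, 27.25)",
"age EQUALS 21"): such a predicate sits on the query's diagonal and is
checked against every candidate cell incident to that term, which covers
all three value-placement conventions (attribute edges, diagonal tabular
cells, key-value metadata edges).
"""

from __future__ import annotations

import re
from dataclasses import dataclass
from numbers import Real

from .graph_code import (
    CellValue,
    DiscreteRange,
    GraphCode,
    GraphCodeError,
    cell_matches,
)
from .relevance import GraphCodeCollection

__all__ = [
    "SimilarityTriple",
    "QueryPredicate",
    "build_query",
    "parse_predicate",
    "similarity",
    "rank",
]


@dataclass(frozen=True)
class SimilarityTriple:
    m_f: float
    m_fr: float
    m_rt: float

    def as_tuple(self) -> tuple[float, float, float]:
        return (self.m_f, self.m_fr, self.m_rt)

    def weighted(self, weights: tuple[float, float, float]) -> float:
        return sum(w * v for w, v in zip(weights, self.as_tuple()))


@dataclass(frozen=True)
class QueryPredicate:
    """One query condition.

    ``operator`` is IN (numeric range), EQUALS (value equality; numeric
    values are treated as the degenerate range [x, x]) or HAS_TYPE (a typed
    relationship, which requires an explicit ``object`` term).
    """

    subject: str
    operator: str
    operand: object
    object: str | None = None

    def __post_init__(self) -> None:
        if self.operator not in ("IN", "EQUALS", "HAS_TYPE"):
            raise GraphCodeError(f"unknown operator {self.operator!r}")
        if self.operator == "IN" and not isinstance(self.operand, DiscreteRange):
            raise GraphCodeError("IN requires a DiscreteRange operand")
        if self.operator == "HAS_TYPE":
            if self.object is None:
                raise GraphCodeError("HAS_TYPE requires an object term")
            if not isinstance(self.operand, int):
                raise GraphCodeError("HAS_TYPE requires an integer type code")

    def cell(self) -> CellValue:
        if self.operator == "IN":
            return CellValue.range(self.operand.low, self.operand.high)
        if self.operator == "EQUALS":
            if isinstance(self.operand, Real) and not isinstance(self.operand, bool):
                x = float(self.operand)
                return CellValue.range(x, x)
            return CellValue.discrete(self.operand)
        return CellValue.rel(self.operand)


_PRED_RE = re.compile(
    r"""^\s*(?P<subject>.+?)\s+
        (?:(?:IN\s*\(\s*(?P<low>-?\d+(?:\.\d+)?)\s*,\s*(?P<high>-?\d+(?:\.\d+)?)\s*\))
          |(?:EQUALS\s+(?P<value>.+?)))\s*$""",
    re.VERBOSE | re.IGNORECASE,
)


def parse_predicate(text: str) -> QueryPredicate:
    """Parse the CLI predicate dialect: ``TERM IN (a, b)`` or ``TERM EQUALS x``."""
    m = _PRED_RE.match(text)
    if not m:
        raise GraphCodeError(f"unparseable predicate: {text!r}")
    subject = m.group("subject").strip()
    if m.group("low") is not None:
        return QueryPredicate(
            subject=subject,
            operator="IN",
            operand=DiscreteRange(float(m.group("low")), float(m.group("high"))),
        )
    value = m.group("value").strip()
    try:
        operand: object = int(value)
    except ValueError:
        try:
            operand = float(value)
        except ValueError:
            operand = value
    return QueryPredicate(subject=subject, operator="EQUALS", operand=operand)


def build_query(predicates: list[QueryPredicate], asset_id: str = "query") -> GraphCode:
    """Assemble a query Graph Code from predicates.

    Each predicate writes its cell at (subject, object), or on the diagonal
    when no object term is given.  Two predicates claiming the same cell
    with different content conflict and raise.
    """
    gc = GraphCode(dictionary=[], asset_id=asset_id, is_query=True)
    for pred in predicates:
        for term in (pred.subject, pred.object):
            if term is not None and term not in gc.term_set:
                gc.dictionary.append(term)
    for pred in predicates:
        row = pred.subject
        col = pred.object if pred.object is not None else pred.subject
        new = pred.cell()
        old = gc.cell(row, col)
        if not old.is_empty and old != new:
            raise GraphCodeError(f"conflicting predicates on cell ({row!r}, {col!r})")
        gc.set_cell(row, col, new)
    return gc


def _queried_cells(query: GraphCode):
    """Cells of the query that constrain the candidate: everything except
    bare presence markers."""
    return [(r, c, v) for r, c, v in query.nonempty_cells() if v.tag != "presence"]


def _incident_cells(candidate: GraphCode, term: str):
    for (r, c), v in candidate.cells.items():
        if term in (r, c):
            yield v


def similarity(query: GraphCode, candidate: GraphCode) -> SimilarityTriple:
    """Similarity metric triple of a candidate against a query.

    An empty query is vacuous and matches everything at (1, 1, 1).  When the
    query constrains no cells, m_fr and m_rt are 1 if the whole query
    vocabulary occurs in the candidate and 0 otherwise (so disjoint
    dictionaries score (0, 0, 0)).
    """
    if not query.dictionary:
        return SimilarityTriple(1.0, 1.0, 1.0)
    shared = query.term_set & candidate.term_set
    m_f = len(shared) / len(query.dictionary)
    queried = _queried_cells(query)
    if not queried:
        vac = 1.0 if query.term_set <= candidate.term_set else 0.0
        return SimilarityTriple(m_f, vac, vac)
    hits_pos = 0
    hits_val = 0
    for r, c, qcell in queried:
        if r == c and qcell.tag in ("discrete", "range"):
            # single-term value predicate: any incident candidate cell may hold it
            incident = [
                v for v in _incident_cells(candidate, r) if v.tag == "discrete"
            ]
            if incident:
                hits_pos += 1
                if any(cell_matches(qcell, v) for v in incident):
                    hits_val += 1
        else:
            ccell = candidate.cell(r, c)
            if r in candidate.term_set and c in candidate.term_set and not ccell.is_empty:
                hits_pos += 1
                if cell_matches(qcell, ccell):
                    hits_val += 1
    n = len(queried)
    return SimilarityTriple(m_f, hits_pos / n, hits_val / n)


def rank(
    coll: GraphCodeCollection,
    query: GraphCode,
    weights: tuple[float, float, float] | None = None,
    top: int | None = None,
) -> list[tuple[str, SimilarityTriple]]:
    """Order the collection by similarity to the query.

    Default ranking is descending lexicographic on (m_f, m_fr, m_rt); with
    ``weights`` a descending weighted sum is used instead.  Ties break on
    asset_id so the output is deterministic.
    """
    if not len(coll):
        raise GraphCodeError("cannot rank an empty collection")
    scored = [(gc.asset_id, similarity(query, gc)) for gc in coll]
    if weights is None:
        scored.sort(key=lambda kv: (tuple(-x for x in kv[1].as_tuple()), kv[0]))
    else:
        scored.sort(key=lambda kv: (-kv[1].weighted(weights), kv[0]))
    return scored[:top] if top is not None else scored
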