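"""Feature relevance over Graph Code collections.

Terms that occur in every element of a collection carry no retrieval
signal; an adapted TF-IDF exposes them.  Because a Graph Code dictionary
holds unique terms, plain term frequency is unavailable, so the number of
non-empty off-diagonal cells in a term's matrix row (its discrimination
weight) stands in for it, floored at 1 so a structurally isolated but
present term is not auto-eliminated:

    tfidf(t, gc)   = max(row_weight(t, gc), 1) * ln(N / df(t))
    tfidf_coll(t)  = sum of tfidf(t, gc) over the codes containing t

where N is the collection size and df(t) the number of codes whose
dictionary contains t.  tfidf_coll(t) = 0 exactly when t is ubiquitous
(df = N).  Those terms form the collection's stop code SGC_STOP; subtracting
it from an element yields its Feature Relevant Graph Code (FRSGC), shrinking
a d-term index to (d - k)^2 cells.
"""

from __future__ import annotations

import json
import logging
import math
from dataclasses import dataclass, field

import pandas as pd

from .algebra import TimedPatientCollection, diff, patient_code_at, project_diff, subtract
from .graph_code import CellValue, GraphCode, GraphCodeError

__all__ = [
    "GraphCodeCollection",
    "TermRelevance",
    "RelevanceReport",
    "row_weight",
    "m_dis",
    "gc_tfidf",
    "collection_tfidf",
    "m_rel",
    "build_stop_code",
    "edit_stop_code",
    "feature_relevant",
    "m_abt",
    "frsgc_hist",
]

log = logging.getLogger(__name__)


@dataclass
class GraphCodeCollection:
    """A collection of Graph Codes with unique asset ids (SGC_Coll)."""

    codes: list[GraphCode]
    id: str = ""

    def __post_init__(self) -> None:
        ids = [gc.asset_id for gc in self.codes]
        if len(set(ids)) != len(ids):
            raise GraphCodeError("collection asset_ids must be unique")

    def __len__(self) -> int:
        return len(self.codes)

    def __iter__(self):
        return iter(self.codes)

    def terms(self) -> list[str]:
        """Union of dictionaries, in first-appearance order."""
        seen: list[str] = []
        known = set()
        for gc in self.codes:
            for t in gc.dictionary:
                if t not in known:
                    known.add(t)
                    seen.append(t)
        return seen

    def df(self, term: str) -> int:
        """Document frequency: in how many codes the term's dictionary occurs."""
        return sum(1 for gc in self.codes if term in gc.term_set)


def row_weight(gc: GraphCode, term: str) -> int:
    """Number of non-empty off-diagonal cells in the term's matrix row."""
    if term not in gc.term_set:
        raise GraphCodeError(f"term {term!r} not in the code's dictionary")
    return sum(1 for (r, c) in gc.cells if r == term and c != term)


def m_dis(gc: GraphCode, term_i: str, term_j: str) -> int:
    """Feature discrimination: difference of the two terms' row weights.

    The sign orders the pair; rankings use the magnitude (the greater the
    difference, the more discriminative term_i is relative to term_j).
    Antisymmetric by construction.
    """
    return row_weight(gc, term_i) - row_weight(gc, term_j)


def gc_tfidf(term: str, gc: GraphCode, coll: GraphCodeCollection) -> float:
    """Adapted TF-IDF of a term within one code of a collection."""
    if term not in gc.term_set:
        raise GraphCodeError(f"term {term!r} not in the code's dictionary")
    df = coll.df(term)
    if df == 0:
        raise GraphCodeError(f"term {term!r} does not occur in the collection")
    weight = max(row_weight(gc, term), 1)
    return weight * math.log(len(coll) / df)


def collection_tfidf(term: str, coll: GraphCodeCollection) -> float:
    """Collection-level relevance: the term's tfidf summed over the codes
    containing it."""
    df = coll.df(term)
    if df == 0:
        raise GraphCodeError(f"term {term!r} does not occur in the collection")
    idf = math.log(len(coll) / df)
    weight = sum(max(row_weight(gc, term), 1) for gc in coll if term in gc.term_set)
    return weight * idf


def m_rel(term_i: str, term_j: str, coll: GraphCodeCollection) -> float:
    """Feature relevance of term_i relative to term_j: the difference of
    their collection-level tfidf values."""
    return collection_tfidf(term_i, coll) - collection_tfidf(term_j, coll)


@dataclass(frozen=True)
class TermRelevance:
    df: int
    weight: int
    tfidf: float


@dataclass
class RelevanceReport:
    """Per-term relevance table plus the derived stop-word code."""

    per_term: dict[str, TermRelevance]
    stop_code: GraphCode
    threshold_fraction: float = 0.0
    n_codes: int = 0

    def is_stopped(self, term: str) -> bool:
        return term in self.stop_code.term_set

    def to_frame(self) -> pd.DataFrame:
        rows = [
            {
                "term": t,
                "df": rel.df,
                "weight": rel.weight,
                "tfidf": rel.tfidf,
                "stopped": self.is_stopped(t),
            }
            for t, rel in sorted(self.per_term.items())
        ]
        return pd.DataFrame(rows, columns=["term", "df", "weight", "tfidf", "stopped"])

    def to_csv(self, path_or_buf=None):
        return self.to_frame().to_csv(path_or_buf, index=False)

    def to_dict(self) -> dict:
        return {
            "n_codes": self.n_codes,
            "threshold_fraction": self.threshold_fraction,
            "per_term": {
                t: {"df": r.df, "weight": r.weight, "tfidf": r.tfidf}
                for t, r in self.per_term.items()
            },
            "stop_code": self.stop_code.to_dict(),
        }

    def to_json(self, **kwargs) -> str:
        return json.dumps(self.to_dict(), **kwargs)


def _presence_code(terms: list[str], asset_id: str) -> GraphCode:
    gc = GraphCode(dictionary=list(terms), asset_id=asset_id)
    for t in terms:
        gc.set_cell(t, t, CellValue.presence())
    return gc


def _relevance_table(coll: GraphCodeCollection) -> dict[str, TermRelevance]:
    n = len(coll)
    table: dict[str, TermRelevance] = {}
    for term in coll.terms():
        df = coll.df(term)
        weight = sum(max(row_weight(gc, term), 1) for gc in coll if term in gc.term_set)
        table[term] = TermRelevance(df=df, weight=weight, tfidf=weight * math.log(n / df))
    return table


def build_stop_code(
    coll: GraphCodeCollection, threshold_fraction: float = 0.0
) -> RelevanceReport:
    """Compute the collection's stop-word code SGC_STOP.

    All zero-relevance terms (exactly the ubiquitous ones, df = N) are
    stopped.  With ``threshold_fraction`` > 0, additionally the lowest
    floor(fraction * remaining) terms by (tfidf, label) — the lexicographic
    tie-break keeps the result deterministic.
    """
    if len(coll) < 2:
        raise GraphCodeError("relevance needs a collection of at least 2 codes")
    if not (0 <= threshold_fraction < 1):
        raise GraphCodeError("threshold_fraction must lie in [0, 1)")
    table = _relevance_table(coll)
    stopped = sorted(t for t, rel in table.items() if rel.tfidf == 0.0)
    remaining = sorted(
        ((rel.tfidf, t) for t, rel in table.items() if rel.tfidf != 0.0)
    )
    k = int(threshold_fraction * len(remaining))
    stopped += [t for _tfidf, t in remaining[:k]]
    return RelevanceReport(
        per_term=table,
        stop_code=_presence_code(sorted(stopped), asset_id="SGC_STOP"),
        threshold_fraction=threshold_fraction,
        n_codes=len(coll),
    )


def edit_stop_code(
    report: RelevanceReport,
    add_terms: list[str] = (),
    remove_terms: list[str] = (),
) -> GraphCode:
    """Produce the edited stop code SGC_STOP-ED: the calculated stop code
    with user-required terms added and protected terms removed.  Unknown
    removals are logged, never fatal."""
    terms = list(report.stop_code.dictionary)
    for t in remove_terms:
        if t in terms:
            terms.remove(t)
        else:
            log.warning("cannot remove %r: not in the stop code", t)
    for t in add_terms:
        if t not in terms:
            terms.append(t)
    return _presence_code(sorted(terms), asset_id="SGC_STOP-ED")


def feature_relevant(gc: GraphCode, stop_code: GraphCode) -> GraphCode:
    """FRSGC = SGC - SGC_STOP: drop every stopped term with all its
    relationships.  Idempotent."""
    return subtract(gc, stop_code)


def m_abt(gc: GraphCode, stop_ed: GraphCode) -> float:
    """Aboutness of a code relative to an (edited) stop code: the fraction
    of its vocabulary that survives the subtraction, in [0, 1].  Assets whose
    value falls below an application cutoff are out of the collection's
    topical domain."""
    if not gc.dictionary:
        raise GraphCodeError("aboutness of an empty code is undefined")
    return len(subtract(gc, stop_ed).dictionary) / len(gc.dictionary)


def frsgc_hist(
    timelines: list[TimedPatientCollection], window: tuple[str, str]
) -> RelevanceReport:
    """Emerging-entity relevance over patient histories.

    For each patient with at least two snapshots inside the window, only the
    change between the cumulative codes at the window's ends is regarded as
    relevant; the per-patient change projections form the baseline
    collection on which the relevance table is computed.  A term that newly
    appears across many patients' windows (think "COVID-19" in 2020) then
    has a high document frequency in this baseline — that df is the
    emergence signal (ubiquitous emergence drives its tfidf to zero by
    construction, exactly like any other collection-wide term).
    """
    t_from, t_to = window
    projections: list[GraphCode] = []
    for tl in timelines:
        labels = tl.timestamps
        if t_from in labels and t_to in labels:
            lo, hi = labels.index(t_from), labels.index(t_to)
        else:
            in_window = [i for i, ts in enumerate(labels) if t_from <= ts <= t_to]
            if len(in_window) < 2:
                continue
            lo, hi = in_window[0], in_window[-1]
        if hi <= lo:
            continue
        earlier = patient_code_at(tl, labels[lo])
        later = patient_code_at(tl, labels[hi])
        delta = diff(earlier, later, labels=(labels[lo], labels[hi]))
        projections.append(project_diff(delta, asset_id=f"diff:{tl.patient_id}"))
    if not projections:
        raise GraphCodeError("no timeline with two snapshots inside the window")
    coll = GraphCodeCollection(codes=projections, id=f"hist[{t_from}..{t_to}]")
    table = _relevance_table(coll)
    stopped = sorted(t for t, rel in table.items() if rel.tfidf == 0.0)
    return RelevanceReport(
        per_term=table,
        stop_code=_presence_code(stopped, asset_id="SGC_STOP"),
        threshold_fraction=0.0,
        n_codes=len(coll),
    )
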