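"""Set algebra over Graph Codes.

A patient is treated as a multimedia object: every new asset (image,
letter, lab panel) contributes a timed Graph Code snapshot, and the
patient's cumulative code at time t is the union of all snapshots up to t.
Subtraction removes a stop code's terms wholesale (rows and columns), and
diff produces the change-set between two timed codes — the raw material for
"what happened between January and July?" explanations.
"""

from __future__ import annotations

import json
import logging
from dataclasses import dataclass, field

from .graph_code import EMPTY, CellValue, GraphCode, GraphCodeError

__all__ = [
    "TimedPatientCollection",
    "DiffResult",
    "union",
    "union_all",
    "patient_code_at",
    "subtract",
    "diff",
    "apply_diff",
    "project_diff",
]

log = logging.getLogger(__name__)


def union(a: GraphCode, b: GraphCode, newer: str = "b") -> GraphCode:
    """Cell-wise union of two non-query codes.

    The result dictionary is a's order followed by b's unseen terms.  An
    empty cell unites with anything; equal cells are kept; a genuine
    conflict (two different non-empty values) is resolved in favor of the
    code named by ``newer`` ("a" or "b") and logged — a timeline must
    surface the latest measurement while the snapshot store retains history.
    """
    if a.is_query or b.is_query:
        raise GraphCodeError("union is defined over non-query codes")
    if newer not in ("a", "b"):
        raise ValueError("newer must be 'a' or 'b'")
    new_code = b if newer == "b" else a
    dictionary = list(a.dictionary) + [t for t in b.dictionary if t not in a.term_set]
    out = GraphCode(
        dictionary=dictionary,
        asset_id=new_code.asset_id,
        timestamp=new_code.timestamp,
    )
    out.cells.update(a.cells)
    for key, cell in b.cells.items():
        old = out.cells.get(key, EMPTY)
        if old.is_empty or old == cell:
            out.cells[key] = cell
        else:
            winner = cell if newer == "b" else old
            log.warning(
                "union conflict at (%s, %s): %s vs %s -> keeping %s",
                key[0], key[1], old, cell, winner,
            )
            out.cells[key] = winner
    return out


def union_all(codes, newer_last: bool = True) -> GraphCode:
    """Left fold of :func:`union` over an iterable of codes (later = newer)."""
    codes = list(codes)
    if not codes:
        raise GraphCodeError("union of an empty sequence")
    acc = codes[0]
    for gc in codes[1:]:
        acc = union(acc, gc, newer="b" if newer_last else "a")
    return acc


@dataclass
class TimedPatientCollection:
    """Ordered snapshots GC_P(0) ... GC_P(t) of one patient's information.

    Timestamps are strings; the given order is authoritative and must be
    strictly increasing whenever the labels are lexicographically comparable
    (ISO-8601 instants are; month names like "Jan"/"Jul" are looked up by
    label instead).
    """

    patient_id: str
    snapshots: list[tuple[str, GraphCode]] = field(default_factory=list)

    def __post_init__(self) -> None:
        labels = [ts for ts, _ in self.snapshots]
        if len(set(labels)) != len(labels):
            raise GraphCodeError("duplicate snapshot timestamps")
        for _, gc in self.snapshots:
            if gc.is_query:
                raise GraphCodeError("timeline snapshots must be non-query codes")

    def add_snapshot(self, timestamp: str, gc: GraphCode) -> None:
        if gc.is_query:
            raise GraphCodeError("timeline snapshots must be non-query codes")
        if any(ts == timestamp for ts, _ in self.snapshots):
            raise GraphCodeError(f"duplicate snapshot timestamp {timestamp!r}")
        self.snapshots.append((timestamp, gc))

    @property
    def timestamps(self) -> list[str]:
        return [ts for ts, _ in self.snapshots]

    def _cutoff_index(self, t: str) -> int:
        labels = self.timestamps
        if t in labels:
            return labels.index(t)
        # fall back to string comparison (ISO-8601 timestamps sort correctly)
        idx = -1
        for i, ts in enumerate(labels):
            if ts <= t:
                idx = i
        if idx < 0:
            raise GraphCodeError(f"no snapshot at or before {t!r}")
        return idx

    def code_at(self, t: str) -> GraphCode:
        return patient_code_at(self, t)

    # -- JSON document ------------------------------------------------------
    def to_dict(self) -> dict:
        return {
            "patient_id": self.patient_id,
            "snapshots": [
                {"timestamp": ts, "graph_code": gc.to_dict()} for ts, gc in self.snapshots
            ],
        }

    def to_json(self, **kwargs) -> str:
        return json.dumps(self.to_dict(), **kwargs)

    @classmethod
    def from_dict(cls, data: dict) -> "TimedPatientCollection":
        return cls(
            patient_id=data["patient_id"],
            snapshots=[
                (s["timestamp"], GraphCode.from_dict(s["graph_code"]))
                for s in data["snapshots"]
            ],
        )

    @classmethod
    def from_json(cls, text: str) -> "TimedPatientCollection":
        return cls.from_dict(json.loads(text))


def patient_code_at(tl: TimedPatientCollection, t: str) -> GraphCode:
    """Cumulative patient code at time t: the union of all snapshots up to
    and including t, later snapshots winning conflicts."""
    idx = tl._cutoff_index(t)
    return union_all(gc for _, gc in tl.snapshots[: idx + 1])


def subtract(a: GraphCode, stop: GraphCode) -> GraphCode:
    """Remove every term of ``stop`` from ``a``, with all its relationships.

    Dropped terms take their whole matrix row and column with them; the
    surviving cells are untouched, so a d-term code with k stopped terms
    shrinks from d^2 to (d-k)^2 cells.
    """
    banned = stop.term_set
    dictionary = [t for t in a.dictionary if t not in banned]
    out = GraphCode(
        dictionary=dictionary,
        asset_id=a.asset_id,
        timestamp=a.timestamp,
        is_query=a.is_query,
    )
    keep = out.term_set
    for (r, c), v in a.cells.items():
        if r in keep and c in keep:
            out.cells[(r, c)] = v
    return out


@dataclass
class DiffResult:
    """Change-set between two timed codes.

    ``added_terms``/``removed_terms`` are kept in dictionary order for
    determinism; ``changed_cells`` covers cell pairs over terms present at
    both times whose values differ (old and new retained so explanations can
    verbalize the change); ``added_cells`` holds the later code's cells that
    touch an added term, which is what makes the change-set a faithful patch.
    """

    added_terms: list[str]
    removed_terms: list[str]
    changed_cells: list[tuple[str, str, CellValue, CellValue]]
    added_cells: list[tuple[str, str, CellValue]]
    window: tuple[str, str] = ("", "")

    @property
    def is_empty(self) -> bool:
        return not (
            self.added_terms or self.removed_terms or self.changed_cells or self.added_cells
        )

    # -- JSON ---------------------------------------------------------------
    def to_dict(self) -> dict:
        def cell_repr(v: CellValue):
            if v.is_empty:
                return None
            if v.tag == "presence":
                return {"type": 1}
            if v.tag == "rel_type":
                return {"type": v.code}
            if v.tag == "discrete":
                return {"value": v.value}
            return {"range": [v.low, v.high]}

        return {
            "window": list(self.window),
            "added_terms": self.added_terms,
            "removed_terms": self.removed_terms,
            "changed_cells": [
                {"row": r, "col": c, "old": cell_repr(o), "new": cell_repr(n)}
                for r, c, o, n in self.changed_cells
            ],
            "added_cells": [
                {"row": r, "col": c, "cell": cell_repr(v)} for r, c, v in self.added_cells
            ],
        }

    def to_json(self, **kwargs) -> str:
        return json.dumps(self.to_dict(), **kwargs)

    @classmethod
    def from_dict(cls, data: dict) -> "DiffResult":
        def cell_from(payload):
            if payload is None:
                return EMPTY
            if "range" in payload:
                return CellValue.range(*payload["range"])
            if "value" in payload:
                return CellValue.discrete(payload["value"])
            if payload.get("type") == 1:
                return CellValue.presence()
            return CellValue.rel(payload["type"])

        return cls(
            added_terms=list(data["added_terms"]),
            removed_terms=list(data["removed_terms"]),
            changed_cells=[
                (d["row"], d["col"], cell_from(d["old"]), cell_from(d["new"]))
                for d in data["changed_cells"]
            ],
            added_cells=[
                (d["row"], d["col"], cell_from(d["cell"])) for d in data["added_cells"]
            ],
            window=tuple(data.get("window", ("", ""))),
        )

    @classmethod
    def from_json(cls, text: str) -> "DiffResult":
        return cls.from_dict(json.loads(text))


def diff(
    earlier: GraphCode, later: GraphCode, labels: tuple[str, str] = ("", "")
) -> DiffResult:
    """Change-set from ``earlier`` to ``later``.

    Added/removed terms are those present only on one side; changed cells
    range over shared-term pairs with unequal values (including empty to
    non-empty and back).  Applying the result to ``earlier`` with
    :func:`apply_diff` reconstructs ``later`` exactly (up to term order).
    """
    if earlier.is_query or later.is_query:
        raise GraphCodeError("diff is defined over non-query codes")
    e_terms, l_terms = earlier.term_set, later.term_set
    added = [t for t in later.dictionary if t not in e_terms]
    removed = [t for t in earlier.dictionary if t not in l_terms]
    shared = e_terms & l_terms
    changed: list[tuple[str, str, CellValue, CellValue]] = []
    keys = {
        k
        for k in (set(earlier.cells) | set(later.cells))
        if k[0] in shared and k[1] in shared
    }
    l_index = {t: i for i, t in enumerate(later.dictionary)}
    for r, c in sorted(keys, key=lambda k: (l_index[k[0]], l_index[k[1]])):
        old, new = earlier.cell(r, c), later.cell(r, c)
        if old != new:
            changed.append((r, c, old, new))
    added_set = set(added)
    added_cells = [
        (r, c, v)
        for r, c, v in later.nonempty_cells()
        if r in added_set or c in added_set
    ]
    return DiffResult(
        added_terms=added,
        removed_terms=removed,
        changed_cells=changed,
        added_cells=added_cells,
        window=labels,
    )


def apply_diff(earlier: GraphCode, delta: DiffResult) -> GraphCode:
    """Patch ``earlier`` with a change-set; inverse of :func:`diff`."""
    removed = set(delta.removed_terms)
    dictionary = [t for t in earlier.dictionary if t not in removed] + list(
        delta.added_terms
    )
    out = GraphCode(dictionary=dictionary, asset_id=earlier.asset_id)
    for (r, c), v in earlier.cells.items():
        if r not in removed and c not in removed:
            out.cells[(r, c)] = v
    for r, c, old, new in delta.changed_cells:
        out.set_cell(r, c, new)
    for r, c, v in delta.added_cells:
        out.set_cell(r, c, v)
    return out


def project_diff(delta: DiffResult, asset_id: str = "diff") -> GraphCode:
    """Plain-code projection of a change-set, for metric use: the added terms
    and every term touched by a changed or added cell, with the new values."""
    terms: list[str] = []

    def note(t: str) -> None:
        if t not in terms:
            terms.append(t)

    for t in delta.added_terms:
        note(t)
    for r, c, _old, new in delta.changed_cells:
        if not new.is_empty:
            note(r)
            note(c)
    for r, c, _v in delta.added_cells:
        note(r)
        note(c)
    out = GraphCode(dictionary=terms, asset_id=asset_id)
    for t in terms:
        out.set_cell(t, t, CellValue.presence())
    for r, c, _old, new in delta.changed_cells:
        if not new.is_empty and r != c:
            out.set_cell(r, c, new)
        elif not new.is_empty:
            out.set_cell(r, c, new)
    for r, c, v in delta.added_cells:
        if v.tag != "presence" or r == c:
            out.set_cell(r, c, v)
    return out
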