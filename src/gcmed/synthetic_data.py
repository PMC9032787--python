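"""Deterministic generators for test collections and patient timelines.

The collection generator emulates the structure of a photo-shoot-style test
collection: every element shares a common vocabulary (the same model, the
same studio, the same camera metadata appear in each picture's feature
graph) plus a few element-specific terms, with typed relationships sampled
at a configurable density.  Shared terms therefore have document frequency
n_elements and unique terms document frequency 1 — exactly the regime in
which zero-relevance stop-code construction removes all and only the
shared vocabulary.

The timeline generator replays scripted measurement events (timestamp,
term, value) into cumulative patient snapshots, e.g. a blood pressure of
140 in January rising to 155 by July.

All randomness flows from the single integer seed in the spec; the global
random state is never touched, and identical seeds give identical output.
"""

from __future__ import annotations

import json
from dataclasses import dataclass, field

import numpy as np

from .algebra import TimedPatientCollection
from .graph_code import CellValue, GraphCode, GraphCodeError
from .relevance import GraphCodeCollection

__all__ = ["CollectionSpec", "TimelineSpec", "make_collection", "make_timeline"]

#: Relationship-type codes the generator samples from (association,
#: belongs-to, is-a, above).
_SAMPLED_TYPES = (2, 3, 4, 5)


@dataclass(frozen=True)
class CollectionSpec:
    """Shape of a synthetic collection: ``n_elements`` codes, each carrying
    the ``n_shared_terms`` common terms plus ``n_unique_per_element`` of its
    own, with off-diagonal relationships present at ``density``."""

    n_elements: int
    n_shared_terms: int
    n_unique_per_element: int
    density: float = 0.3
    seed: int = 0

    def __post_init__(self) -> None:
        if min(self.n_elements, self.n_shared_terms, self.n_unique_per_element) < 0:
            raise GraphCodeError("counts must be non-negative")
        if not (0 <= self.density <= 1):
            raise GraphCodeError("density must lie in [0, 1]")


def make_collection(spec: CollectionSpec) -> GraphCodeCollection:
    """Generate the collection; reproducible from the seed alone."""
    rng = np.random.default_rng(spec.seed)
    shared = [f"shared_{k:03d}" for k in range(spec.n_shared_terms)]
    codes = []
    for e in range(spec.n_elements):
        unique = [f"u{e:02d}_{k:03d}" for k in range(spec.n_unique_per_element)]
        dictionary = shared + unique
        gc = GraphCode(dictionary=dictionary, asset_id=f"asset-{e:03d}")
        for t in dictionary:
            gc.set_cell(t, t, CellValue.presence())
        n = len(dictionary)
        if n > 1 and spec.density > 0:
            mask = rng.random((n, n)) < spec.density
            types = rng.integers(0, len(_SAMPLED_TYPES), size=(n, n))
            for i in range(n):
                for j in range(n):
                    if i != j and mask[i, j]:
                        gc.set_cell(
                            dictionary[i],
                            dictionary[j],
                            CellValue.rel(_SAMPLED_TYPES[types[i, j]]),
                        )
        codes.append(gc)
    return GraphCodeCollection(codes=codes, id=f"synthetic-{spec.seed}")


@dataclass(frozen=True)
class TimelineSpec:
    """Scripted patient history: ordered measurement events on top of a set
    of baseline terms present from the first snapshot on."""

    patient_id: str
    events: tuple[tuple[str, str, object], ...] = ()
    baseline_terms: tuple[str, ...] = ()

    def __post_init__(self) -> None:
        object.__setattr__(self, "events", tuple(tuple(e) for e in self.events))
        object.__setattr__(self, "baseline_terms", tuple(self.baseline_terms))


def make_timeline(spec: TimelineSpec) -> TimedPatientCollection:
    """Replay the events into cumulative snapshots, one per distinct
    timestamp (in the order given, which must be grouped and ordered).

    Each snapshot carries the patient root term, the baseline terms, and
    every measurement up to that time — later values of the same term
    overriding earlier ones — stored as discrete payloads on the edge
    term -> patient root.
    """
    order: list[str] = []
    for ts, _term, _value in spec.events:
        if ts not in order:
            order.append(ts)
        elif ts != order[-1]:
            raise GraphCodeError(f"events for timestamp {ts!r} are not contiguous")
    root = spec.patient_id
    tl = TimedPatientCollection(patient_id=spec.patient_id)

    def snapshot(upto: int, ts: str | None) -> GraphCode:
        state: dict[str, object] = {}
        for t, term, value in spec.events[:upto]:
            state[term] = value
        dictionary = [root] + [t for t in spec.baseline_terms if t != root]
        for term in state:
            if term not in dictionary:
                dictionary.append(term)
        gc = GraphCode(
            dictionary=dictionary, asset_id=f"{spec.patient_id}@{ts}", timestamp=ts
        )
        for t in dictionary:
            gc.set_cell(t, t, CellValue.presence())
        for term, value in state.items():
            gc.set_cell(term, root, CellValue.discrete(value))
        return gc

    if not order:
        tl.add_snapshot("0", snapshot(0, "0"))
        return tl
    upto = 0
    for ts in order:
        while upto < len(spec.events) and spec.events[upto][0] == ts:
            upto += 1
        tl.add_snapshot(ts, snapshot(upto, ts))
    return tl
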