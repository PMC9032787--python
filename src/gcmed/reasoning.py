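"""Knowledge validity and minimal rule inference over a collection.

Following a Poole-style default theory T = (F, D), typed relationships
observed in a collection are split into justified facts F and hypotheses D
by their knowledge validity: the support ratio

    kv(i, j, type) = s / p

where p is the number of collection codes containing both terms and s the
number of those whose (i, j) cell carries exactly that type code.  A
relationship unanimously present among co-occurring codes (kv = 1) is
common knowledge; a threshold (say 0.9) promotes near-unanimous ones.  A
small forward chainer over binary Horn rules (e.g. transitivity of a
spatial type) then grows F to its finite fixpoint, recording provenance
per derived fact.
"""

from __future__ import annotations

import json
import math
from dataclasses import dataclass, field

from .graph_code import GraphCodeError
from .relevance import GraphCodeCollection

__all__ = [
    "Fact",
    "InferenceRule",
    "TheoryState",
    "kv",
    "extend_facts",
    "infer",
    "load_rules",
]

#: A typed relationship: (row term, column term, relationship-type code).
Fact = tuple[str, str, int]


@dataclass(frozen=True)
class InferenceRule:
    """Binary Horn rule chaining two typed relationships through a shared
    middle term: (a, b, t1) and (b, c, t2) entail (a, c, t3)."""

    name: str
    premise_types: tuple[int, int]
    conclusion_type: int

    @classmethod
    def transitive(cls, type_code: int, name: str | None = None) -> "InferenceRule":
        return cls(
            name=name or f"transitive({type_code})",
            premise_types=(type_code, type_code),
            conclusion_type=type_code,
        )


@dataclass
class TheoryState:
    """Facts with provenance plus scored hypotheses; F and D stay disjoint."""

    facts: dict[Fact, str] = field(default_factory=dict)
    hypotheses: dict[Fact, float] = field(default_factory=dict)
    threshold: float = 0.9

    def __post_init__(self) -> None:
        overlap = set(self.facts) & set(self.hypotheses)
        if overlap:
            raise GraphCodeError(f"facts and hypotheses overlap: {sorted(overlap)!r}")

    def promote(self, fact: Fact, provenance: str) -> None:
        self.hypotheses.pop(fact, None)
        self.facts[fact] = provenance

    def to_dict(self) -> dict:
        return {
            "threshold": self.threshold,
            "facts": [
                {"subject": i, "object": j, "type": t, "provenance": prov}
                for (i, j, t), prov in sorted(self.facts.items())
            ],
            "hypotheses": [
                {"subject": i, "object": j, "type": t, "kv": score}
                for (i, j, t), score in sorted(self.hypotheses.items())
            ],
        }

    def to_json(self, **kwargs) -> str:
        return json.dumps(self.to_dict(), **kwargs)


def kv(
    coll: GraphCodeCollection,
    term_i: str,
    term_j: str,
    type_code: int,
    log_scale: bool = False,
) -> float:
    """Knowledge validity of a typed relationship within a collection.

    The plain support ratio s/p in [0, 1] by default; ``log_scale`` returns
    ln(s/p) instead (in (-inf, 0]), for callers who prefer the logarithmic
    form — thresholds must then be transformed the same way.
    """
    p = 0
    s = 0
    for gc in coll:
        if term_i in gc.term_set and term_j in gc.term_set:
            p += 1
            cell = gc.cell(term_i, term_j)
            if cell.tag == "rel_type" and cell.code == type_code:
                s += 1
    if p == 0:
        raise GraphCodeError(
            f"no collection code contains both {term_i!r} and {term_j!r}"
        )
    ratio = s / p
    if log_scale:
        return math.log(ratio) if ratio > 0 else -math.inf
    return ratio


def extend_facts(coll: GraphCodeCollection, threshold: float = 0.9) -> TheoryState:
    """Split every observed typed relationship into facts and hypotheses.

    Candidates are the (i, j, type) triples carried by at least one code;
    those with kv >= threshold join F (provenance records the support),
    the rest stay in D with their scores.  Lowering the threshold can only
    grow F (monotone)."""
    if not (0 < threshold <= 1):
        raise GraphCodeError("threshold must lie in (0, 1]")
    candidates: set[Fact] = set()
    for gc in coll:
        for r, c, v in gc.nonempty_cells():
            if v.tag == "rel_type":
                candidates.add((r, c, v.code))
    state = TheoryState(threshold=threshold)
    for fact in sorted(candidates):
        score = kv(coll, *fact)
        if score >= threshold:
            state.facts[fact] = f"observed: kv={score:.6g}"
        else:
            state.hypotheses[fact] = score
    return state


def infer(state: TheoryState, rules: list[InferenceRule]) -> TheoryState:
    """Forward chain the rules over F to its fixpoint.

    Each firing promotes the conclusion into F (moving it out of D if it was
    hypothesized there) with the rule name and premises as provenance.  The
    fact universe over known terms and type codes is finite, so iteration
    terminates; once at the fixpoint, re-running is a no-op.
    """
    out = TheoryState(
        facts=dict(state.facts),
        hypotheses=dict(state.hypotheses),
        threshold=state.threshold,
    )
    changed = True
    while changed:
        changed = False
        facts = sorted(out.facts)
        by_subject: dict[tuple[str, int], list[Fact]] = {}
        for f in facts:
            by_subject.setdefault((f[0], f[2]), []).append(f)
        for rule in rules:
            t1, t2 = rule.premise_types
            for a, b, t in facts:
                if t != t1:
                    continue
                for b2, c, _t in by_subject.get((b, t2), []):
                    conclusion: Fact = (a, c, rule.conclusion_type)
                    if a == c or conclusion in out.facts:
                        continue
                    out.promote(
                        conclusion,
                        f"{rule.name}: ({a}, {b}, {t1}) + ({b}, {c}, {t2})",
                    )
                    changed = True
    return out


def load_rules(source) -> list[InferenceRule]:
    """Load rules from a JSON list: [{"name", "type", "transitive": true} or
    {"name", "premise_types": [t1, t2], "conclusion_type": t3}, ...]."""
    if hasattr(source, "read"):
        data = json.load(source)
    elif isinstance(source, (list, tuple)):
        data = source
    else:
        with open(str(source), "r", encoding="utf-8") as fh:
            data = json.load(fh)
    rules = []
    for entry in data:
        if entry.get("transitive"):
            rules.append(InferenceRule.transitive(entry["type"], name=entry.get("name")))
        else:
            rules.append(
                InferenceRule(
                    name=entry["name"],
                    premise_types=tuple(entry["premise_types"]),
                    conclusion_type=entry["conclusion_type"],
                )
            )
    return rules
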