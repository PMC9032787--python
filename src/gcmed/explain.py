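"""Natural-language explanation of Graph Codes via a phrase-structure grammar.

Retrieval steps become explainable by verbalizing an Explaining Semantic
Graph Code (ESGC): the subtraction of two codes carrying only the
distinguishing content.  Each non-empty off-diagonal cell expands through
the Graph-Code production

    m_ij != 0  ->  LBL  PHR_type  LBL

where an audience profile maps terms to display labels (LBL) and cell
contents to connective phrases (PHR).  Timeline change-sets are verbalized
through a change-sentence template ("between {from} and {to}, the {label}
{direction} from {old} to {new}").  Clauses whose tokens all belong to the
English lexicon additionally receive the full PS-tree derivation

    S -> NP VP,  VP -> V PP,  NP -> DET N,  PP -> PR NP

so every rendered clause can be parsed back against the declared
productions.  Profiles are data (JSON), not code: new audiences need no
release.
"""

from __future__ import annotations

import json
import logging
from dataclasses import dataclass, field
from numbers import Real
from typing import Union

from .algebra import DiffResult
from .graph_code import CellValue, GraphCode, GraphCodeError

__all__ = [
    "AudienceProfile",
    "ExplanationPlan",
    "Clause",
    "DerivationTree",
    "MEDICAL_PROFILE",
    "PATIENT_PROFILE",
    "GENERIC_PROFILE",
    "ENGLISH_LEXICON",
    "ENGLISH_PRODUCTIONS",
    "explaining_code",
    "plan_clauses",
    "render",
    "derivation",
]

log = logging.getLogger(__name__)


@dataclass
class AudienceProfile:
    """Audience-specific surface vocabulary.

    ``labels`` maps dictionary terms to display text (missing terms fall
    back to the raw label, with a warning); ``phrases`` maps relationship
    type codes (as strings) and the key "D" (discrete values) to connective
    phrases.  Swapping profiles changes only surface text, never which cells
    get explained.
    """

    name: str
    labels: dict[str, str] = field(default_factory=dict)
    phrases: dict[str, str] = field(default_factory=dict)
    change_template: str = (
        "between {from} and {to}, the {label} {direction} from {old} to {new}"
    )
    added_template: str = "between {from} and {to}, {label} was newly recorded"
    removed_template: str = "between {from} and {to}, {label} was no longer recorded"
    no_change_sentence: str = "there is no difference"
    directions: dict[str, str] = field(
        default_factory=lambda: {
            "up": "increased",
            "down": "decreased",
            "other": "changed",
        }
    )
    fallback_phrase: str = "relates to"

    def label(self, term: str) -> str:
        if term in self.labels:
            return self.labels[term]
        log.warning("profile %r has no label for %r, using the raw term", self.name, term)
        return term

    def phrase(self, cell: CellValue) -> str:
        key = "D" if cell.tag == "discrete" else str(cell.code)
        if key in self.phrases:
            return self.phrases[key]
        log.warning("profile %r has no phrase for %r, using the fallback", self.name, key)
        return self.fallback_phrase

    def to_dict(self) -> dict:
        return {
            "name": self.name,
            "labels": self.labels,
            "phrases": self.phrases,
            "change_template": self.change_template,
            "added_template": self.added_template,
            "removed_template": self.removed_template,
            "no_change_sentence": self.no_change_sentence,
            "directions": self.directions,
            "fallback_phrase": self.fallback_phrase,
        }

    def to_json(self, **kwargs) -> str:
        return json.dumps(self.to_dict(), **kwargs)

    @classmethod
    def from_dict(cls, data: dict) -> "AudienceProfile":
        kwargs = {k: v for k, v in data.items() if k in cls.__dataclass_fields__}
        return cls(**kwargs)

    @classmethod
    def from_json(cls, source) -> "AudienceProfile":
        if hasattr(source, "read"):
            return cls.from_dict(json.load(source))
        text = str(source)
        if text.lstrip().startswith("{"):
            return cls.from_dict(json.loads(text))
        with open(text, "r", encoding="utf-8") as fh:
            return cls.from_dict(json.load(fh))


#: Profile for doctors and nurses: terse clinical phrasing.
MEDICAL_PROFILE = AudienceProfile(
    name="medical",
    labels={
        "blood-pressure": "blood pressure",
        "BMI": "BMI",
    },
    phrases={"2": "is associated with", "3": "has a value of", "4": "is a",
             "5": "is above", "D": "has a value of"},
)

#: Profile for patients: didactic labels and second-person phrasing.
PATIENT_PROFILE = AudienceProfile(
    name="patient",
    labels={
        "blood-pressure": "blood pressure",
        "BMI": (
            "BMI is the body mass index and indicates if a person's weight is "
            "normal, too low, or too high. A BMI value of 20 is normal"
        ),
    },
    phrases={"2": "is associated with", "3": "Your value is", "4": "is a",
             "5": "is above", "D": "Your value is"},
    change_template=(
        "between {from} and {to}, your {label} {direction} from {old} to {new}"
    ),
)

#: Neutral profile using "the <term>" labels and field-standard phrases.
GENERIC_PROFILE = AudienceProfile(
    name="generic",
    phrases={"2": "is associated with", "3": "belongs to", "4": "is a",
             "5": "is above", "D": "has a value of"},
)

_BUILTIN = {p.name: p for p in (MEDICAL_PROFILE, PATIENT_PROFILE, GENERIC_PROFILE)}


def get_profile(name_or_path: str) -> AudienceProfile:
    if name_or_path in _BUILTIN:
        return _BUILTIN[name_or_path]
    return AudienceProfile.from_json(name_or_path)


def explaining_code(a: GraphCode, b: GraphCode) -> GraphCode:
    """ESGC = a - b: the code carrying only what distinguishes a from b
    (result element minus query, or result element minus result element)."""
    from .algebra import subtract

    return subtract(a, b)


@dataclass(frozen=True)
class Clause:
    """One verbalized cell, kept segmented for derivation:
    (symbol, text) parts such as (("LBL", "the hat"), ("PHR", "is above"),
    ("LBL", "the head"))."""

    parts: tuple[tuple[str, str], ...]

    @property
    def text(self) -> str:
        return " ".join(text for _sym, text in self.parts)


def _format_value(value) -> str:
    if isinstance(value, float) and value.is_integer():
        return str(int(value))
    return str(value)


def plan_clauses(esgc: GraphCode, profile: AudienceProfile) -> list[Clause]:
    """One clause per non-empty off-diagonal cell, in dictionary order."""
    clauses = []
    for r, c, v in esgc.off_diagonal_cells():
        if v.tag == "discrete":
            obj = _format_value(v.value)
        else:
            obj = profile.label(c)
        clauses.append(
            Clause(
                parts=(
                    ("LBL", profile.label(r)),
                    ("PHR", profile.phrase(v)),
                    ("LBL", obj),
                )
            )
        )
    return clauses


def _direction(old: CellValue, new: CellValue, profile: AudienceProfile) -> str:
    if (
        old.tag == "discrete"
        and new.tag == "discrete"
        and isinstance(old.value, Real)
        and isinstance(new.value, Real)
    ):
        if new.value > old.value:
            return profile.directions["up"]
        if new.value < old.value:
            return profile.directions["down"]
    return profile.directions["other"]


def diff_sentences(delta: DiffResult, profile: AudienceProfile) -> list[str]:
    """Verbalize a timeline change-set, one sentence per change, dictionary
    order preserved from the diff."""
    t_from, t_to = delta.window
    sentences = []
    for r, _c, old, new in delta.changed_cells:
        if old.tag == "discrete" and new.tag == "discrete":
            sentences.append(
                profile.change_template.format(
                    **{
                        "from": t_from,
                        "to": t_to,
                        "label": profile.label(r),
                        "direction": _direction(old, new, profile),
                        "old": _format_value(old.value),
                        "new": _format_value(new.value),
                    }
                )
            )
        elif old.is_empty and new.tag == "discrete":
            sentences.append(
                profile.added_template.format(
                    **{"from": t_from, "to": t_to, "label": profile.label(r)}
                )
            )
    for term in delta.added_terms:
        sentences.append(
            profile.added_template.format(
                **{"from": t_from, "to": t_to, "label": profile.label(term)}
            )
        )
    for term in delta.removed_terms:
        sentences.append(
            profile.removed_template.format(
                **{"from": t_from, "to": t_to, "label": profile.label(term)}
            )
        )
    return sentences


@dataclass
class ExplanationPlan:
    """What to verbalize: an ESGC (result membership or comparison) or a
    DiffResult (timeline), plus the audience profile."""

    source: Union[GraphCode, DiffResult]
    mode: str
    audience: AudienceProfile

    MODES = ("result_membership", "result_comparison", "timeline_diff")

    def __post_init__(self) -> None:
        if self.mode not in self.MODES:
            raise GraphCodeError(f"unknown explanation mode {self.mode!r}")
        if self.mode == "timeline_diff" and not isinstance(self.source, DiffResult):
            raise GraphCodeError("timeline_diff explains a DiffResult")
        if self.mode != "timeline_diff" and not isinstance(self.source, GraphCode):
            raise GraphCodeError(f"{self.mode} explains a Graph Code")


def render(plan: ExplanationPlan) -> str:
    """Render the plan to text: one terminated sentence per clause/change,
    newline-joined, deterministic for a fixed plan and profile."""
    profile = plan.audience
    if plan.mode == "timeline_diff":
        sentences = diff_sentences(plan.source, profile)
    else:
        sentences = [cl.text for cl in plan_clauses(plan.source, profile)]
    if not sentences:
        sentences = [profile.no_change_sentence]
    return "\n".join(s + "." for s in sentences)


# -- phrase-structure derivations ------------------------------------------------

#: The productions of the small English grammar (left side -> right sides).
ENGLISH_PRODUCTIONS: dict[str, tuple[str, ...]] = {
    "S": ("NP", "VP"),
    "NP": ("DET", "N"),
    "VP": ("V", "PP"),
    "PP": ("PR", "NP"),
}

#: Word categories of the grammar's terminal symbols.
ENGLISH_LEXICON: dict[str, set[str]] = {
    "DET": {"the"},
    "N": {"hat", "head", "person"},
    "V": {"is"},
    "PR": {"above"},
}

#: The Graph-Code production: a non-empty cell expands to LBL PHR LBL.
GC_CELL_PRODUCTION = ("LBL", "PHR", "LBL")


@dataclass(frozen=True)
class DerivationTree:
    """PS-tree node: an internal node records one production expansion; a
    leaf carries terminal text.  Concatenating the leaves left to right
    reproduces the derived sentence."""

    symbol: str
    children: tuple["DerivationTree", ...] = ()
    text: str | None = None

    def leaves(self) -> list[str]:
        if not self.children:
            return [self.text] if self.text is not None else []
        out = []
        for child in self.children:
            out.extend(child.leaves())
        return out

    @property
    def sentence(self) -> str:
        return " ".join(self.leaves())


class DerivationError(GraphCodeError):
    pass


def _parse_symbol(symbol: str, tokens: list[str], pos: int, lexicon) -> tuple[DerivationTree, int]:
    if symbol in ENGLISH_PRODUCTIONS:
        children = []
        for child_sym in ENGLISH_PRODUCTIONS[symbol]:
            node, pos = _parse_symbol(child_sym, tokens, pos, lexicon)
            children.append(node)
        return DerivationTree(symbol=symbol, children=tuple(children)), pos
    # pre-terminal: consume one token
    if pos >= len(tokens):
        raise DerivationError(f"sentence ends where {symbol} was expected")
    token = tokens[pos]
    if token not in lexicon.get(symbol, ()):
        raise DerivationError(f"token {token!r} does not fit symbol {symbol}")
    return DerivationTree(symbol=symbol, children=(DerivationTree(symbol=token, text=token),)), pos + 1


def parse_english(sentence: str, lexicon: dict[str, set[str]] | None = None) -> DerivationTree:
    """Parse a sentence with the fixed productions S -> NP VP, NP -> DET N,
    VP -> V PP, PP -> PR NP; errors name the first unmatched symbol/token."""
    tokens = sentence.replace(".", " ").split()
    tree, pos = _parse_symbol("S", tokens, 0, lexicon or ENGLISH_LEXICON)
    if pos != len(tokens):
        raise DerivationError(f"trailing tokens after a complete sentence: {tokens[pos:]!r}")
    return tree


def derivation(
    clause: Union[Clause, str], lexicon: dict[str, set[str]] | None = None
) -> DerivationTree:
    """Derivation tree of one clause under the combined productions.

    If every token fits the English lexicon the full PS-tree (S -> NP VP ...)
    is returned; otherwise a structured clause derives through the Graph-Code
    production m_ij != 0 -> LBL PHR LBL, and a single labeled answer derives
    as dict_answer -> LBL.  A bare string that fits neither is an error
    naming the first unmatched symbol.
    """
    lex = lexicon or ENGLISH_LEXICON
    text = clause.text if isinstance(clause, Clause) else str(clause)
    try:
        return parse_english(text, lex)
    except DerivationError:
        if not isinstance(clause, Clause):
            raise
    if len(clause.parts) == 1:
        sym, txt = clause.parts[0]
        return DerivationTree(
            symbol="dict_answer",
            children=(DerivationTree(symbol=sym, children=(DerivationTree(symbol=txt, text=txt),)),),
        )
    if tuple(sym for sym, _ in clause.parts) != GC_CELL_PRODUCTION:
        raise DerivationError(
            f"clause parts {tuple(s for s, _ in clause.parts)!r} match no production"
        )
    children = tuple(
        DerivationTree(symbol=sym, children=(DerivationTree(symbol=txt, text=txt),))
        for sym, txt in clause.parts
    )
    return DerivationTree(symbol="m_ij", children=children)
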