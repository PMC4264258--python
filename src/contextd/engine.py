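"""Core context-assignment pass.

Given a sentence with marked concept mentions, assign the default property
triple (NotNegated / Recent / Patient), scan the trigger lexicon left to
right, resolve each trigger's scope against the document-type profile and any
termination triggers, and update the properties of every mention falling
inside a scope. Document-specific refinements (the GP minus rule, combined
pre+post rules) run after the generic pass; the regex temporality module runs
last and may upgrade Recent to Historical.
"""

from __future__ import annotations

from dataclasses import dataclass, field, replace
from enum import Enum
from typing import Iterable, Sequence

from .lexicon import (
    CombinedTriggerRule,
    ContextProperty,
    TriggerEntry,
    TriggerLexicon,
    TriggerRole,
)
from .temporality import TemporalPattern, detect_historical
from .textprep import ConceptMention, Sentence, find_phrase_occurrences, is_punct_token


class Negation(str, Enum):
    NEGATED = "Negated"
    NOT_NEGATED = "NotNegated"


class Temporality(str, Enum):
    RECENT = "Recent"
    HISTORICAL = "Historical"
    HYPOTHETICAL = "Hypothetical"


class Experiencer(str, Enum):
    PATIENT = "Patient"
    OTHER = "Other"


#: non-default value asserted by a trigger of each property
_PROPERTY_VALUE = {
    ContextProperty.NEGATION: Negation.NEGATED.value,
    ContextProperty.HISTORICAL: Temporality.HISTORICAL.value,
    ContextProperty.HYPOTHETICAL: Temporality.HYPOTHETICAL.value,
    ContextProperty.EXPERIENCER: Experiencer.OTHER.value,
}

GP_MINUS_RULE = "gp-minus"


class EngineError(ValueError):
    pass


@dataclass(frozen=True)
class DocumentProfile:
    """Per-document-type scope parameters and rule switches.

    ``default_scope_tokens=None`` means the scope runs to the sentence
    boundary (radiology and discharge letters); GP entries cap at 6 words and
    specialist letters at 10, with document-specific punctuation terminators.
    """

    doc_type: str
    default_scope_tokens: int | None
    punctuation_terminators: frozenset[str]
    gp_minus_rule_active: bool
    combined_rules_active: bool = True

    def __post_init__(self) -> None:
        if self.default_scope_tokens is not None and self.default_scope_tokens < 1:
            raise EngineError("default_scope_tokens must be >= 1 or None")
        if self.gp_minus_rule_active and self.doc_type != "GP":
            raise EngineError("minus rule is a GP-only enhancement")

    @classmethod
    def for_doc_type(cls, doc_type: str) -> "DocumentProfile":
        try:
            scope, terms, minus = _PROFILE_PARAMS[doc_type]
        except KeyError:
            raise EngineError(f"unknown doc_type '{doc_type}'") from None
        return cls(doc_type, scope, frozenset(terms), minus)


_PROFILE_PARAMS: dict[str, tuple[int | None, set[str], bool]] = {
    "GP": (6, {",", ";"}, True),
    "SP": (10, {":", ";"}, False),
    "RD": (None, set(), False),
    "DL": (None, set(), False),
}


@dataclass(frozen=True)
class TriggerOccurrence:
    entry: TriggerEntry
    token_start: int
    token_end: int
    char_start: int
    char_end: int

    def overlaps_tokens(self, start: int, end: int) -> bool:
        return self.token_start < end and start < self.token_end


@dataclass(frozen=True)
class Evidence:
    property: str
    phrase_or_rule: str
    char_start: int
    char_end: int


@dataclass
class ContextAnnotation:
    """The property triple assigned to one mention, with its evidence."""

    mention: ConceptMention
    negation: str = Negation.NOT_NEGATED.value
    temporality: str = Temporality.RECENT.value
    experiencer: str = Experiencer.PATIENT.value
    evidence: list[Evidence] = field(default_factory=list)

    def _set(self, prop: ContextProperty, value: str, evidence: list[Evidence]) -> None:
        slot = "negation" if prop is ContextProperty.NEGATION else (
            "experiencer" if prop is ContextProperty.EXPERIENCER else "temporality"
        )
        setattr(self, slot, value)
        # later triggers overwrite: drop superseded evidence for this slot
        affected = {
            "negation": {ContextProperty.NEGATION.value},
            "temporality": {ContextProperty.HISTORICAL.value, ContextProperty.HYPOTHETICAL.value},
            "experiencer": {ContextProperty.EXPERIENCER.value},
        }[slot]
        self.evidence = [e for e in self.evidence if e.property not in affected]
        self.evidence.extend(evidence)


def find_triggers(
    sentence: Sentence, lex: TriggerLexicon, doc_type: str
) -> list[TriggerOccurrence]:
    """Locate all trigger occurrences, longest-match, pseudo-masked, in order.

    Within each (property, role) pair, occurrences strictly contained in a
    longer occurrence are dropped; a pseudo occurrence then masks every
    non-pseudo occurrence lying fully inside its span.
    """
    entries = lex.entries_for(doc_type)
    by_phrase: dict[str, list[TriggerEntry]] = {}
    for e in entries:
        by_phrase.setdefault(e.phrase, []).append(e)
    occs: list[TriggerOccurrence] = []
    for po in find_phrase_occurrences(sentence, by_phrase.keys()):
        for entry in by_phrase[po.phrase]:
            occs.append(
                TriggerOccurrence(entry, po.token_start, po.token_end, po.char_start, po.char_end)
            )

    def contained(a: TriggerOccurrence, b: TriggerOccurrence) -> bool:
        return (
            b.char_start <= a.char_start
            and a.char_end <= b.char_end
            and (a.char_end - a.char_start) < (b.char_end - b.char_start)
        )

    survivors = [
        a
        for a in occs
        if not any(
            contained(a, b)
            and a.entry.property is b.entry.property
            and a.entry.role is b.entry.role
            for b in occs
        )
    ]
    pseudos = [o for o in survivors if o.entry.role is TriggerRole.PSEUDO]
    masked = [
        o
        for o in survivors
        if o.entry.role is TriggerRole.PSEUDO
        or not any(
            p.char_start <= o.char_start and o.char_end <= p.char_end for p in pseudos
        )
    ]
    masked.sort(key=lambda o: (o.token_start, -o.token_end, o.entry.role.value))
    return masked


def resolve_scope(
    occ: TriggerOccurrence,
    sentence: Sentence,
    profile: DocumentProfile,
    terminators: Sequence[TriggerOccurrence] = (),
) -> tuple[int, int]:
    """Token interval a pre/post trigger governs.

    Pre triggers extend rightwards from the trigger's end, post triggers
    leftwards from its start, up to the profile's word cap (punctuation tokens
    are not counted as words) or the sentence boundary, and truncated before
    any termination trigger of the same property or any profile punctuation
    terminator.
    """
    role = occ.entry.role
    if role not in (TriggerRole.PRE, TriggerRole.POST):
        raise EngineError(f"no scope for role {role.value}")
    cap = occ.entry.max_scope_tokens
    if cap is None:
        cap = profile.default_scope_tokens
    relevant = [
        t
        for t in terminators
        if t.entry.role is TriggerRole.TERMINATION and t.entry.property is occ.entry.property
    ]
    term_starts = {t.token_start for t in relevant}
    term_ends = {t.token_end for t in relevant}
    tokens = sentence.tokens

    if role is TriggerRole.PRE:
        start = occ.token_end
        i = start
        words = 0
        while i < len(tokens):
            if i in term_starts:
                break
            surf = tokens[i].surface
            if surf in profile.punctuation_terminators:
                break
            if not is_punct_token(surf):
                if cap is not None and words == cap:
                    break
                words += 1
            i += 1
        return (start, i)

    end = occ.token_start
    i = end - 1
    words = 0
    while i >= 0:
        if (i + 1) in term_ends:
            break
        surf = tokens[i].surface
        if surf in profile.punctuation_terminators:
            break
        if not is_punct_token(surf):
            if cap is not None and words == cap:
                break
            words += 1
        i -= 1
    return (i + 1, end)


def _check_mentions(sentence: Sentence, mentions: Sequence[ConceptMention]) -> None:
    for m in mentions:
        if not (0 <= m.char_start < m.char_end <= len(sentence.text)):
            raise EngineError(
                f"mention '{m.term}' [{m.char_start},{m.char_end}) outside sentence bounds"
            )
        if not (0 <= m.token_start < m.token_end <= len(sentence.tokens)):
            raise EngineError(f"mention '{m.term}' token interval out of bounds")


def apply_gp_minus_rule(
    sentence: Sentence,
    mentions: Sequence[ConceptMention],
    annotations: Sequence[ContextAnnotation],
    profile: DocumentProfile,
) -> None:
    """Negate mentions written as ``term-`` (minus shorthand in GP entries).

    The minus sign must directly follow the mention or be separated by at
    most one space, and must itself be followed by whitespace, punctuation or
    the sentence end — ``koorts-achtig`` is untouched.
    """
    if not profile.gp_minus_rule_active:
        return
    text = sentence.text
    for mention, ann in zip(mentions, annotations):
        pos = mention.char_end
        if pos < len(text) and text[pos] == " ":
            pos += 1
        if pos >= len(text) or text[pos] != "-":
            continue
        after = text[pos + 1 : pos + 2]
        if after and after.isalnum():  # hyphen joins a following word: koorts-achtig
            continue
        ann._set(
            ContextProperty.NEGATION,
            Negation.NEGATED.value,
            [Evidence(ContextProperty.NEGATION.value, GP_MINUS_RULE, pos, pos + 1)],
        )


def apply_combined_rules(
    sentence: Sentence,
    mentions: Sequence[ConceptMention],
    annotations: Sequence[ContextAnnotation],
    rules: Sequence[CombinedTriggerRule],
    profile: DocumentProfile,
) -> None:
    """Fire pre+post combination rules (e.g. "nooit ... doorgemaakt")."""
    if not profile.combined_rules_active or not rules:
        return
    for rule in rules:
        if not rule.applies_to(profile.doc_type):
            continue
        pre_occs = find_phrase_occurrences(sentence, [rule.pre_phrase])
        post_occs = find_phrase_occurrences(sentence, [rule.post_phrase])
        if not pre_occs or not post_occs:
            continue
        for mention, ann in zip(mentions, annotations):
            hits = [
                (pre, post)
                for pre in pre_occs
                for post in post_occs
                if pre.token_end <= mention.token_start
                and post.token_start >= mention.token_end
                and (post.token_end - pre.token_start) <= rule.max_span_tokens
            ]
            if not hits:
                continue
            pre, post = hits[0]
            ann._set(
                rule.property,
                rule.value,
                [
                    Evidence(rule.property.value, rule.name, pre.char_start, pre.char_end),
                    Evidence(rule.property.value, rule.name, post.char_start, post.char_end),
                ],
            )


def apply_context(
    sentence: Sentence,
    mentions: Sequence[ConceptMention],
    lex: TriggerLexicon,
    rules: Sequence[CombinedTriggerRule] = (),
    profile: DocumentProfile | None = None,
    temporal_patterns: Sequence[TemporalPattern] = (),
    reference_year: int | None = None,
) -> list[ContextAnnotation]:
    """Assign the full contextual-property triple to each mention.

    Processing order: defaults → lexicon triggers left to right (pseudo
    skipped, later triggers of the same property overwrite earlier ones) →
    GP minus rule → combined rules → temporality regex module. A mention is
    never affected by a trigger occurrence it overlaps.
    """
    if profile is None:
        profile = DocumentProfile.for_doc_type("GP")
    _check_mentions(sentence, mentions)
    annotations = [ContextAnnotation(mention=m) for m in mentions]

    occurrences = find_triggers(sentence, lex, profile.doc_type)
    terminators = [o for o in occurrences if o.entry.role is TriggerRole.TERMINATION]
    for occ in occurrences:
        if occ.entry.role in (TriggerRole.PSEUDO, TriggerRole.TERMINATION):
            continue
        scope_start, scope_end = resolve_scope(occ, sentence, profile, terminators)
        for mention, ann in zip(mentions, annotations):
            if occ.overlaps_tokens(mention.token_start, mention.token_end):
                continue
            if mention.token_start < scope_end and scope_start < mention.token_end:
                ann._set(
                    occ.entry.property,
                    _PROPERTY_VALUE[occ.entry.property],
                    [
                        Evidence(
                            occ.entry.property.value,
                            occ.entry.phrase,
                            occ.char_start,
                            occ.char_end,
                        )
                    ],
                )

    apply_gp_minus_rule(sentence, mentions, annotations, profile)
    apply_combined_rules(sentence, mentions, annotations, rules, profile)

    if temporal_patterns:
        for mention, ann in zip(mentions, annotations):
            if ann.temporality != Temporality.RECENT.value:
                continue  # lexicon evidence outranks the regex module
            matches = detect_historical(
                sentence, mention, temporal_patterns, reference_year=reference_year
            )
            if matches:
                ann._set(
                    ContextProperty.HISTORICAL,
                    Temporality.HISTORICAL.value,
                    [
                        Evidence(
                            ContextProperty.HISTORICAL.value,
                            f"temporal:{m.pattern_id}",
                            m.char_start,
                            m.char_end,
                        )
                        for m in matches
                    ],
                )
    return annotations
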