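"""Trigger lexicon: the rule base driving contextual-property assignment.

A lexicon is a flat collection of trigger phrases, each tagged with the
contextual property it modifies (negation, historical, hypothetical,
experiencer) and the role it plays:

* ``pre`` — precedes the concept, scope extends rightwards;
* ``post`` — follows the concept, scope extends leftwards;
* ``pseudo`` — looks like a trigger but must not fire, and masks real
  triggers contained in it (e.g. "niet minder" masking "niet");
* ``termination`` — cuts the scope of a pre/post trigger short.

Lexicons are stored as UTF-8 TSV files with the header
``phrase  property  role  doc_types  max_scope_tokens  note``; a second TSV
schema (:func:`load_combined_rules`) holds pre+post combination rules that
fire only when both phrases surround a concept.
"""

from __future__ import annotations

import csv
import logging
from dataclasses import dataclass, field, replace
from enum import Enum
from pathlib import Path
from typing import Iterable, Iterator, Sequence

log = logging.getLogger(__name__)

DOC_TYPES: tuple[str, ...] = ("GP", "SP", "RD", "DL")

LEXICON_COLUMNS = ("phrase", "property", "role", "doc_types", "max_scope_tokens", "note")
COMBINED_COLUMNS = ("pre_phrase", "post_phrase", "property", "value", "max_span_tokens", "doc_types")

#: characters permitted in a phrase without drawing a validation diagnostic
_PHRASE_CHARS = set("abcdefghijklmnopqrstuvwxyz0123456789 -.")


class LexiconError(ValueError):
    """Raised for malformed lexicon files or invalid entries."""


class ContextProperty(str, Enum):
    NEGATION = "negation"
    HISTORICAL = "historical"
    HYPOTHETICAL = "hypothetical"
    EXPERIENCER = "experiencer"


class TriggerRole(str, Enum):
    PRE = "pre"
    POST = "post"
    PSEUDO = "pseudo"
    TERMINATION = "termination"


def _parse_doc_types(raw: str, lineno: int) -> frozenset[str]:
    raw = raw.strip()
    if raw in ("", "*"):
        return frozenset()
    out = set()
    for part in raw.split(","):
        part = part.strip().upper()
        if part not in DOC_TYPES:
            raise LexiconError(f"unknown doc_type '{part}' at line {lineno}")
        out.add(part)
    return frozenset(out)


def _format_doc_types(doc_types: frozenset[str]) -> str:
    if not doc_types:
        return "*"
    return ",".join(sorted(doc_types, key=DOC_TYPES.index))


@dataclass(frozen=True)
class TriggerEntry:
    """One trigger phrase with its property, role and applicability."""

    phrase: str
    property: ContextProperty
    role: TriggerRole
    doc_types: frozenset[str] = frozenset()  # empty = applies to all types
    max_scope_tokens: int | None = None
    note: str = ""

    def __post_init__(self) -> None:
        if not self.phrase or self.phrase != self.phrase.strip():
            raise LexiconError(f"phrase {self.phrase!r} has leading/trailing whitespace or is empty")
        if self.phrase != self.phrase.lower():
            raise LexiconError(f"phrase {self.phrase!r} must be stored lowercase")
        if self.max_scope_tokens is not None and self.max_scope_tokens < 1:
            raise LexiconError(f"max_scope_tokens must be >= 1, got {self.max_scope_tokens}")

    def applies_to(self, doc_type: str) -> bool:
        return not self.doc_types or doc_type in self.doc_types


@dataclass(frozen=True)
class CombinedTriggerRule:
    """A pre-phrase + post-phrase pair that jointly asserts a property value.

    Fires only when the pre phrase occurs before a concept, the post phrase
    after it, and the whole span covers at most ``max_span_tokens`` tokens.
    """

    pre_phrase: str
    post_phrase: str
    property: ContextProperty
    value: str
    max_span_tokens: int
    doc_types: frozenset[str] = frozenset()

    def __post_init__(self) -> None:
        if self.pre_phrase == self.post_phrase:
            raise LexiconError("combined rule pre_phrase must differ from post_phrase")
        if self.max_span_tokens < 1:
            raise LexiconError("max_span_tokens must be >= 1")

    def applies_to(self, doc_type: str) -> bool:
        return not self.doc_types or doc_type in self.doc_types

    @property
    def name(self) -> str:
        return f"combined:{self.pre_phrase}+{self.post_phrase}"


@dataclass(frozen=True)
class TriggerLexicon:
    entries: tuple[TriggerEntry, ...]
    version: str = "unversioned"
    language: str = "nl"

    def __len__(self) -> int:
        return len(self.entries)

    def __iter__(self) -> Iterator[TriggerEntry]:
        return iter(self.entries)

    def counts(self) -> dict[str, int]:
        """Number of entries per contextual property."""
        out: dict[str, int] = {p.value: 0 for p in ContextProperty}
        for e in self.entries:
            out[e.property.value] += 1
        return out

    def entries_for(self, doc_type: str) -> tuple[TriggerEntry, ...]:
        return tuple(e for e in self.entries if e.applies_to(doc_type))

    def without_role(self, role: TriggerRole) -> "TriggerLexicon":
        """A copy with every entry of ``role`` removed (used for ablations)."""
        return replace(self, entries=tuple(e for e in self.entries if e.role is not role))


def load_lexicon(path: str | Path, *, version: str | None = None) -> TriggerLexicon:
    """Parse a trigger lexicon TSV.

    Phrases are lowercased and whitespace-normalized; duplicate
    (phrase, property, role) rows are an error.
    """
    path = Path(path)
    entries: list[TriggerEntry] = []
    seen: set[tuple[str, ContextProperty, TriggerRole]] = set()
    with path.open(encoding="utf-8", newline="") as fh:
        reader = csv.reader(fh, delimiter="\t")
        try:
            header = next(reader)
        except StopIteration:
            raise LexiconError(f"{path}: empty file, expected header {LEXICON_COLUMNS}")
        if tuple(h.strip() for h in header) != LEXICON_COLUMNS:
            raise LexiconError(f"{path}: bad header {header!r}, expected {list(LEXICON_COLUMNS)}")
        for lineno, row in enumerate(reader, start=2):
            if not row or (len(row) == 1 and not row[0].strip()):
                continue
            if len(row) != len(LEXICON_COLUMNS):
                raise LexiconError(f"{path}: malformed row at line {lineno} ({len(row)} fields)")
            phrase_raw, prop_raw, role_raw, dt_raw, scope_raw, note = row
            phrase = " ".join(phrase_raw.lower().split())
            if not phrase:
                raise LexiconError(f"{path}: empty phrase at line {lineno}")
            try:
                prop = ContextProperty(prop_raw.strip().lower())
            except ValueError:
                raise LexiconError(f"unknown property '{prop_raw.strip()}' at line {lineno}") from None
            try:
                role = TriggerRole(role_raw.strip().lower())
            except ValueError:
                raise LexiconError(f"unknown role '{role_raw.strip()}' at line {lineno}") from None
            doc_types = _parse_doc_types(dt_raw, lineno)
            scope_raw = scope_raw.strip()
            max_scope = None
            if scope_raw:
                try:
                    max_scope = int(scope_raw)
                except ValueError:
                    raise LexiconError(f"bad max_scope_tokens '{scope_raw}' at line {lineno}") from None
            key = (phrase, prop, role)
            if key in seen:
                raise LexiconError(f"{path}: duplicate entry {key} at line {lineno}")
            seen.add(key)
            entries.append(
                TriggerEntry(phrase, prop, role, doc_types, max_scope, note.strip())
            )
    if not entries:
        log.warning("lexicon %s contains no entries", path)
    return TriggerLexicon(tuple(entries), version=version or path.stem)


def write_lexicon(lex: TriggerLexicon, path: str | Path) -> None:
    path = Path(path)
    with path.open("w", encoding="utf-8", newline="") as fh:
        writer = csv.writer(fh, delimiter="\t", lineterminator="\n")
        writer.writerow(LEXICON_COLUMNS)
        for e in lex.entries:
            writer.writerow(
                [
                    e.phrase,
                    e.property.value,
                    e.role.value,
                    _format_doc_types(e.doc_types),
                    "" if e.max_scope_tokens is None else str(e.max_scope_tokens),
                    e.note,
                ]
            )


def load_combined_rules(path: str | Path) -> tuple[CombinedTriggerRule, ...]:
    """Parse the combined-rule TSV (pre_phrase, post_phrase, ...)."""
    path = Path(path)
    rules: list[CombinedTriggerRule] = []
    with path.open(encoding="utf-8", newline="") as fh:
        reader = csv.reader(fh, delimiter="\t")
        try:
            header = next(reader)
        except StopIteration:
            raise LexiconError(f"{path}: empty file, expected header {COMBINED_COLUMNS}")
        if tuple(h.strip() for h in header) != COMBINED_COLUMNS:
            raise LexiconError(f"{path}: bad header {header!r}, expected {list(COMBINED_COLUMNS)}")
        for lineno, row in enumerate(reader, start=2):
            if not row or (len(row) == 1 and not row[0].strip()):
                continue
            if len(row) != len(COMBINED_COLUMNS):
                raise LexiconError(f"{path}: malformed row at line {lineno}")
            pre, post, prop_raw, value, span_raw, dt_raw = row
            try:
                prop = ContextProperty(prop_raw.strip().lower())
            except ValueError:
                raise LexiconError(f"unknown property '{prop_raw.strip()}' at line {lineno}") from None
            try:
                span = int(span_raw)
            except ValueError:
                raise LexiconError(f"bad max_span_tokens '{span_raw}' at line {lineno}") from None
            rules.append(
                CombinedTriggerRule(
                    pre_phrase=" ".join(pre.lower().split()),
                    post_phrase=" ".join(post.lower().split()),
                    property=prop,
                    value=value.strip(),
                    max_span_tokens=span,
                    doc_types=_parse_doc_types(dt_raw, lineno),
                )
            )
    return tuple(rules)


def validate_lexicon(lex: TriggerLexicon) -> list[str]:
    """Non-fatal consistency diagnostics.

    Flags pseudo entries that mask nothing (no non-pseudo entry of the same
    property whose phrase is a substring of the pseudo phrase) and phrases
    containing characters outside letters/digits/space/hyphen/period.
    """
    diagnostics: list[str] = []
    non_pseudo: dict[ContextProperty, list[str]] = {p: [] for p in ContextProperty}
    for e in lex.entries:
        if e.role is not TriggerRole.PSEUDO:
            non_pseudo[e.property].append(e.phrase)
    for e in lex.entries:
        if e.role is TriggerRole.PSEUDO:
            if not any(p in e.phrase for p in non_pseudo[e.property]):
                diagnostics.append(
                    f"pseudo trigger '{e.phrase}' ({e.property.value}) masks no non-pseudo entry"
                )
        if "  " in e.phrase:
            diagnostics.append(f"phrase '{e.phrase}' contains unnormalized whitespace")
        bad = {ch for ch in e.phrase if ch not in _PHRASE_CHARS}
        if bad:
            diagnostics.append(
                f"phrase '{e.phrase}' contains unexpected characters: {''.join(sorted(bad))}"
            )
    return diagnostics


def expand_variants(
    base_phrase: str,
    variants: Sequence[str],
    *,
    property: ContextProperty,
    role: TriggerRole,
    doc_types: frozenset[str] = frozenset(),
    max_scope_tokens: int | None = None,
) -> list[TriggerEntry]:
    """Create one entry per variant of a (possibly foreign) base phrase.

    Duplicated variants are collapsed with a warning; each entry records the
    base phrase in its provenance note.
    """
    if not base_phrase or not all(variants):
        raise LexiconError("base phrase and variants must be non-empty")
    out: list[TriggerEntry] = []
    seen: set[str] = set()
    for v in variants:
        norm = " ".join(v.lower().split())
        if norm in seen:
            log.warning("duplicate variant %r of base %r collapsed", v, base_phrase)
            continue
        seen.add(norm)
        out.append(
            TriggerEntry(
                phrase=norm,
                property=property,
                role=role,
                doc_types=doc_types,
                max_scope_tokens=max_scope_tokens,
                note=f"variant of '{base_phrase}'",
            )
        )
    return out
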