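"""Sentence splitting, offset-preserving tokenization and concept marking.

All offsets are 0-based, half-open, relative to the sentence text (sentences
additionally carry their character offset into the source document so the
document can be reconstructed).
"""

from __future__ import annotations

import re
from dataclasses import dataclass, field
from pathlib import Path
from typing import Iterable, NamedTuple, Sequence

#: characters always isolated as standalone tokens (hyphen is special-cased:
#: it stays attached when directly following a word character, which the GP
#: minus rule relies on, e.g. "koorts-")
_PUNCT = set(",;:.<>-?!/()")

_DATA_DIR = Path(__file__).parent / "data"


class Token(NamedTuple):
    surface: str
    char_start: int
    char_end: int


def is_punct_token(surface: str) -> bool:
    """True for tokens made up entirely of punctuation characters."""
    return bool(surface) and not any(ch.isalnum() for ch in surface)


def tokenize(text: str) -> list[Token]:
    """Whitespace tokenization with punctuation isolation and exact offsets.

    ``, ; : . < >`` etc. become standalone tokens; a hyphen directly attached
    to a preceding word character stays glued to it ("koorts-" and
    "koorts-achtig" each remain one token, while "- koorts" yields two).
    """
    tokens: list[Token] = []
    i = 0
    n = len(text)
    while i < n:
        if text[i].isspace():
            i += 1
            continue
        start = i
        while i < n and not text[i].isspace():
            ch = text[i]
            if ch in _PUNCT:
                if ch == "-" and i > start and text[i - 1].isalnum():
                    i += 1
                    continue
                if i == start:
                    i += 1
                break
            i += 1
        tokens.append(Token(text[start:i], start, i))
    return tokens


@dataclass(frozen=True)
class Sentence:
    """One sentence with its token stream and position inside the document."""

    text: str
    tokens: tuple[Token, ...]
    doc_id: str = ""
    index_in_doc: int = 0
    doc_char_offset: int = 0

    @classmethod
    def from_text(
        cls, text: str, doc_id: str = "", index_in_doc: int = 0, doc_char_offset: int = 0
    ) -> "Sentence":
        return cls(text, tuple(tokenize(text)), doc_id, index_in_doc, doc_char_offset)

    def token_index_at(self, char_pos: int) -> int | None:
        for i, t in enumerate(self.tokens):
            if t.char_start <= char_pos < t.char_end:
                return i
        return None


@dataclass(frozen=True)
class ConceptMention:
    """A marked medical term inside one sentence."""

    term: str
    char_start: int
    char_end: int
    token_start: int
    token_end: int
    concept_id: str | None = None


def _default_abbreviations() -> frozenset[str]:
    path = _DATA_DIR / "abbreviations.txt"
    out = set()
    for line in path.read_text(encoding="utf-8").splitlines():
        line = line.strip().lower()
        if line and not line.startswith("#"):
            out.add(line)
    return frozenset(out)


_ABBREV_CACHE: frozenset[str] | None = None


def default_abbreviations() -> frozenset[str]:
    global _ABBREV_CACHE
    if _ABBREV_CACHE is None:
        _ABBREV_CACHE = _default_abbreviations()
    return _ABBREV_CACHE


_BOUNDARY_RE = re.compile(r"[.!?]+(?=\s)")


def split_sentences(
    document_text: str,
    doc_id: str = "",
    abbreviations: frozenset[str] | None = None,
) -> list[Sentence]:
    """Rule-based sentence splitter.

    Splits after ``. ! ?`` when followed by whitespace and an uppercase letter
    or digit, unless the preceding chunk is a known abbreviation; newlines are
    always hard boundaries (clinical notes are often line-structured). Empty
    input yields an empty list; concatenating ``sentence.text`` at each
    sentence's ``doc_char_offset`` reconstructs the document.
    """
    if abbreviations is None:
        abbreviations = default_abbreviations()
    if not document_text.strip():
        return []
    cut_points: set[int] = set()
    for m in _BOUNDARY_RE.finditer(document_text):
        end = m.end()
        follow = document_text[end:].lstrip()
        if not follow or not (follow[0].isupper() or follow[0].isdigit()):
            continue
        if "." in m.group():
            prefix = document_text[: end]
            last_chunk = prefix.split()[-1].lower() if prefix.split() else ""
            if last_chunk in abbreviations:
                continue
        cut_points.add(end)
    for m in re.finditer(r"\n", document_text):
        cut_points.add(m.start())

    bounds = sorted(cut_points | {0, len(document_text)})
    sentences: list[Sentence] = []
    for a, b in zip(bounds, bounds[1:]):
        raw = document_text[a:b]
        stripped = raw.strip()
        if not stripped:
            continue
        offset = a + raw.index(stripped[0])
        sentences.append(
            Sentence.from_text(
                stripped, doc_id=doc_id, index_in_doc=len(sentences), doc_char_offset=offset
            )
        )
    return sentences


def load_term_list(path: str | Path) -> list[str]:
    """Plain-text term list, one term per line, '#' comments allowed."""
    terms: list[str] = []
    seen: set[str] = set()
    for line in Path(path).read_text(encoding="utf-8").splitlines():
        line = line.strip()
        if not line or line.startswith("#"):
            continue
        norm = " ".join(line.lower().split())
        if norm not in seen:
            seen.add(norm)
            terms.append(norm)
    return terms


def _boundary_sets(sentence: Sentence) -> tuple[set[int], set[int]]:
    """Valid match start/end character positions.

    Ends additionally admit the position just before a trailing hyphen glued
    to a word token ("koorts-"), so the term "koorts" is still markable there.
    """
    starts = {t.char_start for t in sentence.tokens}
    ends = {t.char_end for t in sentence.tokens}
    for t in sentence.tokens:
        if len(t.surface) > 1 and t.surface.endswith("-"):
            ends.add(t.char_end - 1)
    return starts, ends


class PhraseOccurrence(NamedTuple):
    phrase: str
    char_start: int
    char_end: int
    token_start: int
    token_end: int


def find_phrase_occurrences(
    sentence: Sentence, phrases: Iterable[str]
) -> list[PhraseOccurrence]:
    """All case-insensitive, token-boundary-aligned occurrences of phrases.

    No overlap resolution here; callers apply their own longest-match policy.
    """
    starts, ends = _boundary_sets(sentence)
    text_lower = sentence.text.lower()
    out: list[PhraseOccurrence] = []
    for phrase in phrases:
        needle = phrase.lower()
        if not needle:
            continue
        pos = text_lower.find(needle)
        while pos != -1:
            end = pos + len(needle)
            if pos in starts and end in ends:
                tok_start = sentence.token_index_at(pos)
                tok_end_idx = sentence.token_index_at(end - 1)
                if tok_start is not None and tok_end_idx is not None:
                    out.append(PhraseOccurrence(phrase, pos, end, tok_start, tok_end_idx + 1))
            pos = text_lower.find(needle, pos + 1)
    out.sort(key=lambda o: (o.char_start, -o.char_end))
    return out


def match_concepts(sentence: Sentence, terms: Sequence[str]) -> list[ConceptMention]:
    """Mark term-list entries in a sentence.

    Case-insensitive exact matching aligned to token boundaries; overlapping
    candidates are resolved longest-first, then leftmost, and the surviving
    mentions never overlap.
    """
    candidates = find_phrase_occurrences(sentence, terms)
    candidates.sort(key=lambda o: (-(o.char_end - o.char_start), o.char_start))
    chosen: list[PhraseOccurrence] = []
    for cand in candidates:
        if all(cand.char_end <= c.char_start or cand.char_start >= c.char_end for c in chosen):
            chosen.append(cand)
    chosen.sort(key=lambda o: o.char_start)
    return [
        ConceptMention(
            term=o.phrase,
            char_start=o.char_start,
            char_end=o.char_end,
            token_start=o.token_start,
            token_end=o.token_end,
        )
        for o in chosen
    ]
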