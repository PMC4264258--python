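"""Regex-based detection of historical temporality.

Runs after the trigger pass, inside tight token windows on either side of a
mention so that time expressions elsewhere in the sentence cannot leak in.
Duration expressions ("3 weken geleden", "sinds 2 jaar") only count as
historical when they exceed the two-week recency bound; guards (relational
operators next to the number, "net"/"recent" in the window) veto a match.
"""

from __future__ import annotations

import re
from dataclasses import dataclass
from pathlib import Path
from typing import NamedTuple, Sequence

import yaml

from .textprep import ConceptMention, Sentence

#: a condition up to this many days old is still "Recent"
RECENCY_BOUND_DAYS = 14

_UNIT_DAYS = {
    "dag": 1,
    "dagen": 1,
    "week": 7,
    "weken": 7,
    "maand": 30,
    "maanden": 30,
    "jaar": 365,
    "jaren": 365,
}


class PatternError(ValueError):
    pass


class TemporalMatch(NamedTuple):
    pattern_id: str
    char_start: int
    char_end: int


@dataclass(frozen=True)
class TemporalPattern:
    """One historical-evidence regex with its window and optional guard."""

    pattern_id: str
    regex_source: str
    side: str  # left | right | either
    window_left: int
    window_right: int
    guard: str | None = None
    numeric_duration: bool = False  # regex has num/unit groups; apply recency bound
    year_before_reference: bool = False  # regex has a year group; needs a reference year

    def __post_init__(self) -> None:
        if self.side not in ("left", "right", "either"):
            raise PatternError(f"pattern '{self.pattern_id}': bad side '{self.side}'")
        if self.window_left < 1 or self.window_right < 1:
            raise PatternError(f"pattern '{self.pattern_id}': window_tokens must be >= 1")
        try:
            object.__setattr__(self, "_compiled", re.compile(self.regex_source, re.IGNORECASE))
        except re.error as exc:
            raise PatternError(f"pattern '{self.pattern_id}': bad regex ({exc})") from None
        compiled_guard = None
        if self.guard:
            try:
                compiled_guard = re.compile(self.guard, re.IGNORECASE)
            except re.error as exc:
                raise PatternError(f"pattern '{self.pattern_id}': bad guard ({exc})") from None
        object.__setattr__(self, "_compiled_guard", compiled_guard)

    @property
    def compiled(self) -> re.Pattern[str]:
        return self._compiled  # type: ignore[attr-defined]

    @property
    def compiled_guard(self) -> re.Pattern[str] | None:
        return self._compiled_guard  # type: ignore[attr-defined]


def _duration_days(match: re.Match[str]) -> int | None:
    groups = match.groupdict()
    num_raw, unit = groups.get("num"), groups.get("unit")
    if num_raw is None or unit is None:
        return None
    try:
        return int(num_raw) * _UNIT_DAYS[unit.lower()]
    except (ValueError, KeyError):
        return None


def _windows(
    sentence: Sentence, mention: ConceptMention, pattern: TemporalPattern
) -> list[tuple[int, int]]:
    """Character spans of the requested token windows around the mention."""
    spans: list[tuple[int, int]] = []
    tokens = sentence.tokens
    if pattern.side in ("left", "either") and mention.token_start > 0:
        lo = max(0, mention.token_start - pattern.window_left)
        spans.append((tokens[lo].char_start, tokens[mention.token_start - 1].char_end))
    if pattern.side in ("right", "either") and mention.token_end < len(tokens):
        hi = min(len(tokens), mention.token_end + pattern.window_right)
        spans.append((tokens[mention.token_end].char_start, tokens[hi - 1].char_end))
    return spans


def detect_historical(
    sentence: Sentence,
    mention: ConceptMention,
    patterns: Sequence[TemporalPattern],
    reference_year: int | None = None,
) -> list[TemporalMatch]:
    """Matches of historical-evidence patterns around a mention.

    A pattern fires when its regex matches inside one of its windows, its
    guard does not match in that window, and (for duration patterns) the
    expressed duration exceeds the two-week recency bound. Year patterns are
    disabled when no document reference year is supplied. The returned list
    is empty when the mention stays Recent.
    """
    out: list[TemporalMatch] = []
    for pattern in patterns:
        for lo, hi in _windows(sentence, mention, pattern):
            window_text = sentence.text[lo:hi]
            m = pattern.compiled.search(window_text)
            if m is None:
                continue
            if pattern.compiled_guard is not None and pattern.compiled_guard.search(window_text):
                continue
            if pattern.numeric_duration:
                days = _duration_days(m)
                if days is None or days <= RECENCY_BOUND_DAYS:
                    continue
            if pattern.year_before_reference:
                if reference_year is None:
                    continue
                year_raw = m.groupdict().get("year")
                if year_raw is None or int(year_raw) >= reference_year:
                    continue
            out.append(TemporalMatch(pattern.pattern_id, lo + m.start(), lo + m.end()))
            break
    return out


def load_patterns(path: str | Path) -> list[TemporalPattern]:
    """Load temporal patterns from a YAML list.

    Each item: ``{id, regex, side, window_tokens, guard?, numeric_duration?,
    year_before_reference?}`` where ``window_tokens`` is either an integer or
    a ``{left: n, right: m}`` mapping.
    """
    raw = yaml.safe_load(Path(path).read_text(encoding="utf-8"))
    if raw is None:
        return []
    if not isinstance(raw, list):
        raise PatternError(f"{path}: expected a YAML list of patterns")
    patterns: list[TemporalPattern] = []
    seen: set[str] = set()
    for item in raw:
        pid = str(item.get("id", "")).strip()
        if not pid:
            raise PatternError(f"{path}: pattern without id")
        if pid in seen:
            raise PatternError(f"{path}: duplicate pattern id '{pid}'")
        seen.add(pid)
        window = item.get("window_tokens", {"left": 5, "right": 3})
        if isinstance(window, int):
            left = right = window
        else:
            left = int(window.get("left", 5))
            right = int(window.get("right", 3))
        patterns.append(
            TemporalPattern(
                pattern_id=pid,
                regex_source=item["regex"],
                side=item.get("side", "either"),
                window_left=left,
                window_right=right,
                guard=item.get("guard"),
                numeric_duration=bool(item.get("numeric_duration", False)),
                year_before_reference=bool(item.get("year_before_reference", False)),
            )
        )
    return patterns
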