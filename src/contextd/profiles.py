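"""Named run configurations binding bundled resources together.

Two configurations ship with the package:

* ``paper-final`` — the final algorithm configuration: curated trigger list
  without the bare pre-trigger "nooit" (covered by a combined rule instead)
  and without post-hoc error-analysis additions;
* ``extended`` — paper-final plus triggers suggested by error analysis
  ("blanco voor", a tight-scope "nee" post-trigger, hypothetical "bij").

Both use the same combined-rule table and temporal pattern set.
"""

from __future__ import annotations

from dataclasses import dataclass
from pathlib import Path

from .lexicon import (
    CombinedTriggerRule,
    TriggerLexicon,
    load_combined_rules,
    load_lexicon,
)
from .temporality import TemporalPattern, load_patterns

DATA_DIR = Path(__file__).parent / "data"

PROFILE_NAMES = ("paper-final", "extended")

_LEXICON_FILES = {
    "paper-final": "lexicon_paper_final.tsv",
    "extended": "lexicon_extended.tsv",
}


class UnknownProfileError(ValueError):
    pass


def lexicon_path(profile: str = "paper-final") -> Path:
    try:
        return DATA_DIR / _LEXICON_FILES[profile]
    except KeyError:
        raise UnknownProfileError(
            f"unknown profile '{profile}', expected one of {PROFILE_NAMES}"
        ) from None


def default_lexicon(profile: str = "paper-final") -> TriggerLexicon:
    return load_lexicon(lexicon_path(profile), version=profile)


def combined_rules_path() -> Path:
    return DATA_DIR / "combined_rules.tsv"


def default_combined_rules() -> tuple[CombinedTriggerRule, ...]:
    return load_combined_rules(combined_rules_path())


def temporal_patterns_path() -> Path:
    return DATA_DIR / "temporal_patterns.yaml"


def default_temporal_patterns() -> list[TemporalPattern]:
    return load_patterns(temporal_patterns_path())


def default_filler_words() -> list[str]:
    return _read_wordlist(DATA_DIR / "fillers.txt")


def default_terms() -> list[str]:
    return _read_wordlist(DATA_DIR / "default_terms.txt")


def _read_wordlist(path: Path) -> list[str]:
    out = []
    for line in path.read_text(encoding="utf-8").splitlines():
        line = line.strip()
        if line and not line.startswith("#"):
            out.append(line.lower())
    return out
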