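"""Deterministic synthetic corpus with gold contextual-property labels.

Stands in for a real annotated clinical corpus: short templated Dutch
sentences, one concept mention per document, with gold labels defined by
template semantics (never by running the engine, which would make round-trip
tests circular). Class quotas are exact: a 12% negated fraction over 1000
documents yields exactly 120 negated gold labels.
"""

from __future__ import annotations

import random
from dataclasses import dataclass, field
from typing import Any, Iterable, Sequence

from . import profiles
from .engine import Experiencer, Negation, Temporality
from .lexicon import DOC_TYPES, TriggerLexicon


class SynthError(ValueError):
    pass


# ---------------------------------------------------------------------------
# Template slots


@dataclass(frozen=True)
class Lit:
    """Literal text (trigger phrases, terminators, minus signs...)."""

    text: str


@dataclass(frozen=True)
class Filler:
    """``n`` neutral filler words drawn from the bundled vocabulary."""

    n: int


@dataclass(frozen=True)
class Concept:
    """The single concept slot; filled with a term from the term list."""


Slot = Lit | Filler | Concept


@dataclass(frozen=True)
class GoldLabels:
    negation: str = Negation.NOT_NEGATED.value
    temporality: str = Temporality.RECENT.value
    experiencer: str = Experiencer.PATIENT.value


@dataclass(frozen=True)
class TemplateSpec:
    """A sentence skeleton whose semantics entail a known gold triple.

    ``doc_type=None`` means the template applies to any document type;
    ``engine_consistent`` records whether the shipped engine (paper-final
    configuration, default profiles) is expected to recover the gold labels.
    """

    template_id: str
    slots: tuple[Slot, ...]
    gold: GoldLabels
    doc_type: str | None = None
    engine_consistent: bool = True
    gold_class: str = "default"  # negated | historical | hypothetical | other | default

    def __post_init__(self) -> None:
        n_concepts = sum(1 for s in self.slots if isinstance(s, Concept))
        if n_concepts != 1:
            raise SynthError(
                f"template '{self.template_id}' must contain exactly one concept slot"
            )

    def applies_to(self, doc_type: str) -> bool:
        return self.doc_type is None or self.doc_type == doc_type


GOLD_CLASSES = ("negated", "historical", "hypothetical", "other", "default")


def _gold_for_class(cls: str) -> GoldLabels:
    return {
        "negated": GoldLabels(negation=Negation.NEGATED.value),
        "historical": GoldLabels(temporality=Temporality.HISTORICAL.value),
        "hypothetical": GoldLabels(temporality=Temporality.HYPOTHETICAL.value),
        "other": GoldLabels(experiencer=Experiencer.OTHER.value),
        "default": GoldLabels(),
    }[cls]


def default_templates() -> list[TemplateSpec]:
    """Engine-consistent templates covering every gold class and doc type."""
    t: list[TemplateSpec] = []

    def add(tid: str, slots: Sequence[Slot], cls: str, doc_type: str | None = None) -> None:
        t.append(
            TemplateSpec(
                template_id=tid,
                slots=tuple(slots),
                gold=_gold_for_class(cls),
                doc_type=doc_type,
                engine_consistent=True,
                gold_class=cls,
            )
        )

    add("neg-geen", [Lit("geen"), Concept()], "negated")
    add("neg-geen-filler", [Lit("geen"), Filler(1), Concept()], "negated")
    add("neg-teken-van", [Lit("geen teken van"), Concept()], "negated")
    add("neg-post-uitgesloten", [Concept(), Lit("uitgesloten")], "negated")
    add("neg-gp-minus", [Concept(), Lit("-")], "negated", doc_type="GP")
    add("neg-combined", [Lit("nooit"), Concept(), Lit("doorgemaakt")], "negated")
    add("hist-status-na", [Lit("status na"), Concept()], "historical")
    add("hist-duration", [Concept(), Lit("3 weken geleden")], "historical")
    add("hist-verleden", [Concept(), Lit("in het verleden")], "historical")
    add("hyp-indien", [Lit("indien"), Concept(), Filler(1)], "hypothetical")
    add("hyp-tenzij", [Lit("tenzij"), Concept()], "hypothetical")
    add("exp-moeder", [Lit("moeder heeft"), Concept()], "other")
    add("exp-vader", [Lit("vader bekend met"), Concept()], "other")
    add("default-plain", [Filler(2), Concept(), Filler(2)], "default")
    add("default-short", [Concept(), Filler(1)], "default")
    return t


def adversarial_suite() -> list[TemplateSpec]:
    """Templates reproducing documented failure modes.

    ``engine_consistent=False`` templates encode behaviors the paper-final
    configuration is known to miss (missing triggers); the rest verify that
    pseudo masking, scope caps, punctuation terminators and temporal guards
    hold the line. Ablating the pseudo list or the GP punctuation terminators
    must strictly lower negation precision on this suite.
    """
    t: list[TemplateSpec] = []

    def add(
        tid: str,
        slots: Sequence[Slot],
        cls: str,
        doc_type: str | None,
        consistent: bool,
    ) -> None:
        t.append(
            TemplateSpec(
                template_id=tid,
                slots=tuple(slots),
                gold=_gold_for_class(cls),
                doc_type=doc_type,
                engine_consistent=consistent,
                gold_class=cls,
            )
        )

    add("adv-neg-plain", [Lit("geen"), Concept()], "negated", "GP", True)
    add("adv-post-colon-nee", [Concept(), Lit(": nee")], "negated", "GP", False)
    add("adv-missing-blanco", [Lit("blanco voor"), Concept()], "negated", "GP", False)
    add("adv-is-weg", [Concept(), Lit("is weg")], "negated", "GP", False)
    add("adv-pseudo-niet-minder", [Lit("niet minder"), Concept()], "default", "GP", True)
    add("adv-out-of-scope", [Lit("geen"), Filler(8), Concept()], "default", "GP", True)
    add("adv-terminator", [Lit("geen"), Filler(1), Lit(","), Concept()], "default", "GP", True)
    add(
        "adv-temporal-guard",
        [Lit("als <3 weken weer"), Concept()],
        "default",
        "GP",
        True,
    )
    return t


# ---------------------------------------------------------------------------
# Mixture configuration


#: per-document-type fractions (negated, historical, hypothetical, other);
#: defaults mirror the observed class distribution of the reference corpus
DEFAULT_MIXTURE: dict[str, dict[str, float]] = {
    "GP": {"negated": 0.12, "historical": 0.02, "hypothetical": 0.01, "other": 0.02},
    "SP": {"negated": 0.15, "historical": 0.08, "hypothetical": 0.02, "other": 0.01},
    "RD": {"negated": 0.16, "historical": 0.03, "hypothetical": 0.01, "other": 0.001},
    "DL": {"negated": 0.13, "historical": 0.06, "hypothetical": 0.0, "other": 0.02},
}


@dataclass(frozen=True)
class MixtureConfig:
    fractions: dict[str, dict[str, float]] = field(
        default_factory=lambda: {dt: dict(v) for dt, v in DEFAULT_MIXTURE.items()}
    )
    size_per_doc_type: int = 1000
    seed: int = 42

    def __post_init__(self) -> None:
        for dt, mix in self.fractions.items():
            if dt not in DOC_TYPES:
                raise SynthError(f"unknown doc_type '{dt}' in mixture")
            for cls, frac in mix.items():
                if cls not in GOLD_CLASSES:
                    raise SynthError(f"unknown class '{cls}' in mixture for {dt}")
                if not 0.0 <= frac <= 1.0:
                    raise SynthError(f"fraction {frac} for {dt}/{cls} outside [0, 1]")
            if sum(mix.values()) > 1.0 + 1e-9:
                raise SynthError(f"fractions for {dt} sum to more than 1")

    def class_counts(self, doc_type: str) -> dict[str, int]:
        """Exact per-class quota; the remainder is the all-default class."""
        mix = self.fractions[doc_type]
        counts = {cls: int(round(mix.get(cls, 0.0) * self.size_per_doc_type)) for cls in GOLD_CLASSES if cls != "default"}
        used = sum(counts.values())
        if used > self.size_per_doc_type:
            raise SynthError(f"class quotas exceed corpus size for {doc_type}")
        counts["default"] = self.size_per_doc_type - used
        return counts


# ---------------------------------------------------------------------------
# Generation


def _render(
    template: TemplateSpec, term: str, rng: random.Random, fillers: Sequence[str]
) -> tuple[str, int, int]:
    """Render a template; returns (text, concept_char_start, concept_char_end)."""
    parts: list[str] = []
    concept_span: tuple[int, int] | None = None
    pos = 0
    for slot in template.slots:
        if isinstance(slot, Lit):
            chunk = slot.text
        elif isinstance(slot, Filler):
            chunk = " ".join(rng.choice(fillers) for _ in range(slot.n))
        else:
            chunk = term
        if parts:
            pos += 1  # joining space
        if isinstance(slot, Concept):
            concept_span = (pos, pos + len(chunk))
        parts.append(chunk)
        pos += len(chunk)
    assert concept_span is not None
    return " ".join(parts), concept_span[0], concept_span[1]


def generate_corpus(
    config: MixtureConfig | None = None,
    templates: Sequence[TemplateSpec] | None = None,
    terms: Sequence[str] | None = None,
    lex: TriggerLexicon | None = None,
) -> tuple[list[dict[str, Any]], list[dict[str, Any]]]:
    """Build (documents, gold annotations) as JSONL-ready dicts.

    Deterministic given ``config.seed``. Every requested class must be
    coverable by at least one template for the document type, otherwise the
    gap is reported as an error. When a lexicon is passed, the filler
    vocabulary is checked for collisions with its phrases.
    """
    config = config or MixtureConfig()
    templates = list(templates) if templates is not None else default_templates()
    terms = list(terms) if terms is not None else profiles.default_terms()
    if not terms:
        raise SynthError("term list is empty")
    fillers = profiles.default_filler_words()
    if lex is not None:
        collisions = {e.phrase for e in lex.entries} & set(fillers)
        if collisions:
            raise SynthError(f"filler vocabulary collides with lexicon phrases: {collisions}")

    rng = random.Random(config.seed)
    docs: list[dict[str, Any]] = []
    gold: list[dict[str, Any]] = []
    for doc_type in DOC_TYPES:
        if doc_type not in config.fractions:
            continue
        counts = config.class_counts(doc_type)
        pool: dict[str, list[TemplateSpec]] = {}
        for cls, count in counts.items():
            if count == 0:
                continue
            matching = [
                tpl
                for tpl in templates
                if tpl.gold_class == cls and tpl.applies_to(doc_type) and tpl.engine_consistent
            ]
            if not matching:
                raise SynthError(f"no template for class '{cls}' and doc_type '{doc_type}'")
            pool[cls] = matching
        schedule = [cls for cls, count in counts.items() for _ in range(count)]
        rng.shuffle(schedule)
        for i, cls in enumerate(schedule):
            template = rng.choice(pool[cls])
            term = rng.choice(terms)
            text, c_start, c_end = _render(template, term, rng, fillers)
            doc_id = f"{doc_type}-{i:05d}"
            docs.append({"id": doc_id, "doc_type": doc_type, "text": text})
            gold.append(
                {
                    "doc_id": doc_id,
                    "doc_type": doc_type,
                    "sentence_index": 0,
                    "char_start": c_start,
                    "char_end": c_end,
                    "term": term,
                    "negation": template.gold.negation,
                    "temporality": template.gold.temporality,
                    "experiencer": template.gold.experiencer,
                    "template_id": template.template_id,
                }
            )
    return docs, gold


def instantiate_suite(
    templates: Sequence[TemplateSpec],
    doc_type: str = "GP",
    copies: int = 5,
    seed: int = 0,
    terms: Sequence[str] | None = None,
) -> tuple[list[dict[str, Any]], list[dict[str, Any]]]:
    """Render each template ``copies`` times (adversarial-suite helper)."""
    terms = list(terms) if terms is not None else profiles.default_terms()
    fillers = profiles.default_filler_words()
    rng = random.Random(seed)
    docs: list[dict[str, Any]] = []
    gold: list[dict[str, Any]] = []
    i = 0
    for template in templates:
        if not template.applies_to(doc_type):
            continue
        for _ in range(copies):
            term = rng.choice(terms)
            text, c_start, c_end = _render(template, term, rng, fillers)
            doc_id = f"{doc_type}-adv-{i:04d}"
            i += 1
            docs.append({"id": doc_id, "doc_type": doc_type, "text": text})
            gold.append(
                {
                    "doc_id": doc_id,
                    "doc_type": doc_type,
                    "sentence_index": 0,
                    "char_start": c_start,
                    "char_end": c_end,
                    "term": term,
                    "negation": template.gold.negation,
                    "temporality": template.gold.temporality,
                    "experiencer": template.gold.experiencer,
                    "template_id": template.template_id,
                    "engine_consistent": template.engine_consistent,
                }
            )
    return docs, gold
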