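"""One-vs-rest precision/recall/F scoring and Cohen's kappa.

Metrics with a zero denominator are UNDEFINED (``None`` in code, rendered as
``"-"`` in reports), never silently zero. Kappa is computed with exact
rational arithmetic before conversion to float.
"""

from __future__ import annotations

from dataclasses import dataclass
from fractions import Fraction
from typing import Any, Hashable, Mapping, Sequence

UNDEFINED = None
UNDEFINED_DISPLAY = "-"

PROPERTY_VALUES: dict[str, tuple[str, ...]] = {
    "negation": ("Negated", "NotNegated"),
    "temporality": ("Recent", "Historical", "Hypothetical"),
    "experiencer": ("Patient", "Other"),
}

#: fields identifying one scored mention across gold/prediction files
MENTION_KEY_FIELDS = ("doc_id", "sentence_index", "char_start", "char_end")


class AlignmentError(ValueError):
    pass


@dataclass(frozen=True)
class ConfusionCounts:
    tp: int
    fp: int
    fn: int
    tn: int
    positive_class: str

    @property
    def n(self) -> int:
        return self.tp + self.fp + self.fn + self.tn

    @property
    def precision(self) -> float | None:
        d = self.tp + self.fp
        return self.tp / d if d else UNDEFINED

    @property
    def recall(self) -> float | None:
        d = self.tp + self.fn
        return self.tp / d if d else UNDEFINED

    @property
    def f_score(self) -> float | None:
        p, r = self.precision, self.recall
        if p is UNDEFINED or r is UNDEFINED or (p + r) == 0:
            return UNDEFINED
        return 2 * p * r / (p + r)


def binary_counts(
    gold: Sequence[str], pred: Sequence[str], positive_value: str
) -> ConfusionCounts:
    """Confusion counts with ``positive_value`` against everything else."""
    if len(gold) != len(pred):
        raise AlignmentError(f"length mismatch: {len(gold)} gold vs {len(pred)} predicted")
    tp = fp = fn = tn = 0
    for g, p in zip(gold, pred):
        if p == positive_value:
            if g == positive_value:
                tp += 1
            else:
                fp += 1
        elif g == positive_value:
            fn += 1
        else:
            tn += 1
    return ConfusionCounts(tp, fp, fn, tn, positive_value)


def mention_key(record: Mapping[str, Any]) -> tuple:
    try:
        return tuple(record[f] for f in MENTION_KEY_FIELDS)
    except KeyError as exc:
        raise AlignmentError(f"annotation record missing key field {exc}") from None


def _align(
    gold: Sequence[Mapping[str, Any]], pred: Sequence[Mapping[str, Any]]
) -> list[tuple[Mapping[str, Any], Mapping[str, Any]]]:
    gold_by_key = {mention_key(r): r for r in gold}
    pred_by_key = {mention_key(r): r for r in pred}
    missing_in_pred = sorted(set(gold_by_key) - set(pred_by_key))
    missing_in_gold = sorted(set(pred_by_key) - set(gold_by_key))
    if missing_in_pred or missing_in_gold:
        raise AlignmentError(
            "gold/prediction mention sets differ; "
            f"missing in predictions: {missing_in_pred[:5]}, "
            f"missing in gold: {missing_in_gold[:5]}"
        )
    return [(gold_by_key[k], pred_by_key[k]) for k in sorted(gold_by_key)]


def score(
    gold: Sequence[Mapping[str, Any]],
    pred: Sequence[Mapping[str, Any]],
    property: str,
    positive_value: str,
) -> ConfusionCounts:
    """Score one property value one-vs-rest over aligned annotation records."""
    if property not in PROPERTY_VALUES:
        raise ValueError(f"unknown property '{property}'")
    pairs = _align(gold, pred)
    return binary_counts(
        [g[property] for g, _ in pairs], [p[property] for _, p in pairs], positive_value
    )


def evaluate(
    gold: Sequence[Mapping[str, Any]],
    pred: Sequence[Mapping[str, Any]],
    by_doc_type: bool = True,
) -> dict[str, dict[str, dict[str, dict[str, Any]]]]:
    """Full report: {doc_type: {property: {value: counts+metrics}}}.

    Doc types come from the gold records' ``doc_type`` field when present; an
    ``ALL`` block always aggregates everything (micro).
    """
    pairs = _align(gold, pred)
    groups: dict[str, list[tuple[Mapping[str, Any], Mapping[str, Any]]]] = {"ALL": pairs}
    if by_doc_type:
        for g, p in pairs:
            dt = g.get("doc_type")
            if dt is not None:
                groups.setdefault(dt, []).append((g, p))
    report: dict[str, dict[str, dict[str, dict[str, Any]]]] = {}
    for group, members in groups.items():
        report[group] = {}
        for prop, values in PROPERTY_VALUES.items():
            report[group][prop] = {}
            gold_vals = [g[prop] for g, _ in members]
            pred_vals = [p[prop] for _, p in members]
            for value in values:
                c = binary_counts(gold_vals, pred_vals, value)
                report[group][prop][value] = {
                    "tp": c.tp,
                    "fp": c.fp,
                    "fn": c.fn,
                    "tn": c.tn,
                    "precision": c.precision,
                    "recall": c.recall,
                    "f_score": c.f_score,
                }
    return report


def render_metric(value: float | None) -> str:
    return UNDEFINED_DISPLAY if value is UNDEFINED else f"{value:.4f}"


def render_report(report: Mapping[str, Any]) -> Any:
    """Replace UNDEFINED metrics by "-" recursively, for JSON output."""
    if isinstance(report, Mapping):
        return {k: render_report(v) for k, v in report.items()}
    if report is UNDEFINED:
        return UNDEFINED_DISPLAY
    return report


def cohens_kappa(labels_a: Sequence[Hashable], labels_b: Sequence[Hashable]) -> float | None:
    """Chance-corrected agreement with marginal-product expected agreement.

    Returns UNDEFINED when expected agreement is 1 (both annotators constant
    with the same label). Computed exactly with rationals, then floated.
    """
    if len(labels_a) != len(labels_b):
        raise AlignmentError(
            f"label sequences differ in length: {len(labels_a)} vs {len(labels_b)}"
        )
    n = len(labels_a)
    if n == 0:
        raise AlignmentError("cannot compute kappa on empty label sequences")
    agree = sum(1 for a, b in zip(labels_a, labels_b) if a == b)
    p_o = Fraction(agree, n)
    labels = set(labels_a) | set(labels_b)
    count_a = {lab: sum(1 for x in labels_a if x == lab) for lab in labels}
    count_b = {lab: sum(1 for x in labels_b if x == lab) for lab in labels}
    p_e = sum(
        (Fraction(count_a[lab], n) * Fraction(count_b[lab], n) for lab in labels),
        Fraction(0),
    )
    if p_e == 1:
        return UNDEFINED
    return float((p_o - p_e) / (1 - p_e))


#: Altman interpretation bands for kappa (upper bound inclusive)
_ALTMAN_BANDS = (
    (0.20, "poor"),
    (0.40, "fair"),
    (0.60, "moderate"),
    (0.80, "good"),
    (1.00, "very good"),
)


def agreement_band(kappa: float) -> str:
    """Altman qualitative band for a kappa in [-1, 1]."""
    if not -1 <= kappa <= 1:
        raise ValueError(f"kappa {kappa} outside [-1, 1]")
    for upper, band in _ALTMAN_BANDS:
        if kappa <= upper:
            return band
    return "very good"  # pragma: no cover — kappa == 1 caught above
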