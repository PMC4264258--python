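# contextd

Rule-based annotation of **contextual properties** for medical terms in Dutch
clinical text. Given documents with pre-marked terms, `contextd` assigns each
mention three labels:

* **negation** — `Negated` / `NotNegated`
* **temporality** — `Recent` / `Historical` / `Hypothetical`
* **experiencer** — `Patient` / `Other`

The engine scans sentences for role-typed trigger phrases (pre, post, pseudo,
termination), resolves each trigger's scope against a document-type profile
(GP entries: 6-word scopes with comma/semicolon terminators; specialist
letters: 10 words with colon/semicolon; radiology and discharge letters:
sentence-end scopes), and applies document-specific refinements: a GP
minus-sign shorthand rule (`koorts-` ⇒ negated), combined pre+post trigger
rules (`nooit … doorgemaakt`), and a regex temporality module with windowed
patterns, a two-week recency bound and relational-operator guards.

Two trigger configurations ship with the package: `paper-final` (the curated
final trigger set) and `extended` (plus error-analysis additions such as
`blanco voor` and hypothetical `bij`). Both are plain TSV files under
`src/contextd/data/` and fully user-replaceable.

## CLI

```bash
# generate a synthetic gold-annotated corpus (deterministic per seed)
contextd generate --out-docs docs.jsonl --out-gold gold.jsonl --seed 42 --size 1000

# annotate documents
contextd annotate --docs docs.jsonl --terms terms.txt \
    --profile paper-final --out ann.jsonl --manifest manifest.json

# score against gold (one-vs-rest P/R/F per property value, per doc type)
contextd evaluate --gold gold.jsonl --pred ann.jsonl --out report.json

# inter-annotator agreement (per-value Cohen's kappa)
contextd kappa --a annA.jsonl --b annB.jsonl --property negation

# lexicon diagnostics and trigger firing counts
contextd lexicon-validate --profile paper-final
contextd trigger-report --annotations ann.jsonl
```

Exit codes: `0` success, `2` input error, `3` configuration error.

### File formats

* **Documents** — JSON Lines: `{"id": ..., "doc_type": "GP|SP|RD|DL",
  "text": ...}` (optional `reference_year` enables year-based temporal
  patterns).
* **Term list** — plain text, one term per line, `#` comments allowed;
  matching is case-insensitive, exact, and token-boundary aligned.
* **Annotations / gold** — JSON Lines, one object per mention with
  `doc_id, doc_type, sentence_index, char_start, char_end, term, negation,
  temporality, experiencer, evidence`. All offsets are 0-based, half-open and
  document-relative.
* **Trigger lexicon** — TSV with header
  `phrase  property  role  doc_types  max_scope_tokens  note`; combined rules
  in a second TSV (`pre_phrase  post_phrase  property  value
  max_span_tokens  doc_types`); temporal patterns in YAML (see
  `src/contextd/data/temporal_patterns.yaml`).

## Library use

```python
from contextd import apply_context, match_concepts, Sentence, DocumentProfile
from contextd import profiles

lex = profiles.default_lexicon("paper-final")
sentence = Sentence.from_text("geen teken van sinusitis")
mentions = match_concepts(sentence, ["sinusitis"])
[ann] = apply_context(sentence, mentions, lex,
                      rules=profiles.default_combined_rules(),
                      profile=DocumentProfile.for_doc_type("GP"),
                      temporal_patterns=profiles.default_temporal_patterns())
print(ann.negation)   # "Negated"
```

## Synthetic corpus

`contextd.synthcorpus` generates deterministic gold-labelled corpora from
sentence templates (exact class quotas per document type, defaults mirroring
realistic clinical label mixtures), plus an adversarial template suite that
encodes documented failure modes (missing triggers, pseudo-trigger
lookalikes, out-of-scope placements, terminator interposition, guarded
temporal expressions). These drive the round-trip and ablation tests.

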