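import pytest

from contextd import profiles
from contextd.engine import DocumentProfile, apply_context
from contextd.textprep import Sentence, match_concepts


@pytest.fixture(scope="session")
def paper_lexicon():
    return profiles.default_lexicon("paper-final")


@pytest.fixture(scope="session")
def extended_lexicon():
    return profiles.default_lexicon("extended")


@pytest.fixture(scope="session")
def combined_rules():
    return profiles.default_combined_rules()


@pytest.fixture(scope="session")
def temporal_patterns():
    return profiles.default_temporal_patterns()


@pytest.fixture(scope="session")
def annotate_one(paper_lexicon, combined_rules, temporal_patterns):
    """Annotate a single term in a single sentence; returns the annotation."""

    def _run(text, term, doc_type="GP", lex=None, rules=None, patterns=None, profile=None):
        sentence = Sentence.from_text(text)
        mentions = match_concepts(sentence, [term])
        assert mentions, f"term {term!r} not found in {text!r}"
        anns = apply_context(
            sentence,
            mentions,
            lex if lex is not None else paper_lexicon,
            rules=combined_rules if rules is None else rules,
            profile=profile or DocumentProfile.for_doc_type(doc_type),
            temporal_patterns=temporal_patterns if patterns is None else patterns,
        )
        return anns[0]

    return _run
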