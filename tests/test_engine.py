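import pytest
from hypothesis import given, settings
from hypothesis import strategies as st

from contextd.engine import (
    DocumentProfile,
    EngineError,
    Experiencer,
    Negation,
    Temporality,
    TriggerOccurrence,
    apply_context,
    find_triggers,
    resolve_scope,
)
from contextd.lexicon import (
    CombinedTriggerRule,
    ContextProperty,
    TriggerEntry,
    TriggerLexicon,
    TriggerRole,
)
from contextd.textprep import ConceptMention, Sentence, is_punct_token, match_concepts

NEG = ContextProperty.NEGATION


def lex_of(*entries):
    return TriggerLexicon(tuple(entries))


def entry(phrase, prop=NEG, role=TriggerRole.PRE, **kw):
    return TriggerEntry(phrase, prop, role, **kw)


def mention_for(sentence, term):
    mentions = match_concepts(sentence, [term])
    assert mentions
    return mentions


class TestProfiles:
    def test_parameters(self):
        gp = DocumentProfile.for_doc_type("GP")
        sp = DocumentProfile.for_doc_type("SP")
        rd = DocumentProfile.for_doc_type("RD")
        dl = DocumentProfile.for_doc_type("DL")
        assert gp.default_scope_tokens == 6
        assert sp.default_scope_tokens == 10
        assert rd.default_scope_tokens is None and dl.default_scope_tokens is None
        assert {",", ";"} <= gp.punctuation_terminators
        assert {":", ";"} <= sp.punctuation_terminators
        assert gp.gp_minus_rule_active
        assert not (sp.gp_minus_rule_active or rd.gp_minus_rule_active or dl.gp_minus_rule_active)

    def test_unknown_doc_type(self):
        with pytest.raises(EngineError, match="unknown doc_type"):
            DocumentProfile.for_doc_type("XX")

    def test_minus_rule_gp_only(self):
        with pytest.raises(EngineError):
            DocumentProfile("SP", 10, frozenset(), gp_minus_rule_active=True)


class TestFindTriggers:
    def test_geen_found_at_token_zero(self):
        s = Sentence.from_text("geen teken van koorts")
        occs = find_triggers(s, lex_of(entry("geen")), "GP")
        assert len(occs) == 1
        assert occs[0].token_start == 0 and occs[0].entry.phrase == "geen"

    def test_pseudo_masks_contained_pre(self):
        s = Sentence.from_text("niet minder krampen")
        lex = lex_of(entry("niet"), entry("niet minder", role=TriggerRole.PSEUDO))
        occs = find_triggers(s, lex, "GP")
        assert len(occs) == 1
        assert occs[0].entry.role is TriggerRole.PSEUDO

    def test_longest_match_within_role(self):
        s = Sentence.from_text("geen teken van koorts")
        lex = lex_of(entry("geen"), entry("geen teken van"))
        occs = find_triggers(s, lex, "GP")
        assert [o.entry.phrase for o in occs] == ["geen teken van"]

    def test_no_lexicon_phrase(self):
        s = Sentence.from_text("alles rustig vandaag")
        assert find_triggers(s, lex_of(entry("geen")), "GP") == []

    def test_doc_type_filter(self):
        s = Sentence.from_text("geen koorts")
        lex = lex_of(entry("geen", doc_types=frozenset({"SP"})))
        assert find_triggers(s, lex, "GP") == []
        assert len(find_triggers(s, lex, "SP")) == 1

    def test_ordered_left_to_right(self):
        s = Sentence.from_text("geen koorts en geen hoest")
        occs = find_triggers(s, lex_of(entry("geen")), "GP")
        assert [o.token_start for o in occs] == [0, 3]


class TestResolveScope:
    def make(self, n_tokens, trigger_at, role=TriggerRole.PRE, phrase="trig"):
        words = ["w%d" % i for i in range(n_tokens)]
        words[trigger_at] = phrase
        s = Sentence.from_text(" ".join(words))
        e = entry(phrase, role=role)
        t = s.tokens[trigger_at]
        occ = TriggerOccurrence(e, trigger_at, trigger_at + 1, t.char_start, t.char_end)
        return s, occ

    def test_rd_pre_extends_to_sentence_end(self):
        s, occ = self.make(8, 0)
        assert resolve_scope(occ, s, DocumentProfile.for_doc_type("RD")) == (1, 8)

    def test_gp_pre_capped_at_six_words(self):
        s, occ = self.make(12, 0)
        assert resolve_scope(occ, s, DocumentProfile.for_doc_type("GP")) == (1, 7)

    def test_gp_comma_terminates(self):
        s = Sentence.from_text("geen koorts , wel hoest")
        e = entry("geen")
        occ = TriggerOccurrence(e, 0, 1, 0, 4)
        start, end = resolve_scope(occ, s, DocumentProfile.for_doc_type("GP"))
        covered = [t.surface for t in s.tokens[start:end]]
        assert covered == ["koorts"]

    def test_post_mirror(self):
        s, occ = self.make(8, 7, role=TriggerRole.POST)
        assert resolve_scope(occ, s, DocumentProfile.for_doc_type("RD")) == (0, 7)
        assert resolve_scope(occ, s, DocumentProfile.for_doc_type("GP")) == (1, 7)

    def test_entry_max_scope_overrides_profile(self):
        s, occ = self.make(8, 0)
        occ = TriggerOccurrence(
            entry("w0", max_scope_tokens=2), 0, 1, occ.char_start, occ.char_end
        )
        assert resolve_scope(occ, s, DocumentProfile.for_doc_type("RD")) == (1, 3)

    def test_lexicon_terminator_same_property_only(self):
        s = Sentence.from_text("geen koorts maar hoest")
        pre = TriggerOccurrence(entry("geen"), 0, 1, 0, 4)
        term_neg = TriggerOccurrence(
            entry("maar", role=TriggerRole.TERMINATION), 2, 3, 12, 16
        )
        term_other = TriggerOccurrence(
            entry("maar", prop=ContextProperty.HISTORICAL, role=TriggerRole.TERMINATION),
            2, 3, 12, 16,
        )
        profile = DocumentProfile.for_doc_type("RD")
        assert resolve_scope(pre, s, profile, [term_neg]) == (1, 2)
        assert resolve_scope(pre, s, profile, [term_other]) == (1, 4)

    def test_no_scope_for_pseudo(self):
        s, occ = self.make(4, 0, role=TriggerRole.PSEUDO)
        with pytest.raises(EngineError, match="no scope for role pseudo"):
            resolve_scope(occ, s, DocumentProfile.for_doc_type("GP"))

    def test_terminator_monotonicity(self):
        # adding a termination occurrence never enlarges a scope
        for n in range(2, 10):
            for trig in range(n):
                for role in (TriggerRole.PRE, TriggerRole.POST):
                    s, occ = self.make(n, trig, role=role)
                    profile = DocumentProfile.for_doc_type("GP")
                    base = resolve_scope(occ, s, profile)
                    for tpos in range(n):
                        if tpos == trig:
                            continue
                        t = s.tokens[tpos]
                        term = TriggerOccurrence(
                            entry(t.surface, role=TriggerRole.TERMINATION),
                            tpos, tpos + 1, t.char_start, t.char_end,
                        )
                        cut = resolve_scope(occ, s, profile, [term])
                        assert cut[0] >= base[0] and cut[1] <= base[1]


class TestApplyContext:
    def test_defaults_with_empty_lexicon(self):
        s = Sentence.from_text("patient heeft koorts en hoest")
        mentions = match_concepts(s, ["koorts", "hoest"])
        anns = apply_context(s, mentions, lex_of(), profile=DocumentProfile.for_doc_type("GP"))
        for ann in anns:
            assert ann.negation == Negation.NOT_NEGATED.value
            assert ann.temporality == Temporality.RECENT.value
            assert ann.experiencer == Experiencer.PATIENT.value
            assert ann.evidence == []

    def test_negation_within_scope(self):
        s = Sentence.from_text("geen koorts")
        anns = apply_context(
            s, mention_for(s, "koorts"), lex_of(entry("geen")),
            profile=DocumentProfile.for_doc_type("GP"),
        )
        assert anns[0].negation == Negation.NEGATED.value
        assert anns[0].evidence[0].phrase_or_rule == "geen"

    def test_mention_beyond_gp_scope_untouched(self):
        words = "geen " + " ".join(f"w{i}" for i in range(8)) + " koorts"
        s = Sentence.from_text(words)
        anns = apply_context(
            s, mention_for(s, "koorts"), lex_of(entry("geen")),
            profile=DocumentProfile.for_doc_type("GP"),
        )
        assert anns[0].negation == Negation.NOT_NEGATED.value

    def test_left_to_right_overwrite(self):
        # second trigger's scope also covers the mention: last writer wins
        s = Sentence.from_text("geen aanwijzing zonder koorts")
        lex = lex_of(entry("geen"), entry("zonder"))
        anns = apply_context(
            s, mention_for(s, "koorts"), lex, profile=DocumentProfile.for_doc_type("RD")
        )
        assert anns[0].negation == Negation.NEGATED.value
        assert [e.phrase_or_rule for e in anns[0].evidence] == ["zonder"]

    def test_mention_overlapping_trigger_not_negated(self):
        # degenerate lexicon/term collision: a trigger cannot negate a
        # mention it overlaps (here the term list contains "geen koorts")
        s = Sentence.from_text("geen koorts")
        lex = lex_of(entry("geen"))
        mentions = match_concepts(s, ["geen koorts"])
        assert mentions[0].token_start == 0 and mentions[0].token_end == 2
        anns = apply_context(s, mentions, lex, profile=DocumentProfile.for_doc_type("RD"))
        assert anns[0].negation == Negation.NOT_NEGATED.value

    def test_mention_out_of_bounds_rejected(self):
        s = Sentence.from_text("geen koorts")
        bad = ConceptMention("x", 5, 99, 0, 1)
        with pytest.raises(EngineError, match="outside sentence bounds"):
            apply_context(s, [bad], lex_of(), profile=DocumentProfile.for_doc_type("GP"))

    def test_experiencer_and_temporality_independent(self, annotate_one):
        ann = annotate_one("moeder heeft status na koorts", "koorts", "DL")
        assert ann.experiencer == Experiencer.OTHER.value
        assert ann.temporality == Temporality.HISTORICAL.value
        assert ann.negation == Negation.NOT_NEGATED.value

    def test_stability_under_rerun(self, paper_lexicon, combined_rules, temporal_patterns):
        s = Sentence.from_text("geen koorts , status na hoest")
        mentions = match_concepts(s, ["koorts", "hoest"])
        profile = DocumentProfile.for_doc_type("GP")
        first = apply_context(
            s, mentions, paper_lexicon, combined_rules, profile, temporal_patterns
        )
        second = apply_context(
            s, mentions, paper_lexicon, combined_rules, profile, temporal_patterns
        )
        assert first == second

    def test_sentence_isolation(self, paper_lexicon):
        # annotations depend only on the sentence the mention is in
        s1 = Sentence.from_text("wel koorts aanwezig")
        anns = apply_context(
            s1, mention_for(s1, "koorts"), paper_lexicon,
            profile=DocumentProfile.for_doc_type("GP"),
        )
        assert anns[0].negation == Negation.NOT_NEGATED.value


class TestGpMinusRule:
    def test_attached_minus(self, annotate_one):
        assert annotate_one("koorts-", "koorts", "GP").negation == Negation.NEGATED.value

    def test_spaced_minus(self, annotate_one):
        ann = annotate_one("koorts -", "koorts", "GP")
        assert ann.negation == Negation.NEGATED.value
        assert ann.evidence[0].phrase_or_rule == "gp-minus"

    def test_inactive_outside_gp(self, annotate_one):
        assert annotate_one("koorts-", "koorts", "DL").negation == Negation.NOT_NEGATED.value

    def test_hyphen_joining_word_untouched(self, annotate_one):
        ann = annotate_one("koorts-achtig beeld bij koorts", "koorts", "GP")
        # first "koorts" is inside "koorts-achtig", not a token-boundary match;
        # the standalone mention is not followed by a minus
        assert ann.negation == Negation.NOT_NEGATED.value

    def test_minus_then_punctuation(self, annotate_one):
        assert annotate_one("koorts- , hoest", "koorts", "GP").negation == Negation.NEGATED.value


class TestCombinedRules:
    def test_pre_and_post_fire(self, annotate_one):
        ann = annotate_one("Nooit urineweginfecties doorgemaakt", "urineweginfecties", "DL")
        assert ann.negation == Negation.NEGATED.value
        assert all("combined:nooit+doorgemaakt" == e.phrase_or_rule for e in ann.evidence)
        assert len(ann.evidence) == 2

    def test_pre_alone_does_not_fire(self, annotate_one):
        ann = annotate_one("Nooit urineweginfecties", "urineweginfecties", "DL")
        assert ann.negation == Negation.NOT_NEGATED.value

    def test_span_gate(self):
        filler = " ".join(f"w{i}" for i in range(25))
        s = Sentence.from_text(f"nooit {filler} koorts doorgemaakt")
        rule = CombinedTriggerRule("nooit", "doorgemaakt", NEG, "Negated", 10)
        anns = apply_context(
            s, mention_for(s, "koorts"), lex_of(), rules=[rule],
            profile=DocumentProfile.for_doc_type("DL"),
        )
        assert anns[0].negation == Negation.NOT_NEGATED.value

    def test_profile_gate(self):
        s = Sentence.from_text("nooit koorts doorgemaakt")
        rule = CombinedTriggerRule("nooit", "doorgemaakt", NEG, "Negated", 10)
        profile = DocumentProfile("DL", None, frozenset(), False, combined_rules_active=False)
        anns = apply_context(s, mention_for(s, "koorts"), lex_of(), rules=[rule], profile=profile)
        assert anns[0].negation == Negation.NOT_NEGATED.value
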