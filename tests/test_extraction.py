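import pytest

from genx.corpus_io import TrialRecord
from genx.extraction import (
    LexiconError,
    MentionLexicon,
    Polarity,
    Provenance,
    apply_section_logic,
    compose_mentions,
    extract_sentence,
    extract_trial,
    match_lexicon,
    segment_criteria,
    verify_mentions,
)
from genx.gender_model import CompositeLabel
from genx.pattern_learning import Pattern
from genx.preprocessing import Section

BIRTH_PATTERN = Pattern(("female", "at", "birth", ","), (",", "will", "not"), 5, 1.0)
BIRTH_TEXT = (
    "Participants who were female at birth, who now identify as male, "
    "will not be excluded."
)


class TestLexicon:
    def test_sex_lists_disjoint(self, rules):
        male = set(rules.lexicon.features["Male"])
        female = set(rules.lexicon.features["Female"])
        assert not (male & female)

    def test_all_expected_types_present(self, rules):
        assert set(rules.lexicon.features) >= {
            "Male",
            "Female",
            "Two_Gender",
            "Biological",
            "Transgender",
            "Male_Abbreviation",
            "Partner",
            "Negation_Word",
        }

    def test_empty_feature_list_rejected(self):
        with pytest.raises(LexiconError):
            MentionLexicon({"Male": []})

    def test_uppercase_feature_rejected(self):
        with pytest.raises(LexiconError):
            MentionLexicon({"Male": ["Man"]})

    def test_overlapping_sex_features_rejected(self):
        with pytest.raises(LexiconError):
            MentionLexicon({"Male": ["person"], "Female": ["person"]})


class TestMatchLexicon:
    def test_msm_sentence(self, rules, make_sentence):
        s = make_sentence("men who have sex with men (msm)")
        hits = match_lexicon(s, rules.lexicon)
        assert [(h.mention_type, h.surface) for h in hits] == [
            ("Male", "men"),
            ("Male", "men"),
            ("Male_Abbreviation", "msm"),
        ]

    def test_longest_match_first(self, rules, make_sentence):
        s = make_sentence("both genders welcome")
        hits = match_lexicon(s, rules.lexicon)
        assert [h.mention_type for h in hits] == ["Two_Gender"]

    def test_no_features(self, rules, make_sentence):
        s = make_sentence("placebo-controlled study")
        assert match_lexicon(s, rules.lexicon) == []

    def test_multiword_negation_trigger(self, rules, make_sentence):
        s = make_sentence("does not identify as female")
        hits = match_lexicon(s, rules.lexicon)
        assert ("Negation_Word", "not identify as") in [
            (h.mention_type, h.surface) for h in hits
        ]


class TestComposeMentions:
    def _compose(self, rules, sentence):
        return compose_mentions(match_lexicon(sentence, rules.lexicon), sentence, rules)

    def test_transgender_woman(self, rules, make_sentence):
        s = make_sentence("Self identify as a transgender woman")
        (m,) = self._compose(rules, s)
        assert m.composite is CompositeLabel.TRANSGENDER_FEMALE
        assert m.surface == "transgender woman"

    def test_biologically_male(self, rules, make_sentence):
        s = make_sentence("Biologically male (not transgendered)")
        composites = {m.composite for m in self._compose(rules, s)}
        assert CompositeLabel.BIOLOGICAL_MALE in composites

    def test_bare_transgender_is_all(self, rules, make_sentence):
        s = make_sentence("transgender participants")
        (m,) = self._compose(rules, s)
        assert m.composite is CompositeLabel.TRANSGENDER_ALL

    def test_either_order_composition(self, rules, make_sentence):
        s = make_sentence("female transgender adults")
        (m,) = self._compose(rules, s)
        assert m.composite is CompositeLabel.TRANSGENDER_FEMALE

    def test_gap_tolerated(self, rules, make_sentence):
        s = make_sentence("transgender or transitioned woman")
        mentions = self._compose(rules, s)
        assert mentions[0].composite is CompositeLabel.TRANSGENDER_FEMALE

    def test_abbreviation_maps_to_male(self, rules, make_sentence):
        s = make_sentence("ymsm cohort")
        (m,) = self._compose(rules, s)
        assert m.composite is CompositeLabel.BIOLOGICAL_MALE

    def test_consumed_hits_not_reused(self, rules, make_sentence):
        s = make_sentence("transgender woman and woman")
        mentions = self._compose(rules, s)
        assert [m.composite for m in mentions] == [
            CompositeLabel.TRANSGENDER_FEMALE,
            CompositeLabel.BIOLOGICAL_FEMALE,
        ]


class TestVerifyMentions:
    def _verified(self, rules, sentence):
        hits = match_lexicon(sentence, rules.lexicon)
        return verify_mentions(compose_mentions(hits, sentence, rules), hits, sentence, rules)

    def test_male_sex_partners_irrelevant(self, rules, make_sentence):
        s = make_sentence("male sex partners")
        (m,) = self._verified(rules, s)
        assert m.polarity is Polarity.IRRELEVANT

    def test_partner_context_spares_subject(self, rules, make_sentence):
        s = make_sentence("Male Patients with female sexual partners")
        male, female = self._verified(rules, s)
        assert male.composite is CompositeLabel.BIOLOGICAL_MALE
        assert male.polarity is Polarity.ASSERTED
        assert female.composite is CompositeLabel.BIOLOGICAL_FEMALE
        assert female.polarity is Polarity.IRRELEVANT

    def test_negated_transgender(self, rules, make_sentence):
        s = make_sentence("Biologically male (not transgendered)")
        by_comp = {m.composite: m for m in self._verified(rules, s)}
        assert by_comp[CompositeLabel.BIOLOGICAL_MALE].polarity is Polarity.ASSERTED
        neg = by_comp[CompositeLabel.TRANSGENDER_ALL]
        assert neg.polarity is Polarity.NEGATED
        assert neg.negation_trigger is not None

    def test_negation_prefers_following_mention(self, rules, make_sentence):
        s = make_sentence("males not females")
        by_comp = {m.composite: m for m in self._verified(rules, s)}
        assert by_comp[CompositeLabel.BIOLOGICAL_MALE].polarity is Polarity.ASSERTED
        assert by_comp[CompositeLabel.BIOLOGICAL_FEMALE].polarity is Polarity.NEGATED

    def test_negation_window_limit(self, rules, make_sentence):
        s = make_sentence("no history of cardiac disease in enrolled adult males")
        (m,) = self._verified(rules, s)
        assert m.polarity is Polarity.ASSERTED

    def test_verification_never_increases_asserted(self, rules, make_sentence):
        texts = [
            "male sex partners",
            "Biologically male (not transgendered)",
            "transgender women and their partners",
            "adult males are eligible",
        ]
        for text in texts:
            s = make_sentence(text)
            hits = match_lexicon(s, rules.lexicon)
            before = compose_mentions(hits, s, rules)
            n_before = sum(m.polarity is Polarity.ASSERTED for m in before)
            after = verify_mentions(before, hits, s, rules)
            assert sum(m.polarity is Polarity.ASSERTED for m in after) <= n_before


class TestSectionLogic:
    def _mention(self, make_sentence, section, polarity):
        s = make_sentence("transgender adults", section=section)
        (m,) = compose_mentions(
            match_lexicon(s, __import__("genx.extraction", fromlist=["default_rules"]).default_rules().lexicon),
            s,
        )
        m.polarity = polarity
        return m

    def test_asserted_flips_in_exclusion(self, rules, make_sentence):
        m = self._mention(make_sentence, Section.EXCLUSION, Polarity.ASSERTED)
        apply_section_logic([m])
        assert m.polarity is Polarity.NEGATED

    def test_double_negation_in_exclusion(self, rules, make_sentence):
        m = self._mention(make_sentence, Section.EXCLUSION, Polarity.NEGATED)
        apply_section_logic([m])
        assert m.polarity is Polarity.ASSERTED

    def test_description_unchanged(self, rules, make_sentence):
        m = self._mention(make_sentence, Section.DESCRIPTION, Polarity.ASSERTED)
        apply_section_logic([m])
        assert m.polarity is Polarity.ASSERTED

    def test_irrelevant_unchanged_in_exclusion(self, rules, make_sentence):
        m = self._mention(make_sentence, Section.EXCLUSION, Polarity.IRRELEVANT)
        apply_section_logic([m])
        assert m.polarity is Polarity.IRRELEVANT


class TestSegmentCriteria:
    def test_header_partition(self, rules):
        text = (
            "General notes first.\nInclusion Criteria:\n- Adults.\n"
            "Exclusion Criteria:\n- Children."
        )
        parts = segment_criteria(text, rules)
        assert "General notes" in parts[Section.OTHER]
        assert "Adults" in parts[Section.INCLUSION]
        assert "Children" in parts[Section.EXCLUSION]

    def test_no_headers_is_other(self, rules):
        parts = segment_criteria("just some text", rules)
        assert parts[Section.OTHER] == "just some text"
        assert parts[Section.INCLUSION] == ""


class TestExtractTrial:
    def test_birth_pattern_double_negation(self, rules):
        trial = TrialRecord("NCT1", exclusion=BIRTH_TEXT)
        mentions = extract_trial(trial, [BIRTH_PATTERN], rules)
        tg = [m for m in mentions if m.composite is CompositeLabel.TRANSGENDER_MALE]
        assert len(tg) == 1
        assert tg[0].polarity is Polarity.ASSERTED
        assert tg[0].provenance is Provenance.PATTERN
        assert tg[0].surface == "who now identify as male"

    def test_rule_only_trial(self, rules):
        trial = TrialRecord("NCT2", inclusion="Inclusion: adult males.")
        mentions = extract_trial(trial, None, rules)
        asserted = [m for m in mentions if m.polarity is Polarity.ASSERTED]
        assert [m.composite for m in asserted] == [CompositeLabel.BIOLOGICAL_MALE]

    def test_empty_trial(self, rules):
        assert extract_trial(TrialRecord("NCT3"), None, rules) == []

    def test_rule_and_pattern_same_span_provenance_both(self, rules):
        pattern = Pattern(("are",), (".",), 5, 1.0)
        trial = TrialRecord("NCT4", inclusion="participants are transgender women.")
        mentions = extract_trial(trial, [pattern], rules)
        (m,) = [x for x in mentions if x.composite is CompositeLabel.TRANSGENDER_FEMALE]
        assert m.provenance is Provenance.BOTH

    def test_removing_patterns_only_loses_mentions(self, rules):
        trial = TrialRecord(
            "NCT5",
            description="The study recruits transgender women.",
            exclusion=BIRTH_TEXT,
        )
        with_p = extract_trial(trial, [BIRTH_PATTERN], rules)
        without_p = extract_trial(trial, None, rules)
        keyed_with = {
            (m.section, m.sentence_index, m.start, m.end): m.polarity
            for m in with_p
            if m.provenance is not Provenance.PATTERN
        }
        for m in without_p:
            key = (m.section, m.sentence_index, m.start, m.end)
            if key in keyed_with:
                assert keyed_with[key] == m.polarity

    def test_output_sorted_and_deterministic(self, rules):
        trial = TrialRecord(
            "NCT6",
            description="Transgender women are welcome. Adult males are not eligible.",
            inclusion="Inclusion: cisgender women.",
            exclusion="Exclusion: pregnant women.",
        )
        a = extract_trial(trial, None, rules)
        b = extract_trial(trial, None, rules)
        assert [m.to_dict() for m in a] == [m.to_dict() for m in b]
        keys = [(m.section.value, m.sentence_index, m.start) for m in a]
        order = {s.value: i for i, s in enumerate(
            [Section.DESCRIPTION, Section.OTHER, Section.INCLUSION, Section.EXCLUSION]
        )}
        assert keys == sorted(keys, key=lambda k: (order[k[0]], k[1], k[2]))
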