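"""Feature extraction: lexicon scoring, readability, concreteness, entities
and the composite style scores."""

import math

import pytest

import oracles
from veristyle.corpus import ConfigurationError, DataError, Statement, tokenize
from veristyle.resources import (CategoryLexicon, ConcretenessTable,
                                 EntityAnnotation, identity_lemmatizer)
from veristyle.stylometry import (FEATURE_NAMES, composite_features,
                                  concreteness_score, entity_counts,
                                  extract_style_vector, readability_block,
                                  score_lexicon, split_sentences)


class TestScoreLexicon:
    def test_hand_counted_percentage(self):
        lex = CategoryLexicon({"i": {"i", "me", "my"}})
        scores = score_lexicon(["i", "lost", "my", "keys", "yesterday"], lex)
        assert scores["i"] == 40.0

    def test_no_hits_scores_zero(self):
        lex = CategoryLexicon({"empty_match": {"zzz"}})
        assert score_lexicon(["alpha", "beta"], lex)["empty_match"] == 0.0

    def test_prefix_wildcard_semantics(self):
        lex = CategoryLexicon({"motion": {"run*"}})
        assert score_lexicon(["running", "ran"], lex)["motion"] == 50.0

    def test_case_insensitive_and_full_coverage_is_100(self):
        lex = CategoryLexicon({"all": {"alpha", "beta"}})
        assert score_lexicon(["Alpha", "BETA", "beta"], lex)["all"] == 100.0

    def test_empty_token_list_is_an_error(self):
        lex = CategoryLexicon({"i": {"i"}})
        with pytest.raises(DataError):
            score_lexicon([], lex)

    def test_matches_naive_counter_on_fixture_lexicon(self, resources):
        text = ("I went to the market with Mary. We thought the bright "
                "harbor looked wonderful, but he never believed my story.")
        tokens = tokenize(text)
        raw = {name: set(entries)
               for name, entries in resources.lexicon.categories.items()}
        expected = oracles.naive_category_percentages(tokens, raw)
        assert score_lexicon(tokens, resources.lexicon) == pytest.approx(expected)


class TestReadability:
    def test_hand_worked_flesch_values(self):
        block = readability_block("The cat sat.")
        assert (block.num_words, block.num_sentences, block.num_syllables) == (3, 1, 3)
        assert block.fk_read == pytest.approx(119.19, abs=0.01)
        assert block.fk_grade == pytest.approx(-2.62, abs=0.01)

    def test_doubling_text_preserves_the_indices(self):
        text = "The harbor was quiet at night. We walked home slowly."
        one = readability_block(text)
        two = readability_block(text + " " + text)
        assert two.fk_grade == pytest.approx(one.fk_grade)
        assert two.fk_read == pytest.approx(one.fk_read)
        assert two.num_words == 2 * one.num_words

    def test_degenerate_one_word_sentences(self):
        block = readability_block("Go. Go. Go.")
        assert block.num_sentences == 3
        assert block.num_words == 3
        assert block.avg_syllabes_per_word == 1.0

    def test_abbreviations_do_not_split(self):
        assert len(split_sentences("Dr. Smith arrived. He sat down.")) == 2

    def test_empty_text_is_an_error(self):
        with pytest.raises(DataError):
            readability_block("...")


class TestConcreteness:
    TABLE = ConcretenessTable({"apple": 5.0, "idea": 1.5})

    def test_mean_of_matched_words(self):
        score, n = concreteness_score("An apple idea!", self.TABLE,
                                      frozenset({"an"}), identity_lemmatizer)
        assert score == pytest.approx(3.25)
        assert n == 2

    def test_all_unmatched_is_undefined_not_zero(self):
        score, n = concreteness_score("entirely unknown words", self.TABLE,
                                      frozenset(), identity_lemmatizer)
        assert score is None and n == 0

    def test_case_folding(self):
        score, n = concreteness_score("APPLE apple", self.TABLE,
                                      frozenset(), identity_lemmatizer)
        assert score == 5.0 and n == 2

    def test_lemmatizer_is_applied(self):
        score, _ = concreteness_score(
            "apples", self.TABLE, frozenset(),
            lambda w: w[:-1] if w.endswith("s") else w)
        assert score == 5.0


class TestEntityCounts:
    def test_uniqueness_under_case_folding(self):
        annotations = [EntityAnnotation("Mary", "People"),
                       EntityAnnotation("mary", "People"),
                       EntityAnnotation("Tokyo", "Spatial")]
        counts = entity_counts("", lambda text: annotations)
        assert counts == {"People": 1, "Temporal_details": 0,
                          "Spatial_details": 1, "Quantity_details": 0}

    def test_no_annotations(self):
        counts = entity_counts("", lambda text: [])
        assert set(counts.values()) == {0}

    def test_distinct_quantity_exemplars(self):
        annotations = [EntityAnnotation("20%", "Quantity"),
                       EntityAnnotation("5 $", "Quantity"),
                       EntityAnnotation("ten", "Quantity")]
        assert entity_counts("", lambda text: annotations)["Quantity_details"] == 3

    def test_stub_recognizer_patterns(self, resources):
        counts = entity_counts(
            "Mary met Paul in Tokyo on Monday at 2:30 PM; tickets cost 5 $ "
            "which is 20% more.", resources.recognizer)
        assert counts["People"] == 2
        assert counts["Spatial_details"] == 1
        assert counts["Temporal_details"] == 2  # Monday and '2:30 pm'
        assert counts["Quantity_details"] == 2  # '5 $' and '20%'


class TestComposites:
    BASE = {name: 0.0 for name in
            ("i", "we", "shehe", "they", "you", "attention", "visual",
             "auditory", "feeling", "space", "motion", "time", "Affect",
             "Cognition", "tone_pos", "tone_neg", "article", "prep", "ppron",
             "ipron", "auxverb", "conj", "adverb", "negate")}

    def test_reference_sums(self):
        c = composite_features({**self.BASE, "i": 40.0})
        assert c["Self_reference"] == 40.0
        c = composite_features({**self.BASE, "shehe": 1.0, "they": 2.0,
                                "you": 3.0})
        assert c["Other_reference"] == 6.0

    def test_reality_monitoring_arithmetic(self):
        c = composite_features({**self.BASE, "attention": 4.0, "visual": 6.0,
                                "space": 5.0, "Affect": 2.0, "Cognition": 3.0})
        assert c["Perceptual_details"] == 10.0
        assert c["Contextual_Embedding"] == 5.0
        assert c["Reality_Monitoring"] == 14.0

    def test_tone_standardization(self):
        c = composite_features({**self.BASE, "tone_pos": 4.0, "tone_neg": 2.0})
        assert c["Tone"] == pytest.approx(66.67, abs=0.01)
        c = composite_features({**self.BASE, "tone_pos": 3.0, "tone_neg": 3.0})
        assert c["Tone"] == 50.0
        assert composite_features(self.BASE)["Tone"] == 50.0

    def test_summary_scales_are_clamped(self):
        c = composite_features({**self.BASE, "ppron": 95.0, "auxverb": 40.0})
        assert c["Analytic"] == 0.0
        c = composite_features({**self.BASE, "i": 50.0, "we": 40.0})
        assert c["Authentic"] == 100.0

    def test_missing_category_names_the_culprit(self):
        broken = dict(self.BASE)
        del broken["ipron"]
        with pytest.raises(ConfigurationError, match="ipron"):
            composite_features(broken)


class TestExtractStyleVector:
    def _statement(self, text):
        return Statement(id="x", subject_id="s", domain="synthetic",
                         veracity="truthful", text=text)

    def test_hand_computed_vector_on_known_words(self, resources):
        # 10 word tokens: i, we (self-ref) / see, heard (perceptual) / the x2
        text = "I see the harbor. We heard the noise loudly yesterday."
        vec = extract_style_vector(self._statement(text), resources)
        assert vec["num_words"] == 10
        assert vec["num_sentences"] == 2
        assert vec["Self_reference"] == pytest.approx(20.0)
        assert vec["tone_pos"] == 0.0
        assert vec["focuspast"] == pytest.approx(10.0)  # 'yesterday'
        assert vec["Perceptual_details"] == pytest.approx(30.0)  # see, heard, noise
        assert set(vec) == set(FEATURE_NAMES)

    def test_determinism(self, resources):
        text = "We walked to the bright harbor and felt happy."
        st = self._statement(text)
        assert (extract_style_vector(st, resources)
                == extract_style_vector(st, resources))

    def test_degenerate_statement_flags_only_concreteness(self, resources):
        vec = extract_style_vector(self._statement("Zorp blick quens."),
                                   resources)
        assert math.isnan(vec["Concreteness_score"])
        assert vec["People"] == vec["Spatial_details"] == 0
        assert all(math.isfinite(vec[f]) for f in FEATURE_NAMES
                   if f != "Concreteness_score")

    def test_word_order_invariance_of_bag_features(self, resources):
        a = extract_style_vector(
            self._statement("I saw the bright harbor yesterday with Mary."),
            resources)
        b = extract_style_vector(
            self._statement("Yesterday with Mary I saw the harbor bright."),
            resources)
        order_sensitive = {"num_sentences", "fk_grade", "fk_read"}
        for f in FEATURE_NAMES:
            if f not in order_sensitive:
                assert a[f] == pytest.approx(b[f], nan_ok=True), f

    def test_percentage_bounds_and_rm_conservation(self, resources):
        text = ("I remember we watched the bright sunset near the harbor "
                "and felt so happy about it.")
        vec = extract_style_vector(self._statement(text), resources)
        for f in ("tone_pos", "tone_neg", "Cognition", "memory", "focuspast",
                  "focuspresent", "focusfuture", "Analytic", "Authentic",
                  "Tone"):
            assert 0.0 <= vec[f] <= 100.0
        # Reality Monitoring recomputed from its parts
        cats = score_lexicon(tokenize(text), resources.lexicon)
        rm = (vec["Perceptual_details"] + vec["Contextual_Embedding"]
              + cats["Affect"] - cats["Cognition"])
        assert vec["Reality_Monitoring"] == pytest.approx(rm)
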