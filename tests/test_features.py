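"""Word shape, POS tagging and fuzzy gazetteer lookup."""

import pytest
from hypothesis import given, settings
from hypothesis import strategies as st

from phitag.corpus import ConfigurationError, LabeledSequence, Token
from phitag.features import (Dictionary, KnowledgeFeatures, NO_FEATURES,
                             damerau_levenshtein, fuzzy_lookup, pos_tag,
                             word_shape)


class TestWordShape:
    @pytest.mark.parametrize("token,expected", [
        ("Smith", "Aaaaa|Aa"),
        ("32610", "00000|0"),
        ("H&P", "A&A|A&A"),
        ("McDonald", "AaAaaaaa|AaAa"),
        ("x", "a|a"),
    ])
    def test_mapping(self, token, expected):
        assert word_shape(token) == expected

    def test_empty_token_rejected(self):
        with pytest.raises(ValueError):
            word_shape("")


class TestPosTag:
    def test_common_words(self):
        assert pos_tag(["the", "patient"]) == ["DT", "NN"]

    def test_empty_sentence(self):
        assert pos_tag([]) == []

    def test_digits_and_punctuation(self):
        assert pos_tag(["81", ",", "Anderson"]) == ["CD", ",", "NNP"]

    @given(st.lists(st.text(
        alphabet=st.characters(codec="ascii", exclude_categories=("Cc", "Zs")),
        min_size=1, max_size=8), max_size=20))
    @settings(max_examples=300, deadline=None)
    def test_length_preserved_and_deterministic(self, tokens):
        tags = pos_tag(tokens)
        assert len(tags) == len(tokens)
        assert tags == pos_tag(tokens)


def _brute_within_one_edit(a: str, b: str) -> bool:
    """All strings within one edit (sub/ins/del/adjacent transposition)."""
    if a == b:
        return True
    alphabet = set(a) | set(b) | {"x"}
    variants = set()
    for i in range(len(a)):
        variants.add(a[:i] + a[i + 1:])                       # deletion
        for c in alphabet:
            variants.add(a[:i] + c + a[i + 1:])               # substitution
    for i in range(len(a) + 1):
        for c in alphabet:
            variants.add(a[:i] + c + a[i:])                   # insertion
    for i in range(len(a) - 1):
        variants.add(a[:i] + a[i + 1] + a[i] + a[i + 2:])     # transposition
    return b in variants


class TestEditDistance:
    @given(st.text(alphabet="abcd", max_size=6),
           st.text(alphabet="abcd", max_size=6))
    @settings(max_examples=500, deadline=None)
    def test_distance_le_one_matches_brute_force(self, a, b):
        assert (damerau_levenshtein(a, b) <= 1) \
            == _brute_within_one_edit(a, b)

    def test_transposition_counts_as_one(self):
        assert damerau_levenshtein("gainesville", "gainesivlle") == 1


@pytest.fixture()
def city_dict():
    return Dictionary("cities", "CITY", {"Gainesville", "New Berlin"})


class TestFuzzyLookup:
    def test_exact_match_case_insensitive(self, city_dict):
        for surface in ("Gainesville", "GAINESVILLE", "gainesville"):
            [kf] = fuzzy_lookup([surface], [city_dict])
            assert kf == KnowledgeFeatures("CITY", "B", "EXACT")

    def test_partial_match_one_edit(self, city_dict):
        [kf] = fuzzy_lookup(["Gainesvile"], [city_dict])
        assert kf == KnowledgeFeatures("CITY", "B", "PARTIAL")

    def test_no_match(self, city_dict):
        [kf] = fuzzy_lookup(["aspirin"], [city_dict])
        assert kf == NO_FEATURES

    def test_short_tokens_never_fuzzy(self):
        d = Dictionary("z", "CITY", {"waldo"})
        assert fuzzy_lookup(["waldO"], [d])[0].condition == "EXACT"
        d2 = Dictionary("z", "CITY", {"wald"})
        # 4-character entry: edit distance matching is off
        assert fuzzy_lookup(["walo"], [d2])[0] == NO_FEATURES

    def test_multi_word_entry_gets_bio_boundaries(self):
        d = Dictionary("inst", "INSTITUTE", {"summit care hospital"})
        feats = fuzzy_lookup(["at", "Summit", "Care", "Hospital", "."], [d])
        assert [f.boundary for f in feats] == ["O", "B", "I", "I", "O"]
        assert all(f.condition == "EXACT" for f in feats[1:4])

    def test_strict_prefix_of_multi_word_entry_is_partial(self):
        d = Dictionary("inst", "INSTITUTE", {"summit care hospital"})
        feats = fuzzy_lookup(["Summit", "Care", "closed"], [d])
        assert feats[0] == KnowledgeFeatures("INSTITUTE", "B", "PARTIAL")
        assert feats[1] == KnowledgeFeatures("INSTITUTE", "I", "PARTIAL")
        assert feats[2] == NO_FEATURES

    def test_priority_rank_breaks_ties(self):
        first = Dictionary("first", "NAME", {"jordan"}, priority=0)
        city = Dictionary("city", "CITY", {"jordan"}, priority=2)
        assert fuzzy_lookup(["Jordan"], [city, first])[0].category == "NAME"

    def test_longer_match_preferred(self):
        name = Dictionary("n", "NAME", {"summit"}, priority=0)
        inst = Dictionary("i", "INSTITUTE", {"summit care"}, priority=0)
        feats = fuzzy_lookup(["Summit", "Care"], [name, inst])
        assert [f.category for f in feats] == ["INSTITUTE", "INSTITUTE"]

    def test_no_dictionaries_degrades_to_none(self, caplog):
        import logging
        logging.getLogger("phitag.features").setLevel(logging.WARNING)
        with caplog.at_level("WARNING", logger="phitag.features"):
            feats = fuzzy_lookup(["Gainesville", "FL"], [])
        assert feats == [NO_FEATURES, NO_FEATURES]
        assert "no dictionaries" in caplog.text

    def test_zip_dictionary_exact_only(self):
        d = Dictionary("zips", "ZIP", {"32601"}, exact_only=True)
        assert fuzzy_lookup(["32601"], [d])[0].condition == "EXACT"
        assert fuzzy_lookup(["32607"], [d])[0] == NO_FEATURES

    def test_output_length_and_boundary_grammar(self, small_corpus):
        from phitag.features import load_dictionaries
        from phitag.preprocess import tokenize
        dicts = load_dictionaries()
        for doc in small_corpus[:5]:
            tokens = [t.surface for t in tokenize(doc.text)]
            feats = fuzzy_lookup(tokens, dicts)
            assert len(feats) == len(tokens)
            tags = [f.boundary if f.boundary == "O" else
                    f"{f.boundary}-{f.category}" for f in feats]
            assert LabeledSequence(
                [Token("x", i, i + 1) for i in range(len(tags))],
                tags).is_valid_bio()

    def test_inconsistent_feature_triple_rejected(self):
        with pytest.raises(ValueError):
            KnowledgeFeatures("CITY", "O", "NONE")

    def test_empty_dictionary_rejected(self):
        with pytest.raises(ConfigurationError):
            Dictionary("d", "CITY", {"", "  "})
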