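import numpy as np
import pytest
from hypothesis import given, settings, strategies as st

from engage import (
    count_gd_references,
    count_ndc_references,
    extract_kwic,
    match_terms,
    tokenize,
)
from engage.text_engine import TokenStream

from conftest import oracle_gd_count, stream_of


class TestTokenize:
    @pytest.mark.parametrize(
        "raw,expected",
        [
            ("Climate change threatens health.", ("climate", "change", "threatens", "health")),
            ("CO_2 emissions rose", ("co2", "emissions", "rose")),
            ("CO₂ and CO2 and co_2", ("co2", "and", "co2", "and", "co2")),
            ("greenhouse-gas emissions", ("greenhouse", "gas", "emissions")),
            ("", ()),
            ("   \n\t ", ()),
        ],
    )
    def test_normalization(self, raw, expected):
        assert tokenize(raw).tokens == expected

    def test_char_offsets_are_increasing_and_in_bounds(self):
        raw = "Net-zero by 2050, CO_2 falls."
        stream = tokenize(raw)
        last_end = 0
        for (s, e), tok in zip(stream.char_offsets, stream.tokens):
            assert 0 <= s < e <= len(raw)
            assert s >= last_end
            last_end = e

    def test_no_empty_or_punctuation_tokens(self):
        stream = tokenize("a -- b ... c!!! _ 42")
        assert all(tok and not tok.isspace() for tok in stream.tokens)
        assert "42" in stream.tokens


class TestMatchTerms:
    def test_longest_match_wins_over_subphrase(self, health_lex):
        mentions = match_terms(stream_of("health", "care", "workers"), health_lex)
        assert [(m.phrase, m.start) for m in mentions] == [(("health", "care"), 0)]

    def test_token_boundaries_no_substring_hits(self, health_lex):
        mentions = match_terms(stream_of("malnutrition", "is", "rising"), health_lex)
        assert [m.phrase for m in mentions] == [("malnutrition",)]

    def test_greenhouse_gas_beats_bare_greenhouse(self, climate_lex):
        mentions = match_terms(stream_of("greenhouse", "gas", "emissions"), climate_lex)
        assert [m.phrase for m in mentions] == [("greenhouse", "gas")]

    def test_mentions_never_overlap_within_category(self, health_lex, climate_lex,
                                                    random_stream_factory):
        rng = np.random.default_rng(42)
        for _ in range(50):
            tokens = random_stream_factory(rng, max_len=200)
            for lex in (health_lex, climate_lex):
                mentions = match_terms(TokenStream(tuple(tokens)), lex)
                for a, b in zip(mentions, mentions[1:]):
                    assert a.end <= b.start
                for m in mentions:
                    assert tuple(tokens[m.start : m.end]) == m.phrase


class TestKwic:
    def test_boundary_truncation_at_document_start(self, health_lex):
        stream = stream_of("health", "of", "our", "people")
        [rec] = extract_kwic(stream, match_terms(stream, health_lex), 25)
        assert rec.left_context == ()
        assert rec.right_context == ("of", "our", "people")

    def test_full_window_in_midstream(self, health_lex):
        tokens = ["the"] * 50 + ["malaria"] + ["of"] * 49
        stream = TokenStream(tuple(tokens))
        [rec] = extract_kwic(stream, match_terms(stream, health_lex), 3)
        assert len(rec.left_context) == 3 and len(rec.right_context) == 3

    def test_empty_mentions_and_bad_window(self, health_lex):
        stream = stream_of("the", "assembly")
        assert extract_kwic(stream, [], 25) == []
        with pytest.raises(ValueError):
            extract_kwic(stream, [], 0)


def _spaced(*parts):
    tokens = []
    for part in parts:
        if isinstance(part, int):
            tokens += ["the"] * part
        else:
            tokens += part.split()
    return TokenStream(tuple(tokens))


class TestGdCount:
    def test_results_fragment_two_sides_of_the_same_coin(self, health_lex, climate_lex):
        # hand count: "diseases" is the one health mention, "climate change"
        # is well inside its 25-token window -> exactly 1 reference
        raw = ("described noncommunicable diseases and climate change as "
               "two sides of the same coin")
        assert count_gd_references(tokenize(raw), health_lex, climate_lex) == 1

    def test_two_health_mentions_share_one_climate_mention(self, health_lex, climate_lex):
        stream = _spaced("malaria", 5, "climate change", 5, "measles")
        assert count_gd_references(stream, health_lex, climate_lex) == 2

    def test_multiple_climate_terms_still_one_reference(self, health_lex, climate_lex):
        stream = _spaced("global warming", 2, "health", 2, "climate change")
        assert count_gd_references(stream, health_lex, climate_lex) == 1

    @pytest.mark.parametrize("gap,expected", [(25, 1), (26, 0)])
    @pytest.mark.parametrize("side", ["before", "after"])
    def test_window_boundary_inclusive_at_25(self, health_lex, climate_lex, gap, expected, side):
        # climate token exactly `gap` tokens from the health phrase edge
        if side == "before":
            stream = _spaced("temperature", gap - 1, "health")
        else:
            stream = _spaced("health", gap - 1, "temperature")
        assert count_gd_references(stream, health_lex, climate_lex, window=25) == expected

    def test_no_mentions_of_either_category(self, health_lex, climate_lex):
        assert count_gd_references(_spaced(40), health_lex, climate_lex) == 0
        assert count_gd_references(_spaced("health", 40), health_lex, climate_lex) == 0
        assert count_gd_references(_spaced("temperature", 40), health_lex, climate_lex) == 0

    def test_window_validation(self, health_lex, climate_lex):
        with pytest.raises(ValueError):
            count_gd_references(_spaced("health"), health_lex, climate_lex, window=0)


class TestNdcCount:
    def test_frequency_sum(self, health_lex):
        stream = _spaced("health", 3, "malaria", 3, "health", 3, "malaria", 3, "health")
        assert count_ndc_references(stream, health_lex) == 5

    def test_longest_match_counts_once(self, health_lex):
        assert count_ndc_references(stream_of("health", "care"), health_lex) == 1

    def test_empty_document(self, health_lex):
        assert count_ndc_references(TokenStream(()), health_lex) == 0


class TestGdCountProperties:
    def test_oracle_equivalence_on_random_streams(self, health_lex, climate_lex,
                                                  random_stream_factory):
        rng = np.random.default_rng(7)
        for _ in range(200):
            tokens = random_stream_factory(rng, max_len=120)
            window = int(rng.integers(1, 30))
            got = count_gd_references(TokenStream(tuple(tokens)), health_lex,
                                      climate_lex, window)
            want = oracle_gd_count(tokens, health_lex.phrases, climate_lex.phrases, window)
            assert got == want, (tokens, window)

    @given(seed=st.integers(0, 10_000))
    @settings(max_examples=60, deadline=None, derandomize=True)
    def test_window_monotonicity(self, seed, health_lex, climate_lex,
                                 random_stream_factory):
        rng = np.random.default_rng(seed)
        stream = TokenStream(tuple(random_stream_factory(rng, max_len=150)))
        counts = [count_gd_references(stream, health_lex, climate_lex, w)
                  for w in (1, 5, 10, 25, 60)]
        assert counts == sorted(counts)
        # bounded above by the number of health mentions
        assert counts[-1] <= len(match_terms(stream, health_lex))

    def test_filler_invariance_far_from_health_mentions(self, health_lex, climate_lex):
        stream = _spaced("health", 10, "climate change", 100)
        padded = _spaced(80, "health", 10, "climate change", 100)
        assert (count_gd_references(stream, health_lex, climate_lex)
                == count_gd_references(padded, health_lex, climate_lex) == 1)
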