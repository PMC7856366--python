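import numpy as np
import pytest

from engage import load_default_lexicon
from engage.text_engine import TokenStream


@pytest.fixture(scope="session")
def health_lex():
    return load_default_lexicon("health")


@pytest.fixture(scope="session")
def climate_lex():
    return load_default_lexicon("climate")


def stream_of(*tokens: str) -> TokenStream:
    return TokenStream(tuple(tokens))


# ---------------------------------------------------------------------------
# Independent brute-force oracle for the general-debate co-occurrence count.
# Deliberately written as a different algorithm from the production matcher:
# explicit index-set arithmetic over all (health, climate) mention pairs.
# ---------------------------------------------------------------------------

def oracle_mentions(tokens, phrases):
    """Longest-match non-overlapping mention spans, by naive rescanning."""
    phrase_set = {tuple(p) for p in phrases}
    longest = max(len(p) for p in phrase_set)
    spans = []
    i = 0
    n = len(tokens)
    while i < n:
        best = 0
        for l in range(1, min(longest, n - i) + 1):
            if tuple(tokens[i : i + l]) in phrase_set:
                best = l
        if best:
            spans.append((i, i + best))
            i += best
        else:
            i += 1
    return spans


def oracle_gd_count(tokens, health_phrases, climate_phrases, window):
    """Count health mentions with a climate token in the +/-window index sets."""
    h_spans = oracle_mentions(tokens, health_phrases)
    c_spans = oracle_mentions(tokens, climate_phrases)
    climate_tokens = set()
    for s, e in c_spans:
        climate_tokens.update(range(s, e))
    count = 0
    for s, e in h_spans:
        nearby = set(range(s - window, s)) | set(range(e, e + window))
        nearby = {t for t in nearby if t >= 0}
        if nearby & climate_tokens:
            count += 1
    return count


@pytest.fixture(scope="session")
def random_stream_factory(health_lex, climate_lex):
    """Streams over a stress vocabulary mixing filler with lexicon fragments,
    so multi-token phrases, near-matches and overlaps all occur."""
    lex_tokens = sorted({t for p in health_lex.phrases + climate_lex.phrases for t in p})
    filler = ["the", "of", "we", "nations", "peace", "support", "delegation"]
    vocab = np.array(lex_tokens + filler)

    def make(rng, max_len=500):
        n = int(rng.integers(0, max_len + 1))
        return list(vocab[rng.integers(0, len(vocab), n)])

    return make
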