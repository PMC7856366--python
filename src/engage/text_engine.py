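"""Tokenization, phrase matching, keyword-in-context extraction and engagement counts.

The unit of distance throughout is the *word token*.  A general-debate
engagement reference is a health-term mention with at least one climate-term
token inside a symmetric window (default 25 tokens) around the health phrase;
an NDC (nationally determined contribution) reference is simply a health-term
mention.  Matching is exact (no stemming), case-insensitive, and uses
longest-match precedence within each lexicon category.
"""

from __future__ import annotations

import re
from dataclasses import dataclass, field
from typing import TYPE_CHECKING, Iterable, Sequence

if TYPE_CHECKING:  # avoid circular import; lexicons imports tokenize from here
    from .lexicons import TermLexicon

__all__ = [
    "TokenStream",
    "Mention",
    "KwicRecord",
    "tokenize",
    "normalize_phrase",
    "match_terms",
    "extract_kwic",
    "count_gd_references",
    "count_ndc_references",
]

# Subscript/superscript digits seen in chemical formulae (CO_2_, CO₂).
_DIGIT_TRANSLATION = str.maketrans("₀₁₂₃₄₅₆₇₈₉⁰¹²³⁴⁵⁶⁷⁸⁹", "01234567890123456789")

# Word = maximal run of letters/digits; hyphens and underscores act as
# separators, so "greenhouse-gas" and "CO_2" split and are rejoined by the
# phrase matcher / the co2 merge rule below.
_WORD_RE = re.compile(r"[^\W_]+", re.UNICODE)


@dataclass(frozen=True)
class TokenStream:
    """Normalized tokens of one document plus their character offsets.

    ``char_offsets[i]`` is the ``(start, end)`` span of token ``i`` in the raw
    text the stream was built from (end exclusive).
    """

    tokens: tuple[str, ...]
    char_offsets: tuple[tuple[int, int], ...] = field(default=())

    def __post_init__(self) -> None:
        if self.char_offsets and len(self.char_offsets) != len(self.tokens):
            raise ValueError("char_offsets length must match tokens length")

    def __len__(self) -> int:
        return len(self.tokens)


@dataclass(frozen=True)
class Mention:
    """One matched lexicon phrase: category, phrase tokens and token span."""

    category: str
    phrase: tuple[str, ...]
    start: int

    @property
    def length(self) -> int:
        return len(self.phrase)

    @property
    def end(self) -> int:
        """Token index one past the last phrase token."""
        return self.start + len(self.phrase)


@dataclass(frozen=True)
class KwicRecord:
    """A mention with up to ``window`` tokens of context on each side."""

    mention: Mention
    left_context: tuple[str, ...]
    right_context: tuple[str, ...]
    window: int


def tokenize(raw_text: str) -> TokenStream:
    """Tokenize raw UTF-8 text into a normalized :class:`TokenStream`.

    Tokens are lowercased; punctuation, hyphens and underscores separate
    tokens; digits are kept.  Subscript digits map to ASCII digits, and a
    "co" token immediately followed by a "2" token merges into "co2", so
    "CO2", "CO_2" and "CO₂" all normalize to the single token "co2".  Total
    function: empty input yields an empty stream.
    """
    translated = raw_text.translate(_DIGIT_TRANSLATION)
    tokens: list[str] = []
    offsets: list[tuple[int, int]] = []
    for m in _WORD_RE.finditer(translated):
        tokens.append(m.group(0).lower())
        offsets.append((m.start(), m.end()))
    # Merge chemical-formula fragments: ("co", "2") -> "co2".
    merged_tokens: list[str] = []
    merged_offsets: list[tuple[int, int]] = []
    i = 0
    while i < len(tokens):
        if tokens[i] == "co" and i + 1 < len(tokens) and tokens[i + 1] == "2":
            merged_tokens.append("co2")
            merged_offsets.append((offsets[i][0], offsets[i + 1][1]))
            i += 2
        else:
            merged_tokens.append(tokens[i])
            merged_offsets.append(offsets[i])
            i += 1
    return TokenStream(tuple(merged_tokens), tuple(merged_offsets))


def normalize_phrase(raw_phrase: str) -> tuple[str, ...]:
    """Normalize a lexicon phrase with the same rules as document text."""
    return tokenize(raw_phrase).tokens


def match_terms(stream: TokenStream, lexicon: "TermLexicon") -> list[Mention]:
    """Find all lexicon mentions in a stream, longest match first.

    Scans left to right; at each position the longest matching phrase wins
    and scanning resumes after it, so mentions of one category never overlap
    and matches respect token boundaries (no substring hits).
    """
    phrases = set(lexicon.phrases)
    if not phrases:
        return []
    max_len = max(len(p) for p in phrases)
    tokens = stream.tokens
    n = len(tokens)
    mentions: list[Mention] = []
    i = 0
    while i < n:
        matched = None
        for length in range(min(max_len, n - i), 0, -1):
            candidate = tokens[i : i + length]
            if candidate in phrases:
                matched = candidate
                break
        if matched is not None:
            mentions.append(Mention(lexicon.category, matched, i))
            i += len(matched)
        else:
            i += 1
    return mentions


def extract_kwic(
    stream: TokenStream, mentions: Iterable[Mention], window: int
) -> list[KwicRecord]:
    """One keyword-in-context record per mention, truncated at document edges."""
    if window < 1:
        raise ValueError(f"window must be >= 1, got {window}")
    tokens = stream.tokens
    records = []
    for m in mentions:
        left = tokens[max(0, m.start - window) : m.start]
        right = tokens[m.end : m.end + window]
        records.append(KwicRecord(m, tuple(left), tuple(right), window))
    return records


def _climate_token_near(
    health: Mention, climate_mentions: Sequence[Mention], window: int
) -> bool:
    """True if any climate-mention token falls within ``window`` tokens
    before the health phrase's first token or after its last token.

    A climate token at index t qualifies iff
    ``health.start - window <= t <= health.start - 1`` or
    ``health.end <= t <= health.end + window - 1`` (distance == window is in).
    """
    lo_before = health.start - window
    hi_after = health.end + window - 1
    for c in climate_mentions:
        # climate tokens occupy [c.start, c.end)
        before = c.end > lo_before and c.start < health.start
        after = c.start <= hi_after and c.end > health.end
        if before or after:
            # at least one token strictly outside the health span and in range
            for t in range(c.start, c.end):
                if lo_before <= t <= health.start - 1 or health.end <= t <= hi_after:
                    return True
    return False


def count_gd_references(
    stream: TokenStream,
    health: "TermLexicon",
    climate: "TermLexicon",
    window: int = 25,
) -> int:
    """Count general-debate engagement references in one statement.

    A reference is a health mention with at least one climate-term token
    within ``window`` tokens before its first or after its last token
    (inclusive at distance == window).  Each qualifying health mention counts
    exactly once however many climate terms are nearby; two health mentions
    sharing one climate mention count twice.
    """
    if window < 1:
        raise ValueError(f"window must be >= 1, got {window}")
    health_mentions = match_terms(stream, health)
    if not health_mentions:
        return 0
    climate_mentions = match_terms(stream, climate)
    if not climate_mentions:
        return 0
    return sum(
        1 for m in health_mentions if _climate_token_near(m, climate_mentions, window)
    )


def count_ndc_references(stream: TokenStream, health: "TermLexicon") -> int:
    """Count health-term mentions (the NDC engagement measure)."""
    return len(match_terms(stream, health))
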