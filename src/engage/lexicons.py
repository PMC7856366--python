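"""Health and climate term lexicons for engagement scoring.

The default lists are the search terms used in studies of government
engagement with the health impacts of climate change:
28 distinct health phrases and (after normalization) 31 distinct climate
phrases.  The printed health list repeats "nutrition"; that duplicate is
treated as a typo and removed, and hyphen/space spelling variants that the
printed lists carry separately ("carbon dioxide"/"carbon-dioxide",
"net zero"/"net-zero", "carbon neutral"/"carbon-neutral") collapse under
normalization.  Matching is case-insensitive everywhere, including acronyms
(SARS, NCD, GHGE): statements use inconsistent casing, and for these strings
the risk of lowercase collisions with ordinary words is negligible.

British spellings are kept as printed ("diarrhoea"); ``us_spellings=True``
adds common US variants (off by default, fidelity to the source list first).
"""

from __future__ import annotations

from dataclasses import dataclass
from pathlib import Path
from typing import Iterable

from .text_engine import normalize_phrase

__all__ = ["TermLexicon", "load_default_lexicon", "load_lexicon_file", "CATEGORIES"]

CATEGORIES = ("health", "climate")

# Default term lists, verbatim as printed (including the duplicated
# "nutrition" and the separately-listed hyphen variants); normalization and
# deduplication happen at load time.
_HEALTH_TERMS_RAW = [
    "malaria", "diarrhoea", "infection", "disease", "diseases", "SARS",
    "measles", "pneumonia", "epidemic", "epidemics", "pandemic", "pandemics",
    "epidemiology", "health care", "health", "mortality", "morbidity",
    "nutrition", "illness", "illnesses", "NCD", "NCDs", "air pollution",
    "nutrition", "malnutrition", "malnourishment", "mental disorder",
    "mental disorders", "stunting",
]

_CLIMATE_TERMS_RAW = [
    "climate change", "changing climate", "climate emergency",
    "climate action", "climate crisis", "climate decay", "global warming",
    "green house", "temperature", "extreme weather",
    "global environmental change", "climate variability", "greenhouse",
    "greenhouse-gas", "low carbon", "GHGE", "GHGEs", "renewable energy",
    "carbon emission", "carbon emissions", "carbon dioxide", "carbon-dioxide",
    "CO_2_ emission", "CO_2_ emissions", "climate pollutant",
    "climate pollutants", "decarbonization", "decarbonisation",
    "carbon neutral", "carbon-neutral", "carbon neutrality",
    "climate neutrality", "net-zero", "net zero",
]

# Optional US spelling variants of the British default terms.
_US_VARIANTS = {"health": ["diarrhea"], "climate": []}

MAX_PHRASE_TOKENS = 4


@dataclass(frozen=True)
class TermLexicon:
    """A categorized set of normalized search phrases.

    ``phrases`` is a sorted tuple of token sequences (1..4 tokens each),
    stored in the same normalized form as document tokens so matching is
    normalization-consistent.  Equality is order-independent by construction.
    """

    category: str
    phrases: tuple[tuple[str, ...], ...]
    source_label: str = ""

    def __post_init__(self) -> None:
        if self.category not in CATEGORIES:
            raise ValueError(
                f"unknown category {self.category!r}; expected one of {CATEGORIES}"
            )
        if len(set(self.phrases)) != len(self.phrases):
            raise ValueError("duplicate phrases after normalization")
        for p in self.phrases:
            if not p or any(not tok or tok.isspace() for tok in p):
                raise ValueError(f"invalid phrase {p!r}: empty or whitespace token")
            if len(p) > MAX_PHRASE_TOKENS:
                raise ValueError(f"phrase {p!r} exceeds {MAX_PHRASE_TOKENS} tokens")

    def __contains__(self, phrase: Iterable[str]) -> bool:
        return tuple(phrase) in set(self.phrases)

    def __len__(self) -> int:
        return len(self.phrases)


def _build(category: str, raw_phrases: Iterable[str], source_label: str) -> TermLexicon:
    normalized = []
    seen = set()
    for raw in raw_phrases:
        phrase = normalize_phrase(raw)
        if not phrase:
            raise ValueError(f"phrase {raw!r} is empty after normalization")
        if phrase not in seen:
            seen.add(phrase)
            normalized.append(phrase)
    return TermLexicon(category, tuple(sorted(normalized)), source_label)


def load_default_lexicon(category: str, us_spellings: bool = False) -> TermLexicon:
    """Load the built-in term list for ``category`` ("health" or "climate").

    Returns the full default list, normalized and deduplicated.  Idempotent:
    repeated calls return equal lexicons.
    """
    if category == "health":
        raw = list(_HEALTH_TERMS_RAW)
    elif category == "climate":
        raw = list(_CLIMATE_TERMS_RAW)
    else:
        raise ValueError(
            f"unknown category {category!r}; expected one of {CATEGORIES}"
        )
    if us_spellings:
        raw += _US_VARIANTS[category]
    label = "default" + (" + US spellings" if us_spellings else "")
    return _build(category, raw, label)


def load_lexicon_file(path: str | Path, category: str) -> TermLexicon:
    """Load a user lexicon: UTF-8 text, one phrase per line, ``#`` comments.

    Phrases are normalized and deduplicated, so any permutation of the same
    phrases loads to an equal lexicon.  An empty file (or all comments) is an
    error.
    """
    path = Path(path)
    lines = path.read_text(encoding="utf-8").splitlines()
    raw = []
    for line in lines:
        phrase = line.split("#", 1)[0].strip()
        if phrase:
            raw.append(phrase)
    if not raw:
        raise ValueError(f"empty lexicon: {path}")
    return _build(category, raw, str(path))
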