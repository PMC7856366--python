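"""Read statement corpora from disk into Documents and summarize them.

One document is one country's statement: per country-year for the
general-debate arm ("gd"), per country for the pledge arm ("ndc").  File
names carry the metadata; the default conventions are ``{ISO3}_{SESSION}_{YEAR}.txt``
for gd and ``{ISO3}.txt`` for ndc, both overridable with a regex whose named
groups ``country`` (and ``year`` for gd) do the parsing.

Country identity is keyed on ISO3 codes validated against a bundled code
table; the European Union's joint pledge is attributed to the pseudo-entity
"EUU" and not fanned out to member states.  Documents whose ASCII ratio
falls below a threshold are flagged (pledges are analysed in their official
English versions; no translation is attempted).
"""

from __future__ import annotations

import csv
import logging
import re
from dataclasses import dataclass, field
from importlib import resources
from pathlib import Path
from typing import Iterable, Sequence

import pandas as pd

from .text_engine import TokenStream, tokenize

__all__ = [
    "Document",
    "CorpusSummary",
    "load_corpus",
    "summarize_corpus",
    "known_iso3_codes",
    "country_aliases",
    "write_scores",
    "write_country_totals",
]

logger = logging.getLogger(__name__)

ARMS = ("gd", "ndc")

DEFAULT_PATTERNS = {
    "gd": r"(?P<country>[A-Za-z]{3})_(?P<session>\d+)_(?P<year>\d{4})\.txt$",
    "ndc": r"(?P<country>[A-Za-z]{3,4})\.txt$",
}

DEFAULT_GD_YEARS = (2000, 2019)
DEFAULT_ASCII_THRESHOLD = 0.9


def known_iso3_codes() -> frozenset[str]:
    """The bundled ISO3 code table (plus EUU and historical entities)."""
    text = resources.files("engage.data").joinpath("iso3_codes.txt").read_text("utf-8")
    return frozenset(
        line.strip() for line in text.splitlines()
        if line.strip() and not line.startswith("#")
    )


def country_aliases() -> dict[str, str]:
    """Corpus country names -> ISO3, from the bundled alias table."""
    text = resources.files("engage.data").joinpath("country_aliases.csv").read_text("utf-8")
    reader = csv.DictReader(line for line in text.splitlines() if not line.startswith("#"))
    return {row["name"]: row["country_iso3"] for row in reader}


@dataclass
class Document:
    doc_id: str
    country_iso3: str
    year: int | None
    arm: str
    raw_text: str
    stream: TokenStream
    flags: tuple[str, ...] = ()


@dataclass
class CorpusSummary:
    n_documents: int
    n_tokens: int
    n_countries: int
    per_arm: dict[str, dict[str, int]] = field(default_factory=dict)


def _ascii_ratio(text: str) -> float:
    if not text:
        return 1.0
    return sum(1 for c in text if ord(c) < 128) / len(text)


def load_corpus(
    root: str | Path,
    arm: str,
    filename_pattern: str | None = None,
    year_range: tuple[int, int] | None = None,
    ascii_threshold: float = DEFAULT_ASCII_THRESHOLD,
) -> list[Document]:
    """Load every ``.txt`` statement under ``root`` into Documents.

    Files that do not match the filename pattern are logged and skipped;
    an empty match set is an error.  Ordering is deterministic (country,
    then year).  Unknown country codes and low-ASCII texts are flagged on
    the document, not dropped.
    """
    if arm not in ARMS:
        raise ValueError(f"unknown arm {arm!r}; expected one of {ARMS}")
    root = Path(root)
    if not root.is_dir():
        raise FileNotFoundError(f"corpus root is not a directory: {root}")
    pattern = re.compile(filename_pattern or DEFAULT_PATTERNS[arm])
    if year_range is None and arm == "gd":
        year_range = DEFAULT_GD_YEARS
    codes = known_iso3_codes()

    docs: list[Document] = []
    for path in sorted(root.iterdir()):
        if not path.is_file():
            continue
        m = pattern.match(path.name)
        if m is None:
            logger.warning("skipping file not matching %s pattern: %s", arm, path.name)
            continue
        country = m.group("country").upper()
        year = int(m.group("year")) if "year" in m.groupdict() and m.group("year") else None
        if year is not None and year_range is not None and not (
            year_range[0] <= year <= year_range[1]
        ):
            logger.warning("skipping %s: year %s outside %s", path.name, year, year_range)
            continue
        raw = path.read_text(encoding="utf-8")
        flags = []
        if country not in codes:
            flags.append("unknown_country")
            logger.warning("unknown country code %s in %s", country, path.name)
        if _ascii_ratio(raw) < ascii_threshold:
            flags.append("low_ascii")
            logger.warning("low ASCII ratio in %s; likely not English", path.name)
        docs.append(
            Document(
                doc_id=path.stem,
                country_iso3=country,
                year=year,
                arm=arm,
                raw_text=raw,
                stream=tokenize(raw),
                flags=tuple(flags),
            )
        )
    if not docs:
        raise ValueError(f"empty corpus: no files under {root} match the {arm} pattern")
    docs.sort(key=lambda d: (d.country_iso3, d.year if d.year is not None else -1))
    return docs


def summarize_corpus(docs: Sequence[Document]) -> CorpusSummary:
    """Document, token and country counts, broken down per arm."""
    if not docs:
        raise ValueError("no documents to summarize")
    per_arm: dict[str, dict[str, int]] = {}
    for arm in sorted({d.arm for d in docs}):
        sub = [d for d in docs if d.arm == arm]
        per_arm[arm] = {
            "n_documents": len(sub),
            "n_tokens": sum(len(d.stream) for d in sub),
            "n_countries": len({d.country_iso3 for d in sub}),
        }
    return CorpusSummary(
        n_documents=len(docs),
        n_tokens=sum(len(d.stream) for d in docs),
        n_countries=len({d.country_iso3 for d in docs}),
        per_arm=per_arm,
    )


def write_scores(scores: pd.DataFrame, path: str | Path) -> None:
    """Write the per-document score table (doc_id, country_iso3, year, arm, count)."""
    scores.to_csv(path, index=False)


def write_country_totals(scores: pd.DataFrame, path: str | Path) -> pd.DataFrame:
    """Aggregate per-document scores to per-country totals and write them.

    This is the mapping-ready table (choropleth rendering itself is out of
    scope).
    """
    totals = (
        scores.groupby("country_iso3", as_index=False)["count"]
        .sum()
        .sort_values("country_iso3")
    )
    totals.to_csv(path, index=False)
    return totals
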