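"""Synthetic statement corpora and predictor tables with known ground truth.

The corpus generator plants health/climate term pairs at controlled
token distances inside filler text, so the true engagement counts of every
document are known exactly: a planted pair is one general-debate reference,
a planted orphan health term is a health mention with no climate term in
range.  Planted structures are separated by more than the window length of
filler, making ground truth unambiguous, and the filler vocabulary is
disjoint from both lexicons so no accidental matches can occur.

The feature generator emulates the statistical structure the importance
analysis assumes: country-level predictors drawn from realistic marginal
distributions, and engagement counts from a Poisson log-link on a chosen
(mostly zero) effect vector over standardized features.
"""

from __future__ import annotations

import warnings
from dataclasses import dataclass, field
from importlib import resources
from pathlib import Path
from typing import Sequence

import numpy as np
import pandas as pd

from .corpus_io import known_iso3_codes
from .feature_table import NUMERIC_FEATURES, FeatureTable
from .lexicons import TermLexicon, load_default_lexicon
from .text_engine import normalize_phrase

__all__ = [
    "CorpusSpec",
    "FeatureSpec",
    "load_filler_vocabulary",
    "generate_corpus",
    "generate_features",
]

# Default planted effect: infant mortality drives engagement (one e-fold per
# standard deviation) among otherwise uninformative predictors; baseline
# mean engagement ~4.5 counts, the scale seen in 20-year country totals.
DEFAULT_FEATURES = (
    "gdp_pc_log",
    "growth",
    "trade_pct_gdp",
    "electricity_pct",
    "democracy",
    "pop_log",
    "latitude_abs",
    "life_expectancy",
    "infant_mortality",
    "maternal_death_risk",
)
DEFAULT_BETA = {"infant_mortality": 1.0}
DEFAULT_INTERCEPT = float(np.log(4.5))


@dataclass
class CorpusSpec:
    """Layout of one synthetic corpus (both arms).

    Per general-debate document: ``planted_gd_pairs`` health+climate
    co-occurrences within the window and ``planted_orphan_health`` isolated
    health terms.  Per pledge document: ``planted_ndc_health_terms`` health
    terms.  ``boundary_distance`` forces every pair's climate term to a
    fixed distance (e.g. window or window+1) instead of sampling uniformly
    in [1, window].
    """

    n_countries: int = 5
    years: tuple[int, int] = (2000, 2004)
    n_filler_tokens: int = 400
    planted_gd_pairs: int = 2
    planted_orphan_health: int = 2
    planted_ndc_health_terms: int = 3
    window: int = 25
    seed: int = 0
    boundary_distance: int | None = None

    def __post_init__(self) -> None:
        if self.n_countries < 1:
            raise ValueError("n_countries must be >= 1")
        if self.years[0] > self.years[1]:
            raise ValueError("invalid year range")
        if self.window < 1:
            raise ValueError("window must be >= 1")
        for name in (
            "planted_gd_pairs",
            "planted_orphan_health",
            "planted_ndc_health_terms",
            "n_filler_tokens",
        ):
            if getattr(self, name) < 0:
                raise ValueError(f"{name} must be >= 0")


def load_filler_vocabulary(
    lexicons: Sequence[TermLexicon] = (),
) -> tuple[str, ...]:
    """Filler words guaranteed disjoint from every lexicon token.

    The bundled wordlist is filtered against the default lexicons at load
    time and against any additional lexicons supplied; an over-aggressive
    lexicon that empties the vocabulary is an error.
    """
    text = resources.files("engage.data").joinpath("filler_words.txt").read_text("utf-8")
    words = [
        w.strip() for w in text.splitlines()
        if w.strip() and not w.startswith("#")
    ]
    forbidden: set[str] = set()
    all_lex = list(lexicons) or []
    for lex in (load_default_lexicon("health"), load_default_lexicon("climate"), *all_lex):
        for phrase in lex.phrases:
            forbidden.update(phrase)
    kept = tuple(w for w in words if normalize_phrase(w) and normalize_phrase(w)[0] not in forbidden)
    if not kept:
        raise ValueError("filler vocabulary is empty after lexicon filtering")
    return kept


def _sample_phrase(rng: np.random.Generator, lex: TermLexicon) -> tuple[str, ...]:
    return lex.phrases[int(rng.integers(len(lex.phrases)))]


def _filler(rng: np.random.Generator, vocab: tuple[str, ...], n: int) -> list[str]:
    return [vocab[int(i)] for i in rng.integers(0, len(vocab), n)]


def _build_gd_tokens(
    rng: np.random.Generator,
    spec: CorpusSpec,
    vocab: tuple[str, ...],
    health: TermLexicon,
    climate: TermLexicon,
) -> list[str]:
    """Token list with the planted structures separated by > window filler."""
    blocks: list[list[str]] = []
    for _ in range(spec.planted_gd_pairs):
        h = list(_sample_phrase(rng, health))
        c = list(_sample_phrase(rng, climate))
        if spec.boundary_distance is not None:
            dist = spec.boundary_distance
        else:
            dist = int(rng.integers(1, spec.window + 1))
        gap = _filler(rng, vocab, dist - 1)
        if rng.random() < 0.5:
            blocks.append(h + gap + c)
        else:
            blocks.append(c + gap + h)
    for _ in range(spec.planted_orphan_health):
        blocks.append(list(_sample_phrase(rng, health)))
    rng.shuffle(blocks)

    sep = spec.window + 1  # guarantees no cross-block co-occurrence
    n_gaps = len(blocks) + 1
    if blocks and spec.n_filler_tokens < sep * (len(blocks) - 1):
        raise ValueError(
            "n_filler_tokens too small to separate planted structures by more "
            f"than the window: need >= {sep * (len(blocks) - 1)}"
        )
    # distribute filler: every interior gap gets sep tokens, the rest random
    gap_sizes = [0] * n_gaps
    for i in range(1, n_gaps - 1):
        gap_sizes[i] = sep
    remaining = spec.n_filler_tokens - sum(gap_sizes)
    if remaining > 0:
        extra = rng.multinomial(remaining, [1 / n_gaps] * n_gaps)
        gap_sizes = [g + int(e) for g, e in zip(gap_sizes, extra)]
    tokens: list[str] = []
    tokens += _filler(rng, vocab, gap_sizes[0])
    for i, block in enumerate(blocks):
        tokens += block
        tokens += _filler(rng, vocab, gap_sizes[i + 1])
    return tokens


def _build_ndc_tokens(
    rng: np.random.Generator,
    spec: CorpusSpec,
    vocab: tuple[str, ...],
    health: TermLexicon,
) -> list[str]:
    blocks = [list(_sample_phrase(rng, health)) for _ in range(spec.planted_ndc_health_terms)]
    n_gaps = len(blocks) + 1
    # one filler token between adjacent health phrases prevents two planted
    # phrases from merging into a longer lexicon phrase
    gap_sizes = [0] + [1] * max(0, n_gaps - 2) + ([0] if n_gaps > 1 else [])
    gap_sizes = gap_sizes[:n_gaps]
    remaining = spec.n_filler_tokens - sum(gap_sizes)
    if remaining < 0:
        raise ValueError("n_filler_tokens too small for the pledge documents")
    if remaining > 0:
        extra = rng.multinomial(remaining, [1 / n_gaps] * n_gaps)
        gap_sizes = [g + int(e) for g, e in zip(gap_sizes, extra)]
    tokens: list[str] = []
    tokens += _filler(rng, vocab, gap_sizes[0])
    for i, block in enumerate(blocks):
        tokens += block
        tokens += _filler(rng, vocab, gap_sizes[i + 1])
    return tokens


def generate_corpus(
    spec: CorpusSpec,
    out_dir: str | Path,
    health: TermLexicon | None = None,
    climate: TermLexicon | None = None,
) -> pd.DataFrame:
    """Write a two-arm synthetic corpus and return its ground-truth table.

    Layout: ``out_dir/gd/{ISO3}_{session}_{year}.txt`` (one statement per
    country-year) and ``out_dir/ndc/{ISO3}.txt`` (one pledge per country),
    plus ``out_dir/truth.csv`` with the exact expected counts per document
    (``true_gd_references`` and ``true_health_mentions``).  Byte-identical
    across runs with the same spec.
    """
    health = health or load_default_lexicon("health")
    climate = climate or load_default_lexicon("climate")
    vocab = load_filler_vocabulary((health, climate))
    rng = np.random.default_rng(spec.seed)
    out_dir = Path(out_dir)
    (out_dir / "gd").mkdir(parents=True, exist_ok=True)
    (out_dir / "ndc").mkdir(parents=True, exist_ok=True)

    countries = sorted(known_iso3_codes() - {"EUU"})[: spec.n_countries]
    if len(countries) < spec.n_countries:
        raise ValueError("n_countries exceeds the bundled code table")

    in_window = (
        spec.boundary_distance is None or spec.boundary_distance <= spec.window
    )
    true_gd_per_doc = spec.planted_gd_pairs if in_window else 0

    rows = []
    for country in countries:
        for year in range(spec.years[0], spec.years[1] + 1):
            tokens = _build_gd_tokens(rng, spec, vocab, health, climate)
            session = year - 1945
            name = f"{country}_{session}_{year}.txt"
            (out_dir / "gd" / name).write_text(" ".join(tokens) + "\n", encoding="utf-8")
            rows.append(
                {
                    "doc_id": name[:-4],
                    "country_iso3": country,
                    "year": year,
                    "arm": "gd",
                    "true_gd_references": true_gd_per_doc,
                    "true_health_mentions": spec.planted_gd_pairs
                    + spec.planted_orphan_health,
                }
            )
        tokens = _build_ndc_tokens(rng, spec, vocab, health)
        name = f"{country}.txt"
        (out_dir / "ndc" / name).write_text(" ".join(tokens) + "\n", encoding="utf-8")
        rows.append(
            {
                "doc_id": country,
                "country_iso3": country,
                "year": spec.years[1],
                "arm": "ndc",
                "true_gd_references": 0,
                "true_health_mentions": spec.planted_ndc_health_terms,
            }
        )
    truth = pd.DataFrame(rows)
    truth.to_csv(out_dir / "truth.csv", index=False)
    return truth


@dataclass
class FeatureSpec:
    """Synthetic predictor table with a planted engagement signal.

    Engagement counts follow ``Poisson(exp(intercept + beta . z))`` where z
    are the standardized features.  ``beta`` maps feature name -> effect on
    the log scale; unnamed features get 0.  At least one zero and one
    non-zero effect are expected (all-zero draws a warning, not an error).
    """

    n_countries: int = 200
    feature_names: tuple[str, ...] = DEFAULT_FEATURES
    beta: dict[str, float] = field(default_factory=lambda: dict(DEFAULT_BETA))
    intercept: float = DEFAULT_INTERCEPT
    group_flags: tuple[str, ...] = ()
    seed: int = 0

    def __post_init__(self) -> None:
        if self.n_countries < 1:
            raise ValueError("n_countries must be >= 1")
        unknown = set(self.beta) - set(self.feature_names) - set(self.group_flags)
        if unknown:
            raise ValueError(f"beta names not in feature_names: {sorted(unknown)}")


# Marginal distributions loosely calibrated to the world-country cross
# section (units as in the predictor table).
def _draw_feature(rng: np.random.Generator, name: str, n: int) -> np.ndarray:
    if name == "gdp_pc_log":
        return rng.normal(8.5, 1.2, n)  # log constant-USD GDP pc
    if name == "growth":
        return rng.normal(3.0, 3.0, n)
    if name == "trade_pct_gdp":
        return np.clip(rng.normal(85, 40, n), 10, 400)
    if name == "electricity_pct":
        return np.clip(100 * rng.beta(5, 1.5, n), 1, 100)
    if name == "democracy":
        return np.clip(rng.normal(6, 3, n), 0, 10)
    if name == "pop_log":
        return rng.normal(16, 2, n)  # log population
    if name == "latitude_abs":
        return np.abs(rng.normal(0, 25, n))
    if name == "life_expectancy":
        return np.clip(rng.normal(71, 8, n), 45, 88)
    if name == "infant_mortality":
        return np.exp(rng.normal(np.log(18), 0.9, n))  # per 1000 births
    if name == "maternal_death_risk":
        return np.exp(rng.normal(np.log(0.5), 1.2, n))  # percent lifetime risk
    if name == "healthy_life_years":
        return np.clip(rng.normal(62, 7, n), 40, 76)
    if name == "health_exp_pct_gdp":
        return np.clip(rng.normal(6.5, 2.5, n), 1, 18)
    if name == "co2_pc":
        return np.exp(rng.normal(np.log(2.5), 1.1, n))
    if name == "fossil_pct":
        return np.clip(rng.normal(65, 25, n), 0, 100)
    if name == "renewable_pct":
        return np.clip(rng.normal(30, 25, n), 0, 100)
    if name == "carbon_footprint":
        return np.exp(rng.normal(np.log(1.5), 0.9, n))
    if name == "oil_rents_pct":
        return np.clip(np.exp(rng.normal(np.log(0.5), 1.8, n)) - 0.3, 0, 50)
    # unknown names: standard normal noise feature
    return rng.normal(0, 1, n)


def generate_features(spec: FeatureSpec) -> tuple[FeatureTable, dict[str, float]]:
    """Generate a seeded feature table and return it with the true effects."""
    rng = np.random.default_rng(spec.seed)
    n = spec.n_countries
    data: dict[str, np.ndarray] = {}
    for name in spec.feature_names:
        data[name] = _draw_feature(rng, name, n)
    for g in spec.group_flags:
        data[g] = rng.binomial(1, 0.3, n).astype(float)

    all_cols = tuple(spec.feature_names) + tuple(spec.group_flags)
    beta_full = {name: float(spec.beta.get(name, 0.0)) for name in all_cols}
    if all(v == 0.0 for v in beta_full.values()):
        warnings.warn("all effects are zero: outcome is pure noise", stacklevel=2)

    eta = np.full(n, spec.intercept)
    for name in all_cols:
        x = data[name]
        sd = x.std()
        z = (x - x.mean()) / sd if sd > 0 else np.zeros(n)
        # winsorize at +/-3 SD: keeps counts from skewed predictors (e.g.
        # lognormal mortality) in the realistic 0-50 range
        eta += beta_full[name] * np.clip(z, -3.0, 3.0)
    outcome = rng.poisson(np.exp(eta)).astype(float)

    codes = sorted(known_iso3_codes() - {"EUU"})
    if n <= len(codes):
        country = codes[:n]
    else:
        country = [f"X{i:03d}" for i in range(n)]
    df = pd.DataFrame({"country_iso3": country, **data, "engagement": outcome})
    table = FeatureTable(df, all_cols, "engagement")
    return table, beta_full
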