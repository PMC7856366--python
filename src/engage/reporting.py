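"""Engagement summaries, score tables and the end-to-end pipeline.

Summaries mirror the study's reporting style: mean references per country
(2 decimals), the min-max range, the number of zero-engagement countries,
and a top-k ranking (ties broken alphabetically and flagged).  Shares of
countries are rounded half-up to whole percent.
"""

from __future__ import annotations

import hashlib
import json
import logging
import sys
from dataclasses import dataclass
from decimal import ROUND_HALF_UP, Decimal
from pathlib import Path
from typing import Sequence

import pandas as pd
import yaml

from . import __version__
from .corpus_io import Document, load_corpus, write_country_totals, write_scores
from .feature_table import aggregate_gd_outcome, build_features
from .lexicons import TermLexicon, load_default_lexicon, load_lexicon_file
from .rf_importance import (
    RFConfig,
    fit_forest,
    permutation_importance,
    write_importance_csv,
    write_model_card,
)
from .text_engine import (
    count_gd_references,
    count_ndc_references,
    extract_kwic,
    match_terms,
)

__all__ = [
    "EngagementSummary",
    "summarize_engagement",
    "score_documents",
    "kwic_table",
    "percent_half_up",
    "plot_importance",
    "run_pipeline",
    "PipelineConfigError",
]

logger = logging.getLogger(__name__)


class PipelineConfigError(ValueError):
    """Raised when a pipeline config is missing or malformed."""


@dataclass
class EngagementSummary:
    mean: float
    min: int
    max: int
    n_zero: int
    n_countries: int
    top_k: tuple[tuple[str, int], ...]
    tie_at_cutoff: bool = False

    def to_dict(self) -> dict:
        return {
            "mean": round(self.mean, 2),
            "min": self.min,
            "max": self.max,
            "n_zero": self.n_zero,
            "n_countries": self.n_countries,
            "pct_any_engagement": percent_half_up(
                self.n_countries - self.n_zero, self.n_countries
            ),
            "top_k": [list(t) for t in self.top_k],
            "tie_at_cutoff": self.tie_at_cutoff,
        }


def percent_half_up(numerator: int, denominator: int) -> int:
    """Whole-percent share rounded half-up (so 72.5% reports as 73)."""
    if denominator == 0:
        raise ValueError("denominator is zero")
    pct = Decimal(numerator) * 100 / Decimal(denominator)
    return int(pct.quantize(Decimal("1"), rounding=ROUND_HALF_UP))


def summarize_engagement(records: pd.DataFrame, k: int = 20) -> EngagementSummary:
    """Summary statistics over per-country engagement records.

    ``records`` needs ``country_iso3`` and ``engagement`` (or ``count``)
    columns, one row per country; the mean includes zero-count countries.
    """
    if records.empty:
        raise ValueError("no engagement records to summarize")
    col = "engagement" if "engagement" in records.columns else "count"
    counts = records[[c for c in ("country_iso3", col)]].copy()
    counts[col] = counts[col].astype(int)
    ranked = counts.sort_values(
        by=[col, "country_iso3"], ascending=[False, True], ignore_index=True
    )
    top = ranked.head(k)
    tie = False
    if len(ranked) > k and ranked[col].iloc[k] == ranked[col].iloc[k - 1]:
        tie = True
    return EngagementSummary(
        mean=float(counts[col].mean()),
        min=int(counts[col].min()),
        max=int(counts[col].max()),
        n_zero=int((counts[col] == 0).sum()),
        n_countries=len(counts),
        top_k=tuple((r.country_iso3, int(getattr(r, col))) for r in top.itertuples()),
        tie_at_cutoff=tie,
    )


def score_documents(
    docs: Sequence[Document],
    health: TermLexicon,
    climate: TermLexicon | None = None,
    window: int = 25,
) -> pd.DataFrame:
    """Per-document engagement counts for either arm.

    General-debate documents are scored with the co-occurrence count
    (climate required); pledge documents with the plain health-term count.
    """
    rows = []
    for doc in docs:
        if doc.arm == "gd":
            if climate is None:
                raise ValueError("gd scoring requires a climate lexicon")
            count = count_gd_references(doc.stream, health, climate, window)
        else:
            count = count_ndc_references(doc.stream, health)
        rows.append(
            {
                "doc_id": doc.doc_id,
                "country_iso3": doc.country_iso3,
                "year": doc.year,
                "arm": doc.arm,
                "count": count,
            }
        )
    return pd.DataFrame(rows)


def kwic_table(
    docs: Sequence[Document],
    lexicons: Sequence[TermLexicon],
    window: int = 25,
) -> pd.DataFrame:
    """Keyword-in-context export across documents and lexicon categories."""
    rows = []
    for doc in docs:
        for lex in lexicons:
            mentions = match_terms(doc.stream, lex)
            for rec in extract_kwic(doc.stream, mentions, window):
                rows.append(
                    {
                        "doc_id": doc.doc_id,
                        "country_iso3": doc.country_iso3,
                        "year": doc.year,
                        "category": rec.mention.category,
                        "phrase": " ".join(rec.mention.phrase),
                        "start_token": rec.mention.start,
                        "left_context": " ".join(rec.left_context),
                        "right_context": " ".join(rec.right_context),
                    }
                )
    columns = [
        "doc_id", "country_iso3", "year", "category", "phrase",
        "start_token", "left_context", "right_context",
    ]
    return pd.DataFrame(rows, columns=columns)


def plot_importance(result, path: str | Path, title: str = "Predictor importance") -> None:
    """Horizontal bar chart of mean permutation importances (top rank first)."""
    import matplotlib

    matplotlib.use("Agg")
    import matplotlib.pyplot as plt

    df = result.importances.sort_values("rank", ascending=False)
    fig, ax = plt.subplots(figsize=(7, 0.35 * len(df) + 1.5))
    ax.barh(df["feature"], df["mean_importance"], xerr=df["sd"], color="#4878a8")
    ax.axvline(0, color="black", lw=0.8)
    ax.set_xlabel("Permutation importance (increase in OOB error)")
    ax.set_title(title)
    fig.tight_layout()
    fig.savefig(path, dpi=150)
    plt.close(fig)


def _load_lexicon(cfg: dict, category: str) -> TermLexicon:
    path = (cfg.get("lexicons") or {}).get(category)
    if path:
        return load_lexicon_file(path, category)
    return load_default_lexicon(category)


def _config_hash(config: dict) -> str:
    return hashlib.sha256(
        json.dumps(config, sort_keys=True, default=str).encode()
    ).hexdigest()[:16]


def run_pipeline(config_path: str | Path) -> Path:
    """Run load -> score -> aggregate -> summarize (-> features -> forest).

    The YAML/JSON config names the corpus root, arm, optional lexicon
    overrides, window, optional predictor CSVs + groups file, forest
    settings and the output directory.  Writes scores.csv,
    country_totals.csv, summary.json, kwic.csv and, when feature inputs are
    given, importance.csv + model_card.json.  Returns the artifact
    directory.
    """
    config_path = Path(config_path)
    if not config_path.is_file():
        raise PipelineConfigError(f"config file not found: {config_path}")
    config = yaml.safe_load(config_path.read_text(encoding="utf-8"))
    if not isinstance(config, dict):
        raise PipelineConfigError("config must be a mapping")
    for key in ("corpus_root", "arm", "output_dir"):
        if key not in config:
            raise PipelineConfigError(f"config is missing required key {key!r}")
    arm = config["arm"]
    if arm not in ("gd", "ndc"):
        raise PipelineConfigError(f"arm must be 'gd' or 'ndc', got {arm!r}")
    corpus_root = Path(config["corpus_root"])
    if not corpus_root.is_dir():
        raise PipelineConfigError(f"corpus root does not exist: {corpus_root}")
    out = Path(config["output_dir"])
    out.mkdir(parents=True, exist_ok=True)
    window = int(config.get("window", 25))
    seed = int(config.get("seed", 0))

    health = _load_lexicon(config, "health")
    climate = _load_lexicon(config, "climate")
    docs = load_corpus(corpus_root, arm, config.get("filename_pattern"))
    scores = score_documents(docs, health, climate, window)
    write_scores(scores, out / "scores.csv")
    write_country_totals(scores, out / "country_totals.csv")
    records = aggregate_gd_outcome(scores, mode="total_2000_2019")
    summary = summarize_engagement(records, k=int(config.get("top_k", 20)))
    kwic = kwic_table(docs, [health, climate] if arm == "gd" else [health], window)
    kwic.to_csv(out / "kwic.csv", index=False)

    artifacts = {
        "version": __version__,
        "python": sys.version.split()[0],
        "seed": seed,
        "config_hash": _config_hash(config),
        "summary": summary.to_dict(),
    }

    features_cfg = config.get("features")
    if features_cfg:
        for key in ("predictors",):
            if key not in features_cfg:
                raise PipelineConfigError(f"features config is missing {key!r}")
        missing = [p for p in features_cfg["predictors"] if not Path(p).is_file()]
        if missing:
            raise PipelineConfigError(f"predictor CSV not found: {missing[0]}")
        table = build_features(
            features_cfg["predictors"],
            features_cfg.get("groups"),
            records,
            arm,
        )
        rf_cfg = config.get("rf") or {}
        rf = RFConfig(
            n_trees=int(rf_cfg.get("n_trees", 1000)),
            task=rf_cfg.get("task", "regression_count"),
            n_permutation_repeats=int(rf_cfg.get("n_permutation_repeats", 50)),
            seed=seed,
        )
        fitted = fit_forest(table, rf)
        result = permutation_importance(fitted, table)
        write_importance_csv(result, out / "importance.csv")
        write_model_card(fitted, result, out / "model_card.json")
        artifacts["completeness"] = table.report.to_dict()
        artifacts["chosen_params"] = fitted.chosen_params
        artifacts["oob_error"] = fitted.oob_error
    else:
        logger.info("no feature CSVs configured; forest stage skipped")
        artifacts["rf_stage"] = "skipped (no feature inputs)"

    (out / "summary.json").write_text(
        json.dumps(artifacts, indent=2), encoding="utf-8"
    )
    return out
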