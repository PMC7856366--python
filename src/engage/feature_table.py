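"""Assemble the country-level predictor matrix and join engagement outcomes.

Predictors follow the study's Table-1-style set: economic (log GDP per
capita, growth, trade, electricity access), political (a pre-combined
democracy score), geographic/demographic (log population, absolute
latitude), health (life expectancy, infant mortality, maternal death risk,
healthy life years, health expenditure) and climate-related (CO2 per
capita, fossil/renewable shares, carbon footprint, oil rents), plus eight
binary negotiating-group indicators.  Log and absolute-value transforms are
applied here; the democracy score is consumed as given, never recomputed.

Missing data are handled by listwise deletion: rows with any missing
predictor are excluded from modelling and counted in a completeness report.
"""

from __future__ import annotations

import csv
import math
from dataclasses import dataclass, field
from importlib import resources
from pathlib import Path
from typing import Iterable, Sequence

import numpy as np
import pandas as pd

from .corpus_io import known_iso3_codes

__all__ = [
    "NUMERIC_FEATURES",
    "GROUP_FEATURES",
    "RAW_TRANSFORMS",
    "FeatureTable",
    "CompletenessReport",
    "load_group_members",
    "default_groups_path",
    "aggregate_gd_outcome",
    "build_features",
]

NUMERIC_FEATURES = (
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
    "healthy_life_years",
    "health_exp_pct_gdp",
    "co2_pc",
    "fossil_pct",
    "renewable_pct",
    "carbon_footprint",
    "oil_rents_pct",
)

GROUP_FEATURES = ("g77", "agn", "arab", "eu", "ldc", "sids", "umbrella", "eig")

# raw input column -> (derived column, transform). Non-positive inputs to a
# log transform are flagged missing rather than erroring.
RAW_TRANSFORMS = {
    "gdp_pc": ("gdp_pc_log", "log"),
    "population": ("pop_log", "log"),
    "latitude": ("latitude_abs", "abs"),
}

OUTCOME = "engagement"


@dataclass
class CompletenessReport:
    n_total: int
    n_complete: int
    n_dropped: int
    n_unmatched: int
    dropped_countries: tuple[str, ...] = ()
    unmatched_countries: tuple[str, ...] = ()

    def to_dict(self) -> dict:
        return {
            "n_total": self.n_total,
            "n_complete": self.n_complete,
            "n_dropped": self.n_dropped,
            "n_unmatched": self.n_unmatched,
            "dropped_countries": list(self.dropped_countries),
            "unmatched_countries": list(self.unmatched_countries),
        }


@dataclass
class FeatureTable:
    """Complete-case modelling table plus its provenance report.

    ``data`` is indexed by row with a ``country_iso3`` column (and ``year``
    in panel mode); ``feature_columns`` are the predictors present, and
    ``outcome_column`` holds the engagement count.
    """

    data: pd.DataFrame
    feature_columns: tuple[str, ...]
    outcome_column: str = OUTCOME
    report: CompletenessReport | None = None

    @property
    def X(self) -> pd.DataFrame:
        return self.data[list(self.feature_columns)]

    @property
    def y(self) -> pd.Series:
        return self.data[self.outcome_column]

    def __len__(self) -> int:
        return len(self.data)


def default_groups_path() -> Path:
    """Bundled negotiating-group membership CSV (editable fixture)."""
    return Path(str(resources.files("engage.data").joinpath("negotiating_groups.csv")))


def load_group_members(path: str | Path | None = None) -> dict[str, frozenset[str]]:
    """Read a group,country_iso3 CSV (``#`` comments allowed) into sets."""
    path = Path(path) if path is not None else default_groups_path()
    lines = [
        line for line in path.read_text(encoding="utf-8").splitlines()
        if line.strip() and not line.startswith("#")
    ]
    members: dict[str, set[str]] = {g: set() for g in GROUP_FEATURES}
    for row in csv.DictReader(lines):
        members.setdefault(row["group"], set()).add(row["country_iso3"].upper())
    return {g: frozenset(s) for g, s in members.items()}


def aggregate_gd_outcome(
    per_doc_scores: pd.DataFrame, mode: str = "total_2000_2019"
) -> pd.DataFrame:
    """Aggregate per-document engagement counts into outcome records.

    ``total_2000_2019`` sums each country's counts across its statements
    (the outcome behind the 20-year totals); ``per_year`` keeps the
    country-year panel.  Countries with no documents are simply absent
    (never zero-filled); all-zero countries are retained with total 0.
    """
    required = {"country_iso3", "count"}
    if not required <= set(per_doc_scores.columns):
        raise ValueError(f"scores table must have columns {sorted(required)}")
    if mode == "total_2000_2019":
        out = (
            per_doc_scores.groupby("country_iso3", as_index=False)["count"]
            .sum()
            .sort_values("country_iso3", ignore_index=True)
        )
    elif mode == "per_year":
        if "year" not in per_doc_scores.columns:
            raise ValueError("per_year mode requires a 'year' column")
        out = (
            per_doc_scores.groupby(["country_iso3", "year"], as_index=False)["count"]
            .sum()
            .sort_values(["country_iso3", "year"], ignore_index=True)
        )
    else:
        raise ValueError(f"unknown aggregation mode {mode!r}")
    return out.rename(columns={"count": OUTCOME})


def _apply_transforms(df: pd.DataFrame) -> pd.DataFrame:
    df = df.copy()
    for raw, (derived, kind) in RAW_TRANSFORMS.items():
        if raw in df.columns and derived not in df.columns:
            if kind == "log":
                vals = pd.to_numeric(df[raw], errors="coerce").to_numpy(float)
                with np.errstate(divide="ignore", invalid="ignore"):
                    df[derived] = np.where(vals > 0, np.log(vals), np.nan)
            elif kind == "abs":
                df[derived] = pd.to_numeric(df[raw], errors="coerce").abs()
            df = df.drop(columns=[raw])
    return df


def build_features(
    predictor_csvs: Sequence[str | Path],
    groups_file: str | Path | None,
    scores: pd.DataFrame,
    arm: str,
    column_map: dict[str, str] | None = None,
) -> FeatureTable:
    """Join predictor CSVs, group indicators and engagement outcomes.

    Predictor CSVs are wide, one row per country, keyed on ``country_iso3``
    (names remappable via ``column_map``).  Raw ``gdp_pc``, ``population``
    and ``latitude`` columns are transformed to ``gdp_pc_log``, ``pop_log``
    and ``latitude_abs``.  Rows with unknown country codes are logged and
    excluded; rows with any missing predictor are dropped from the modelling
    table and reported.  ``scores`` must already be aggregated (one row per
    country), e.g. via :func:`aggregate_gd_outcome`.
    """
    if not predictor_csvs:
        raise ValueError("at least one predictor CSV is required")
    frames = []
    for path in predictor_csvs:
        df = pd.read_csv(path, comment="#")
        if column_map:
            df = df.rename(columns=column_map)
        if "country_iso3" not in df.columns:
            raise ValueError(f"{path}: no country_iso3 column")
        df["country_iso3"] = df["country_iso3"].str.upper()
        frames.append(df)
    merged = frames[0]
    for df in frames[1:]:
        merged = merged.merge(df, on="country_iso3", how="outer")
    merged = _apply_transforms(merged)

    codes = known_iso3_codes()
    known = merged["country_iso3"].isin(codes)
    excluded_unknown = tuple(sorted(merged.loc[~known, "country_iso3"]))
    merged = merged.loc[known].copy()

    members = load_group_members(groups_file)
    for g in GROUP_FEATURES:
        merged[g] = merged["country_iso3"].isin(members.get(g, frozenset())).astype(int)

    if OUTCOME not in scores.columns:
        raise ValueError(f"scores must carry an '{OUTCOME}' column (aggregate first)")
    joined = merged.merge(
        scores[["country_iso3", OUTCOME]], on="country_iso3", how="inner"
    )
    unmatched = tuple(
        sorted(set(scores["country_iso3"]) - set(joined["country_iso3"]))
    ) + excluded_unknown

    feature_cols = tuple(
        c for c in NUMERIC_FEATURES + GROUP_FEATURES if c in joined.columns
    )
    complete = joined[list(feature_cols)].notna().all(axis=1) & joined[OUTCOME].notna()
    dropped = tuple(sorted(joined.loc[~complete, "country_iso3"]))
    table = joined.loc[complete].sort_values("country_iso3", ignore_index=True)

    report = CompletenessReport(
        n_total=len(scores),
        n_complete=len(table),
        n_dropped=len(dropped),
        n_unmatched=len(unmatched),
        dropped_countries=dropped,
        unmatched_countries=unmatched,
    )
    return FeatureTable(table, feature_cols, OUTCOME, report)
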