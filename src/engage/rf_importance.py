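"""Random-forest engagement models and out-of-bag permutation importance.

The outcome is a per-country engagement count, modelled either directly
(``regression_count``, squared-error trees) or as any-engagement-versus-none
(``classification_any_engagement``, misclassification error): the pledge-arm
phrasing of "whether countries engaged" is ambiguous, so both tasks are
offered with regression as the default.

Hyperparameters (number of candidate features per split, minimum node size)
are chosen by grid search on the out-of-bag (OOB) error.  Variable
importance is permutation-based and computed on OOB predictions: for each
repeat, one feature column is shuffled, OOB predictions are re-aggregated
across trees, and the importance contribution is the increase in OOB error
over the unpermuted baseline.  Negative values — a random permutation
predicting *better* than the real feature — are meaningful for
uninformative features and are passed through unmodified.  Importance
magnitudes depend on the task and error metric; only ranks are comparable
across runs.

Correlated predictors are deliberately kept (the forest tolerates
multicollinearity) and features are never weighted.
"""

from __future__ import annotations

import json
import math
from dataclasses import dataclass, field
from pathlib import Path
from typing import Sequence

import numpy as np
import pandas as pd
from sklearn.ensemble import RandomForestClassifier, RandomForestRegressor
from sklearn.ensemble._forest import (
    _generate_unsampled_indices,
    _get_n_samples_bootstrap,
)

from .feature_table import FeatureTable

__all__ = [
    "RFConfig",
    "FittedForest",
    "ImportanceResult",
    "fit_forest",
    "permutation_importance",
    "write_importance_csv",
    "write_model_card",
]

TASKS = ("regression_count", "classification_any_engagement")

MIN_ROWS = 10


@dataclass
class RFConfig:
    """Forest and importance settings.

    ``mtry_grid`` defaults (given p features) to {p//3, floor(sqrt(p)), p//2};
    ``min_node_grid`` to {1, 5, 10}.  1000 trees and 50 permutation repeats
    unless overridden.  The seed drives the bootstrap, the grid-search fits
    and the permutation draws, so identical inputs and seed give identical
    results.
    """

    n_trees: int = 1000
    mtry_grid: tuple[int, ...] | None = None
    min_node_grid: tuple[int, ...] = (1, 5, 10)
    task: str = "regression_count"
    n_permutation_repeats: int = 50
    seed: int = 0

    def __post_init__(self) -> None:
        if self.task not in TASKS:
            raise ValueError(f"unknown task {self.task!r}; expected one of {TASKS}")
        if self.n_trees < 100:
            raise ValueError("n_trees must be >= 100")
        if self.mtry_grid is not None and not self.mtry_grid:
            raise ValueError("mtry_grid must be non-empty")
        if not self.min_node_grid:
            raise ValueError("min_node_grid must be non-empty")
        if self.n_permutation_repeats < 1:
            raise ValueError("n_permutation_repeats must be >= 1")

    def resolved_mtry_grid(self, p: int) -> tuple[int, ...]:
        if self.mtry_grid is not None:
            return tuple(sorted(set(self.mtry_grid)))
        return tuple(
            sorted({max(1, p // 3), max(1, math.isqrt(p)), max(1, p // 2)})
        )


@dataclass
class FittedForest:
    model: RandomForestRegressor | RandomForestClassifier
    feature_names: tuple[str, ...]
    task: str
    chosen_params: dict
    oob_error: float
    config: RFConfig


@dataclass
class ImportanceResult:
    """Per-feature permutation importances with repeat-level detail.

    ``importances`` has columns feature, mean_importance, sd, rank (rank 1 =
    most important; ties broken alphabetically and listed in
    ``tied_features``).  ``repeats`` is the (n_repeats x p) table of
    per-repeat error increases.
    """

    importances: pd.DataFrame
    repeats: pd.DataFrame
    task: str
    chosen_params: dict
    baseline_error: float
    tied_features: tuple[str, ...] = ()

    def rank_of(self, feature: str) -> int:
        row = self.importances.loc[self.importances["feature"] == feature, "rank"]
        if row.empty:
            raise KeyError(feature)
        return int(row.iloc[0])


def _as_matrix(table: FeatureTable) -> tuple[np.ndarray, np.ndarray, tuple[str, ...]]:
    X = table.X.to_numpy(dtype=np.float64)
    y = table.y.to_numpy(dtype=np.float64)
    if np.isnan(X).any() or np.isnan(y).any():
        raise ValueError("feature table must be complete-case (no NaN)")
    return X, y, tuple(table.feature_columns)


def _oob_masks(model, n_samples: int) -> list[np.ndarray]:
    """Boolean OOB mask per tree, from each tree's bootstrap random state."""
    n_boot = _get_n_samples_bootstrap(n_samples, model.max_samples, None)
    masks = []
    for est in model.estimators_:
        idx = _generate_unsampled_indices(est.random_state, n_samples, n_boot, None)
        mask = np.zeros(n_samples, dtype=bool)
        mask[idx] = True
        masks.append(mask)
    return masks


def _oob_predictions_regression(model, X, masks) -> tuple[np.ndarray, np.ndarray]:
    n = X.shape[0]
    sums = np.zeros(n)
    counts = np.zeros(n)
    for est, mask in zip(model.estimators_, masks):
        if mask.any():
            sums[mask] += est.predict(X[mask])
            counts[mask] += 1
    covered = counts > 0
    preds = np.full(n, np.nan)
    preds[covered] = sums[covered] / counts[covered]
    return preds, covered


def _oob_predictions_classification(model, X, masks) -> tuple[np.ndarray, np.ndarray]:
    n = X.shape[0]
    k = len(model.classes_)
    votes = np.zeros((n, k))
    for est, mask in zip(model.estimators_, masks):
        if mask.any():
            votes[mask] += est.predict_proba(X[mask])
    covered = votes.sum(axis=1) > 0
    preds = np.full(n, np.nan)
    preds[covered] = model.classes_[np.argmax(votes[covered], axis=1)]
    return preds, covered


def _oob_error(model, X, y, task, masks) -> float:
    if task == "regression_count":
        preds, covered = _oob_predictions_regression(model, X, masks)
        return float(np.mean((y[covered] - preds[covered]) ** 2))
    preds, covered = _oob_predictions_classification(model, X, masks)
    return float(np.mean(preds[covered] != y[covered]))


def _make_forest(task, n_trees, mtry, min_node, seed):
    common = dict(
        n_estimators=n_trees,
        max_features=mtry,
        min_samples_leaf=min_node,
        bootstrap=True,
        random_state=seed,
        n_jobs=1,
    )
    if task == "regression_count":
        return RandomForestRegressor(**common)
    return RandomForestClassifier(**common)


def fit_forest(table: FeatureTable, config: RFConfig) -> FittedForest:
    """Grid-search forest hyperparameters by OOB error and fit the winner.

    Requires at least 10 complete rows and a non-constant outcome.  In the
    classification task the count outcome is binarized to any-vs-none first.
    Deterministic given the config seed; grid ties go to the first candidate
    in (mtry, min_node) order.
    """
    X, y, names = _as_matrix(table)
    if X.shape[0] < MIN_ROWS:
        raise ValueError(f"insufficient data: {X.shape[0]} rows < {MIN_ROWS}")
    if config.task == "classification_any_engagement":
        y = (y > 0).astype(float)
    if np.unique(y).size < 2:
        raise ValueError("constant outcome: nothing to model")

    best = None
    for mtry in config.resolved_mtry_grid(X.shape[1]):
        for min_node in sorted(set(config.min_node_grid)):
            model = _make_forest(config.task, config.n_trees, mtry, min_node, config.seed)
            model.fit(X, y)
            masks = _oob_masks(model, X.shape[0])
            err = _oob_error(model, X, y, config.task, masks)
            if best is None or err < best[0]:
                best = (err, model, {"mtry": mtry, "min_node": min_node})
    err, model, params = best
    return FittedForest(model, names, config.task, params, err, config)


def permutation_importance(
    fitted: FittedForest, table: FeatureTable, config: RFConfig | None = None
) -> ImportanceResult:
    """Out-of-bag permutation importance for every feature.

    For each repeat, each feature column is shuffled over all rows, OOB
    predictions are re-aggregated across the forest, and the repeat-level
    importance is (permuted OOB error - baseline OOB error).  The mean over
    repeats is the reported importance; negative means are passed through.
    """
    config = config or fitted.config
    X, y, names = _as_matrix(table)
    if names != fitted.feature_names:
        raise ValueError("table features do not match the fitted model")
    if fitted.task == "classification_any_engagement":
        y = (y > 0).astype(float)
    n, p = X.shape
    R = config.n_permutation_repeats
    model = fitted.model
    masks = _oob_masks(model, n)
    baseline = _oob_error(model, X, y, fitted.task, masks)
    covered_counts = np.zeros(n)
    for mask in masks:
        covered_counts[mask] += 1
    covered = covered_counts > 0

    rng = np.random.default_rng(config.seed)
    perms = [rng.permutation(n) for _ in range(R)]
    is_reg = fitted.task == "regression_count"
    classes = None if is_reg else model.classes_

    repeat_errors = np.empty((R, p))
    for j in range(p):
        # stack the R permuted copies so each tree predicts once per feature
        X_stack = np.tile(X, (R, 1))
        for r, perm in enumerate(perms):
            X_stack[r * n : (r + 1) * n, j] = X[perm, j]
        if is_reg:
            sums = np.zeros((R, n))
        else:
            votes = np.zeros((R, n, len(classes)))
        for est, mask in zip(model.estimators_, masks):
            if not mask.any():
                continue
            idx = np.flatnonzero(mask)
            rows = (np.arange(R)[:, None] * n + idx[None, :]).ravel()
            if is_reg:
                preds = est.predict(X_stack[rows]).reshape(R, idx.size)
                sums[:, idx] += preds
            else:
                proba = est.predict_proba(X_stack[rows]).reshape(R, idx.size, -1)
                votes[:, idx, :] += proba
        for r in range(R):
            if is_reg:
                preds = sums[r, covered] / covered_counts[covered]
                err = float(np.mean((y[covered] - preds) ** 2))
            else:
                pred_cls = classes[np.argmax(votes[r, covered], axis=1)]
                err = float(np.mean(pred_cls != y[covered]))
            repeat_errors[r, j] = err - baseline

    means = repeat_errors.mean(axis=0)
    sds = repeat_errors.std(axis=0, ddof=1) if R > 1 else np.zeros(p)
    order = sorted(range(p), key=lambda j: (-means[j], names[j]))
    ranks = np.empty(p, dtype=int)
    for rank, j in enumerate(order, start=1):
        ranks[j] = rank
    mean_counts = pd.Series(means).round(12).value_counts()
    tied = tuple(
        sorted(
            names[j]
            for j in range(p)
            if mean_counts.get(round(float(means[j]), 12), 0) > 1
        )
    )
    importances = pd.DataFrame(
        {
            "feature": names,
            "mean_importance": means,
            "sd": sds,
            "rank": ranks,
        }
    ).sort_values("rank", ignore_index=True)
    repeats = pd.DataFrame(repeat_errors, columns=list(names))
    return ImportanceResult(
        importances, repeats, fitted.task, fitted.chosen_params, baseline, tied
    )


def write_importance_csv(result: ImportanceResult, path: str | Path) -> None:
    result.importances.to_csv(path, index=False)


def write_model_card(
    fitted: FittedForest, result: ImportanceResult, path: str | Path
) -> None:
    """JSON model card: task, chosen hyperparameters, OOB error, tie flags."""
    card = {
        "task": fitted.task,
        "n_trees": fitted.config.n_trees,
        "chosen_params": fitted.chosen_params,
        "oob_error": fitted.oob_error,
        "n_permutation_repeats": int(result.repeats.shape[0]),
        "baseline_error": result.baseline_error,
        "tied_features": list(result.tied_features),
        "seed": fitted.config.seed,
        "features": list(fitted.feature_names),
    }
    Path(path).write_text(json.dumps(card, indent=2), encoding="utf-8")
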