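import json
import subprocess
import textwrap

import numpy as np
import pandas as pd
import pytest

from engage import (
    FeatureSpec,
    FeatureTable,
    RFConfig,
    fit_forest,
    generate_features,
    permutation_importance,
)

FAST = dict(n_trees=150, mtry_grid=(3,), min_node_grid=(5,), n_permutation_repeats=5)


@pytest.fixture(scope="module")
def planted_table():
    table, beta = generate_features(FeatureSpec(n_countries=200, seed=11))
    return table, beta


@pytest.fixture(scope="module")
def fitted(planted_table):
    table, _ = planted_table
    config = RFConfig(seed=11, **FAST)
    return fit_forest(table, config), config


class TestFitForest:
    def test_insufficient_rows_rejected(self):
        table, _ = generate_features(FeatureSpec(n_countries=5, seed=0))
        with pytest.raises(ValueError, match="insufficient"):
            fit_forest(table, RFConfig(seed=0, **FAST))

    def test_constant_outcome_rejected(self):
        table, _ = generate_features(FeatureSpec(n_countries=50, seed=0))
        table.data["engagement"] = 3.0
        with pytest.raises(ValueError, match="constant outcome"):
            fit_forest(table, RFConfig(seed=0, **FAST))

    def test_seeded_determinism_of_grid_search(self, planted_table):
        table, _ = planted_table
        config = RFConfig(seed=5, n_trees=100, mtry_grid=(2, 3),
                          min_node_grid=(1, 5), n_permutation_repeats=2)
        a = fit_forest(table, config)
        b = fit_forest(table, config)
        assert a.chosen_params == b.chosen_params
        assert a.oob_error == b.oob_error

    def test_oob_error_beats_outcome_variance_with_planted_signal(self, fitted, planted_table):
        table, _ = planted_table
        fit, _ = fitted
        assert fit.oob_error < table.y.var()

    def test_config_validation(self):
        with pytest.raises(ValueError):
            RFConfig(n_trees=50)
        with pytest.raises(ValueError):
            RFConfig(task="ranking")
        with pytest.raises(ValueError):
            RFConfig(min_node_grid=())

    def test_classification_task_fits(self, planted_table):
        table, _ = planted_table
        config = RFConfig(seed=2, task="classification_any_engagement", **FAST)
        fit = fit_forest(table, config)
        assert 0.0 <= fit.oob_error <= 1.0


class TestPermutationImportance:
    def test_planted_feature_ranked_first(self, fitted, planted_table):
        table, beta = planted_table
        fit, config = fitted
        result = permutation_importance(fit, table, config)
        planted = [k for k, v in beta.items() if v != 0]
        assert result.importances.iloc[0].feature in planted

    def test_constant_feature_importance_is_zero(self, planted_table):
        table, _ = planted_table
        df = table.data.copy()
        df["flat"] = 1.0
        table2 = FeatureTable(df, table.feature_columns + ("flat",), "engagement")
        config = RFConfig(seed=4, **FAST)
        fit = fit_forest(table2, config)
        result = permutation_importance(fit, table2, config)
        flat = result.importances.set_index("feature").loc["flat"]
        assert abs(flat.mean_importance) < 1e-9

    def test_seeded_determinism(self, fitted, planted_table):
        table, _ = planted_table
        fit, config = fitted
        a = permutation_importance(fit, table, config)
        b = permutation_importance(fit, table, config)
        pd.testing.assert_frame_equal(a.importances, b.importances)
        pd.testing.assert_frame_equal(a.repeats, b.repeats)

    def test_ranks_are_a_permutation_and_repeats_kept(self, fitted, planted_table):
        table, _ = planted_table
        fit, config = fitted
        result = permutation_importance(fit, table, config)
        p = len(table.feature_columns)
        assert sorted(result.importances["rank"]) == list(range(1, p + 1))
        assert result.repeats.shape == (config.n_permutation_repeats, p)
        # means in the table equal the repeat-level means
        np.testing.assert_allclose(
            result.importances.sort_values("feature").mean_importance.to_numpy(),
            result.repeats.mean().sort_index().to_numpy(),
        )

    def test_negative_importances_passed_through(self, fitted, planted_table):
        table, _ = planted_table
        fit, config = fitted
        result = permutation_importance(fit, table, config)
        assert (result.importances.mean_importance < 0).any()


class TestRangerCrossCheck:
    def test_top_predictor_agrees_with_ranger(self, tmp_path, planted_table):
        """Independent oracle: ranger's OOB permutation importance should
        also rank the planted feature first on the same table."""
        table, beta = planted_table
        csv = tmp_path / "table.csv"
        cols = list(table.feature_columns) + ["engagement"]
        table.data[cols].to_csv(csv, index=False)
        script = tmp_path / "imp.R"
        script.write_text(textwrap.dedent("""
            library(ranger)
            d <- read.csv(commandArgs(trailingOnly=TRUE)[1])
            fit <- ranger(engagement ~ ., data=d, num.trees=500,
                          importance="permutation", seed=1)
            imp <- sort(fit$variable.importance, decreasing=TRUE)
            cat(names(imp)[1], "\n")
        """))
        out = subprocess.run(
            ["Rscript", str(script), str(csv)],
            capture_output=True, text=True, timeout=300, check=True,
        )
        planted = [k for k, v in beta.items() if v != 0]
        assert out.stdout.strip() in planted
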