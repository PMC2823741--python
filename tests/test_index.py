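"""Asset-index construction: screening, PC1 fitting, scoring, normalization."""

import numpy as np
import pandas as pd
import pytest
from oracles import align_sign, power_iteration_pc1, streaming_mean_by_group
from scipy import stats
from sklearn.decomposition import PCA

from needsalloc import (
    AssetIndex,
    aggregate_to_districts,
    fit_pc1,
    normalize_indices,
    score_household,
    score_households,
    screen_variables,
)
from needsalloc.index import ZERO_VARIANCE


def latent_binary_survey(seed: int, n_vars: int, n: int = 500) -> pd.DataFrame:
    """Correlated binary columns driven by one latent factor."""
    rng = np.random.default_rng(seed)
    z = rng.normal(size=n)
    cols = {}
    for k in range(n_vars):
        load = rng.uniform(0.5, 1.5) * (1 if k % 2 == 0 else -1)
        p = 1 / (1 + np.exp(-(rng.normal(0, 0.5) + load * z)))
        cols[f"v{k}"] = (rng.random(n) < p).astype(int)
    return pd.DataFrame(cols)


class TestScreening:
    def test_constant_column_screened_with_zero_variance_reason(self):
        df = latent_binary_survey(0, 4)
        df["always"] = 1
        retained, screened = screen_variables(df)
        assert ("always", ZERO_VARIANCE) in screened
        assert "always" not in retained

    def test_independent_coinflip_column_is_screened_out(self):
        """Two identical columns are maximally correlated; an independent
        coin flip correlates with them only by chance (< alpha), so across
        10 seeds it should essentially always be dropped."""
        dropped = 0
        for seed in range(10):
            rng = np.random.default_rng(seed)
            a = rng.integers(0, 2, size=1_000)
            df = pd.DataFrame(
                {"a": a, "a_copy": a, "coin": rng.integers(0, 2, size=1_000)}
            )
            retained, _ = screen_variables(df)
            assert {"a", "a_copy"} <= set(retained)
            dropped += "coin" not in retained
        assert dropped >= 8

    def test_strongly_correlated_set_fully_retained(self):
        df = latent_binary_survey(1, 6, n=2_000)
        retained, screened = screen_variables(df)
        assert retained == [f"v{k}" for k in range(6)]
        assert screened == []

    def test_everything_screened_out_is_hard_error(self):
        df = pd.DataFrame({"a": [1] * 20, "b": [0] * 20})
        with pytest.raises(ValueError, match="screened out"):
            screen_variables(df)


class TestPC1Fit:
    def test_two_perfectly_correlated_columns_closed_form(self):
        rng = np.random.default_rng(0)
        a = rng.integers(0, 2, size=1_000)
        df = pd.DataFrame({"a": a, "b": a})
        model = fit_pc1(df, ["a", "b"])
        assert np.allclose(np.abs(model.loadings_), 1 / np.sqrt(2))
        assert model.explained_variance_ratio_ == pytest.approx(1.0)

    @pytest.mark.parametrize("seed,n_vars", [(0, 3), (1, 4), (2, 5), (3, 6)])
    def test_loadings_match_power_iteration_oracle(self, seed, n_vars):
        df = latent_binary_survey(seed, n_vars)
        model = AssetIndex(screen=False).fit(df)
        corr = np.corrcoef(df.to_numpy(dtype=float), rowvar=False)
        oracle = align_sign(model.loadings_, power_iteration_pc1(corr))
        assert np.allclose(model.loadings_, oracle, atol=1e-6)

    def test_loadings_match_sklearn_pca_cross_check(self):
        df = latent_binary_survey(7, 6, n=2_000)
        model = AssetIndex(screen=False).fit(df)
        Z = (df - df.mean()) / df.std(ddof=0)
        ref = align_sign(model.loadings_, PCA(n_components=1).fit(Z).components_[0])
        assert np.allclose(model.loadings_, ref, atol=1e-8)

    def test_squared_loadings_sum_to_one(self, default_fit):
        _, _, model = default_fit
        assert np.sum(model.loadings_**2) == pytest.approx(1.0, abs=1e-9)

    def test_single_household_is_error(self):
        with pytest.raises(ValueError, match="one household"):
            AssetIndex(screen=False).fit(pd.DataFrame({"a": [1], "b": [0]}))

    def test_wealth_marker_orientation_on_default_survey(self, default_fit):
        """Households holding the wealth markers must outscore households
        holding none, i.e. the component points toward higher SES."""
        survey, _, model = default_fit
        markers = ["car_truck", "refrigerator", "toilet_flush"]
        scores = score_households(survey, model)
        rich = scores[survey[markers].sum(axis=1) >= 2]
        poor = scores[survey[markers].sum(axis=1) == 0]
        assert rich.mean() > poor.mean()

    def test_duplicated_variable_preserves_household_ranking(self, default_fit):
        survey, _, model = default_fit
        dup = survey.drop(columns="district").copy()
        dup["radio_copy"] = dup["radio"]
        model2 = AssetIndex(screen=False).fit(dup)
        rho = stats.spearmanr(
            score_households(survey, model), model2.transform(dup)
        ).statistic
        assert rho > 0.95


class TestScoring:
    def _toy_model(self, variables, means, stds, loadings):
        m = AssetIndex()
        m.retained_variables_ = list(variables)
        m.means_ = np.asarray(means, dtype=float)
        m.stds_ = np.asarray(stds, dtype=float)
        m.loadings_ = np.asarray(loadings, dtype=float)
        m.factor_scores_ = m.loadings_
        return m

    def test_household_at_the_sample_mean_scores_zero(self):
        m = self._toy_model(["a", "b"], [0.3, 0.7], [0.46, 0.46], [0.7, 0.7])
        assert score_household({"a": 0.3, "b": 0.7}, m) == pytest.approx(0.0)

    def test_single_variable_hand_arithmetic(self):
        m = self._toy_model(["a"], [0.5], [0.5], [1.0])
        assert score_household({"a": 1}, m) == pytest.approx(1.0)

    def test_published_car_truck_weights_give_printed_contribution(self):
        # owner household under the published mean/SD/factor score:
        # 0.068 * (1 - 0.009) / 0.093 = 0.7246
        m = self._toy_model(["car_truck"], [0.009], [0.093], [0.068])
        assert score_household({"car_truck": 1}, m) == pytest.approx(0.7246, abs=5e-5)

    def test_missing_retained_variable_is_named(self):
        m = self._toy_model(["a", "b"], [0.5, 0.5], [0.5, 0.5], [0.7, 0.7])
        with pytest.raises(ValueError, match="'b'"):
            score_household({"a": 1}, m)
        with pytest.raises(ValueError, match="'b'"):
            m.transform(pd.DataFrame({"a": [1]}))


class TestAggregation:
    def test_single_district_mean(self):
        out = aggregate_to_districts(
            pd.Series([1.0, 2.0, 3.0]), pd.Series(["A", "A", "A"])
        )
        assert out["A"] == pytest.approx(2.0)

    def test_two_singleton_districts(self):
        out = aggregate_to_districts(
            pd.Series([-1.0, 1.0]), pd.Series(["A", "B"])
        )
        assert out.tolist() == [-1.0, 1.0]

    def test_matches_streaming_one_pass_oracle(self, default_fit):
        survey, _, model = default_fit
        scores = score_households(survey, model)
        batch = aggregate_to_districts(scores, survey["district"])
        stream = streaming_mean_by_group(scores.tolist(), survey["district"].tolist())
        for d, v in stream.items():
            assert batch[d] == pytest.approx(v, abs=1e-12)

    def test_population_weighted_option(self):
        out = aggregate_to_districts(
            pd.Series([0.0, 1.0]), pd.Series(["A", "A"]),
            weights=pd.Series([1.0, 3.0]),
        )
        assert out["A"] == pytest.approx(0.75)


class TestNormalization:
    def test_published_shift_arithmetic(self):
        # the printed shift 1.4669 brings a raw value of -0.4669 to 1
        raw = pd.Series({"Ntchisi": -0.4669, "Other": 0.5})
        idx = normalize_indices(raw)
        assert idx.shift_constant == pytest.approx(1.4669)
        assert idx.normalized_index["Ntchisi"] == 1.0
        assert idx.normalized_index["Other"] == pytest.approx(1.9669)

    def test_already_normalized_is_unchanged(self):
        raw = pd.Series({"A": 1.0, "B": 2.0})
        idx = normalize_indices(raw)
        assert idx.shift_constant == 0.0
        assert idx.normalized_index.tolist() == [1.0, 2.0]

    def test_degenerate_equal_raw_all_map_to_one(self):
        idx = normalize_indices(pd.Series({"A": 3.3, "B": 3.3}))
        assert (idx.normalized_index == 1.0).all()

    def test_minimum_maps_to_exactly_one(self):
        rng = np.random.default_rng(5)
        for _ in range(20):
            raw = pd.Series(rng.normal(size=10))
            idx = normalize_indices(raw)
            assert idx.normalized_index.min() == 1.0

    def test_empty_input_is_error(self):
        with pytest.raises(ValueError):
            normalize_indices(pd.Series(dtype=float))


class TestEndToEndDirection:
    def test_normalized_index_anticorrelates_with_true_stunting(self, default_fit):
        """Negative stunting slope: richer districts (higher index) have
        lower true stunting, matching the published direction."""
        survey, truth, model = default_fit
        scores = score_households(survey, model)
        idx = normalize_indices(aggregate_to_districts(scores, survey["district"]))
        t = truth.set_index("district")
        rho = stats.spearmanr(
            idx.normalized_index, t["true_stunting_rate"].reindex(idx.normalized_index.index)
        ).statistic
        assert rho < -0.5
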