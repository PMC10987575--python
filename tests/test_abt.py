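"""Aggregated boosted trees: fitting, determinism and relative influence."""

import numpy as np
import pandas as pd
import pytest

from pamg.abt import AbtParams, fit_abt, predict, raw_influence, relative_influence

FAST = AbtParams(n_trees=150, max_depth=2, shrinkage=0.1, bag_fraction=0.8, n_replicates=3)


def make_data(n=100, seed=0, n_noise=3):
    rng = np.random.default_rng(seed)
    X = pd.DataFrame({"x1": rng.normal(size=n)})
    for i in range(n_noise):
        X[f"noise{i}"] = rng.normal(size=n)
    y = 3 * X["x1"] + rng.normal(scale=0.1, size=n)
    return X, y


class TestFit:
    def test_deterministic_given_seed(self):
        X, y = make_data()
        m1 = fit_abt(X, y, FAST, seed=7)
        m2 = fit_abt(X, y, FAST, seed=7)
        assert np.allclose(predict(m1, X), predict(m2, X))
        pd.testing.assert_series_equal(relative_influence(m1), relative_influence(m2))

    def test_different_seed_differs(self):
        X, y = make_data()
        m1 = fit_abt(X, y, FAST, seed=7)
        m2 = fit_abt(X, y, FAST, seed=8)
        assert not np.allclose(predict(m1, X), predict(m2, X))

    def test_exact_linear_target_is_learned(self):
        rng = np.random.default_rng(1)
        X = pd.DataFrame({"x1": rng.normal(size=200)})
        y = X["x1"].copy()
        params = AbtParams(n_trees=500, max_depth=3, shrinkage=0.1,
                           bag_fraction=1.0, n_replicates=1)
        model = fit_abt(X, y, params, seed=7)
        mse = float(np.mean((predict(model, X) - y) ** 2))
        assert mse < 1e-3

    def test_parameter_validation(self):
        with pytest.raises(ValueError):
            AbtParams(n_trees=0)
        with pytest.raises(ValueError):
            AbtParams(shrinkage=0.0)
        with pytest.raises(ValueError):
            AbtParams(bag_fraction=1.5)

    def test_constant_response_errors(self):
        X, _ = make_data(n=30)
        with pytest.raises(ValueError):
            fit_abt(X, np.ones(30), FAST)

    def test_too_few_rows_errors(self):
        X, y = make_data(n=10)
        with pytest.raises(ValueError):
            fit_abt(X, y, FAST)

    def test_missing_values_error(self):
        X, y = make_data(n=30)
        X.loc[0, "x1"] = np.nan
        with pytest.raises(ValueError):
            fit_abt(X, y, FAST)

    def test_single_level_categorical_warns(self):
        X, y = make_data(n=30)
        X["site"] = "only_site"
        with pytest.warns(UserWarning):
            fit_abt(X, y, FAST, categorical=["site"])


class TestInfluence:
    def test_single_predictor_is_100(self):
        rng = np.random.default_rng(2)
        X = pd.DataFrame({"x1": rng.normal(size=50)})
        y = X["x1"] + rng.normal(scale=0.1, size=50)
        infl = relative_influence(fit_abt(X, y, FAST, seed=1))
        assert infl["x1"] == pytest.approx(100.0)

    def test_sums_to_100(self):
        X, y = make_data(seed=3)
        infl = relative_influence(fit_abt(X, y, FAST, seed=3))
        assert infl.sum() == pytest.approx(100.0, abs=1e-6)
        assert (infl >= 0).all()

    def test_dominant_signal_ranked_first(self):
        X, y = make_data(n=200, seed=4)
        infl = relative_influence(fit_abt(X, y, FAST, seed=4))
        assert infl.index[0] == "x1"
        assert infl["x1"] > 70

    def test_categorical_site_grouped_to_one_predictor(self):
        rng = np.random.default_rng(5)
        n = 120
        X = pd.DataFrame(
            {
                "x1": rng.normal(size=n),
                "site": rng.choice([f"s{i}" for i in range(10)], size=n),
            }
        )
        y = 2 * X["x1"] + rng.normal(scale=0.5, size=n)
        infl = relative_influence(fit_abt(X, y, FAST, seed=5, categorical=["site"]))
        assert set(infl.index) == {"x1", "site"}
        assert infl.sum() == pytest.approx(100.0, abs=1e-6)

    def test_duplicated_signal_predictors_dominate_jointly(self):
        rng = np.random.default_rng(6)
        n = 150
        x = rng.normal(size=n)
        X = pd.DataFrame(
            {"a": x, "b": x.copy(), "noise1": rng.normal(size=n), "noise2": rng.normal(size=n)}
        )
        y = 3 * x + rng.normal(scale=0.2, size=n)
        infl = relative_influence(fit_abt(X, y, FAST, seed=6))
        assert infl["a"] + infl["b"] > max(infl["noise1"], infl["noise2"])

    def test_noise_permutation_changes_influence_little(self):
        X, y = make_data(n=150, seed=7)
        infl1 = relative_influence(fit_abt(X, y, FAST, seed=7))
        X2 = X.copy()
        rng = np.random.default_rng(123)
        X2["noise0"] = rng.permutation(X2["noise0"].to_numpy())
        infl2 = relative_influence(fit_abt(X2, y, FAST, seed=7))
        assert abs(infl1["noise0"] - infl2["noise0"]) < 5.0

    def test_unfitted_model_errors(self):
        from pamg.abt import AbtModel

        model = AbtModel([], [], {}, FAST, 0, [])
        with pytest.raises(ValueError):
            raw_influence(model)

    def test_added_irrelevant_predictor_does_not_boost_signal(self):
        """Statistically over 20 seeds, adding pure noise never systematically
        increases the signal predictor's raw (unnormalized) influence."""
        small = AbtParams(n_trees=100, max_depth=2, shrinkage=0.1,
                          bag_fraction=0.8, n_replicates=2)
        deltas, bases = [], []
        for seed in range(20):
            X, y = make_data(n=60, seed=seed, n_noise=2)
            base = raw_influence(fit_abt(X, y, small, seed=seed))["x1"]
            rng = np.random.default_rng(1000 + seed)
            X2 = X.copy()
            X2["extra"] = rng.normal(size=len(X2))
            wider = raw_influence(fit_abt(X2, y, small, seed=seed))["x1"]
            deltas.append(wider - base)
            bases.append(base)
        assert np.mean(deltas) <= 0.05 * np.mean(bases)
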