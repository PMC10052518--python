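"""Selection, training and cross-validation on tabular synthetic data
with known generative truth (no structure modeling in this module)."""

import numpy as np
import pandas as pd
import pytest

from fcaffinity.learning import (
    LearningError,
    RegressorConfig,
    correlation_prune,
    cross_validate,
    eliminate_features,
    importance_rank,
    shuffled_control,
    standardize,
)

ALGOS = ("SVR", "MLR", "MLP", "RFR")


def linear_table(n=500, n_noise=5, sigma=0.1, seed=0, weights=(3.0,)):
    """y = w·x + noise over standard-normal informative features plus
    pure-noise features."""
    rng = np.random.default_rng(seed)
    k = len(weights)
    X = pd.DataFrame(
        rng.normal(size=(n, k + n_noise)),
        columns=[f"x{i + 1}" for i in range(k)]
        + [f"noise{i + 1}" for i in range(n_noise)],
    )
    y = X.iloc[:, :k].to_numpy() @ np.array(weights) + \
        rng.normal(0, sigma, size=n)
    return X, y


class TestStandardize:
    def test_training_set_maps_to_zero_mean_unit_var(self):
        X, _ = linear_table(n=200)
        Xs, _, scaler, kept = standardize(X)
        assert kept == list(X.columns)
        np.testing.assert_allclose(Xs.mean(axis=0), 0.0, atol=1e-12)
        np.testing.assert_allclose(Xs.std(axis=0, ddof=0), 1.0, rtol=1e-9)

    def test_constant_column_dropped_with_warning(self):
        X, _ = linear_table(n=50)
        X["flat"] = 3.14
        with pytest.warns(UserWarning, match="constant"):
            Xs, _, _, kept = standardize(X)
        assert "flat" not in kept and "flat" not in Xs.columns

    def test_apply_to_uses_training_parameters(self):
        X, _ = linear_table(n=200)
        train, test = X.iloc[:150], X.iloc[150:]
        _, test_s, scaler, kept = standardize(train, test)
        manual = (test[kept] - train[kept].mean()) / train[kept].std(ddof=0)
        np.testing.assert_allclose(test_s.values, manual.values, rtol=1e-9)


class TestImportance:
    @pytest.mark.parametrize("algo", ALGOS)
    def test_informative_feature_ranks_first(self, algo):
        X, y = linear_table(n=500, sigma=0.1, seed=1)
        imps = importance_rank(X, y, RegressorConfig(algo), seed=1)
        assert imps.idxmax() == "x1"
        assert imps.sum() == pytest.approx(1.0, abs=1e-9)

    @pytest.mark.parametrize("algo", ("SVR", "MLP"))
    def test_noise_features_have_negligible_permutation_importance(self, algo):
        X, y = linear_table(n=500, sigma=0.1, seed=1)
        imps = importance_rank(X, y, RegressorConfig(algo), seed=1)
        assert imps[[c for c in X.columns if c.startswith("noise")]].max() < 0.05


class TestElimination:
    def test_informative_features_survive(self):
        X, y = linear_table(n=400, n_noise=7, sigma=0.1, seed=2,
                            weights=(3.0, 2.0, 1.5))
        kept = eliminate_features(X, y, RegressorConfig("MLR"), seed=2)
        assert {"x1", "x2", "x3"} <= set(kept)

    def test_single_feature_returned_unchanged(self):
        X, y = linear_table(n=100, n_noise=0)
        assert eliminate_features(X, y, RegressorConfig("MLR")) == ["x1"]

    def test_infinite_tolerance_reduces_to_one_feature(self):
        X, y = linear_table(n=200, n_noise=4, seed=3)
        kept = eliminate_features(X, y, RegressorConfig("MLR"), seed=3,
                                  tolerance=np.inf)
        assert len(kept) == 1


class TestCorrelationPrune:
    def test_duplicated_column_dropped_once(self):
        X, _ = linear_table(n=300, seed=4)
        X["x1_copy"] = X["x1"]
        imps = pd.Series(1.0, index=X.columns)
        imps["x1_copy"] = 0.1
        kept = correlation_prune(X, importances=imps)
        assert "x1" in kept and "x1_copy" not in kept

    def test_independent_columns_untouched(self):
        X, _ = linear_table(n=1000, n_noise=8, seed=5)
        assert correlation_prune(X) == list(X.columns)

    def test_idempotent(self):
        X, _ = linear_table(n=300, seed=6)
        X["dup"] = X["noise1"]
        kept = correlation_prune(X)
        assert correlation_prune(X[kept]) == kept


class TestFit:
    def test_mlr_recovers_exact_linear_coefficients(self):
        X, _ = linear_table(n=100, n_noise=0, weights=(2.0, -1.0))
        y = 2.0 * X["x1"].to_numpy() - 1.0 * X["x2"].to_numpy() + 0.5
        est = RegressorConfig("MLR").make_estimator()
        est.fit(X.values, y)
        np.testing.assert_allclose(est.coef_, [2.0, -1.0], atol=1e-8)
        assert est.intercept_ == pytest.approx(0.5, abs=1e-8)

    def test_svr_on_constant_target_stays_within_tube(self):
        X, _ = linear_table(n=100, n_noise=0)
        y = np.full(len(X), -7.0)
        est = RegressorConfig("SVR").make_estimator()
        est.fit(X.values, y)
        assert np.all(np.abs(est.predict(X.values) + 7.0) <= 0.1 + 1e-9)

    def test_rfr_train_score_bounds_test_score(self):
        X, y = linear_table(n=400, sigma=0.5, seed=7)
        est = RegressorConfig("RFR").make_estimator(seed=7)
        tr, te = slice(0, 300), slice(300, 400)
        est.fit(X.values[tr], y[tr])
        assert est.score(X.values[tr], y[tr]) >= est.score(X.values[te], y[te])


class TestCrossValidation:
    def test_noiseless_linear_data_is_perfect_for_mlr(self):
        X, _ = linear_table(n=200, n_noise=2)
        y = X["x1"].to_numpy() * 2.0 - 1.0
        report = cross_validate(X, y, RegressorConfig("MLR"), seed=0)
        assert report.mean_r2 >= 0.999
        assert report.n_folds == 10

    def test_fold_sizes_differ_by_at_most_one(self):
        X, y = linear_table(n=105)
        from sklearn.model_selection import KFold
        sizes = [len(te) for _, te in KFold(10, shuffle=True,
                                            random_state=0).split(X)]
        assert max(sizes) - min(sizes) <= 1

    def test_r2_matches_analytic_signal_fraction(self):
        # Var(signal)/Var(total) = 0.8 -> expected R² ≈ 0.8
        scores = []
        for seed in range(10):
            X, y = linear_table(n=1000, n_noise=2, sigma=0.5, seed=seed,
                                weights=(1.0,))
            report = cross_validate(X, y, RegressorConfig("MLR"), seed=seed)
            scores.append(report.mean_r2)
        assert np.mean(scores) == pytest.approx(0.8, abs=0.05)

    def test_monotone_degradation_with_noise(self):
        means = []
        for sigma in (0.0, 0.1, 0.3, 1.0):
            vals = [cross_validate(*linear_table(n=300, sigma=sigma, seed=s),
                                   RegressorConfig("MLR"), seed=s).mean_r2
                    for s in range(10)]
            means.append(np.mean(vals))
        assert all(a >= b for a, b in zip(means, means[1:]))

    def test_too_few_samples_rejected(self):
        X, y = linear_table(n=5)
        with pytest.raises(LearningError):
            cross_validate(X, y, RegressorConfig("MLR"), k=10)


class TestShuffledControl:
    @pytest.mark.parametrize("algo", ALGOS)
    def test_shuffling_destroys_the_fit(self, algo):
        X, y = linear_table(n=300, sigma=0.2, seed=8)
        scores = [shuffled_control(X, y, RegressorConfig(algo), seed=s).mean_r2
                  for s in range(5)]
        assert np.mean(scores) <= 0.05

    def test_shuffled_error_exceeds_unshuffled(self):
        X, y = linear_table(n=300, sigma=0.2, seed=9)
        cfg = RegressorConfig("MLR")
        real = cross_validate(X, y, cfg, seed=9)
        shuffled = shuffled_control(X, y, cfg, seed=9)
        assert shuffled.mean_mae >= real.mean_mae

    def test_identity_permutation_equals_cross_validate(self):
        X, y = linear_table(n=200, seed=10)
        cfg = RegressorConfig("MLR")
        a = cross_validate(X, y, cfg, seed=10)
        b = shuffled_control(X, y, cfg, seed=10,
                             permutation=np.arange(len(y)))
        assert a.r2 == b.r2 and a.mae == b.mae


def test_cvreport_serializes_to_plain_types():
    X, y = linear_table(n=100)
    report = cross_validate(X, y, RegressorConfig("MLR"))
    d = report.to_dict()
    import json
    json.dumps(d)
    assert d["folds"] == 10 and len(d["r2"]) == 10
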