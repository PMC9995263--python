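"""Prediction pipelines: leakage-free fitting, overfitting behaviour, netmats."""

from __future__ import annotations

import numpy as np
import pytest

import bwasrep as b
from bwasrep.errors import ConfigError, DataError, FitError, NumericalError, SizeError
from bwasrep.models import _VarianceCappedPCA


@pytest.fixture(scope="module")
def small_signal():
    rng = np.random.default_rng(0)
    X = rng.standard_normal((60, 8))
    y = X[:, 0].copy()
    return X, y


class TestFitPredict:
    def test_exact_linear_signal_near_interpolated(self, small_signal):
        X, y = small_signal
        m = b.fit(b.ModelSpec(ridge_shrinkage=1e-8), X, y)
        r = b.prediction_outcome_r(b.predict(m, X), y)
        assert r >= 0.999

    def test_underdetermined_ridge_interpolates_any_outcome(self):
        rng = np.random.default_rng(1)
        X = rng.standard_normal((30, 40))
        y = rng.standard_normal(30)
        m = b.fit(b.ModelSpec(ridge_shrinkage=1e-8), X, y)
        assert b.prediction_outcome_r(b.predict(m, X), y) >= 0.99

    def test_pca_svr_overfits_permuted_outcome_insample(self, ds_wide):
        rng = np.random.default_rng(2)
        rs = []
        for i in range(5):
            idx = rng.choice(ds_wide.n_samples, 200, replace=False)
            y_perm = rng.permutation(ds_wide.outcome[idx])
            m = b.fit(b.ModelSpec(family="pca_svr"), ds_wide.features[idx], y_perm)
            rs.append(b.prediction_outcome_r(b.predict(m, ds_wide.features[idx]), y_perm))
        assert np.mean(rs) > 0.3

    def test_constant_outcome_rejected(self, small_signal):
        X, _ = small_signal
        with pytest.raises(FitError, match="constant"):
            b.fit(b.ModelSpec(), X, np.ones(len(X)))

    def test_too_few_samples_rejected(self):
        with pytest.raises(SizeError):
            b.fit(b.ModelSpec(), np.ones((3, 2)), np.array([1.0, 2.0, 3.0]))

    def test_predict_pure_and_shape_checked(self, small_signal):
        X, y = small_signal
        m = b.fit(b.ModelSpec(), X, y)
        np.testing.assert_array_equal(b.predict(m, X), b.predict(m, X))
        assert b.predict(m, X[0]).shape == (1,)
        with pytest.raises(DataError, match="feature count"):
            b.predict(m, X[:, :5])

    def test_infinite_shrinkage_predicts_training_mean(self, small_signal):
        X, y = small_signal
        m = b.fit(b.ModelSpec(ridge_shrinkage=1e12), X, y)
        np.testing.assert_allclose(b.predict(m, X), np.full(len(y), y.mean()), atol=1e-3)

    def test_weight_table_reproduces_ridge_predictions(self, small_signal):
        X, y = small_signal
        m = b.fit(b.ModelSpec(), X, y, feature_names=np.array([f"e{i}" for i in range(8)]))
        w = m.weight_table()
        assert list(w.columns) == ["feature", "weight"]
        # manual linear readout: weights on raw features + implied intercept
        manual = X @ w["weight"].to_numpy()
        manual += b.predict(m, np.zeros((1, 8)))[0]
        np.testing.assert_allclose(manual, b.predict(m, X), atol=1e-8)


class TestCrossValidation:
    def test_loo_strong_signal(self, small_signal):
        X, y = small_signal
        preds = b.cross_validated_predictions(
            b.ModelSpec(ridge_shrinkage=1e-8), X, y, k_folds=len(y), seed=0
        )
        assert b.prediction_outcome_r(preds, y) >= 0.99

    def test_same_seed_identical_predictions(self, small_signal):
        X, y = small_signal
        p1 = b.cross_validated_predictions(b.ModelSpec(), X, y, k_folds=5, seed=3)
        p2 = b.cross_validated_predictions(b.ModelSpec(), X, y, k_folds=5, seed=3)
        np.testing.assert_array_equal(p1, p2)

    def test_leakage_guard_corrupting_heldout_outcomes(self, small_signal):
        """Out-of-fold predictions must not depend on the held-out fold's y."""
        from sklearn.model_selection import KFold

        X, y = small_signal
        spec = b.ModelSpec()
        baseline = b.cross_validated_predictions(spec, X, y, k_folds=5, seed=7)
        rng = np.random.default_rng(7)
        kf_seed = int(rng.integers(2**31))
        kf = KFold(n_splits=5, shuffle=True, random_state=kf_seed)
        test_idx = next(iter(kf.split(X)))[1]
        y_corrupt = y.copy()
        y_corrupt[test_idx] += 100.0  # only held-out outcomes of the first fold
        corrupted = b.cross_validated_predictions(spec, X, y_corrupt, k_folds=5, seed=7)
        np.testing.assert_array_equal(baseline[test_idx], corrupted[test_idx])

    def test_ridge_invariant_to_feature_rescaling(self, small_signal):
        X, y = small_signal
        spec = b.ModelSpec()
        p1 = b.cross_validated_predictions(spec, X, y, k_folds=5, seed=1)
        p2 = b.cross_validated_predictions(spec, X * 37.0 - 5.0, y, k_folds=5, seed=1)
        np.testing.assert_allclose(p1, p2, atol=1e-8)

    def test_k_folds_bounds(self, small_signal):
        X, y = small_signal
        with pytest.raises(SizeError):
            b.cross_validated_predictions(b.ModelSpec(), X, y, k_folds=len(y) + 1)
        with pytest.raises(SizeError):
            b.cross_validated_predictions(b.ModelSpec(), X, y, k_folds=1)


class TestPCAComponentCap:
    def test_components_never_exceed_n_train_minus_one(self):
        rng = np.random.default_rng(3)
        X = rng.standard_normal((20, 100))
        pca = _VarianceCappedPCA(variance_kept=1.0, max_components=250).fit(X)
        assert pca.n_components_ <= 19

    def test_variance_target_reached_with_fewest_components(self):
        rng = np.random.default_rng(4)
        X = rng.standard_normal((200, 10))
        pca = _VarianceCappedPCA(variance_kept=0.5, max_components=250).fit(X)
        cum = np.cumsum(pca.pca_.explained_variance_ratio_)
        assert cum[pca.n_components_ - 1] >= 0.5
        assert pca.n_components_ == 1 or cum[pca.n_components_ - 2] < 0.5

    def test_pca_svr_metadata_records_components(self):
        rng = np.random.default_rng(5)
        X = rng.standard_normal((40, 60))
        y = rng.standard_normal(40)
        m = b.fit(b.ModelSpec(family="pca_svr"), X, y)
        md = m.metadata()
        assert md["n_components"] == m.n_components <= 39
        assert md["svr_epsilon"] == 0.1


class TestPartialCorrelation:
    def test_two_nodes_equals_pearson(self):
        rng = np.random.default_rng(6)
        x = rng.standard_normal(500)
        ts = np.stack([x, 0.6 * x + 0.8 * rng.standard_normal(500)], axis=1)
        pc = b.partial_correlation_matrix(ts, regularization=0.0)
        assert pc[0, 1] == pytest.approx(np.corrcoef(ts, rowvar=False)[0, 1], abs=1e-10)

    def test_chain_conditional_independence(self):
        omega = np.array([[2.0, -0.8, 0.0], [-0.8, 2.5, -0.8], [0.0, -0.8, 2.0]])
        ts, _ = b.generate_node_timeseries(3, 10_000, seed=10, precision=omega)
        pc = b.partial_correlation_matrix(ts, regularization=0.0)
        assert pc[0, 2] == pytest.approx(0.0, abs=0.05)

    def test_zero_regularization_matches_precision_formula(self):
        rng = np.random.default_rng(7)
        ts = rng.standard_normal((400, 5))
        pc = b.partial_correlation_matrix(ts, regularization=0.0)
        omega = np.linalg.inv(np.cov(ts, rowvar=False))
        d = np.sqrt(np.diag(omega))
        expected = -omega / np.outer(d, d)
        np.fill_diagonal(expected, 1.0)
        np.testing.assert_allclose(pc, expected, rtol=1e-10)

    def test_singular_covariance_instructs_regularization(self):
        ts = np.random.default_rng(8).standard_normal((5, 10))  # rank-deficient
        with pytest.raises(NumericalError, match="regularization"):
            b.partial_correlation_matrix(ts, regularization=0.0)


class TestVectorizeEdges:
    def test_upper_triangle_order_and_length(self):
        m = np.array([[1.0, 2.0, 3.0], [2.0, 1.0, 4.0], [3.0, 4.0, 1.0]])
        np.testing.assert_array_equal(b.vectorize_edges(m), [2.0, 3.0, 4.0])
        assert b.vectorize_edges(np.eye(5)).tolist() == [0.0] * 10
        d = 100
        sym = np.zeros((d, d))
        assert b.vectorize_edges(sym).shape == (d * (d - 1) // 2,)

    def test_asymmetric_rejected(self):
        m = np.array([[1.0, 0.5], [0.4, 1.0]])
        with pytest.raises(DataError, match="asymmetric"):
            b.vectorize_edges(m)


class TestModelSpec:
    def test_round_trip_and_unknown_fields(self):
        spec = b.ModelSpec(family="pca_svr", pca_variance_kept=0.8)
        assert b.ModelSpec.from_dict(spec.to_dict()) == spec
        with pytest.raises(ConfigError, match="unknown"):
            b.ModelSpec.from_dict({"kernel": "rbf"})

    @pytest.mark.parametrize(
        "bad",
        [
            {"family": "lasso"},
            {"ridge_shrinkage": 0.0},
            {"pca_variance_kept": 1.5},
            {"svr_c": -1.0},
        ],
    )
    def test_invalid_specs_rejected(self, bad):
        with pytest.raises(ConfigError):
            b.ModelSpec(**bad).validate()
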