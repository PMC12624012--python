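"""Modeling protocol: metrics, scaling policies, HPO, dynamic CV, leakage."""

import numpy as np
import pandas as pd
import pytest
from hypothesis import given, settings
from hypothesis import strategies as st

from cpsrec.augmentation import MixupAugmenter
from cpsrec.cohort import OUTCOME
from cpsrec.modeling import (
    FeedforwardRegressor,
    FittedPredictor,
    MetricsReport,
    ModelSpec,
    compute_metrics,
    dynamic_cv,
    evaluate_holdout,
    train_final,
    tune_hyperparameters,
)
from cpsrec.partitioning import make_folds


class TestComputeMetrics:
    def test_perfect_prediction(self):
        m = compute_metrics([1.0, 2.0, 3.0], [1.0, 2.0, 3.0])
        assert (m.mae, m.rmse, m.r2) == (0.0, 0.0, 1.0)

    def test_mean_predictor_r2_zero(self):
        y = np.array([1.0, 2.0, 3.0, 4.0])
        m = compute_metrics(y, np.full(4, y.mean()))
        assert m.r2 == pytest.approx(0.0)

    def test_hand_arithmetic_case(self):
        m = compute_metrics([0.0, 0.0, 3.0], [0.0, 0.0, 0.0])
        assert m.mae == pytest.approx(1.0)
        assert m.rmse == pytest.approx(np.sqrt(3.0))

    def test_zero_variance_truth_flagged(self):
        m = compute_metrics([5.0, 5.0, 5.0], [4.0, 5.0, 6.0])
        assert m.flagged and np.isnan(m.r2)

    @settings(max_examples=100, deadline=None)
    @given(st.integers(0, 10_000))
    def test_rmse_dominates_mae(self, seed):
        rng = np.random.default_rng(seed)
        n = int(rng.integers(2, 50))
        y, p = rng.normal(size=n), rng.normal(size=n)
        m = compute_metrics(y, p)
        assert m.rmse >= m.mae - 1e-12
        assert m.r2 <= 1.0

    def test_input_validation(self):
        with pytest.raises(ValueError):
            compute_metrics([1.0], [1.0])
        with pytest.raises(ValueError):
            compute_metrics([1.0, 2.0], [1.0, np.nan])


def _linear_table(n=120, d=4, noise=0.0, seed=0, scale=1.0):
    rng = np.random.default_rng(seed)
    X = rng.normal(size=(n, d))
    cols = {f"f{i}": X[:, i] for i in range(d)}
    y = scale * (3.0 * X[:, 0] - 2.0 * X[:, 1]) + rng.normal(0, noise, n)
    t = pd.DataFrame(cols)
    t[OUTCOME] = y
    return t


class TestScalingPolicies:
    def test_policy_determined_by_family(self):
        assert ModelSpec("boosted-trees").scaling_policy == "none"
        assert ModelSpec("kernel-svr").scaling_policy == "X-only"
        assert ModelSpec("feedforward-net").scaling_policy == "X-and-y"
        with pytest.raises(ValueError, match="family"):
            ModelSpec("random-forest")

    def test_x_and_y_roundtrip_returns_original_scale(self):
        """The net trains on z-scored targets but predicts in meters."""
        t = _linear_table(n=300, noise=0.01, seed=1, scale=500.0)
        t[OUTCOME] += 14_000
        spec = ModelSpec(
            "feedforward-net",
            {"hidden_dims": (64,), "learning_rate": 0.01, "batch_size": 32,
             "dropout_rate": 0.0, "weight_decay": 0.0},
            seed=0,
        )
        pred = train_final(t, None, spec, augmentation_ratio=0.0, seed=0)
        yhat = pred.predict(t.drop(columns=[OUTCOME]))
        assert 10_000 < yhat.mean() < 18_000
        m = compute_metrics(t[OUTCOME].to_numpy(), yhat)
        assert m.r2 > 0.9

    def test_svr_x_only_keeps_target_scale(self):
        t = _linear_table(n=200, noise=0.01, seed=2, scale=100.0)
        t[OUTCOME] += 5_000
        spec = ModelSpec("kernel-svr", {"kernel": "linear", "C": 100, "epsilon": 0.1})
        pred = train_final(t, None, spec, augmentation_ratio=0.0, seed=0)
        assert pred.y_scaler_ is None and pred.x_scaler_ is not None
        yhat = pred.predict(t.drop(columns=[OUTCOME]))
        assert 4_000 < yhat.mean() < 6_000


class TestTuneHyperparameters:
    def test_one_to_one_table_size(self, dev_table):
        """With |dev| = 184 the HPO table holds 368 rows (tracked via the
        augmenter's sample count)."""
        calls = []

        class Spy(MixupAugmenter):
            def sample(self, n, seed=0):
                calls.append(n)
                return super().sample(n, seed)

        aug = Spy().fit(dev_table)
        tune_hyperparameters(
            dev_table, aug, "boosted-trees",
            space={"n_estimators": [50], "max_depth": [3]}, n_iter=1, seed=0,
        )
        assert calls == [184]  # 184 original + 184 synthetic = 368

    def test_single_candidate_returned(self, dev_table):
        best, score = tune_hyperparameters(
            dev_table, None, "boosted-trees",
            space={"n_estimators": [60], "max_depth": [4]}, n_iter=1, seed=0,
        )
        assert best == {"n_estimators": 60, "max_depth": 4}
        assert score < 0  # negative MAE

    def test_planted_winner_selected(self):
        """On a learnable signal, the crippled configuration loses to the
        one with adequate capacity."""
        t = _linear_table(n=250, noise=0.05, seed=3)
        space = {"n_estimators": [1, 300], "max_depth": [1, 5],
                 "learning_rate": [0.3]}
        best, _ = tune_hyperparameters(
            t, None, "boosted-trees", space=space, n_iter=4, seed=0
        )
        assert best["n_estimators"] == 300

    def test_empty_space_rejected(self, dev_table):
        with pytest.raises(ValueError, match="empty"):
            tune_hyperparameters(dev_table, None, "boosted-trees", space={})

    def test_unfitted_or_mismatched_augmenter_rejected(self, dev_table):
        with pytest.raises(ValueError, match="not fitted"):
            tune_hyperparameters(dev_table, MixupAugmenter(), "boosted-trees",
                                 space={"n_estimators": [10]}, n_iter=1)
        other = MixupAugmenter().fit(dev_table.iloc[:50])
        with pytest.raises(ValueError, match="leakage"):
            tune_hyperparameters(dev_table, other, "boosted-trees",
                                 space={"n_estimators": [10]}, n_iter=1)


XGB_FAST = {"n_estimators": 80, "max_depth": 5, "learning_rate": 0.3}


class TestDynamicCv:
    def test_fold_sizes_with_one_to_one_ratio(self, dev_table, split_231):
        folds = make_folds(split_231.development_indices, 5, seed=42,
                           bin_labels=split_231.bin_labels)
        spec = ModelSpec("boosted-trees", XGB_FAST, seed=0)
        cv = dynamic_cv(dev_table, folds, spec,
                        augmenter_factory=MixupAugmenter,
                        augmentation_ratio=1.0, seed=0)
        for n_orig, n_synth, n_val in cv.fold_sizes:
            assert n_orig == n_synth  # 1:1 per-fold augmentation
            assert n_orig + n_synth in (294, 296)  # ~147 + ~147
            assert n_orig + n_val == 184

    def test_ratio_zero_is_plain_cv(self, dev_table, split_231):
        folds = make_folds(split_231.development_indices, 5, seed=42)
        spec = ModelSpec("boosted-trees", XGB_FAST, seed=0)
        cv = dynamic_cv(dev_table, folds, spec, augmenter_factory=MixupAugmenter,
                        augmentation_ratio=0.0, seed=0)
        assert all(s == 0 for _, s, _ in cv.fold_sizes)

    def test_learnable_signal_high_validation_r2(self):
        t = _linear_table(n=300, noise=0.01, seed=4)
        folds = make_folds(t.index.to_numpy(), 5, seed=0)
        spec = ModelSpec("boosted-trees",
                         {"n_estimators": 300, "max_depth": 6, "learning_rate": 0.1},
                         seed=0)
        cv = dynamic_cv(t, folds, spec, augmentation_ratio=0.0, seed=0)
        assert cv.mean_validation.r2 > 0.95

    def test_rejects_non_partitioning_folds(self, dev_table):
        bad_folds = [dev_table.index.to_numpy()[:10]]
        spec = ModelSpec("boosted-trees", XGB_FAST)
        with pytest.raises(ValueError, match="partition"):
            dynamic_cv(dev_table, bad_folds, spec)

    def test_learning_curves_recorded_for_trees(self, dev_table, split_231):
        folds = make_folds(split_231.development_indices, 5, seed=42)
        spec = ModelSpec("boosted-trees", XGB_FAST, seed=0)
        cv = dynamic_cv(dev_table, folds, spec, augmentation_ratio=0.0, seed=0)
        assert all("val_mae" in c and len(c["val_mae"]) > 0 for c in cv.learning_curves)


class TestFinalTrainingAndHoldout:
    def test_two_to_one_training_rows(self, dev_table):
        aug = MixupAugmenter().fit(dev_table)
        spec = ModelSpec("boosted-trees", XGB_FAST, seed=0)
        pred = train_final(dev_table, aug, spec, augmentation_ratio=2.0, seed=0)
        assert pred.n_training_rows_ == 552  # 184 + 368

    def test_ratio_zero_baseline_rows(self, dev_table):
        spec = ModelSpec("boosted-trees", XGB_FAST, seed=0)
        pred = train_final(dev_table, None, spec, augmentation_ratio=0.0, seed=0)
        assert pred.n_training_rows_ == 184

    def test_holdout_metrics_consistency(self, dev_table, holdout_table):
        spec = ModelSpec("boosted-trees", XGB_FAST, seed=0)
        pred = train_final(dev_table, None, spec, augmentation_ratio=0.0, seed=0)
        m = evaluate_holdout(pred, holdout_table)
        assert m.n == 47
        standalone = compute_metrics(
            holdout_table[OUTCOME].to_numpy(),
            pred.predict(holdout_table.drop(columns=[OUTCOME])),
        )
        assert m.mae == standalone.mae
        assert m.rmse == standalone.rmse
        assert m.r2 == standalone.r2

    def test_holdout_overlap_refused(self, dev_table):
        spec = ModelSpec("boosted-trees", XGB_FAST, seed=0)
        pred = train_final(dev_table, None, spec, augmentation_ratio=0.0, seed=0)
        with pytest.raises(ValueError, match="overlap"):
            evaluate_holdout(pred, dev_table.iloc[:5])

    def test_missing_feature_at_predict_time(self, dev_table, holdout_table):
        spec = ModelSpec("boosted-trees", XGB_FAST, seed=0)
        pred = train_final(dev_table, None, spec, augmentation_ratio=0.0, seed=0)
        with pytest.raises(ValueError, match="lack"):
            pred.predict(holdout_table.drop(columns=[OUTCOME, "CHO"]))


class TestFeedforwardRegressor:
    def test_learns_linear_map_and_is_deterministic(self):
        rng = np.random.default_rng(8)
        X = rng.normal(size=(400, 3))
        y = X @ np.array([1.0, -2.0, 0.5])
        a = FeedforwardRegressor(hidden_dims=(32,), learning_rate=0.01,
                                 batch_size=32, epochs=100, seed=0).fit(X, y)
        b = FeedforwardRegressor(hidden_dims=(32,), learning_rate=0.01,
                                 batch_size=32, epochs=100, seed=0).fit(X, y)
        np.testing.assert_array_equal(a.predict(X), b.predict(X))
        resid = a.predict(X) - y
        assert np.sqrt(np.mean(resid**2)) < 0.2

    def test_early_stopping_restores_best_weights(self):
        rng = np.random.default_rng(9)
        X = rng.normal(size=(200, 2))
        y = X[:, 0] + rng.normal(0, 0.1, 200)
        model = FeedforwardRegressor(hidden_dims=(16,), learning_rate=0.02,
                                     batch_size=32, epochs=500, patience=10,
                                     seed=1).fit(X, y)
        assert len(model.loss_trace_["train"]) < 500  # stopped early
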