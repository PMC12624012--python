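"""Predictive modeling protocol.

Three regressor families predict rowing distance (meters) from the selected
features:

* ``boosted-trees`` — gradient-boosted tree ensemble (XGBoost), no scaling;
* ``kernel-svr`` — kernel support-vector regression, features standardized,
  target on the original scale;
* ``feedforward-net`` — a dropout MLP trained with Adam, features and target
  standardized independently, predictions inverse-transformed to meters.

The augmented protocol has three stages: hyperparameter search on the
development set combined with an equal-size synthetic sample (1:1);
five-fold cross-validation in which each fold's training partition is
independently augmented 1:1 while the validation partition stays purely
original; and final training on the development set plus a double-size
synthetic sample (2:1), evaluated once on the isolated hold-out set.
Every fitted predictor records the original row labels it was trained on,
and the hold-out evaluation refuses any overlap.
"""

from __future__ import annotations

from dataclasses import dataclass, field

import numpy as np
import pandas as pd
from sklearn.metrics import mean_absolute_error, mean_squared_error, r2_score
from sklearn.model_selection import KFold, ParameterSampler
from sklearn.preprocessing import StandardScaler
from sklearn.svm import SVR
from xgboost import XGBRegressor

from cpsrec._nn import MLP, Adam
from cpsrec.cohort import OUTCOME
from cpsrec.spaces import N_ITER, SPACES

FAMILIES = ("boosted-trees", "kernel-svr", "feedforward-net")
SCALING_POLICY = {
    "boosted-trees": "none",
    "kernel-svr": "X-only",
    "feedforward-net": "X-and-y",
}


@dataclass(frozen=True)
class ModelSpec:
    family: str
    hyperparameters: dict = field(default_factory=dict)
    seed: int = 42

    def __post_init__(self):
        if self.family not in FAMILIES:
            raise ValueError(f"unknown model family {self.family!r}")

    @property
    def scaling_policy(self) -> str:
        return SCALING_POLICY[self.family]


@dataclass(frozen=True)
class MetricsReport:
    mae: float
    rmse: float
    r2: float
    n: int
    flagged: bool = False  # R^2 undefined (zero-variance truth)


def compute_metrics(y_true, y_pred) -> MetricsReport:
    """MAE, RMSE and R^2 (SST about the mean of ``y_true``)."""
    y_true = np.asarray(y_true, dtype=float)
    y_pred = np.asarray(y_pred, dtype=float)
    if y_true.shape != y_pred.shape or y_true.ndim != 1:
        raise ValueError("y_true and y_pred must be equal-length vectors")
    if len(y_true) < 2:
        raise ValueError("need at least 2 observations")
    if not (np.isfinite(y_true).all() and np.isfinite(y_pred).all()):
        raise ValueError("non-finite values in metric inputs")
    mae = float(mean_absolute_error(y_true, y_pred))
    rmse = float(np.sqrt(mean_squared_error(y_true, y_pred)))
    if np.var(y_true) == 0:
        return MetricsReport(mae=mae, rmse=rmse, r2=float("nan"),
                             n=len(y_true), flagged=True)
    return MetricsReport(
        mae=mae, rmse=rmse, r2=float(r2_score(y_true, y_pred)), n=len(y_true)
    )


# ---------------------------------------------------------------------------
# feedforward regressor (NumPy)


class FeedforwardRegressor:
    """Dropout MLP regressor trained with Adam on standardized inputs.

    Fixed training settings: MSE loss, ReLU hidden activations, up to 200
    epochs with early stopping (patience 20) on a 10% inner validation
    split; ``weight_decay`` is an L2 penalty on the weights.  Deterministic
    under ``seed``.
    """

    def __init__(
        self,
        hidden_dims=(64, 32),
        learning_rate=1e-3,
        batch_size=32,
        dropout_rate=0.0,
        weight_decay=0.0,
        epochs=200,
        patience=20,
        val_fraction=0.1,
        seed=0,
    ):
        self.hidden_dims = tuple(hidden_dims)
        self.learning_rate = learning_rate
        self.batch_size = batch_size
        self.dropout_rate = dropout_rate
        self.weight_decay = weight_decay
        self.epochs = epochs
        self.patience = patience
        self.val_fraction = val_fraction
        self.seed = seed

    def fit(self, X, y):
        X = np.asarray(X, dtype=float)
        y = np.asarray(y, dtype=float).reshape(-1, 1)
        rng = np.random.default_rng(
            np.random.SeedSequence([int(self.seed) & 0x7FFFFFFF, 0xFF2E])
        )
        n = len(X)
        perm = rng.permutation(n)
        n_val = max(1, int(round(self.val_fraction * n))) if n >= 10 else 0
        val_idx, tr_idx = perm[:n_val], perm[n_val:]
        Xtr, ytr = X[tr_idx], y[tr_idx]
        Xva, yva = X[val_idx], y[val_idx]

        self.net_ = MLP([X.shape[1], *self.hidden_dims, 1], slope=0.0, rng=rng)
        opt = Adam(self.net_.params, lr=self.learning_rate)
        nW = len(self.net_.Ws)
        best_val, best_params, wait = np.inf, None, 0
        self.loss_trace_ = {"train": [], "val": []}
        B = self.batch_size
        for _epoch in range(self.epochs):
            order = rng.permutation(len(Xtr))
            ep_losses = []
            for start in range(0, len(Xtr), B):
                idx = order[start : start + B]
                xb, yb = Xtr[idx], ytr[idx]
                pred, cache = self.net_.forward(
                    xb, dropout_rate=self.dropout_rate, rng=rng, train=True
                )
                err = pred - yb
                ep_losses.append(float(np.mean(err**2)))
                grads, _ = self.net_.backward(cache, 2.0 * err / len(xb))
                if self.weight_decay > 0:
                    for k in range(nW):
                        grads[k] = grads[k] + self.weight_decay * self.net_.Ws[k]
                opt.step(grads)
            self.loss_trace_["train"].append(float(np.mean(ep_losses)))
            if n_val > 0:
                pv, _ = self.net_.forward(Xva)
                val = float(np.mean((pv - yva) ** 2))
                self.loss_trace_["val"].append(val)
                if val < best_val - 1e-12:
                    best_val, wait = val, 0
                    best_params = [p.copy() for p in self.net_.params]
                else:
                    wait += 1
                    if wait >= self.patience:
                        break
        if best_params is not None:
            for p, bp in zip(self.net_.params, best_params):
                p[...] = bp
        return self

    def predict(self, X):
        out, _ = self.net_.forward(np.asarray(X, dtype=float))
        return out.ravel()


def _make_estimator(spec: ModelSpec):
    params = dict(spec.hyperparameters)
    if spec.family == "boosted-trees":
        return XGBRegressor(**params, random_state=spec.seed, n_jobs=1, verbosity=0)
    if spec.family == "kernel-svr":
        return SVR(**params)
    return FeedforwardRegressor(**params, seed=spec.seed)


# ---------------------------------------------------------------------------
# fitted predictor with scaling policy and provenance


class FittedPredictor:
    """A fitted model plus its scaling policy, exposing meters-scale
    predictions on record DataFrames, and carrying the original row labels
    used in fitting for the leakage audit."""

    def __init__(self, spec: ModelSpec, feature_columns, train_index):
        self.spec = spec
        self.feature_columns = list(feature_columns)
        self.train_index = np.asarray(train_index)
        self.x_scaler_ = None
        self.y_scaler_ = None
        self.estimator_ = None
        self.learning_curve_ = {}

    def fit(self, X: pd.DataFrame, y: np.ndarray, eval_set=None):
        policy = self.spec.scaling_policy
        Xv = X[self.feature_columns].to_numpy(dtype=float)
        yv = np.asarray(y, dtype=float)
        if policy in ("X-only", "X-and-y"):
            self.x_scaler_ = StandardScaler().fit(Xv)
            Xv = self.x_scaler_.transform(Xv)
        if policy == "X-and-y":
            self.y_scaler_ = StandardScaler().fit(yv.reshape(-1, 1))
            yv = self.y_scaler_.transform(yv.reshape(-1, 1)).ravel()
        self.estimator_ = _make_estimator(self.spec)
        if self.spec.family == "boosted-trees" and eval_set is not None:
            Xe, ye = eval_set
            Xe = Xe[self.feature_columns].to_numpy(dtype=float)
            self.estimator_.set_params(eval_metric="mae")
            self.estimator_.fit(
                Xv, yv, eval_set=[(Xv, yv), (Xe, np.asarray(ye, dtype=float))],
                verbose=False,
            )
            res = self.estimator_.evals_result()
            self.learning_curve_ = {
                "train_mae": res["validation_0"]["mae"],
                "val_mae": res["validation_1"]["mae"],
            }
        else:
            self.estimator_.fit(Xv, yv)
            if self.spec.family == "feedforward-net":
                self.learning_curve_ = dict(self.estimator_.loss_trace_)
        return self

    def predict(self, records: pd.DataFrame) -> np.ndarray:
        missing = [c for c in self.feature_columns if c not in records.columns]
        if missing:
            raise ValueError(f"records lack predictor features: {missing}")
        Xv = records[self.feature_columns].to_numpy(dtype=float)
        if self.x_scaler_ is not None:
            Xv = self.x_scaler_.transform(Xv)
        pred = np.asarray(self.estimator_.predict(Xv), dtype=float).ravel()
        if self.y_scaler_ is not None:
            pred = self.y_scaler_.inverse_transform(pred.reshape(-1, 1)).ravel()
        return pred


def _split_xy(table: pd.DataFrame):
    return table.drop(columns=[OUTCOME]), table[OUTCOME].to_numpy(dtype=float)


def _check_fitted_on(augmenter, table: pd.DataFrame, what: str) -> None:
    if augmenter is None:
        return
    fitted = getattr(augmenter, "fit_index_", None)
    if fitted is None:
        raise ValueError(f"augmenter passed to {what} is not fitted")
    if set(fitted) != set(table.index):
        raise ValueError(
            f"augmenter passed to {what} was fitted on different rows than "
            "the table it augments (leakage guard)"
        )


# ---------------------------------------------------------------------------
# stage 1: hyperparameter search on the 1:1-augmented development set


def tune_hyperparameters(
    dev: pd.DataFrame,
    augmenter,
    family: str,
    space: dict | None = None,
    n_iter: int | None = None,
    seed: int = 42,
    cv: int = 5,
) -> tuple[dict, float]:
    """Randomized search scored by negative MAE under k-fold CV.

    The search table is the development set plus an equal-size synthetic
    sample from ``augmenter`` (pass ``augmenter=None`` for the baseline arm,
    which searches on the original development set alone).  Sampling is
    uniform over the cartesian grid, without replacement when the grid is
    small.  Returns ``(best_hyperparameters, best_score)``.
    """
    space = SPACES[family] if space is None else space
    if not space or any(len(v) == 0 for v in space.values()):
        raise ValueError("empty hyperparameter search space")
    n_iter = N_ITER[family] if n_iter is None else n_iter
    _check_fitted_on(augmenter, dev, "tune_hyperparameters")

    combined = dev
    if augmenter is not None:
        synth = augmenter.sample(len(dev), seed=seed)
        combined = pd.concat([dev.reset_index(drop=True), synth], ignore_index=True)
    X, y = _split_xy(combined)

    candidates = list(ParameterSampler(space, n_iter=n_iter, random_state=seed))
    splitter = KFold(n_splits=cv, shuffle=True, random_state=seed)
    best_params, best_score = None, -np.inf
    for params in candidates:
        maes = []
        for tr, va in splitter.split(X):
            spec = ModelSpec(family, params, seed=seed)
            pred = FittedPredictor(spec, X.columns, combined.index[tr])
            pred.fit(X.iloc[tr], y[tr])
            maes.append(float(np.mean(np.abs(pred.predict(X.iloc[va]) - y[va]))))
        score = -float(np.mean(maes))
        if score > best_score:
            best_score, best_params = score, params
    return best_params, best_score


# ---------------------------------------------------------------------------
# stage 2: dynamic per-fold augmentation CV


@dataclass(frozen=True)
class CvResult:
    fold_train: list  # MetricsReport per fold (on the augmented training table)
    fold_validation: list  # MetricsReport per fold (original validation rows)
    mean_validation: MetricsReport
    learning_curves: list  # per-fold traces
    fold_sizes: list  # (n_original_train, n_synthetic, n_validation)


def dynamic_cv(
    dev: pd.DataFrame,
    folds: list,
    spec: ModelSpec,
    augmenter_factory=None,
    augmentation_ratio: float = 1.0,
    seed: int = 42,
) -> CvResult:
    """Cross-validation with per-fold augmentation.

    For each fold the augmenter is fitted on that fold's training partition
    only, ``ratio x |partition|`` synthetic rows are generated and appended,
    the family's scaling policy is fitted on the combined training table,
    and the model is evaluated on the untouched original validation fold on
    the original outcome scale.  ``augmentation_ratio=0`` (or
    ``augmenter_factory=None``) reduces to plain CV — the baseline arm.
    """
    all_fold = np.concatenate(folds)
    if set(all_fold) != set(dev.index) or len(all_fold) != len(dev):
        raise ValueError("folds do not partition the development set")

    fold_train, fold_val, curves, sizes = [], [], [], []
    for f, val_idx in enumerate(folds):
        val_idx = np.asarray(val_idx)
        train_idx = np.setdiff1d(dev.index.to_numpy(), val_idx)
        assert len(np.intersect1d(train_idx, val_idx)) == 0
        train_part = dev.loc[train_idx]
        val_part = dev.loc[val_idx]

        n_synth = int(round(augmentation_ratio * len(train_part)))
        if augmenter_factory is not None and n_synth > 0:
            aug = augmenter_factory()
            aug.fit(train_part)
            synth = aug.sample(n_synth, seed=seed + f)
            combined = pd.concat(
                [train_part.reset_index(drop=True), synth], ignore_index=True
            )
        else:
            n_synth = 0
            combined = train_part.reset_index(drop=True)
        sizes.append((len(train_part), n_synth, len(val_part)))

        Xc, yc = _split_xy(combined)
        Xv, yv = _split_xy(val_part)
        predictor = FittedPredictor(spec, Xc.columns, train_idx)
        predictor.fit(Xc, yc, eval_set=(Xv, yv))
        fold_train.append(compute_metrics(yc, predictor.predict(Xc)))
        fold_val.append(compute_metrics(yv, predictor.predict(Xv)))
        curves.append(predictor.learning_curve_)

    mean_validation = MetricsReport(
        mae=float(np.mean([m.mae for m in fold_val])),
        rmse=float(np.mean([m.rmse for m in fold_val])),
        r2=float(np.mean([m.r2 for m in fold_val])),
        n=int(sum(m.n for m in fold_val)),
    )
    return CvResult(fold_train, fold_val, mean_validation, curves, sizes)


# ---------------------------------------------------------------------------
# final training and hold-out evaluation


def train_final(
    dev: pd.DataFrame,
    augmenter,
    spec: ModelSpec,
    augmentation_ratio: float = 2.0,
    seed: int = 42,
) -> FittedPredictor:
    """Train the definitive model on dev + ratio x |dev| synthetic rows.

    ``augmenter=None`` or ``ratio=0`` trains the baseline model on the
    original development set alone.
    """
    _check_fitted_on(augmenter, dev, "train_final")
    n_synth = int(round(augmentation_ratio * len(dev)))
    if augmenter is not None and n_synth > 0:
        synth = augmenter.sample(n_synth, seed=seed)
        combined = pd.concat([dev.reset_index(drop=True), synth], ignore_index=True)
    else:
        combined = dev.reset_index(drop=True)
    X, y = _split_xy(combined)
    predictor = FittedPredictor(spec, X.columns, dev.index.to_numpy())
    predictor.fit(X, y)
    predictor.n_training_rows_ = len(combined)
    return predictor


def evaluate_holdout(predictor: FittedPredictor, holdout: pd.DataFrame) -> MetricsReport:
    """Metrics on the hold-out rows, original scale.

    Refuses evaluation if any hold-out row label appears among the rows the
    predictor (or its augmenter/scalers) was fitted on.
    """
    overlap = np.intersect1d(predictor.train_index, holdout.index.to_numpy())
    if len(overlap):
        raise ValueError(
            f"hold-out rows overlap the training provenance: {overlap[:5]}..."
        )
    X, y = _split_xy(holdout)
    return compute_metrics(y, predictor.predict(X))
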