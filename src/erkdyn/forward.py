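"""Forward prediction of endpoint stain levels from ERK activity traces.

Three model families map a cell's activity history onto one endpoint target:
a time-series linear regression (each timepoint a predictor), a featurized
linear regression (the nine dynamic features as predictors), and a small 1-D
convolutional network.  Evaluation uses stratified folds holding out 20% of
cells as test, with the remainder split 64/16 into train/validation.
Per-timepoint integrated-gradients attribution quantifies which parts of the
history a trained network relies on.
"""

from __future__ import annotations

from dataclasses import dataclass

import numpy as np
import pandas as pd
from sklearn.base import BaseEstimator, RegressorMixin
from sklearn.linear_model import LinearRegression
from sklearn.metrics import mean_squared_error, r2_score
from sklearn.model_selection import StratifiedKFold, train_test_split

from ._nn import ConvNet1d


@dataclass
class SplitSpec:
    """One evaluation fold: disjoint train/validation/test cell indices."""

    fold_id: int
    train: np.ndarray
    validation: np.ndarray
    test: np.ndarray


def make_splits(strata, n_folds: int = 5, seed: int = 0) -> list[SplitSpec]:
    """Stratified folds: 20% test per fold, remainder split 64/16 train/val.

    ``strata`` is one label per cell combining the stratification keys
    (typically well and treatment); every stratum must have at least
    ``n_folds`` cells.
    """
    strata = np.asarray(strata)
    _, counts = np.unique(strata, return_counts=True)
    if counts.min() < n_folds:
        raise ValueError("every stratum needs at least n_folds cells")
    skf = StratifiedKFold(n_splits=n_folds, shuffle=True, random_state=seed)
    splits = []
    for fold_id, (rest, test) in enumerate(skf.split(strata, strata)):
        train, val = train_test_split(
            rest, test_size=0.2, random_state=seed + fold_id, stratify=strata[rest])
        splits.append(SplitSpec(fold_id, np.sort(train), np.sort(val), np.sort(test)))
    return splits


def _eval_folds(fit_one, X, y, splits):
    rows, models = [], []
    for sp in splits:
        model = fit_one(X[sp.train], y[sp.train], sp)
        models.append(model)
        row = {"fold": sp.fold_id}
        for name, idx in (("train", sp.train), ("validation", sp.validation),
                          ("test", sp.test)):
            pred = model.predict(X[idx])
            row[f"{name}_r2"] = r2_score(y[idx], pred)
            row[f"{name}_mse"] = mean_squared_error(y[idx], pred)
        rows.append(row)
    return models, pd.DataFrame(rows)


def fit_ts_linear(traces: np.ndarray, target: np.ndarray, splits: list[SplitSpec]):
    """Least-squares regression of the target on every trace timepoint.

    Collinearity is handled by the minimum-norm pseudoinverse solution.
    Returns (per-fold models, metrics table with train/validation/test R²
    and MSE).
    """
    X = np.asarray(traces, dtype=float)
    y = np.asarray(target, dtype=float)
    return _eval_folds(lambda Xt, yt, sp: LinearRegression().fit(Xt, yt), X, y, splits)


def fit_featurized_linear(features, target: np.ndarray, splits: list[SplitSpec]):
    """As :func:`fit_ts_linear` with the nine dynamic features as predictors."""
    X = features.to_numpy(dtype=float) if isinstance(features, pd.DataFrame) \
        else np.asarray(features, dtype=float)
    return fit_ts_linear(X, target, splits)


class CnnRegressor(BaseEstimator, RegressorMixin):
    """1-D convolutional regressor over activity traces.

    Two same-padding convolutional layers (``channels`` filters of width
    ``kernel``) feed three rectified dense layers and a linear output.
    Inputs and targets are z-scored with dataset-level statistics inside
    ``fit``; predictions are returned on the original target scale.

    Parameters mirror the training configuration: ``epochs``, learning rate
    ``lr``, L2 penalty ``l2``, ``batch_size``, and ``seed`` for weight
    initialization and batch shuffling.
    """

    def __init__(self, channels=16, kernel=16, fc_sizes=(192, 64, 64),
                 n_conv_layers=2, epochs=100, lr=1e-3, l2=1e-3,
                 batch_size=256, seed=0):
        self.channels = channels
        self.kernel = kernel
        self.fc_sizes = fc_sizes
        self.n_conv_layers = n_conv_layers
        self.epochs = epochs
        self.lr = lr
        self.l2 = l2
        self.batch_size = batch_size
        self.seed = seed

    def fit(self, X, y):
        X = np.asarray(X, dtype=float)
        y = np.asarray(y, dtype=float)
        if self.epochs < 1 or self.lr <= 0:
            raise ValueError("epochs must be >= 1 and lr > 0")
        self.input_len_ = X.shape[1]
        self.x_mean_ = X.mean()
        self.x_std_ = X.std() or 1.0
        self.y_mean_ = y.mean()
        self.y_std_ = y.std() or 1.0
        self.net_ = ConvNet1d(self.input_len_, self.channels, self.kernel,
                              self.fc_sizes, self.n_conv_layers, seed=self.seed)
        self.history_ = self.net_.fit(
            (X - self.x_mean_) / self.x_std_, (y - self.y_mean_) / self.y_std_,
            epochs=self.epochs, lr=self.lr, l2=self.l2,
            batch_size=self.batch_size, seed=self.seed + 1)
        return self

    def _check_X(self, X):
        X = np.asarray(X, dtype=float)
        if X.shape[1] != self.input_len_:
            raise ValueError(
                f"trace length {X.shape[1]} != trained length {self.input_len_}")
        return (X - self.x_mean_) / self.x_std_

    def predict(self, X):
        return self.net_.forward(self._check_X(X)).astype(float) * self.y_std_ + self.y_mean_

    def predict_std(self, X_std):
        """Prediction in standardized units from standardized input."""
        return self.net_.forward(np.asarray(X_std, dtype=float)).astype(float)

    def input_gradients_std(self, X_std):
        """d(standardized prediction)/d(standardized input)."""
        return self.net_.input_gradients(np.asarray(X_std, dtype=float)).astype(float)


def fit_cnn(traces, target, splits, **cnn_params):
    """Train one CNN per fold; returns (models, metrics table)."""
    X = np.asarray(traces, dtype=float)
    y = np.asarray(target, dtype=float)

    def fit_one(Xt, yt, sp):
        return CnnRegressor(**{"seed": sp.fold_id, **cnn_params}).fit(Xt, yt)

    return _eval_folds(fit_one, X, y, splits)


@dataclass
class AttributionMap:
    """Integrated-gradients attribution for one target."""

    per_cell: np.ndarray   # (n_cells, n_timepoints)
    mean: np.ndarray       # cell-averaged per-timepoint importance
    baseline_policy: str
    n_steps: int
    window_offset: int = 0


def integrated_gradients(grad_fn, X, baseline=None, n_steps: int = 64) -> np.ndarray:
    """Straight-path integrated gradients with a midpoint Riemann sum.

    ``grad_fn(X) -> dF/dX`` of a scalar-output model.  Attribution of input
    i is (x_i - b_i) times the path-averaged gradient; summed attributions
    converge to F(x) - F(baseline) as ``n_steps`` grows (exactly, for a
    linear model).
    """
    if n_steps < 8:
        raise ValueError("n_steps must be >= 8")
    X = np.asarray(X, dtype=float)
    b = np.zeros_like(X) if baseline is None else np.broadcast_to(
        np.asarray(baseline, dtype=float), X.shape)
    diff = X - b
    acc = np.zeros_like(X)
    for k in range(n_steps):
        alpha = (k + 0.5) / n_steps
        acc += grad_fn(b + alpha * diff)
    return diff * acc / n_steps


def attribute(model: CnnRegressor, traces, baseline_policy: str = "zeros",
              n_steps: int = 64, window_offset: int = 0) -> AttributionMap:
    """Per-timepoint attribution of a trained CNN, averaged over cells.

    The path runs from an all-zeros standardized trace (default) or the
    dataset-mean trace to each cell's standardized trace.
    """
    X_std = model._check_X(np.asarray(traces, dtype=float))
    if baseline_policy == "zeros":
        baseline = np.zeros(X_std.shape[1])
    elif baseline_policy == "mean":
        baseline = X_std.mean(axis=0)
    else:
        raise ValueError(f"unknown baseline policy {baseline_policy!r}")
    per_cell = integrated_gradients(model.input_gradients_std, X_std,
                                    baseline=baseline, n_steps=n_steps)
    return AttributionMap(per_cell=per_cell, mean=per_cell.mean(axis=0),
                          baseline_policy=baseline_policy, n_steps=n_steps,
                          window_offset=window_offset)


def truncate_window(traces: np.ndarray, keep_last_n: int):
    """Trailing-window view of the trace matrix.

    Returns (truncated traces, start offset in samples).
    """
    X = np.asarray(traces)
    if keep_last_n <= 0:
        raise ValueError("keep_last_n must be > 0")
    if keep_last_n > X.shape[1]:
        raise ValueError("keep_last_n exceeds trace length")
    return X[:, X.shape[1] - keep_last_n:], X.shape[1] - keep_last_n
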