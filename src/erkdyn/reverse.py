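"""Reverse inference: predicting ERK dynamic features from endpoint stains.

Single-predictor and multiple linear regressions are evaluated with 10-fold
cross-validation; following the study procedure, the fold model with the
lowest test RMSE is refit on the full data and its R² reported.  Stains
enter on log10 scale by default (intensities are long-tailed and batch
correction operates in log space).  Additional analyses: incremental
predictor addition in order of single-predictor R², condition-average
models, and condition-exclusion filtering.
"""

from __future__ import annotations

from dataclasses import dataclass, field

import numpy as np
import pandas as pd
from sklearn.linear_model import LinearRegression
from sklearn.metrics import mean_squared_error, r2_score
from sklearn.model_selection import KFold


@dataclass
class RegressionResult:
    """Cross-validated regression of one dynamic feature on stain predictors."""

    feature: str
    predictors: list[str]
    coefficients: np.ndarray        # on the (possibly z-scored) fit scale
    coefficients_raw: np.ndarray    # on the predictor's input scale
    intercept: float
    fold_test_rmse: np.ndarray
    best_fold: int
    r2: float                       # full-data R² of the refit best model
    rmse: float
    n_cells: int
    log_scale: bool
    standardized: bool


def _design(panel: pd.DataFrame, predictors, log_scale: bool, standardize: bool):
    X = panel[list(predictors)].to_numpy(dtype=float)
    if log_scale:
        if (X <= 0).any():
            raise ValueError("log-scale predictors require positive intensities")
        X = np.log10(X)
    mu = X.mean(axis=0)
    sd = X.std(axis=0)
    if (sd == 0).any():
        bad = [p for p, s in zip(predictors, sd) if s == 0]
        raise ValueError(f"zero-variance predictor(s): {bad}")
    if standardize:
        return (X - mu) / sd, mu, sd
    return X, np.zeros_like(mu), np.ones_like(sd)


def _cv_fit(X, y, feature, predictors, folds, seed, log_scale, standardized, sd):
    n = len(y)
    if n < 50:
        raise ValueError("need >= 50 cells for cross-validated regression")
    if not np.isfinite(y).all():
        raise ValueError("feature values must be finite")
    kf = KFold(n_splits=folds, shuffle=True, random_state=seed)
    rmses = []
    for tr, te in kf.split(X):
        m = LinearRegression().fit(X[tr], y[tr])
        rmses.append(np.sqrt(mean_squared_error(y[te], m.predict(X[te]))))
    rmses = np.asarray(rmses)
    best = int(np.argmin(rmses))
    # study procedure: refit the winning model form on the entire dataset
    final = LinearRegression().fit(X, y)
    pred = final.predict(X)
    return RegressionResult(
        feature=feature, predictors=list(predictors),
        coefficients=final.coef_.copy(),
        coefficients_raw=final.coef_ / sd,
        intercept=float(final.intercept_),
        fold_test_rmse=rmses, best_fold=best,
        r2=float(r2_score(y, pred)),
        rmse=float(np.sqrt(mean_squared_error(y, pred))),
        n_cells=n, log_scale=log_scale, standardized=standardized)


def fit_single(panel: pd.DataFrame, target: str, feature_values, feature_name: str,
               folds: int = 10, seed: int = 0, log_scale: bool = True,
               standardize: bool = True) -> RegressionResult:
    """One-stain regression of a dynamic feature with 10-fold CV."""
    X, _, sd = _design(panel, [target], log_scale, standardize)
    y = np.asarray(feature_values, dtype=float)
    return _cv_fit(X, y, feature_name, [target], folds, seed, log_scale, standardize, sd)


def fit_mlr(panel: pd.DataFrame, feature_values, feature_name: str,
            folds: int = 10, seed: int = 0, log_scale: bool = True,
            standardize: bool = True, predictors=None) -> RegressionResult:
    """Multiple regression using all stains (or a chosen subset) as predictors."""
    predictors = list(predictors) if predictors is not None else list(panel.columns)
    X, _, sd = _design(panel, predictors, log_scale, standardize)
    y = np.asarray(feature_values, dtype=float)
    return _cv_fit(X, y, feature_name, predictors, folds, seed, log_scale, standardize, sd)


def incremental_predictors(panel: pd.DataFrame, feature_values, feature_name: str = "",
                           log_scale: bool = True) -> pd.DataFrame:
    """Cumulative in-sample R² as predictors are added in single-R² rank order.

    Returns a table (added predictor, single_r2, cumulative_r2); the
    cumulative curve is non-decreasing and ends at the full-MLR in-sample R².
    """
    y = np.asarray(feature_values, dtype=float)
    X, _, _ = _design(panel, list(panel.columns), log_scale, standardize=True)
    singles = {}
    for j, name in enumerate(panel.columns):
        m = LinearRegression().fit(X[:, [j]], y)
        singles[name] = r2_score(y, m.predict(X[:, [j]]))
    order = sorted(singles, key=singles.get, reverse=True)
    rows, cols = [], []
    for name in order:
        cols.append(list(panel.columns).index(name))
        m = LinearRegression().fit(X[:, cols], y)
        rows.append({"predictor": name, "single_r2": singles[name],
                     "cumulative_r2": r2_score(y, m.predict(X[:, cols]))})
    return pd.DataFrame(rows)


def condition_average_model(panel: pd.DataFrame, feature_values, conditions,
                            feature_name: str = "", log_scale: bool = True,
                            folds: int = 10, seed: int = 0) -> RegressionResult:
    """Regression on per-condition means of stains and features.

    Averaging removes independent per-cell noise, so condition-level fits
    bound the single-cell fits from above when cell noise dominates.
    """
    conditions = np.asarray(conditions)
    uniq = pd.unique(conditions)
    if len(uniq) < 5:
        raise ValueError("need >= 5 conditions for condition-average modeling")
    df = panel.copy()
    if log_scale:
        if (df.to_numpy() <= 0).any():
            raise ValueError("log-scale predictors require positive intensities")
        df = np.log10(df)
    df["_y"] = np.asarray(feature_values, dtype=float)
    df["_cond"] = conditions
    means = df.groupby("_cond", sort=True).mean()
    if len(means) < 3:
        raise ValueError("fewer than 3 conditions after filtering")
    y = means["_y"].to_numpy()
    Xdf = means.drop(columns="_y")
    X = Xdf.to_numpy(dtype=float)
    sd = X.std(axis=0)
    if (sd == 0).any():
        raise ValueError("zero-variance predictor at condition level")
    Xs = (X - X.mean(axis=0)) / sd
    n = len(y)
    kf = KFold(n_splits=min(folds, n), shuffle=True, random_state=seed)
    rmses = []
    for tr, te in kf.split(Xs):
        m = LinearRegression().fit(Xs[tr], y[tr])
        rmses.append(np.sqrt(mean_squared_error(y[te], m.predict(Xs[te]))))
    final = LinearRegression().fit(Xs, y)
    pred = final.predict(Xs)
    return RegressionResult(
        feature=feature_name, predictors=list(Xdf.columns),
        coefficients=final.coef_.copy(), coefficients_raw=final.coef_ / sd,
        intercept=float(final.intercept_),
        fold_test_rmse=np.asarray(rmses), best_fold=int(np.argmin(rmses)),
        r2=float(r2_score(y, pred)),
        rmse=float(np.sqrt(mean_squared_error(y, pred))),
        n_cells=n, log_scale=log_scale, standardized=True)


def exclude_conditions(cells: pd.DataFrame, predicate, *tables):
    """Drop cells whose condition satisfies ``predicate`` from every table.

    ``predicate`` receives the condition label; returns the filtered cells
    table followed by each auxiliary table/array filtered to the same rows.
    """
    drop = cells["condition"].map(predicate).to_numpy(dtype=bool)
    keep = ~drop
    if not keep.any():
        raise ValueError("predicate removed every cell")
    rows = np.flatnonzero(keep)
    out = [cells.iloc[rows].reset_index(drop=True)]
    for tab in tables:
        if isinstance(tab, pd.DataFrame):
            out.append(tab.iloc[rows])
        else:
            out.append(np.asarray(tab)[rows])
    return tuple(out)
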