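"""Signaling-history classes: trace prototypes, stain-based classification,
and spatial aggregation.

Activity traces are clustered into k=5 prototypes by k-means; cells whose
trace correlates poorly (Pearson r < 0.7) with their class centroid are
dropped from training.  A boosted multiclass ensemble (500 shallow trees)
then predicts the history class from the endpoint stain panel.  The same
procedure runs on hexagonal spatial region averages (default circumradius
50 um) and on whole-image averages (a single decision tree, for the small
sample size).
"""

from __future__ import annotations

import warnings
from dataclasses import dataclass, field

import numpy as np
import pandas as pd
from sklearn.cluster import KMeans
from sklearn.ensemble import AdaBoostClassifier
from sklearn.metrics import accuracy_score, confusion_matrix
from sklearn.model_selection import StratifiedKFold, cross_val_predict, KFold
from sklearn.tree import DecisionTreeClassifier

# distinguishable class colors for overlays (matplotlib tab10 hex values)
CLASS_COLORS = ["#1f77b4", "#ff7f0e", "#2ca02c", "#d62728", "#9467bd",
                "#8c564b", "#e377c2", "#7f7f7f", "#bcbd22", "#17becf"]


@dataclass
class PrototypeModel:
    """k-means prototypes of ERK activity histories."""

    centroids: np.ndarray       # (k, n_timepoints)
    labels: np.ndarray          # per-cell class id in {1..k}
    correlation: np.ndarray     # Pearson r of each cell to its class centroid
    inertia: float
    kept: np.ndarray | None = None  # set by filter_members

    @property
    def k(self) -> int:
        return self.centroids.shape[0]


def cluster_prototypes(traces: np.ndarray, k: int = 5, seed: int = 0,
                       n_init: int = 10, zscore: bool = False) -> PrototypeModel:
    """k-means on raw trace vectors; best of ``n_init`` restarts.

    Traces are clustered on calibrated activity without per-cell
    normalization by default (``zscore=True`` switches to per-cell
    z-scoring).  Centroids are member means; labels are 1-based.
    """
    X = np.asarray(traces, dtype=float)
    if k > X.shape[0]:
        raise ValueError("k exceeds the number of cells")
    if k < 2:
        raise ValueError("k must be >= 2")
    if zscore:
        X = (X - X.mean(axis=1, keepdims=True)) / X.std(axis=1, keepdims=True)
    km = KMeans(n_clusters=k, n_init=n_init, random_state=seed).fit(X)
    labels = km.labels_ + 1
    corr = _corr_to_centroid(X, km.cluster_centers_, km.labels_)
    return PrototypeModel(centroids=km.cluster_centers_, labels=labels,
                          correlation=corr, inertia=float(km.inertia_))


def _corr_to_centroid(X, centroids, labels0):
    Xc = X - X.mean(axis=1, keepdims=True)
    Cc = centroids - centroids.mean(axis=1, keepdims=True)
    Cm = Cc[labels0]
    num = (Xc * Cm).sum(axis=1)
    den = np.sqrt((Xc ** 2).sum(axis=1) * (Cm ** 2).sum(axis=1))
    with np.errstate(invalid="ignore", divide="ignore"):
        r = np.where(den > 0, num / np.where(den > 0, den, 1.0), 0.0)
    return r


def filter_members(model: PrototypeModel, r_min: float = 0.7) -> np.ndarray:
    """Keep-mask of cells with Pearson r >= ``r_min`` to their centroid.

    Raises if any class loses all members (its prototype would be
    untrainable downstream).
    """
    kept = model.correlation >= r_min
    for c in range(1, model.k + 1):
        if not kept[model.labels == c].any():
            raise ValueError(f"class {c} lost all members at r_min={r_min}")
    model.kept = kept
    return kept


@dataclass
class HistoryClassifier:
    """Boosted stain-based predictor of the signaling-history class."""

    estimator: AdaBoostClassifier
    predictors: list[str]
    classes: np.ndarray
    accuracy: float                  # best-fold held-out accuracy
    fold_accuracy: np.ndarray
    best_fold: int
    per_class_accuracy: pd.Series
    confusion: pd.DataFrame
    n_rounds: int
    log_scale: bool

    def predict(self, panel: pd.DataFrame) -> np.ndarray:
        X = panel[self.predictors].to_numpy(dtype=float)
        if self.log_scale:
            X = np.log10(X)
        return self.estimator.predict(X)


def fit_history_classifier(panel: pd.DataFrame, labels, n_rounds: int = 500,
                           folds: int = 10, seed: int = 0, max_depth: int = 2,
                           log_scale: bool = True,
                           min_cells_per_class: int = 20) -> HistoryClassifier:
    """Multiclass boosting over shallow trees with fold-selected reporting.

    10-fold stratified CV; the fold model with the lowest test error is
    retained and its held-out accuracy, per-class accuracy and confusion
    matrix reported.
    """
    y = np.asarray(labels)
    X = panel.to_numpy(dtype=float)
    if log_scale:
        X = np.log10(X)
    classes, counts = np.unique(y, return_counts=True)
    if counts.min() < min_cells_per_class:
        raise ValueError(
            f"every class needs >= {min_cells_per_class} cells, got {counts.min()}")
    if folds > counts.min():
        warnings.warn(f"reducing folds from {folds} to {counts.min()}")
        folds = int(counts.min())
    skf = StratifiedKFold(n_splits=folds, shuffle=True, random_state=seed)
    best = None
    accs = []
    for fold_id, (tr, te) in enumerate(skf.split(X, y)):
        ens = AdaBoostClassifier(
            estimator=DecisionTreeClassifier(max_depth=max_depth),
            n_estimators=n_rounds, random_state=seed).fit(X[tr], y[tr])
        pred = ens.predict(X[te])
        acc = accuracy_score(y[te], pred)
        accs.append(acc)
        if best is None or acc > best[1]:
            best = (fold_id, acc, ens, te, pred)
    fold_id, acc, ens, te, pred = best
    cm = confusion_matrix(y[te], pred, labels=classes)
    cm = pd.DataFrame(cm, index=classes, columns=classes)
    with np.errstate(invalid="ignore"):
        per_class = pd.Series(np.diag(cm) / cm.sum(axis=1), index=classes)
    return HistoryClassifier(
        estimator=ens, predictors=list(panel.columns), classes=classes,
        accuracy=float(acc), fold_accuracy=np.asarray(accs), best_fold=fold_id,
        per_class_accuracy=per_class, confusion=cm, n_rounds=n_rounds,
        log_scale=log_scale)


def predictor_importance(model: HistoryClassifier) -> pd.Series:
    """Split-gain importance summed over all weak learners, per stain."""
    if not hasattr(model.estimator, "estimators_"):
        raise ValueError("classifier is not trained")
    return pd.Series(model.estimator.feature_importances_, index=model.predictors)


@dataclass
class RegionGrid:
    """Hexagonal partition of the imaging field (pointy-top lattice)."""

    radius_um: float
    region_id: np.ndarray           # per cell
    centers: pd.DataFrame           # region_id -> (x_um, y_um)
    counts: pd.Series


def hex_regions(coords: pd.DataFrame, radius_um: float = 50.0,
                groups=None) -> RegionGrid:
    """Assign each cell to its nearest hexagon center.

    Pointy-top lattice with circumradius ``radius_um`` anchored at the field
    origin; assignment uses exact axial-coordinate rounding, so the result
    is a partition (every cell in exactly one region).  ``groups`` (e.g.
    well ids) separates regions between imaging fields that share a
    coordinate system.
    """
    if radius_um <= 0:
        raise ValueError("radius must be > 0")
    x = coords["x_um"].to_numpy(dtype=float)
    y = coords["y_um"].to_numpy(dtype=float)
    q = (np.sqrt(3.0) / 3.0 * x - y / 3.0) / radius_um
    r = (2.0 / 3.0 * y) / radius_um
    qi, ri = _cube_round(q, r)
    keys = pd.DataFrame({"q": qi, "r": ri})
    if groups is not None:
        keys.insert(0, "g", np.asarray(groups))
    region_id, uniq = pd.factorize(pd.MultiIndex.from_frame(keys))
    cq = np.array([u[-2] for u in uniq], dtype=float)
    cr = np.array([u[-1] for u in uniq], dtype=float)
    centers = pd.DataFrame({
        "x_um": radius_um * np.sqrt(3.0) * (cq + cr / 2.0),
        "y_um": radius_um * 1.5 * cr,
    })
    if groups is not None:
        centers.insert(0, "group", [u[0] for u in uniq])
    centers.index.name = "region_id"
    counts = pd.Series(region_id).value_counts().sort_index()
    return RegionGrid(radius_um=radius_um, region_id=region_id,
                      centers=centers, counts=counts)


def _cube_round(q, r):
    s = -q - r
    qi, ri, si = np.round(q), np.round(r), np.round(s)
    dq, dr, ds = np.abs(qi - q), np.abs(ri - r), np.abs(si - s)
    fix_q = (dq > dr) & (dq > ds)
    fix_r = ~fix_q & (dr > ds)
    qi = np.where(fix_q, -ri - si, qi)
    ri = np.where(fix_r, -qi - si, ri)
    return qi.astype(int), ri.astype(int)


def region_means(region_id: np.ndarray, values) -> pd.DataFrame:
    """Per-region means over member cells; index is region_id."""
    df = pd.DataFrame(np.asarray(values, dtype=float))
    cols = values.columns if isinstance(values, pd.DataFrame) else df.columns
    df.columns = cols
    df["_rid"] = region_id
    out = df.groupby("_rid", sort=True).mean()
    out.index.name = "region_id"
    return out


def regional_pipeline(traces: np.ndarray, stains: pd.DataFrame,
                      coords: pd.DataFrame, radius_um: float = 50.0,
                      k: int = 5, seed: int = 0, r_min: float = 0.7,
                      n_rounds: int = 500, folds: int = 10,
                      min_cells_per_class: int = 20, groups=None) -> dict:
    """Prototype clustering + classification on hexagonal region averages.

    Single-cell clustering and the correlation filter run first; region
    averages are computed over the kept cells, then the full procedure
    repeats at region level.  Returns a report with single-cell and
    regional accuracies.
    """
    proto = cluster_prototypes(traces, k=k, seed=seed)
    kept = filter_members(proto, r_min=r_min)
    sc = fit_history_classifier(stains[kept], proto.labels[kept],
                                n_rounds=n_rounds, folds=folds, seed=seed,
                                min_cells_per_class=min_cells_per_class)

    grid = hex_regions(coords[kept].reset_index(drop=True), radius_um=radius_um,
                       groups=np.asarray(groups)[kept] if groups is not None else None)
    r_traces = region_means(grid.region_id, traces[kept]).to_numpy()
    r_stains = region_means(grid.region_id, stains[kept].reset_index(drop=True))
    r_proto = cluster_prototypes(r_traces, k=min(k, r_traces.shape[0]), seed=seed)
    r_kept = filter_members(r_proto, r_min=r_min)
    counts = np.unique(r_proto.labels[r_kept], return_counts=True)[1]
    r_folds = min(folds, int(counts.min()))
    if r_folds < folds:
        warnings.warn(f"regional folds reduced to {r_folds}")
    if r_folds < 2:
        raise ValueError("too few regions per class for cross-validation")
    rc = fit_history_classifier(
        r_stains[r_kept], r_proto.labels[r_kept], n_rounds=n_rounds,
        folds=r_folds, seed=seed, min_cells_per_class=min(min_cells_per_class,
                                                          int(counts.min())))
    return {
        "single_cell": sc, "regional": rc,
        "single_cell_accuracy": sc.accuracy, "regional_accuracy": rc.accuracy,
        "n_regions": len(grid.counts), "radius_um": radius_um,
        "prototypes": proto, "regional_prototypes": r_proto, "regions": grid,
    }


def whole_image_model(image_ids, traces: np.ndarray, stains: pd.DataFrame,
                      k: int = 5, seed: int = 0, folds: int = 5) -> dict:
    """One sample per image: mean trace and mean stains, single decision tree.

    Image-mean traces are clustered into k classes; a standard decision tree
    predicts the class from image-mean stains with as much cross-validation
    as the sample size permits.
    """
    image_ids = np.asarray(image_ids)
    images = pd.unique(image_ids)
    if len(images) < 20:
        raise ValueError("need >= 20 images")
    pos = pd.factorize(image_ids)[0]
    m_traces = region_means(pos, traces).to_numpy()
    m_stains = region_means(pos, stains.reset_index(drop=True))
    proto = cluster_prototypes(m_traces, k=min(k, len(images) - 1), seed=seed)
    y = proto.labels
    if len(np.unique(y)) < 2:
        raise ValueError("fewer than 2 classes represented at image level")
    X = np.log10(m_stains.to_numpy(dtype=float))
    cv = KFold(n_splits=min(folds, len(images)), shuffle=True, random_state=seed)
    pred = cross_val_predict(DecisionTreeClassifier(random_state=seed), X, y, cv=cv)
    return {
        "accuracy": float(accuracy_score(y, pred)),
        "n_samples": int(len(images)),
        "labels": y, "predictions": pred,
    }


def annotate(predictions: pd.Series, coords: pd.DataFrame) -> pd.DataFrame:
    """Overlay table of inferred histories on spatial coordinates.

    ``predictions`` is indexed by cell_id and may be missing for cells with
    incomplete predictor data; those rows come back unlabeled and flagged.
    """
    out = coords[["cell_id", "x_um", "y_um"]].copy()
    mapped = out["cell_id"].map(predictions)
    out["predicted_class"] = mapped.astype("Int64")
    out["labeled"] = mapped.notna()
    out["color"] = [
        CLASS_COLORS[(int(c) - 1) % len(CLASS_COLORS)] if pd.notna(c) else ""
        for c in mapped
    ]
    return out
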