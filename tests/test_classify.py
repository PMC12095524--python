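"""History prototypes, boosted classification, spatial aggregation."""

import numpy as np
import pandas as pd
import pytest
from sklearn.metrics import adjusted_rand_score

from erkdyn.classify import (
    annotate,
    cluster_prototypes,
    filter_members,
    fit_history_classifier,
    hex_regions,
    predictor_importance,
    region_means,
    whole_image_model,
)
from erkdyn.simulate import TraceParams, TreatmentSpec, generate_erk_trace

ARCHETYPE_TREATMENTS = {
    1: TreatmentSpec(20.0, meki_time_min=570.0),
    2: TreatmentSpec(0.0),
    3: TreatmentSpec(20.0, egf_time_min=960.0),
    4: TreatmentSpec(20.0, egf_time_min=420.0, meki_time_min=900.0),
    5: TreatmentSpec(100.0),
}


def _archetype_traces(n_per=40, seed=0):
    rng = np.random.default_rng(seed)
    p = TraceParams(het_sigma=0.15)
    X, y = [], []
    for cls, tr in ARCHETYPE_TREATMENTS.items():
        for _ in range(n_per):
            X.append(generate_erk_trace(tr, p, rng))
            y.append(cls)
    return np.vstack(X), np.array(y)


class TestClusterPrototypes:
    def test_recovers_archetype_partition(self):
        X, y = _archetype_traces()
        model = cluster_prototypes(X, k=5, seed=0)
        assert adjusted_rand_score(y, model.labels) > 0.9

    def test_centroid_is_member_mean(self):
        X, _ = _archetype_traces(n_per=10)
        model = cluster_prototypes(X, k=5, seed=1)
        for c in range(1, 6):
            members = X[model.labels == c]
            np.testing.assert_allclose(model.centroids[c - 1], members.mean(axis=0),
                                       atol=1e-10)

    def test_default_k_is_five(self):
        import inspect
        assert inspect.signature(cluster_prototypes).parameters["k"].default == 5

    def test_k_exceeding_cells_rejected(self):
        with pytest.raises(ValueError):
            cluster_prototypes(np.zeros((3, 10)), k=5)


class TestFilterMembers:
    def test_correlated_kept_anticorrelated_dropped(self):
        X, _ = _archetype_traces(n_per=20)
        model = cluster_prototypes(X, k=5, seed=0)
        # a cell identical to its centroid has r = 1
        c = model.labels[0] - 1
        X2 = np.vstack([X, model.centroids[c]])
        model2 = cluster_prototypes(X2, k=5, seed=0)
        kept = filter_members(model2, r_min=0.7)
        assert kept[-1]

    def test_default_threshold(self):
        import inspect
        assert inspect.signature(filter_members).parameters["r_min"].default == 0.7

    def test_emptied_class_raises_with_class_name(self):
        X, _ = _archetype_traces(n_per=8)
        model = cluster_prototypes(X, k=5, seed=0)
        with pytest.raises(ValueError, match="class"):
            filter_members(model, r_min=1.1)


def _blobs_panel(rng, n_per=60, k=5, p=6, sep=3.0):
    X, y = [], []
    for c in range(1, k + 1):
        center = rng.normal(0, 1, p) * 0 + np.eye(k, p)[c - 1] * sep
        X.append(rng.normal(center, 0.5, (n_per, p)))
        y += [c] * n_per
    X = np.vstack(X)
    panel = pd.DataFrame(10.0 ** (X * 0.2 + 2.0),
                         columns=[f"s{i}" for i in range(p)])
    return panel, np.array(y)


class TestHistoryClassifier:
    def test_separable_classes_learned(self, rng):
        panel, y = _blobs_panel(rng)
        hc = fit_history_classifier(panel, y, n_rounds=120, folds=5, seed=0)
        assert hc.accuracy > 0.95
        assert len(hc.fold_accuracy) == 5

    def test_shuffled_labels_at_chance(self, rng):
        panel, y = _blobs_panel(rng, n_per=100)
        ys = rng.permutation(y)
        hc = fit_history_classifier(panel, ys, n_rounds=60, folds=5, seed=0)
        assert abs(hc.accuracy - 0.2) < 0.12

    def test_confusion_rows_sum_to_class_test_counts(self, rng):
        panel, y = _blobs_panel(rng)
        hc = fit_history_classifier(panel, y, n_rounds=60, folds=5, seed=0)
        assert hc.confusion.to_numpy().sum() == len(y) // 5

    def test_min_class_size_enforced(self, rng):
        panel, y = _blobs_panel(rng, n_per=10)
        with pytest.raises(ValueError, match="class"):
            fit_history_classifier(panel, y, folds=5)


class TestPredictorImportance:
    def test_shuffled_column_scores_below_informative(self, rng):
        panel, y = _blobs_panel(rng)
        panel["noise"] = rng.permutation(panel["s0"].to_numpy())
        hc = fit_history_classifier(panel, y, n_rounds=120, folds=5, seed=0)
        imp = predictor_importance(hc)
        assert (imp >= 0).all()
        assert imp["noise"] < imp.drop("noise").min()

    def test_stable_under_column_order(self, rng):
        # tree tie-breaks depend on column order, so scores match only up to
        # a small tolerance; the informative/uninformative ranking is stable
        panel, y = _blobs_panel(rng, n_per=40)
        hc1 = fit_history_classifier(panel, y, n_rounds=40, folds=4, seed=0)
        rev_cols = list(panel.columns)[::-1]
        hc2 = fit_history_classifier(panel[rev_cols], y, n_rounds=40, folds=4, seed=0)
        imp1 = predictor_importance(hc1)
        imp2 = predictor_importance(hc2)
        for col in panel.columns:
            assert imp1[col] == pytest.approx(imp2[col], abs=0.05)


class TestHexRegions:
    def test_cell_at_center_assigned_to_that_hex(self):
        r = 50.0
        centers = pd.DataFrame({"x_um": [r * np.sqrt(3) * 2, 0.0],
                                "y_um": [r * 1.5 * 2, 0.0]})
        grid = hex_regions(centers, radius_um=r)
        assert grid.region_id[0] != grid.region_id[1]
        np.testing.assert_allclose(
            grid.centers.iloc[grid.region_id[0]].to_numpy(),
            centers.iloc[0].to_numpy(), atol=1e-9)

    def test_every_cell_in_exactly_one_region(self, rng):
        coords = pd.DataFrame({"x_um": rng.uniform(0, 702, 500),
                               "y_um": rng.uniform(0, 785, 500)})
        grid = hex_regions(coords, radius_um=50.0)
        assert grid.region_id.shape == (500,)
        assert grid.counts.sum() == 500
        # nearest-center property: assigned center is the closest one
        cx = grid.centers["x_um"].to_numpy()
        cy = grid.centers["y_um"].to_numpy()
        d = np.hypot(coords["x_um"].to_numpy()[:, None] - cx,
                     coords["y_um"].to_numpy()[:, None] - cy)
        np.testing.assert_array_equal(d.argmin(axis=1), grid.region_id)

    def test_groups_separate_fields(self, rng):
        coords = pd.DataFrame({"x_um": [10.0, 10.0], "y_um": [10.0, 10.0]})
        grid = hex_regions(coords, radius_um=50.0, groups=["w1", "w2"])
        assert grid.region_id[0] != grid.region_id[1]

    def test_region_mean_of_identical_members(self):
        coords = pd.DataFrame({"x_um": [1.0, 2.0], "y_um": [1.0, 2.0]})
        grid = hex_regions(coords, radius_um=50.0)
        vals = np.array([[3.0, 4.0], [3.0, 4.0]])
        means = region_means(grid.region_id, vals)
        np.testing.assert_allclose(means.to_numpy()[0], [3.0, 4.0])

    def test_bad_radius(self):
        with pytest.raises(ValueError):
            hex_regions(pd.DataFrame({"x_um": [0.0], "y_um": [0.0]}), radius_um=0)


class TestWholeImageModel:
    def test_runs_on_enough_images(self, rng):
        n_img, per = 30, 20
        X, y = _archetype_traces(n_per=n_img * per // 5, seed=3)
        images = np.repeat(np.arange(n_img), per)
        panel, _ = _blobs_panel(rng, n_per=n_img * per // 5)
        rep = whole_image_model(images, X, panel, seed=0)
        assert rep["n_samples"] == n_img
        assert 0.0 <= rep["accuracy"] <= 1.0

    def test_too_few_images_rejected(self, rng):
        X = rng.random((40, 19))
        panel = pd.DataFrame({"s": 10.0 ** rng.random(40)})
        with pytest.raises(ValueError, match="images"):
            whole_image_model(np.repeat(np.arange(10), 4), X, panel)


class TestAnnotate:
    def _coords(self):
        return pd.DataFrame({"cell_id": [1, 2, 3],
                             "x_um": [0.0, 1.0, 2.0],
                             "y_um": [0.0, 1.0, 2.0]})

    def test_missing_predictions_flagged_unlabeled(self):
        preds = pd.Series({1: 2, 3: 5})
        out = annotate(preds, self._coords())
        assert out["labeled"].tolist() == [True, False, True]
        assert out.loc[1, "color"] == ""

    def test_complete_predictions_all_labeled(self):
        preds = pd.Series({1: 1, 2: 2, 3: 3})
        out = annotate(preds, self._coords())
        assert out["labeled"].all()
        assert out["color"].str.startswith("#").all()

    def test_roundtrip_preserves_labels(self, tmp_path):
        preds = pd.Series({1: 4, 2: 1, 3: 3})
        out = annotate(preds, self._coords())
        path = tmp_path / "overlay.csv"
        out.to_csv(path, index=False)
        back = pd.read_csv(path)
        assert back["predicted_class"].tolist() == [4, 1, 3]
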