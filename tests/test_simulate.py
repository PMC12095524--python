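"""Synthetic dataset generator: traces, coordinates, stain panels, bundles."""

import numpy as np
import pandas as pd
import pytest

from erkdyn.simetg import SimEtgParams, run_survey
from erkdyn.simulate import (
    DEFAULT_STAIN_PANEL,
    PlateLayout,
    SimConfig,
    TraceParams,
    TreatmentSpec,
    WellSpec,
    archetype_of,
    assign_coordinates,
    default_layout,
    generate_dataset,
    generate_erk_trace,
    generate_etg_panel,
)

T = np.arange(190) * 6.0
P = TraceParams()


class TestGenerateErkTrace:
    def test_unstimulated_trace_stays_near_baseline(self):
        rng = np.random.default_rng(2)
        means = [generate_erk_trace(TreatmentSpec(0.0), P, rng).mean()
                 for _ in range(50)]
        assert abs(np.mean(means) - P.baseline) < 2 * P.baseline_sd

    def test_meki_clamps_activity_to_floor(self):
        rng = np.random.default_rng(3)
        tr = TreatmentSpec(20.0, meki_time_min=720.0)
        post = slice(int(740 / 6) + 1, None)
        for _ in range(20):
            x = generate_erk_trace(tr, P, rng)
            assert x[post].mean() < P.baseline + 0.05

    def test_default_horizon_is_190_samples_over_19h(self):
        x = generate_erk_trace(TreatmentSpec(20.0), P, np.random.default_rng(0))
        assert x.shape == (190,)
        assert T[-1] == pytest.approx(1134.0)  # 19 h at 6-min increments

    def test_activity_nonnegative_and_stimulus_raises_mean(self):
        rng = np.random.default_rng(4)
        lo = np.mean([generate_erk_trace(TreatmentSpec(0.0), P, rng).mean()
                      for _ in range(30)])
        hi = np.mean([generate_erk_trace(TreatmentSpec(100.0), P, rng).mean()
                      for _ in range(30)])
        assert hi > lo + 0.1

    def test_invalid_inputs_raise(self):
        with pytest.raises(ValueError):
            generate_erk_trace(TreatmentSpec(1.0), P, np.random.default_rng(0), dt_min=0)
        with pytest.raises(ValueError):
            TreatmentSpec(1.0, meki_time_min=-5.0)

    def test_dose_monotonicity_of_mean_activity(self):
        rng = np.random.default_rng(9)
        doses = [0.0, 0.5, 2.0, 20.0, 100.0]
        means = []
        for d in doses:
            m = [generate_erk_trace(TreatmentSpec(d), P, rng).mean()
                 for _ in range(500)]
            means.append(np.mean(m))
        assert all(b >= a for a, b in zip(means, means[1:]))

    def test_meki_efficacy_for_every_stimulated_cell(self):
        rng = np.random.default_rng(10)
        tr = TreatmentSpec(20.0, meki_time_min=600.0)
        cut = int(600 / 6)
        for _ in range(100):
            x = generate_erk_trace(tr, P, rng)
            assert x[cut + 3:].mean() < x[:cut].mean()


class TestAssignCoordinates:
    def test_single_cell_no_cluster(self):
        df = assign_coordinates(1, (702.0, 785.0), np.random.default_rng(0))
        assert len(df) == 1
        assert df["burst_cluster"].iloc[0] == -1

    def test_cluster_sizes_within_bounds_and_in_field(self):
        df = assign_coordinates(400, (702.0, 785.0), np.random.default_rng(1),
                                clustered_fraction=0.4)
        sizes = df[df["burst_cluster"] >= 0]["burst_cluster"].value_counts()
        assert ((sizes >= 5) & (sizes <= 30)).all()
        assert df["x_um"].between(0, 702).all()
        assert df["y_um"].between(0, 785).all()

    def test_same_seed_reproducible(self):
        a = assign_coordinates(50, (702.0, 785.0), np.random.default_rng(7))
        b = assign_coordinates(50, (702.0, 785.0), np.random.default_rng(7))
        pd.testing.assert_frame_equal(a, b)

    def test_bad_field_raises(self):
        with pytest.raises(ValueError):
            assign_coordinates(5, (0.0, 10.0), np.random.default_rng(0))


class TestGenerateEtgPanel:
    def _traces(self, n=6):
        rng = np.random.default_rng(0)
        return np.abs(rng.normal(0.3, 0.1, (n, 190))), T

    def test_noiseless_panel_equals_ode_endpoints(self):
        X, t = self._traces()
        genes = {"g": SimEtgParams()}
        factors = pd.DataFrame(1.0, index=[1], columns=["g"])
        panel = generate_etg_panel(X, t, genes, 0.0, factors,
                                   np.ones(len(X), dtype=int),
                                   np.random.default_rng(0), ode_dt=2.0)
        expected = run_survey([SimEtgParams()], X, t, dt=2.0)[0]
        np.testing.assert_allclose(panel["g"].to_numpy(), expected, rtol=1e-12)

    def test_batch_factor_scales_replicate_medians(self):
        X, t = self._traces(200)
        genes = {"g": SimEtgParams()}
        reps = np.r_[np.ones(100, int), np.full(100, 3, int)]
        factors = pd.DataFrame({"g": [2.0, 1.0]}, index=[1, 3])
        panel = generate_etg_panel(X, t, genes, 0.05, factors, reps,
                                   np.random.default_rng(1), ode_dt=2.0)
        ratio = panel["g"][reps == 1].median() / panel["g"][reps == 3].median()
        assert ratio == pytest.approx(2.0, rel=0.1)

    def test_seeded_run_reproducible(self):
        X, t = self._traces()
        genes = {"g": SimEtgParams()}
        factors = pd.DataFrame(1.0, index=[1], columns=["g"])
        args = (X, t, genes, 0.2, factors, np.ones(len(X), dtype=int))
        a = generate_etg_panel(*args, np.random.default_rng(3), ode_dt=2.0)
        b = generate_etg_panel(*args, np.random.default_rng(3), ode_dt=2.0)
        pd.testing.assert_frame_equal(a, b)

    def test_validation_errors(self):
        X, t = self._traces()
        factors = pd.DataFrame({"g": [-1.0]}, index=[1])
        with pytest.raises(ValueError, match="batch factors"):
            generate_etg_panel(X, t, {"g": SimEtgParams()}, 0.1, factors,
                               np.ones(len(X), dtype=int), np.random.default_rng(0))
        with pytest.raises(ValueError, match="empty"):
            generate_etg_panel(X, t, {}, 0.1, pd.DataFrame(index=[1]),
                               np.ones(len(X), dtype=int), np.random.default_rng(0))


class TestGenerateDataset:
    def test_conservation_and_counts(self, small_dataset):
        ds = small_dataset
        n = ds.n_cells
        assert len(ds.cells) == n
        assert len(ds.stains) == n
        assert ds.cells["cell_id"].is_unique
        assert set(ds.stains.index) == set(ds.cells["cell_id"])
        assert set(ds.truth["true_class"]) == set(ds.cells["cell_id"])
        # per-well counts match the layout request
        assert (ds.cells.groupby("well").size() == 30).all()

    def test_determinism(self):
        layout = default_layout(n_cells_per_well=5, replicates=2)
        cfg = SimConfig(ode_dt=3.0)
        a = generate_dataset(layout, cfg, seed=4)
        b = generate_dataset(layout, cfg, seed=4)
        np.testing.assert_array_equal(a.traces, b.traces)
        pd.testing.assert_frame_equal(a.stains, b.stains)
        pd.testing.assert_frame_equal(a.cells, b.cells)

    def test_batch_correction_inputs_exist_for_matched_conditions(self, small_dataset):
        ds = small_dataset
        by = ds.cells.groupby(["condition", "replicate"]).size().unstack()
        assert by.notna().all().all()  # every condition present in every replicate

    def test_roundtrip_to_dir(self, small_dataset, tmp_path):
        small_dataset.to_dir(tmp_path)
        traces = pd.read_csv(tmp_path / "traces.csv")
        assert len(traces) == small_dataset.n_cells * 190
        stains = pd.read_csv(tmp_path / "stains.csv").set_index("cell_id")
        np.testing.assert_allclose(stains.to_numpy(),
                                   small_dataset.stains.to_numpy(), rtol=1e-9)

    def test_layout_validation(self):
        tr = TreatmentSpec(1.0)
        with pytest.raises(ValueError, match="unique"):
            PlateLayout([WellSpec("A1", tr, 1, 5), WellSpec("A1", tr, 2, 5)])
        with pytest.raises(ValueError):
            default_layout(replicates=0)


class TestArchetypes:
    @pytest.mark.parametrize("treatment,expected", [
        (TreatmentSpec(20.0, meki_time_min=570.0), 1),
        (TreatmentSpec(0.0), 2),
        (TreatmentSpec(20.0, meki_time_min=30.0), 2),
        (TreatmentSpec(20.0, egf_time_min=960.0), 3),
        (TreatmentSpec(20.0, egf_time_min=420.0, meki_time_min=900.0), 4),
        (TreatmentSpec(100.0), 5),
    ])
    def test_treatment_to_class_mapping(self, treatment, expected):
        assert archetype_of(treatment) == expected

    def test_default_layout_covers_all_five_classes(self):
        classes = {archetype_of(w.treatment) for w in default_layout().wells}
        assert classes == {1, 2, 3, 4, 5}
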