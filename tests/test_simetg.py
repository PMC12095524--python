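"""Delay-ODE gene-expression model: integration, steady states, surveys."""

import numpy as np
import pandas as pd
import pytest

from erkdyn.features import featurize_table
from erkdyn.simetg import (
    DEFAULT_VARIED_RANGES,
    SimEtgParams,
    regulation_sign,
    run_survey,
    sample_params,
    screen_predictivity,
    simulate_gene,
    steady_state,
    survey_timepoint_profile,
)

T = np.arange(190) * 6.0


def _closed_form(p: SimEtgParams, erk: float):
    """Independent algebraic fixed point with the feedback term set to 1."""
    tfp = p.k_ptf * erk * p.tf_total / (p.k_ptf * erk + p.k_dtf) \
        if (p.k_ptf * erk + p.k_dtf) > 0 else 0.0
    m = (p.k_b + p.k_m * tfp) / p.k_dm
    b = p.k_pp * erk
    c = p.k_dpp + p.k_deph
    pr = p.k_p * m / (p.k_dp_prot + b * p.k_dpp / c)
    pp = b * pr / c
    return tfp, m, pr, pp


class TestSimulateGene:
    def test_zero_input_zero_basal_stays_at_zero(self):
        p = SimEtgParams(k_b=0.0, k_m=1.0)
        traj = simulate_gene(p, np.zeros(190), T, dt=3.0)
        for sp in (traj.tfp, traj.mrna, traj.p, traj.pp):
            np.testing.assert_array_equal(sp, 0.0)

    def test_constant_erk_no_feedback_reaches_closed_form(self):
        p = SimEtgParams(k_d=1e12)  # feedback off
        slowest = 1.0 / min(p.k_dm, p.k_dp_prot, p.k_dpp + p.k_deph)
        horizon = 50.0 * slowest
        traj = simulate_gene(p, np.array([1.0, 1.0]),
                             np.array([0.0, horizon]), dt=10.0, y0=(0, 0, 0, 0))
        expected = _closed_form(p, 1.0)
        got = (traj.tfp[-1], traj.mrna[-1], traj.p[-1], traj.pp[-1])
        np.testing.assert_allclose(got, expected, rtol=0.01)

    def test_species_nonnegative_and_tfp_bounded(self, rng):
        p = SimEtgParams(k_d=50.0)
        erk = np.abs(rng.normal(0.5, 0.5, 190))
        traj = simulate_gene(p, erk, T, dt=2.0)
        assert (traj.tfp <= p.tf_total + 1e-9).all()
        for sp in (traj.tfp, traj.mrna, traj.p, traj.pp):
            assert (sp >= 0).all()

    def test_protein_mass_conserved_without_degradation(self):
        p = SimEtgParams(k_b=0.0, k_m=0.0, k_dm=0.0, k_dp_prot=0.0,
                         k_dpp=0.0, k_deph=0.02)
        erk = 0.3 + 0.2 * np.sin(T / 60.0)
        traj = simulate_gene(p, erk, T, dt=1.0, y0=(0.0, 0.0, 5.0, 1.0))
        total = traj.p + traj.pp
        np.testing.assert_allclose(total, 6.0, rtol=1e-8)

    def test_halving_dt_changes_endpoint_below_tolerance(self, rng):
        erk = np.abs(0.3 + 0.3 * np.sin(T / 90.0) + rng.normal(0, 0.05, 190))
        for p in (SimEtgParams(k_d=50.0), SimEtgParams(k_dm=0.05, k_deph=0.05)):
            a = simulate_gene(p, erk, T, dt=2.0).readout
            b = simulate_gene(p, erk, T, dt=1.0).readout
            assert abs(a - b) / a < 1e-3

    def test_invalid_dt_raises(self):
        with pytest.raises(ValueError):
            simulate_gene(SimEtgParams(), np.zeros(190), T, dt=0.0)


class TestSteadyState:
    def test_zero_erk_zero_basal_gives_zeros(self):
        assert steady_state(SimEtgParams(k_b=0.0), 0.0) == (0.0, 0.0, 0.0, 0.0)

    def test_feedback_off_equals_closed_form(self):
        p = SimEtgParams(k_d=1e15)
        np.testing.assert_allclose(steady_state(p, 0.7), _closed_form(p, 0.7),
                                   rtol=1e-9)

    def test_feedback_reduces_but_preserves_positivity(self):
        strong = steady_state(SimEtgParams(k_d=10.0), 1.0)
        weak = steady_state(SimEtgParams(k_d=1e12), 1.0)
        assert 0 < strong[2] + strong[3] < weak[2] + weak[3]

    def test_mrna_decreasing_in_degradation_rate(self):
        vals = [steady_state(SimEtgParams(k_dm=k, k_d=1e12), 1.0)[1]
                for k in np.logspace(-3, -1, 10)]
        assert all(b < a for a, b in zip(vals, vals[1:]))

    def test_negative_erk_rejected(self):
        with pytest.raises(ValueError):
            steady_state(SimEtgParams(), -0.1)


class TestSampleParams:
    def test_count_bounds_and_determinism(self):
        genes = sample_params(200, np.random.default_rng(5))
        assert len(genes) == 200
        for g in genes:
            for k, (lo, hi) in DEFAULT_VARIED_RANGES.items():
                assert lo <= getattr(g, k) <= hi
            assert 0.0 <= g.baseline_fraction <= 1.0
            assert g.k_b + g.k_m == pytest.approx(1.0)
        again = sample_params(200, np.random.default_rng(5))
        assert all(a == b for a, b in zip(genes, again))

    def test_invalid_bounds_raise(self):
        with pytest.raises(ValueError):
            sample_params(5, np.random.default_rng(0), ranges={"k_dm": (0.1, 0.01)})


class TestRunSurvey:
    def test_shape_and_single_cell_consistency(self, rng):
        genes = [SimEtgParams(k_d=100.0), SimEtgParams(k_dm=0.05)]
        X = np.abs(rng.normal(0.4, 0.15, (3, 190)))
        E = run_survey(genes, X, T, dt=2.0)
        assert E.shape == (2, 3)
        single = simulate_gene(genes[0], X[1], T, dt=2.0).readout
        assert E[0, 1] == pytest.approx(single, rel=1e-9)

    def test_permuting_cells_permutes_columns(self, rng):
        genes = [SimEtgParams()]
        X = np.abs(rng.normal(0.4, 0.15, (4, 190)))
        E = run_survey(genes, X, T, dt=3.0)
        Ep = run_survey(genes, X[::-1], T, dt=3.0)
        np.testing.assert_allclose(Ep, E[:, ::-1], rtol=1e-12)


class TestRegulationSign:
    def test_pure_induction_is_positive(self):
        p = SimEtgParams(k_b=0.0, k_m=1.0, k_dpp=1e-4, k_dp_prot=1e-4)
        sign, degenerate = regulation_sign(p, dt=2.0)
        assert sign == "positive" and not degenerate

    def test_phospho_degradation_channel_gives_negative(self):
        p = SimEtgParams(k_b=1.0, k_m=0.0, k_dpp=0.05, k_dp_prot=1e-4,
                         k_pp=0.1, k_deph=1e-3)
        sign, degenerate = regulation_sign(p, dt=2.0)
        assert sign == "negative" and not degenerate

    def test_erk_insensitive_gene_flagged_degenerate(self):
        p = SimEtgParams(k_b=1.0, k_m=0.0, k_ptf=0.0, k_pp=0.0)
        sign, degenerate = regulation_sign(p, dt=2.0)
        assert sign == "positive" and degenerate


class TestScreenPredictivity:
    def _features(self, X):
        return featurize_table(X, T)

    def test_endpoint_equal_to_mean_feature_gives_r2_one(self, rng):
        X = np.abs(rng.normal(0.4, 0.2, (40, 190)))
        feats = self._features(X)
        E = feats["mean"].to_numpy()[None, :]
        r2, fractions = screen_predictivity(E, feats)
        assert r2.loc[0, "mean"] == pytest.approx(1.0)
        assert fractions[0.8] == 1.0

    def test_permuted_endpoint_uninformative(self, rng):
        X = np.abs(rng.normal(0.4, 0.2, (200, 190)))
        feats = self._features(X)
        E = rng.permutation(feats["mean"].to_numpy())[None, :]
        r2, _ = screen_predictivity(E, feats)
        assert r2.loc[0].max() < 0.1

    def test_matches_naive_ols_r2(self, rng):
        from sklearn.linear_model import LinearRegression
        from ._oracles import r2_two_pass

        X = np.abs(rng.normal(0.4, 0.2, (60, 190)))
        feats = self._features(X)
        E = (feats["mean"] * 2 + rng.normal(0, 0.05, 60)).to_numpy()[None, :]
        r2, _ = screen_predictivity(E, feats)
        lr = LinearRegression().fit(E.T, feats["mean"])
        expected = r2_two_pass(feats["mean"], lr.predict(E.T))
        assert r2.loc[0, "mean"] == pytest.approx(expected, abs=1e-10)


class TestSurveyTimepointProfile:
    def test_fast_gene_concentrates_late_slow_gene_spreads(self, rng):
        # temporally autocorrelated activity (smoothed noise) from a shared
        # pre-stimulus baseline, as in a serum-starved-then-stimulated plate
        raw = rng.normal(0, 1, (80, 220))
        kernel = np.ones(30) / 30.0
        X = np.abs(0.4 + 0.6 * np.vstack(
            [np.convolve(r, kernel, mode="valid") for r in raw])[:, :190])
        X[:, 0] = 0.1
        fast = SimEtgParams(k_dm=0.1, k_dp_prot=0.01, k_dpp=0.01, k_deph=0.1)
        slow = SimEtgParams(k_dm=0.002, k_dp_prot=2e-4, k_dpp=2e-4, k_deph=0.002)
        E = run_survey([fast, slow], X, T, dt=2.0)
        prof = survey_timepoint_profile(E, X).abs()
        # the fast tracker's correlation peaks late (its memory is ~2 h)
        assert prof.loc["gene_0"].idxmax() >= 150
        # the slow integrator correlates broadly: more timepoints near its max
        breadth = lambda row: (row > 0.5 * row.max()).sum()
        assert breadth(prof.loc["gene_1"]) > breadth(prof.loc["gene_0"])

    def test_constant_gene_gives_missing_profile(self, rng):
        X = np.abs(rng.normal(0.4, 0.2, (10, 190)))
        prof = survey_timepoint_profile(np.ones((1, 10)), X)
        assert prof.isna().all().all()
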