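"""Harmonic regression: exact recovery, oracles, calibration, invariances."""

import numpy as np
import pandas as pd
import pytest

from dieltx.harmonics import call_periodic, fit_harmonic, taxon_total_periodicity
from dieltx.matrix import NormalizedMatrix, normalize
from dieltx.synthetic import SimulationConfig, TaxonSpec, simulate_expression
from dieltx.timeline import Timeline
from tests.conftest import make_matrix


def drift_clock(timeline: Timeline) -> np.ndarray:
    return timeline.start_clock + timeline.sample_times


def grid_search_peak(y, t, step_h=0.001, period=24.0):
    """Dense-grid oracle: the phase whose cosine best correlates with y."""
    phis = np.arange(0.0, period, step_h)
    basis = np.cos(2 * np.pi * (t[None, :] - phis[:, None]) / period)
    yc = y - y.mean()
    bc = basis - basis.mean(axis=1, keepdims=True)
    corr = (bc @ yc) / (np.linalg.norm(bc, axis=1) * np.linalg.norm(yc))
    return phis[np.argmax(corr)]


class TestFitHarmonic:
    def test_noise_free_cosine_recovered_exactly(self, drift_timeline):
        t = drift_clock(drift_timeline)
        y = 3.0 + np.cos(2 * np.pi * (t - 11.0) / 24.0)
        fit = fit_harmonic(y, t)
        assert fit.peak_time == pytest.approx(11.0, abs=1e-9)
        assert fit.amplitude == pytest.approx(1.0, abs=1e-9)
        assert fit.mesor == pytest.approx(3.0, abs=1e-9)
        assert fit.p_value < 1e-10

    def test_constant_series_convention(self, drift_timeline):
        t = drift_clock(drift_timeline)
        fit = fit_harmonic(np.full(16, 5.0), t)
        assert fit.amplitude == 0.0
        assert np.isnan(fit.peak_time)
        assert fit.p_value == 1.0

    def test_too_few_observations_rejected(self):
        with pytest.raises(ValueError, match="at least 5"):
            fit_harmonic([1, 2, 3, 4], [0, 4, 8, 12])

    def test_degenerate_phase_coverage_rejected(self):
        # all samples at the same clock phase mod 24
        t = np.array([0.0, 24.0, 48.0, 72.0, 96.0])
        with pytest.raises(ValueError, match="degenerate"):
            fit_harmonic(np.array([1.0, 2, 3, 4, 5]), t)

    @pytest.mark.parametrize("seed", range(25))
    def test_matches_grid_search_oracle(self, seed, drift_timeline):
        t = drift_clock(drift_timeline)
        rng = np.random.default_rng(seed)
        phi = rng.uniform(0, 24)
        y = 10.0 * (1 + 0.5 * np.cos(2 * np.pi * (t - phi) / 24.0))
        y *= rng.lognormal(0, 0.25, size=t.size)
        fit = fit_harmonic(y, t)
        oracle = grid_search_peak(y, t)
        err = abs(fit.peak_time - oracle)
        assert min(err, 24 - err) < 0.002

    def test_phase_equivariance(self, drift_timeline):
        t = drift_clock(drift_timeline)
        rng = np.random.default_rng(3)
        y = 5 + 2 * np.cos(2 * np.pi * (t - 7.0) / 24.0) + rng.normal(0, 0.3, t.size)
        f0 = fit_harmonic(y, t)
        delta = 5.25
        f1 = fit_harmonic(y, t + delta)
        assert f1.peak_time == pytest.approx((f0.peak_time + delta) % 24, abs=1e-9)
        assert f1.p_value == pytest.approx(f0.p_value, abs=1e-9)

    def test_scale_invariance(self, drift_timeline):
        t = drift_clock(drift_timeline)
        rng = np.random.default_rng(4)
        y = 5 + 2 * np.cos(2 * np.pi * (t - 7.0) / 24.0) + rng.normal(0, 0.3, t.size)
        f0, f1 = fit_harmonic(y, t), fit_harmonic(3.7 * y, t)
        assert f1.mesor == pytest.approx(3.7 * f0.mesor)
        assert f1.amplitude == pytest.approx(3.7 * f0.amplitude)
        assert f1.peak_time == pytest.approx(f0.peak_time, abs=1e-12)
        assert f1.r_squared == pytest.approx(f0.r_squared, abs=1e-12)
        assert f1.p_value == pytest.approx(f0.p_value, abs=1e-12)

    def test_permutation_p_agrees_with_f_test(self, drift_timeline):
        """On a moderate signal the parametric and permutation p agree
        within Monte-Carlo error."""
        t = drift_clock(drift_timeline)
        rng = np.random.default_rng(8)
        y = 10 + 3 * np.cos(2 * np.pi * (t - 11.0) / 24.0) + rng.normal(0, 3.0, t.size)
        f = fit_harmonic(y, t)
        p = fit_harmonic(y, t, test="permutation", n_permutations=10000, seed=0)
        se = np.sqrt(f.p_value * (1 - f.p_value) / 10000)
        assert abs(p.p_value - f.p_value) < max(4 * se, 0.01)


class TestBenjaminiHochberg:
    def test_q_values_match_textbook_bh(self, drift_timeline):
        """q-values from the callset equal the step-up definition
        q_(i) = min_{j>=i} ( m * p_(j) / j ) computed from scratch."""
        rng = np.random.default_rng(0)
        n = 200
        counts = rng.gamma(2.0, 10.0, size=(n, 16))
        m = make_matrix(counts, taxa=["a"] * n, labels=drift_timeline.sample_labels)
        norm = normalize(m, mode="taxon_group")
        cs = call_periodic(norm, drift_timeline, fdr_scope="global")
        p = cs.fits["p"].to_numpy()
        order = np.argsort(p)
        q_text = np.empty_like(p)
        prev = 1.0
        for rank_idx in range(len(p) - 1, -1, -1):
            i = order[rank_idx]
            prev = min(prev, p[i] * len(p) / (rank_idx + 1))
            q_text[i] = prev
        np.testing.assert_allclose(cs.fits["q"].to_numpy(), q_text, atol=1e-12)


class TestCallPeriodic:
    def test_null_simulation_fdr_controlled(self, drift_timeline):
        """With no cyclic ORFs the q<=0.1 call rate stays within three
        binomial standard errors of the nominal rate."""
        taxa = [TaxonSpec("null", 2000, 0.0)]
        cfg = SimulationConfig(taxa=taxa, noise_model="negative_binomial", seed=101)
        matrix, truth = simulate_expression(cfg)
        norm = normalize(matrix, mode="taxon_group")
        cs = call_periodic(norm, cfg.timeline())
        rate = cs.fits["called"].mean()
        bound = 0.1 + 3 * np.sqrt(0.1 * 0.9 / len(cs.fits))
        assert rate <= bound

    def test_power_run_recovers_planted_cyclic(self, drift_timeline):
        taxa = [TaxonSpec("phot", 400, 0.25, amplitude_range=(0.6, 0.9))]
        cfg = SimulationConfig(taxa=taxa, noise_model="lognormal", cv=0.2, seed=7)
        matrix, truth = simulate_expression(cfg)
        norm = normalize(matrix, mode="taxon_group")
        cs = call_periodic(norm, cfg.timeline())
        cyc = truth.table.index[truth.table["is_cyclic"]]
        recovered = cs.fits.loc[cyc, "called"].mean()
        assert recovered >= 0.90
        pct = cs.taxon_summary().iloc[0]["pct_orfs_periodic"]
        assert abs(pct - 100 * truth.table["is_cyclic"].mean()) <= 5.0

    def test_called_set_is_q_threshold_definition(self, drift_timeline):
        taxa = [TaxonSpec("t", 100, 0.3)]
        cfg = SimulationConfig(taxa=taxa, seed=3)
        matrix, _ = simulate_expression(cfg)
        cs = call_periodic(normalize(matrix, "taxon_group"), cfg.timeline())
        assert (cs.fits["called"] == (cs.fits["q"] <= cs.q_threshold)).all()

    def test_sparse_orfs_listed_ineligible(self, drift_timeline):
        counts = np.zeros((2, 16))
        counts[0] = np.arange(16.0) + 1
        counts[1, :3] = 1.0  # only 3 nonzero points
        m = make_matrix(counts, taxa=["a", "a"], labels=drift_timeline.sample_labels)
        norm = NormalizedMatrix(counts=m.counts, meta=m.meta, mode="taxon_group")
        cs = call_periodic(norm, drift_timeline)
        assert list(cs.ineligible) == ["orf1"]


class TestTaxonAggregates:
    def test_shared_phase_passes_to_aggregate(self, drift_timeline):
        t = drift_clock(drift_timeline)
        phi = 9.0
        rows = [b * (1 + 0.5 * np.cos(2 * np.pi * (t - phi) / 24)) for b in (1.0, 5.0, 20.0)]
        m = make_matrix(np.array(rows), taxa=["a"] * 3, labels=drift_timeline.sample_labels)
        norm = NormalizedMatrix(counts=m.counts, meta=m.meta, mode="taxon_group")
        out = taxon_total_periodicity(norm, drift_timeline)
        assert out.loc["a", "peak_time"] == pytest.approx(phi, abs=1e-9)

    def test_antiphase_pair_cancels(self, drift_timeline):
        t = drift_clock(drift_timeline)
        up = 10 * (1 + 0.5 * np.cos(2 * np.pi * (t - 6.0) / 24))
        down = 10 * (1 + 0.5 * np.cos(2 * np.pi * (t - 18.0) / 24))
        m = make_matrix(np.array([up, down]), taxa=["a"] * 2, labels=drift_timeline.sample_labels)
        norm = NormalizedMatrix(counts=m.counts, meta=m.meta, mode="taxon_group")
        out = taxon_total_periodicity(norm, drift_timeline)
        assert out.loc["a", "amplitude"] == pytest.approx(0.0, abs=1e-9)

    def test_aggregate_equals_fit_of_summed_series(self, drift_timeline):
        cfg = SimulationConfig(taxa=[TaxonSpec("x", 50, 0.4), TaxonSpec("y", 30, 0.1)], seed=12)
        matrix, _ = simulate_expression(cfg)
        norm = normalize(matrix, "taxon_group")
        out = taxon_total_periodicity(norm, cfg.timeline())
        t = drift_clock(cfg.timeline())
        for g in ("x", "y"):
            summed = norm.counts.loc[norm.taxon_group == g].sum(axis=0).to_numpy()
            direct = fit_harmonic(summed, t)
            assert out.loc[g, "peak_time"] == pytest.approx(direct.peak_time, abs=1e-9)
            assert out.loc[g, "p"] == pytest.approx(direct.p_value, rel=1e-9)
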