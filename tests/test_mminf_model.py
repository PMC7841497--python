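"""M/M/inf model tests: steady-state equations, running counts,
observed-vs-predicted comparison, birth-death spectrum and contrasts."""

import numpy as np
import pandas as pd
import pytest
from hypothesis import given, settings
from hypothesis import strategies as st

from fibrenew import mminf_model as mm
from fibrenew import renewal_stats as rs
from fibrenew import synthetic_data as sd
from fibrenew.types import (
    EVENT_COLUMNS,
    EventTable,
    MMInfParams,
    ParameterError,
    PopulationSeries,
)


def _table(onsets, offsets, epoch_ms):
    df = pd.DataFrame({
        "id": range(len(onsets)), "kind": "PS", "onset_ms": onsets,
        "offset_ms": offsets, "x": 0.0, "y": 0.0, "chirality": 1,
        "censored_left": False, "censored_right": False,
    }, columns=EVENT_COLUMNS)
    return EventTable(df, epoch_ms=epoch_ms)


class TestSteadyState:
    def test_mean_is_rate_ratio(self):
        assert mm.predict_mean(0.27, 0.05) == pytest.approx(5.4)
        assert round(mm.predict_mean(0.37, 0.11), 2) == 3.36

    @given(st.floats(1e-6, 1e3))
    @settings(max_examples=30, deadline=None)
    def test_equal_rates_give_unit_mean(self, x):
        assert mm.predict_mean(x, x) == pytest.approx(1.0)

    def test_invalid_rates_rejected(self):
        with pytest.raises(ParameterError):
            mm.predict_mean(0.1, 0.0)
        with pytest.raises(ParameterError):
            mm.predict_mean(-0.1, 0.1)

    def test_pmf_degenerate_at_zero_load(self):
        pred = mm.predict_pmf(0.0, 0.1, 10)
        assert pred.pmf[0] == pytest.approx(1.0)
        np.testing.assert_allclose(pred.pmf[1:], 0.0, atol=1e-15)

    def test_pmf_normalizes_with_wide_truncation(self):
        pred = mm.predict_pmf(0.27, 0.05, n_max=60)
        assert pred.pmf.sum() >= 1 - 1e-6
        assert (pred.pmf >= 0).all()

    def test_pmf_mode_at_floor_of_load(self):
        pred = mm.predict_pmf(0.27, 0.05, n_max=60)  # rho = 5.4
        assert int(np.argmax(pred.pmf)) == 5


class TestPopulationSeries:
    def test_single_event_counts_half_open(self):
        s = mm.population_series(_table([0.0], [100.0], 150.0), dt_ms=10.0)
        np.testing.assert_array_equal(s.counts, [1] * 10 + [0] * 5)

    def test_overlapping_events_stack(self):
        s = mm.population_series(_table([0.0, 20.0], [40.0, 60.0], 60.0),
                                 dt_ms=10.0)
        np.testing.assert_array_equal(s.counts, [1, 1, 2, 2, 1, 1])

    def test_empty_table_all_zero(self):
        s = mm.population_series(_table([], [], 100.0), dt_ms=10.0)
        np.testing.assert_array_equal(s.counts, np.zeros(10))

    def test_invalid_dt_rejected(self):
        with pytest.raises(ParameterError):
            mm.population_series(_table([], [], 100.0), dt_ms=0.0)


class TestCompareToObserved:
    def test_matching_histogram_gives_high_p(self):
        # counts replicated in proportion to the predicted pmf
        pred = mm.predict_pmf(0.2, 0.1, 12)  # rho = 2
        reps = np.round(pred.pmf * 10_000).astype(int)
        counts = np.repeat(np.arange(13), reps)
        series = PopulationSeries(counts, dt_ms=1.0)
        rep = mm.compare_to_observed(pred, series)
        assert rep.chi2_stat < 1.0
        assert rep.chi2_p > 0.99

    def test_simulator_consistent_with_poisson_prediction(self):
        ok = 0
        n_seeds = 10
        pred = mm.predict_pmf(0.05, 0.01, 30)
        for seed in range(n_seeds):
            ev = sd.simulate_mminf_events(MMInfParams(0.05, 0.01, 5e5, seed=seed))
            series = mm.population_series(ev, dt_ms=1.0)
            rep = mm.compare_to_observed(pred, series, stride=500)
            ok += rep.chi2_p > 0.05
        assert ok >= 0.9 * n_seeds

    def test_mismatched_load_rejected_by_chi2(self):
        ev = sd.simulate_mminf_events(MMInfParams(0.05, 0.01, 5e5, seed=0))
        series = mm.population_series(ev, dt_ms=1.0)
        rep = mm.compare_to_observed(mm.predict_pmf(0.05, 0.02, 30), series,
                                     stride=500)
        assert rep.chi2_p < 0.001

    def test_degenerate_series_rejected(self):
        pred = mm.predict_pmf(0.1, 0.1, 5)
        with pytest.raises(ParameterError):
            mm.compare_to_observed(pred, PopulationSeries(np.ones(500), 1.0))

    def test_predicted_vs_observed_means_correlate_across_epochs(self):
        rng = np.random.default_rng(8)
        predicted, observed = [], []
        for i in range(20):
            lf = rng.uniform(0.02, 0.3)
            ld = rng.uniform(0.01, 0.05)
            ev = sd.simulate_mminf_events(MMInfParams(lf, ld, 2e5, seed=100 + i))
            inter, life = rs.extract_intervals(ev)
            lf_hat = rs.fit_exponential(inter, gof=False).lambda_per_ms
            ld_hat = rs.fit_exponential(life, gof=False).lambda_per_ms
            predicted.append(mm.predict_mean(lf_hat, ld_hat))
            observed.append(mm.population_series(ev, dt_ms=1.0).mean)
        res = mm.predicted_observed_correlation(predicted, observed)
        assert res["r2"] > 0.95
        assert res["p"] < 0.001


class TestBDSpectrum:
    def test_period_two_chain_has_zero_gap(self):
        spec = mm.estimate_bd_matrix(PopulationSeries(np.tile([0, 1], 50), 1.0))
        np.testing.assert_allclose(spec.matrix, [[0, 1], [1, 0]])
        np.testing.assert_allclose(spec.eigen_moduli, [1.0, 1.0])
        assert spec.spectral_gap == pytest.approx(0.0, abs=1e-12)

    def test_ergodic_series_has_positive_gap(self):
        ev = sd.simulate_mminf_events(MMInfParams(0.27, 0.05, 1e5, seed=2))
        spec = mm.estimate_bd_matrix(mm.population_series(ev, dt_ms=1.0))
        assert spec.eigen_moduli[0] == pytest.approx(1.0, abs=1e-6)
        assert 0 < spec.spectral_gap < 1
        assert spec.slem + spec.spectral_gap == 1.0
        rows = spec.matrix.sum(axis=1)
        np.testing.assert_allclose(rows, 1.0, atol=1e-9)

    def test_empirical_gap_matches_generator_oracle(self):
        lf, ld = 0.27, 0.05
        ev = sd.simulate_mminf_events(MMInfParams(lf, ld, 5e5, seed=9))
        spec = mm.estimate_bd_matrix(mm.population_series(ev, dt_ms=1.0))
        Q = mm.analytic_generator(lf, ld, int(spec.states.max()))
        P = mm.discretize_generator(Q, 1.0)
        oracle_gap = 1.0 - np.sort(np.abs(np.linalg.eigvals(P)))[::-1][1]
        assert spec.spectral_gap == pytest.approx(oracle_gap, rel=0.15)

    def test_unvisited_state_gets_flagged_self_loop(self):
        counts = np.array([0, 0, 3, 3, 0, 3, 0, 3, 3, 0] * 20)
        spec = mm.estimate_bd_matrix(PopulationSeries(counts, 1.0))
        assert set(spec.unvisited_states) == {1, 2}
        assert spec.matrix[1, 1] == 1.0 and spec.matrix[2, 2] == 1.0

    def test_constant_series_rejected(self):
        with pytest.raises(ParameterError):
            mm.estimate_bd_matrix(PopulationSeries(np.full(100, 2), 1.0))


class TestAnalyticGenerator:
    def test_rows_sum_to_zero(self):
        Q = mm.analytic_generator(0.27, 0.05, 50)
        np.testing.assert_allclose(Q.sum(axis=1), 0.0, atol=1e-12)

    def test_stationary_law_is_truncated_poisson(self):
        from scipy import stats as ss

        Q = mm.analytic_generator(0.27, 0.05, 54)  # n_max = 10 rho
        pi = mm.generator_stationary(Q)
        pois = ss.poisson.pmf(np.arange(55), 5.4)
        pois /= pois.sum()
        assert 0.5 * np.abs(pi - pois).sum() < 1e-6

    def test_slowest_relaxation_mode_is_minus_lambda_d(self):
        Q = mm.analytic_generator(0.27, 0.05, 54)
        eig = np.sort(np.linalg.eigvals(Q).real)[::-1]
        assert eig[0] == pytest.approx(0.0, abs=1e-9)
        assert eig[1] == pytest.approx(-0.05, rel=1e-6)

    def test_gap_scales_linearly_with_common_rate_factor(self):
        # equal rho, slower tempo: continuous-time gap scales by c
        for c in (0.5, 0.25):
            Q1 = mm.analytic_generator(0.27, 0.05, 54)
            Qc = mm.analytic_generator(0.27 * c, 0.05 * c, 54)
            g1 = -np.sort(np.linalg.eigvals(Q1).real)[::-1][1]
            gc = -np.sort(np.linalg.eigvals(Qc).real)[::-1][1]
            assert gc == pytest.approx(c * g1, rel=1e-9)

    def test_tiny_state_space_rejected(self):
        with pytest.raises(ParameterError):
            mm.analytic_generator(0.1, 0.1, 1)


class TestTerminationContrast:
    @staticmethod
    def _metrics(tables, dt_ms=1.0):
        out = []
        for t in tables:
            inter, life = rs.extract_intervals(t)
            lf = rs.fit_exponential(inter, gof=False).lambda_per_ms
            ld = rs.fit_exponential(life, gof=False).lambda_per_ms
            series = mm.population_series(t, dt_ms=dt_ms)
            spec = mm.estimate_bd_matrix(series)
            out.append({"lambda_f": lf, "lambda_d": ld,
                        "mean_count": series.mean, "slem": spec.slem,
                        "spectral_gap": spec.spectral_gap,
                        "mixing_rate": spec.mixing_rate})
        return out

    def test_identical_groups_show_no_differences(self):
        tabs = sd.simulate_cohort(0.035, 0.013, 6, epoch_ms=5e4, seed=1)
        m = self._metrics(tabs)
        res = mm.termination_contrast(m, m)
        assert all(v["p"] > 0.05 for v in res.metrics.values())

    def test_equal_load_different_tempo_dissociates(self):
        # same rho -> same mean count; slower tempo -> slower mixing
        fast = sd.simulate_cohort(0.052, 0.026, 12, epoch_ms=9e4,
                                  rate_cv=0.2, seed=2)
        slow = sd.simulate_cohort(0.026, 0.013, 12, epoch_ms=9e4,
                                  rate_cv=0.2, seed=3)
        res = mm.termination_contrast(self._metrics(slow), self._metrics(fast),
                                      labels=("slow", "fast"))
        assert res.metrics["mean_count"]["p"] > 0.05
        assert res.metrics["mixing_rate"]["p"] < 0.05
        assert (res.metrics["mixing_rate"]["mean_slow"]
                < res.metrics["mixing_rate"]["mean_fast"])

    def test_small_groups_rejected(self):
        with pytest.raises(ParameterError):
            mm.termination_contrast([{"lambda_f": 1}], [{"lambda_f": 1}] * 3)
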