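import math

import numpy as np
import pytest

from conftest import random_cohort
from oracles import nelson_aalen_oracle, pohar_perme_oracle

from survtrend import (
    IndividualRecord,
    LifeTable,
    NetSurvivalCurve,
    StandardWeights,
    TrueTrend,
    age_standardize,
    default_survival_weights,
    expected_survival,
    period_window_estimate,
    pohar_perme,
    se_from_ci,
    simulate_cohort,
)


class TestSeFromCi:
    def test_degenerate_interval(self):
        assert se_from_ci((70.0, 70.0)) == 0.0

    def test_symmetric_196(self):
        assert se_from_ci((68.04, 71.96)) == pytest.approx(1.0, abs=1e-3)

    def test_arithmetic(self):
        assert se_from_ci((60.5, 66.3)) == pytest.approx(1.4796, abs=1e-4)

    def test_reversed_bounds_rejected(self):
        with pytest.raises(ValueError):
            se_from_ci((71.0, 70.0))


class TestExpectedSurvival:
    def test_zero_table(self, zero_life_table):
        r = IndividualRecord("1", "x", "m", 50.0, 2000.0, 5.0, "censored")
        for t in (0.0, 1.0, 5.0, 10.0):
            assert expected_survival(r, zero_life_table, t) == 1.0

    def test_constant_hazard_closed_form(self, const_life_table):
        r = IndividualRecord("1", "x", "m", 50.3, 2000.7, 5.0, "censored")
        assert expected_survival(r, const_life_table, 5.0) == pytest.approx(
            math.exp(-0.05), rel=1e-12
        )

    def test_piecewise_hazard_independent_integral(self):
        # hazard 0.01 in the first calendar year, 0.02 afterwards
        hz = np.full((10, 100), 0.02)
        hz[0, :] = 0.01
        lt = LifeTable("x", "m", 2000, hz)
        r = IndividualRecord("1", "x", "m", 50.0, 2000.0, 5.0, "censored")
        expected = math.exp(-(0.01 + 0.02 * 2))
        assert expected_survival(r, lt, 3.0) == pytest.approx(expected, rel=1e-12)

    def test_s0_is_one(self, makeham_life_table):
        r = IndividualRecord("1", "x", "m", 60.0, 2000.0, 5.0, "censored")
        assert expected_survival(r, makeham_life_table, 0.0) == 1.0

    def test_out_of_span_names_cell(self, const_life_table):
        r = IndividualRecord("1", "x", "m", 50.0, 2038.5, 5.0, "censored")
        with pytest.raises(KeyError, match="year=2040"):
            expected_survival(r, const_life_table, 3.0)


class TestPoharPerme:
    def test_zero_table_equals_nelson_aalen(self, zero_life_table):
        rng = np.random.default_rng(10)
        recs, _ = random_cohort(rng, 60)
        grid = np.array([0.0, 0.5, 1.0, 2.0, 3.5, 5.0])
        c = pohar_perme(recs, zero_life_table, grid, method="exact")
        oracle = nelson_aalen_oracle(recs, grid)
        assert np.array_equal(c.estimate, np.array(oracle))

    def test_single_censored_subject_net_above_one(self):
        lt = LifeTable("x", "m", 1990, np.full((40, 100), 0.02))
        r = IndividualRecord("1", "x", "m", 50.0, 2000.0, 5.0, "censored")
        c = pohar_perme([r], lt, [0.0, 5.0])
        assert c.estimate[-1] == pytest.approx(math.exp(0.1), rel=1e-9)

    def test_three_records_vs_oracle(self, const_life_table):
        recs = [
            IndividualRecord("1", "x", "m", 60.0, 2000.0, 1.0, "died"),
            IndividualRecord("2", "x", "m", 70.0, 2000.5, 3.0, "died"),
            IndividualRecord("3", "x", "m", 55.0, 2001.0, 5.0, "censored"),
        ]
        grid = np.array([0.0, 1.0, 2.0, 3.0, 4.0, 5.0])
        c = pohar_perme(recs, const_life_table, grid, method="exact")
        S, V = pohar_perme_oracle(recs, const_life_table, grid)
        assert np.abs(c.estimate - S).max() < 1e-10
        assert np.abs(c.variance - V).max() < 1e-10

    def test_oracle_equivalence_with_entry(self, makeham_life_table):
        rng = np.random.default_rng(5)
        for rep in range(10):
            recs, ent = random_cohort(rng, 25, with_entry=(rep % 2 == 1))
            grid = np.array([0.0, 1.0, 2.5, 5.0])
            c = pohar_perme(recs, makeham_life_table, grid, entry=ent, method="exact")
            S, _ = pohar_perme_oracle(recs, makeham_life_table, grid, entry=ent)
            assert np.abs(c.estimate - S).max() < 1e-10

    def test_binned_close_to_exact(self, makeham_life_table):
        rng = np.random.default_rng(11)
        recs, _ = random_cohort(rng, 400)
        grid = np.array([0.0, 1.0, 2.0, 5.0])
        ce = pohar_perme(recs, makeham_life_table, grid, method="exact")
        cb = pohar_perme(recs, makeham_life_table, grid, method="binned", step=0.01)
        assert np.abs(ce.estimate - cb.estimate).max() < 0.01

    def test_empty_records_error(self, zero_life_table):
        with pytest.raises(ValueError):
            pohar_perme([], zero_life_table, [0.0, 5.0])

    def test_grid_must_start_at_zero(self, zero_life_table):
        r = IndividualRecord("1", "x", "m", 50.0, 2000.0, 5.0, "censored")
        with pytest.raises(ValueError):
            pohar_perme([r], zero_life_table, [1.0, 5.0])

    def test_curve_invariants(self, makeham_life_table):
        rng = np.random.default_rng(12)
        recs, _ = random_cohort(rng, 50)
        c = pohar_perme(recs, makeham_life_table, [0.0, 1.0, 5.0])
        assert c.estimate[0] == 1.0
        assert np.all(c.variance >= 0)
        assert c.n_at_risk[0] == 50


class TestAgeStandardize:
    @staticmethod
    def _curve(values, grid=None):
        grid = np.array([0.0, 1.0, 5.0]) if grid is None else grid
        values = np.asarray(values, dtype=float)
        return NetSurvivalCurve(
            group="g", grid=grid, estimate=values,
            variance=np.full_like(values, 0.01), n_at_risk=np.full_like(values, 10),
        )

    def test_identical_curves_unchanged(self):
        w = StandardWeights([((0.0, 45.0), 0.5), ((45.0, 90.0), 0.5)])
        c = self._curve([1.0, 0.8, 0.6])
        out = age_standardize({(0.0, 45.0): c, (45.0, 90.0): c}, w)
        assert np.allclose(out.estimate, c.estimate)

    def test_two_band_arithmetic(self):
        w = StandardWeights([((0.0, 45.0), 0.5), ((45.0, 90.0), 0.5)])
        out = age_standardize(
            {(0.0, 45.0): self._curve([1.0, 0.7, 0.6]), (45.0, 90.0): self._curve([1.0, 0.9, 0.8])},
            w,
        )
        assert out.estimate[-1] == pytest.approx(0.7)

    def test_three_band_spreadsheet(self):
        w = StandardWeights([((0.0, 30.0), 0.2), ((30.0, 60.0), 0.3), ((60.0, 90.0), 0.5)])
        grid = np.linspace(0, 9, 10)
        rng = np.random.default_rng(3)
        vals = {b: np.concatenate([[1.0], rng.uniform(0.4, 1.0, 9)]) for b in w.bands}
        curves = {b: self._curve(vals[b], grid) for b in w.bands}
        out = age_standardize(curves, w)
        manual = 0.2 * vals[(0.0, 30.0)] + 0.3 * vals[(30.0, 60.0)] + 0.5 * vals[(60.0, 90.0)]
        assert np.allclose(out.estimate, manual, atol=1e-12)
        manual_var = (0.2**2 + 0.3**2 + 0.5**2) * 0.01
        assert np.allclose(out.variance, manual_var, atol=1e-12)

    def test_bad_weights_rejected(self):
        with pytest.raises(ValueError):
            StandardWeights([((0.0, 45.0), 0.5), ((45.0, 90.0), 0.6)])

    def test_empty_band_renormalized_with_warning(self, caplog):
        w = StandardWeights([((0.0, 45.0), 0.4), ((45.0, 90.0), 0.6)])
        c = self._curve([1.0, 0.8, 0.6])
        with caplog.at_level("WARNING"):
            out = age_standardize({(45.0, 90.0): c}, w)
        assert np.allclose(out.estimate, c.estimate)
        assert any("dropping empty bands" in r.message for r in caplog.records)

    def test_default_weights_sum_to_one(self):
        w = default_survival_weights()
        assert w.weights.sum() == pytest.approx(1.0, abs=1e-12)
        assert w.bands[0][0] == 0.0 and w.bands[-1][1] == 90.0


class TestPeriodWindowEstimate:
    def test_cohort_equals_pohar_perme_single_band(self, makeham_life_table):
        rng = np.random.default_rng(21)
        truth = TrueTrend.constant("x_m", "5y", 0.6)
        recs = simulate_cohort(
            truth, makeham_life_table, 500, [(2000, 2004)], seed=8, study_end=2012.0
        )
        w = StandardWeights([((0.0, 90.0), 1.0)])
        p1, p5 = period_window_estimate(
            recs, makeham_life_table, (2000, 2004), "cohort", weights=w, study_end=2012.0
        )
        direct = pohar_perme(recs, makeham_life_table, np.arange(0.0, 5.5, 1.0))
        assert p1.estimate == pytest.approx(100 * direct.estimate[1], rel=1e-9)
        assert p5.estimate == pytest.approx(100 * direct.estimate[5], rel=1e-9)

    def test_hybrid_degenerates_to_cohort(self, makeham_life_table):
        # every diagnosis year has complete 5-year potential follow-up
        truth = TrueTrend.constant("x_m", "5y", 0.6)
        recs = simulate_cohort(
            truth, makeham_life_table, 800, [(2000, 2004)], seed=9, study_end=2012.0
        )
        pc = period_window_estimate(
            recs, makeham_life_table, (2000, 2004), "cohort", study_end=2012.0
        )
        ph = period_window_estimate(
            recs, makeham_life_table, (2000, 2004), "hybrid", study_end=2012.0
        )
        assert pc[0].estimate == ph[0].estimate
        assert pc[1].estimate == ph[1].estimate
        assert ph[1].design == "hybrid"

    def test_hybrid_truth_recovery_truncated_follow_up(self, makeham_life_table):
        # last 4 diagnosis years truncated by the study end
        truth = TrueTrend.constant("x_m", "5y", 0.55)
        recs = simulate_cohort(
            truth,
            makeham_life_table,
            20_000,
            [(2011, 2015), (2016, 2020)],
            seed=10,
            study_end=2021.0,
        )
        _, p5 = period_window_estimate(
            recs, makeham_life_table, (2016, 2020), "hybrid",
            study_end=2021.0, method="binned", step=0.02,
        )
        assert abs(p5.estimate - 55.0) < 2 * p5.se

    def test_empty_window_error_names_window(self, makeham_life_table):
        truth = TrueTrend.constant("x_m", "5y", 0.6)
        recs = simulate_cohort(truth, makeham_life_table, 10, [(2000, 2004)], seed=1)
        with pytest.raises(ValueError, match="1980-1984"):
            period_window_estimate(recs, makeham_life_table, (1980, 1984), "cohort")

    def test_invalid_design_rejected(self, makeham_life_table):
        truth = TrueTrend.constant("x_m", "5y", 0.6)
        recs = simulate_cohort(truth, makeham_life_table, 10, [(2000, 2004)], seed=1)
        with pytest.raises(ValueError):
            period_window_estimate(recs, makeham_life_table, (2000, 2004), "period")

    def test_point_metadata(self, makeham_life_table):
        truth = TrueTrend.constant("x_m", "5y", 0.6)
        recs = simulate_cohort(
            truth, makeham_life_table, 300, [(2000, 2004)], seed=2, study_end=2012.0
        )
        p1, p5 = period_window_estimate(
            recs, makeham_life_table, (2000, 2004), "cohort", study_end=2012.0, site="rectum"
        )
        assert p1.horizon == "1y" and p5.horizon == "5y"
        assert p1.midyear == 2002.0
        assert p1.site == "rectum"
        assert p1.ci[0] <= p1.estimate <= p1.ci[1]
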