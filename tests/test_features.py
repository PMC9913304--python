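import numpy as np
import pytest

from survtrend import (
    PosteriorCurveSet,
    annual_change,
    conditional_ratio,
    detect_breakpoints,
    extract_features,
    plausible_intervals,
)


def make_curveset(grid, draws, deriv1=None, deriv2=None, metric="5y", group="g"):
    """Hand-built curve set (draws and derivative draws supplied directly)."""
    K = draws.shape[0]
    z = np.zeros_like(draws)
    return PosteriorCurveSet(
        metric=metric,
        grid=np.asarray(grid, dtype=float),
        draws={group: draws},
        deriv1={group: z if deriv1 is None else deriv1},
        deriv2={group: z if deriv2 is None else deriv2},
    )


GRID = np.arange(1971.0, 2020.25, 0.25)


class TestConditionalRatio:
    def test_x_over_x_is_100(self, fitted_pair):
        five, _ = fitted_pair
        ratio = conditional_ratio(five, five)
        for g in ratio.groups:
            assert np.allclose(ratio.draws[g], 100.0, atol=1e-10)

    def test_simple_arithmetic(self):
        g = np.array([1971.0, 1971.5, 1972.0])
        five = make_curveset(g, np.full((4, 3), 40.0))
        one = make_curveset(g, np.full((4, 3), 80.0))
        ratio = conditional_ratio(five, one)
        assert np.allclose(ratio.draws["g"], 50.0)

    def test_round_trip_identity(self, fitted_pair):
        five, one = fitted_pair
        ratio = conditional_ratio(five, one)
        for g in five.groups:
            back = ratio.draws[g] * one.draws[g] / 100.0
            assert np.abs(back - five.draws[g]).max() < 1e-10

    def test_grid_mismatch_rejected(self, fitted_pair):
        five, one = fitted_pair
        other = make_curveset(GRID[:10], np.full((five.n_draws, 10), 80.0))
        with pytest.raises(ValueError, match="grid"):
            conditional_ratio(five, other)

    def test_draw_count_mismatch_rejected(self):
        g = np.array([1971.0, 1971.5])
        five = make_curveset(g, np.full((4, 2), 40.0))
        one = make_curveset(g, np.full((5, 2), 80.0))
        with pytest.raises(ValueError, match="draw counts"):
            conditional_ratio(five, one)

    def test_nonpositive_one_year_draws_excluded_and_logged(self, caplog):
        g = np.array([1971.0, 1971.5])
        five = make_curveset(g, np.full((4, 2), 40.0))
        one_draws = np.full((4, 2), 80.0)
        one_draws[2, 1] = -1.0  # this draw cannot form a ratio
        one = make_curveset(g, one_draws)
        with caplog.at_level("WARNING"):
            ratio = conditional_ratio(five, one)
        assert ratio.draws["g"].shape[0] == 3
        assert ratio.provenance["excluded_draws"] == 1
        assert any("excluded 1 draws" in r.message for r in caplog.records)

    def test_metric_label(self, fitted_pair):
        five, one = fitted_pair
        assert conditional_ratio(five, one).metric == "5/1y"

    def test_ratio_derivative_consistency_fd(self, fitted_pair):
        # quotient-rule derivatives vs finite differences of the ratio draws
        five, one = fitted_pair
        ratio = conditional_ratio(five, one)
        g = ratio.groups[0]
        h = ratio.grid[1] - ratio.grid[0]
        fd = (ratio.draws[g][:, 2:] - ratio.draws[g][:, :-2]) / (2 * h)
        assert np.abs(ratio.deriv1[g][:, 1:-1] - fd).max() < 0.05


class TestAnnualChange:
    def test_flat_draws_zero(self):
        cs = make_curveset(GRID, np.full((6, GRID.size), 70.0))
        ac = annual_change(cs)["g"]
        assert np.all(ac["median"] == 0.0)

    def test_linear_draws_constant_slope(self):
        slope = 0.8
        draws = 50 + slope * (GRID - GRID[0])[None, :] * np.ones((6, 1))
        d1 = np.full_like(draws, slope)
        cs = make_curveset(GRID, draws, deriv1=d1)
        ac = annual_change(cs)["g"]
        assert np.allclose(ac["median"], slope)
        assert np.allclose(ac["lo"], slope)

    def test_median_integral_vs_endpoint_difference(self, fitted_pair):
        five, _ = fitted_pair
        g = five.groups[0]
        med_d = np.median(five.deriv1[g], axis=0)
        med_c = np.median(five.draws[g], axis=0)
        integral = np.trapezoid(med_d, five.grid)
        assert abs(integral - (med_c[-1] - med_c[0])) < 0.1

    def test_coarse_grid_rejected(self):
        coarse = np.arange(1971.0, 2020.0, 2.0)
        cs = make_curveset(coarse, np.full((4, coarse.size), 70.0))
        with pytest.raises(ValueError, match="spacing"):
            annual_change(cs)


def _ci_curveset(grid, lo_hi_fn, metric="5y"):
    """Curve set whose deriv1 draws produce a prescribed CI band.

    ``lo_hi_fn(year) -> (lo, hi)``; two draws bracket the band (median at
    the midpoint).
    """
    los = np.array([lo_hi_fn(x)[0] for x in grid])
    his = np.array([lo_hi_fn(x)[1] for x in grid])
    # 41 draws spanning [lo, hi] uniformly: 2.5/97.5 percentiles ~ lo/hi
    qs = np.linspace(0, 1, 41)
    d1 = los[None, :] + qs[:, None] * (his - los)[None, :]
    draws = np.zeros_like(d1) + 70.0
    return make_curveset(grid, draws, deriv1=d1, metric=metric)


class TestPlausibleIntervals:
    def test_long_positive_run_detected(self):
        cs = _ci_curveset(GRID, lambda x: (0.2, 0.6) if 1980 <= x <= 1995 else (-0.5, 0.5))
        spans = plausible_intervals(cs)["g"]
        assert len(spans) == 1
        s, e = spans[0]
        assert s == pytest.approx(1980.0) and e == pytest.approx(1995.0)

    def test_just_below_five_years_excluded(self):
        cs = _ci_curveset(GRID, lambda x: (0.2, 0.6) if 1980 <= x < 1984.75 + 0.01 else (-0.5, 0.5))
        # run spans exactly 4.75 years -> below the 5-year rule
        assert plausible_intervals(cs)["g"] == []

    def test_exactly_five_years_included(self):
        cs = _ci_curveset(GRID, lambda x: (0.2, 0.6) if 1980 <= x <= 1985 else (-0.5, 0.5))
        assert len(plausible_intervals(cs)["g"]) == 1

    def test_sign_change_splits_run(self):
        def band(x):
            if 1980 <= x < 1990:
                return (0.2, 0.6)
            if 1990 <= x <= 2000:
                return (-0.6, -0.2)
            return (-0.5, 0.5)

        cs = _ci_curveset(GRID, band)
        spans = plausible_intervals(cs)["g"]
        assert len(spans) == 2

    def test_empty_is_valid(self):
        cs = _ci_curveset(GRID, lambda x: (-0.5, 0.5))
        assert plausible_intervals(cs)["g"] == []


class TestDetectBreakpoints:
    @staticmethod
    def _d2_curveset(grid, lo_hi_fn, med_fn):
        los = np.array([lo_hi_fn(x)[0] for x in grid])
        his = np.array([lo_hi_fn(x)[1] for x in grid])
        meds = np.array([med_fn(x) for x in grid])
        qs = np.linspace(0, 1, 41)
        base = los[None, :] + qs[:, None] * (his - los)[None, :]
        d2 = base - np.median(base, axis=0) + meds[None, :]
        draws = np.zeros_like(d2) + 70.0
        return make_curveset(grid, draws, deriv2=d2)

    def test_peak_year_and_direction(self):
        cs = self._d2_curveset(
            GRID,
            lambda x: (0.02, 0.06) if 1994 <= x <= 2002 else (-0.05, 0.05),
            lambda x: max(0.0, 0.05 - 0.01 * abs(x - 1998.0)),
        )
        bps = detect_breakpoints(cs)["g"]
        assert len(bps) == 1
        assert bps[0].year == pytest.approx(1998.0)
        assert bps[0].direction == "upward"
        s, e = bps[0].interval
        assert s <= bps[0].year <= e

    def test_short_run_excluded(self):
        cs = self._d2_curveset(
            GRID,
            lambda x: (0.02, 0.06) if 1996 <= x <= 1998.5 else (-0.05, 0.05),
            lambda x: 0.04,
        )
        assert detect_breakpoints(cs)["g"] == []

    def test_time_reversal_symmetry(self):
        def band(x):
            return (0.02, 0.06) if 1990 <= x <= 1996 else (-0.05, 0.05)

        def med(x):
            return max(0.0, 0.05 - 0.02 * abs(x - 1993.0))

        cs = self._d2_curveset(GRID, band, med)
        fw = detect_breakpoints(cs)["g"]
        # reverse in time: mirror the draw matrices around the grid center
        rev = PosteriorCurveSet(
            metric=cs.metric,
            grid=cs.grid,
            draws={"g": cs.draws["g"][:, ::-1]},
            deriv1={"g": -cs.deriv1["g"][:, ::-1]},
            deriv2={"g": cs.deriv2["g"][:, ::-1]},
        )
        bw = detect_breakpoints(rev)["g"]
        c0, c1 = cs.grid[0], cs.grid[-1]
        assert len(fw) == len(bw) == 1
        assert bw[0].year == pytest.approx(c0 + c1 - fw[0].year)
        assert bw[0].direction == fw[0].direction  # d2 sign is preserved under reversal

    def test_downward_direction(self):
        cs = self._d2_curveset(
            GRID,
            lambda x: (-0.06, -0.02) if 1990 <= x <= 1996 else (-0.05, 0.05),
            lambda x: -0.04,
        )
        bps = detect_breakpoints(cs)["g"]
        assert len(bps) == 1 and bps[0].direction == "downward"

    def test_breakpoint_containment_on_fitted_curves(self, fitted_pair):
        five, one = fitted_pair
        for cs in (five, one, conditional_ratio(five, one)):
            for g, bps in detect_breakpoints(cs).items():
                for bp in bps:
                    assert bp.interval[0] <= bp.year <= bp.interval[1]
                    assert bp.interval[1] - bp.interval[0] >= 3.0


class TestExtractFeatures:
    def test_bundles_all_groups(self, fitted_pair):
        five, _ = fitted_pair
        feats = extract_features(five)
        assert sorted(f.group for f in feats) == five.groups
        for f in feats:
            assert f.metric == "5y"
            assert {"year", "median", "lo", "hi"} <= set(f.annual_change.columns)
            for s, e in f.plausible_intervals:
                assert e - s >= 5.0

    def test_derivative_fd_consistency(self, fitted_pair):
        # analytic first derivative vs central finite differences (h=0.01)
        five, _ = fitted_pair
        g = five.groups[0]
        x = five.grid[5:-5:10]
        h = 0.01
        fd = (five.curve_at(g, x + h) - five.curve_at(g, x - h)) / (2 * h)
        an = five.deriv1_at(g, x)
        assert np.abs(an - fd).max() < 1e-6
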