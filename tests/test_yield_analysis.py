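"""Yield-loss statistics, correlations and ratio-threshold regressions."""

import numpy as np
import pytest
from hypothesis import given, settings
from hypothesis import strategies as st

from wheatdyn import datasets
from wheatdyn.yield_analysis import (
    RatioPoint,
    YieldAnalysisError,
    fit_ratio_regression,
    loss_per_day_regression,
    pct_advantage,
    pearson_r,
    productive_tiller_pct,
    significance_stars,
    threshold_from_lines,
    yield_loss,
)


@pytest.fixture(scope="module")
def season_yields():
    ydf = datasets.yield_components()
    return {
        season: dict(zip(grp.sowing_label, grp.grain_yield))
        for season, grp in ydf.groupby("season")
    }


class TestYieldLoss:
    def test_published_treatment_pair(self):
        assert yield_loss(6578.9, 5674.8) == pytest.approx(13.74, abs=0.005)

    def test_no_change_is_zero(self):
        assert yield_loss(5000.0, 5000.0) == 0.0

    def test_gain_is_negative_loss(self):
        assert yield_loss(100.0, 120.0) == pytest.approx(-20.0)

    def test_nonpositive_reference_rejected(self):
        with pytest.raises(YieldAnalysisError):
            yield_loss(0.0, 100.0)

    @settings(max_examples=100, deadline=None, derandomize=True)
    @given(
        st.floats(100.0, 10000.0),
        st.floats(100.0, 10000.0),
        st.floats(0.01, 100.0),
    )
    def test_scale_invariance(self, y_ns, y, c):
        assert yield_loss(c * y_ns, c * y) == pytest.approx(yield_loss(y_ns, y), rel=1e-9)


class TestPctAdvantage:
    def test_normal_vs_latest_sowing(self, season_yields):
        a = {s: m["5-Nov"] for s, m in season_yields.items()}
        b = {s: m["21-Nov"] for s, m in season_yields.items()}
        assert pct_advantage(a, b) == pytest.approx(23.4, abs=0.05)

    def test_normal_vs_earliest_sowing(self, season_yields):
        a = {s: m["5-Nov"] for s, m in season_yields.items()}
        b = {s: m["28-Oct"] for s, m in season_yields.items()}
        assert pct_advantage(a, b) == pytest.approx(3.2, abs=0.05)

    def test_self_advantage_is_zero(self, season_yields):
        a = {s: m["5-Nov"] for s, m in season_yields.items()}
        assert pct_advantage(a, a) == 0.0

    def test_mismatched_seasons_rejected(self):
        with pytest.raises(YieldAnalysisError):
            pct_advantage({"a": 1.0}, {"b": 1.0})


class TestPearson:
    def test_filling_days_vs_filling_temperature(self):
        g2 = datasets.growth_time_summary().query("season == '2019-2020'")
        r, p = pearson_r(g2.filling_days.tolist(), g2.mean_filling_temp.tolist())
        assert r == pytest.approx(-0.94, abs=0.005)

    def test_spike_number_vs_grain_yield(self):
        ydf = datasets.yield_components()
        r, p = pearson_r(ydf.spike_number.tolist(), ydf.grain_yield.tolist())
        assert r == pytest.approx(0.73, abs=0.005)
        assert p < 0.05

    def test_perfect_linear_relation(self):
        x = [1.0, 2.0, 3.0, 4.0]
        r, p = pearson_r(x, [2 * v + 1 for v in x])
        assert r == pytest.approx(1.0)

    def test_zero_variance_rejected(self):
        with pytest.raises(YieldAnalysisError):
            pearson_r([1.0, 1.0, 1.0], [1.0, 2.0, 3.0])

    @settings(max_examples=100, deadline=None, derandomize=True)
    @given(st.floats(0.1, 10.0), st.floats(-5.0, 5.0))
    def test_affine_invariance(self, scale, shift):
        x = [1.0, 2.5, 3.0, 4.7, 6.0]
        y = [2.0, 1.0, 4.0, 3.5, 5.0]
        r0, _ = pearson_r(x, y)
        r1, _ = pearson_r([scale * v + shift for v in x], y)
        assert abs(r1) <= 1.0 + 1e-12
        assert r1 == pytest.approx(r0, rel=1e-9)


class TestLossPerDay:
    """Frozen closed-form OLS oracle values from the published yield means."""

    def test_through_origin_first_season(self, season_yields):
        offsets = {k: v - 8 for k, v in datasets.SOWING_OFFSETS.items()}
        est = loss_per_day_regression(
            {"2018-2019": season_yields["2018-2019"]}, offsets, "5-Nov", "through_origin"
        )
        assert est.slope == pytest.approx(0.98, abs=0.005)

    def test_pooled_ols_both_seasons(self, season_yields):
        offsets = {k: v - 8 for k, v in datasets.SOWING_OFFSETS.items()}
        est = loss_per_day_regression(season_yields, offsets, "5-Nov", "pooled_ols")
        assert est.slope == pytest.approx(1.18, abs=0.005)
        # agrees with the closed-form normal-equation oracle
        xs, ys = [], []
        for season, by_label in season_yields.items():
            for lab, y in by_label.items():
                xs.append(abs(offsets[lab]))
                ys.append(yield_loss(by_label["5-Nov"], y))
        x, y = np.array(xs), np.array(ys)
        slope = ((x - x.mean()) * (y - y.mean())).sum() / ((x - x.mean()) ** 2).sum()
        assert est.slope == pytest.approx(slope, abs=1e-10)

    def test_all_zero_losses_give_zero_slope(self):
        yields = {"s": {"a": 5000.0, "b": 5000.0, "c": 5000.0}}
        offsets = {"a": 0.0, "b": 8.0, "c": 16.0}
        for method in ("pooled_ols", "through_origin"):
            assert loss_per_day_regression(yields, offsets, "a", method).slope == pytest.approx(0.0)

    def test_all_methods_labelled_and_distinct(self, season_yields):
        offsets = {k: v - 8 for k, v in datasets.SOWING_OFFSETS.items()}
        methods = ("pooled_ols", "per_season_ols_mean", "through_origin")
        out = {
            m: loss_per_day_regression(season_yields, offsets, "5-Nov", m) for m in methods
        }
        assert {e.method for e in out.values()} == set(methods)
        assert all(np.isfinite(e.slope) for e in out.values())

    def test_too_few_sowing_dates_rejected(self):
        with pytest.raises(YieldAnalysisError):
            loss_per_day_regression({"s": {"a": 1.0, "b": 2.0}}, {"a": 0, "b": 8}, "a")


class TestRatioRegression:
    def test_published_dma_lines_solve_to_4_06(self):
        mean_thr, per = threshold_from_lines(datasets.ratio_regression_lines("dma"), 6000.0)
        assert per["2018-2019"] == pytest.approx(4.863, abs=0.001)
        assert per["2019-2020"] == pytest.approx(3.259, abs=0.001)
        assert mean_thr == pytest.approx(4.06, abs=0.005)

    def test_published_na_lines_solve_to_2_49(self):
        mean_thr, per = threshold_from_lines(datasets.ratio_regression_lines("na"), 6000.0)
        assert per["2018-2019"] == pytest.approx(2.998, abs=0.001)
        assert per["2019-2020"] == pytest.approx(1.974, abs=0.001)
        assert mean_thr == pytest.approx(2.49, abs=0.005)

    def test_points_on_line_through_target(self):
        ratio_star = 4.2
        points = [
            RatioPoint("s", str(i), ratio_star + d, 6000.0 + 500.0 * d)
            for i, d in enumerate([-1.0, -0.5, 0.5, 1.0])
        ]
        res = fit_ratio_regression(points, target=6000.0)
        assert res.threshold_ratio == pytest.approx(ratio_star, rel=1e-9)

    def test_noise_free_recovery_of_generating_line(self):
        rng = np.random.default_rng(9)
        slope, intercept = 420.0, 4100.0
        for sd, tol in ((0.0, 1e-9), (30.0, 25.0)):
            points = []
            for season in ("A", "B"):
                ratios = rng.uniform(3.0, 6.5, 6)
                for i, x in enumerate(ratios):
                    y = slope * x + intercept + rng.normal(0, sd)
                    points.append(RatioPoint(season, str(i), float(x), float(y)))
            res = fit_ratio_regression(points, target=6000.0)
            for line in res.lines:
                assert line.slope == pytest.approx(slope, abs=max(tol, 1e-6))

    def test_zero_slope_threshold_rejected(self):
        with pytest.raises(YieldAnalysisError):
            threshold_from_lines({"s": (0.0, 5000.0)}, 6000.0)


class TestProductiveTillers:
    def test_direct_ratio(self):
        assert productive_tiller_pct(785.33, 444.00) == pytest.approx(56.54, abs=0.01)

    def test_all_tillers_productive(self):
        assert productive_tiller_pct(600.0, 600.0) == 100.0

    def test_none_productive(self):
        assert productive_tiller_pct(600.0, 0.0) == 0.0

    def test_zero_peak_rejected(self):
        with pytest.raises(YieldAnalysisError):
            productive_tiller_pct(0.0, 0.0)


def test_significance_stars_two_tier():
    assert significance_stars(0.005) == "**"
    assert significance_stars(0.02) == "*"
    assert significance_stars(0.2) == ""
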