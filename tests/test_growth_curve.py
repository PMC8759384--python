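"""Logistic curve evaluation, eigenvalue derivation and fitting."""

import math

import numpy as np
import pytest
from hypothesis import given, settings
from hypothesis import strategies as st

from wheatdyn.growth_curve import (
    FAST_PHASE_HALF_LOG,
    ROOT3,
    GrowthSeries,
    InitializationError,
    InsufficientDataError,
    InvalidParameterError,
    LogisticParams,
    UndefinedPhaseError,
    UndefinedRSquaredError,
    eigenvalues,
    fit_logistic,
    init_guess,
    logistic_value,
    r_squared,
)

REFERENCE_DMA = LogisticParams(3.6217, 4101240.31, 0.0976)


def series_from(params, t, noise=None):
    w = logistic_value(params, np.asarray(t, dtype=float))
    if noise is not None:
        w = w * np.exp(noise)
    return GrowthSeries("s", "x", "dma", "g_per_stem", np.asarray(t, float), w)


def params_strategy():
    return st.builds(
        lambda w, k, tm: LogisticParams(w, math.exp(k * tm), k),
        st.floats(0.1, 100.0),
        st.floats(0.051, 0.149),
        st.floats(10.0, 300.0),
    )


class TestLogisticValue:
    def test_half_asymptote_at_inflection(self):
        tm = math.log(REFERENCE_DMA.a) / REFERENCE_DMA.k
        assert logistic_value(REFERENCE_DMA, tm) == pytest.approx(
            REFERENCE_DMA.w_max / 2, rel=1e-12
        )

    def test_asymptote(self):
        assert logistic_value(REFERENCE_DMA, 1e6) == pytest.approx(3.6217, rel=1e-12)

    def test_value_at_phase_onset_is_wmax_over_3_plus_root3(self):
        # at T1 the shape factor a*exp(-k*T1) equals 2+sqrt(3) exactly
        ev = eigenvalues(REFERENCE_DMA)
        assert logistic_value(REFERENCE_DMA, ev.t1) == pytest.approx(
            REFERENCE_DMA.w_max / (3 + ROOT3), rel=1e-10
        )
        assert logistic_value(REFERENCE_DMA, 142.5) == pytest.approx(0.7655, abs=2e-3)

    def test_invalid_parameters_rejected(self):
        with pytest.raises(InvalidParameterError):
            LogisticParams(-1.0, 2.0, 0.1)
        with pytest.raises(InvalidParameterError):
            LogisticParams(1.0, 2.0, 0.0)
        with pytest.raises(InvalidParameterError):
            LogisticParams(1.0, float("nan"), 0.1)

    @settings(max_examples=100, deadline=None, derandomize=True)
    @given(params_strategy(), st.floats(0.0, 80.0))
    def test_symmetry_about_inflection(self, params, delta):
        ev = eigenvalues(params)
        total = logistic_value(params, ev.tm + delta) + logistic_value(params, ev.tm - delta)
        assert total == pytest.approx(params.w_max, rel=1e-9)


class TestEigenvalues:
    @pytest.mark.parametrize(
        "params, expected",
        [
            # published DMA row: t1, t2, duration, vt, tm, vm
            (REFERENCE_DMA, (142.5, 169.5, 27.0, 0.08, 156.0, 0.09)),
            # published NA row for the latest sowing date
            (LogisticParams(50.2932, 3464573.17, 0.1109), (123.9, 147.7, 23.8, 1.22, 135.8, 1.39)),
        ],
    )
    def test_reproduces_published_rows(self, params, expected):
        ev = eigenvalues(params)
        t1, t2, dur, vt, tm, vm = expected
        assert ev.t1 == pytest.approx(t1, abs=0.15)
        assert ev.t2 == pytest.approx(t2, abs=0.15)
        assert ev.duration == pytest.approx(dur, abs=0.15)
        assert ev.tm == pytest.approx(tm, abs=0.15)
        assert ev.vt == pytest.approx(vt, abs=0.015)
        assert ev.vm == pytest.approx(vm, abs=0.015)

    def test_symmetric_unit_curve_centred_at_zero(self):
        ev = eigenvalues(LogisticParams(1.0, 1.0, 1.0))
        assert ev.tm == 0.0
        assert ev.t1 == pytest.approx(-math.log(2 + ROOT3), rel=1e-12)
        assert ev.t2 == pytest.approx(math.log(2 + ROOT3), rel=1e-12)
        assert ev.vm == 0.25

    def test_degenerate_shape_constant_rejected(self):
        with pytest.raises(UndefinedPhaseError):
            eigenvalues(LogisticParams(1.0, 0.2, 0.1))

    @settings(max_examples=200, deadline=None, derandomize=True)
    @given(params_strategy())
    def test_algebraic_invariants(self, params):
        ev = eigenvalues(params)
        assert ev.t1 < ev.tm < ev.t2
        assert ev.duration * params.k == pytest.approx(2 * FAST_PHASE_HALF_LOG, rel=1e-12)
        # phase rise is w_max/sqrt(3); mean-to-peak rate ratio is universal
        assert ev.vt * ev.duration == pytest.approx(params.w_max / ROOT3, rel=1e-12)
        assert ev.vm / ev.vt == pytest.approx(ROOT3 / 2 * FAST_PHASE_HALF_LOG, rel=1e-12)
        assert ev.w1 < params.w_max / 2 < ev.w2 < params.w_max
        assert ev.vm >= ev.vt > 0


class TestInitGuess:
    def test_linearization_lands_near_truth(self):
        truth = LogisticParams(3.6, 1e6, 0.1)
        s = series_from(truth, [60.0, 120.0, 150.0, 180.0, 200.0])
        p0 = init_guess(s)
        # the 5% asymptote inflation biases the linearisation; the guess
        # only needs to land in the fit's basin of attraction
        assert abs(p0.k / truth.k - 1) < 0.25
        tm0 = math.log(p0.a) / p0.k
        tm_true = math.log(truth.a) / truth.k
        assert abs(tm0 / tm_true - 1) < 0.10

    def test_degenerate_flat_series_rejected(self):
        s = GrowthSeries("s", "x", "dma", "g_per_stem", [1.0, 2.0, 3.0], [2.0, 2.0, 2.0])
        with pytest.raises(InitializationError):
            init_guess(s)

    def test_two_point_series_solves_exactly(self):
        truth = LogisticParams(3.0, 5e4, 0.08)
        t = np.array([100.0, 140.0])
        w = logistic_value(truth, t)
        s = GrowthSeries("s", "x", "dma", "g_per_stem", t, w)
        p0 = init_guess(s)
        # independent 2x2 solve of ln(w_max0/w - 1) = ln a - k t
        w_max0 = 1.05 * w.max()
        y = np.log(w_max0 / w - 1)
        k_exp = -(y[1] - y[0]) / (t[1] - t[0])
        a_exp = math.exp(y[0] + k_exp * t[0])
        assert p0.k == pytest.approx(k_exp, rel=1e-9)
        assert p0.a == pytest.approx(a_exp, rel=1e-9)


class TestFitLogistic:
    def test_noiseless_recovery_is_exact(self):
        truth = LogisticParams(3.1812, 109524.11, 0.0862)
        s = series_from(truth, [20.0, 60.0, 100.0, 130.0, 160.0, 190.0])
        fit = fit_logistic(s)
        assert fit.converged
        assert fit.params.w_max == pytest.approx(truth.w_max, rel=1e-6)
        assert fit.params.a == pytest.approx(truth.a, rel=1e-4)
        assert fit.params.k == pytest.approx(truth.k, rel=1e-6)
        assert fit.r_squared == pytest.approx(1.0, abs=1e-12)

    def test_insufficient_points_rejected(self):
        truth = LogisticParams(3.0, 1e5, 0.09)
        s = series_from(truth, [50.0, 120.0, 160.0])
        with pytest.raises(InsufficientDataError):
            fit_logistic(s)

    def test_replicates_are_averaged_before_fitting(self):
        truth = LogisticParams(3.0, 1e5, 0.09)
        t = np.array([50.0, 50.0, 120.0, 120.0, 150.0, 150.0, 180.0, 180.0])
        w = logistic_value(truth, t) * np.array([0.9, 1.1, 0.95, 1.05, 1.02, 0.98, 1.0, 1.0])
        s = GrowthSeries("s", "x", "dma", "g_per_stem", t, w)
        fit = fit_logistic(s)
        assert fit.n_points == 4  # four distinct times after averaging

    def test_fitted_eigenvalues_match_numeric_roots(self):
        """Eigenvalues of a fitted curve agree with bisection on its derivatives."""
        import sympy as sp
        from scipy.optimize import brentq

        rng = np.random.default_rng(11)
        truth = LogisticParams(3.5, 2e5, 0.085)
        noise = rng.normal(0, 0.05, 6)
        s = series_from(truth, [15.0, 40.0, 110.0, 140.0, 165.0, 200.0], noise)
        fit = fit_logistic(s)
        ev = eigenvalues(fit.params)

        t_s, w_s, a_s, k_s = sp.symbols("t w a k", positive=True)
        W = w_s / (1 + a_s * sp.exp(-k_s * t_s))
        args = (fit.params.w_max, fit.params.a, fit.params.k)
        f2 = sp.lambdify(t_s, sp.diff(W, t_s, 2).subs(dict(zip((w_s, a_s, k_s), args))))
        f3 = sp.lambdify(t_s, sp.diff(W, t_s, 3).subs(dict(zip((w_s, a_s, k_s), args))))
        grid = np.linspace(0.0, 400.0, 801)
        for fn, expected in ((f2, [ev.tm]), (f3, [ev.t1, ev.t2])):
            y = fn(grid)
            idx = np.nonzero(np.diff(np.sign(y)) != 0)[0]
            roots = [brentq(fn, grid[i], grid[i + 1], xtol=1e-12) for i in idx]
            assert len(roots) == len(expected)
            for r, e in zip(roots, expected):
                assert r == pytest.approx(e, abs=1e-6)


class TestRSquared:
    def test_perfect_fit_is_one(self):
        truth = LogisticParams(3.0, 1e5, 0.09)
        s = series_from(truth, [40.0, 100.0, 140.0, 180.0])
        fit = fit_logistic(s)
        assert r_squared(fit, s) == pytest.approx(1.0, abs=1e-12)

    def test_matches_direct_sse_sst_recomputation(self):
        rng = np.random.default_rng(3)
        truth = LogisticParams(3.0, 1e5, 0.09)
        t = np.array([30.0, 70.0, 110.0, 140.0, 170.0, 200.0])
        w = logistic_value(truth, t) * np.exp(rng.normal(0, 0.08, t.size))
        s = GrowthSeries("s", "x", "dma", "g_per_stem", t, w)
        fit = fit_logistic(s)
        fitted = logistic_value(fit.params, t)
        expected = 1 - np.sum((w - fitted) ** 2) / np.sum((w - w.mean()) ** 2)
        assert r_squared(fit, s) == pytest.approx(expected, abs=1e-12)

    def test_zero_variance_rejected(self):
        truth = LogisticParams(3.0, 1e5, 0.09)
        fit = fit_logistic(series_from(truth, [40.0, 100.0, 140.0, 180.0]))
        flat = GrowthSeries("s", "x", "dma", "g_per_stem", [1.0, 2.0, 3.0], [2.0, 2.0, 2.0])
        with pytest.raises(UndefinedRSquaredError):
            r_squared(fit, flat)


class TestGrowthSeriesValidation:
    def test_negative_values_rejected(self):
        with pytest.raises(Exception):
            GrowthSeries("s", "x", "dma", "g_per_stem", [1.0, 2.0], [-0.5, 1.0])

    def test_unknown_variable_rejected(self):
        with pytest.raises(Exception):
            GrowthSeries("s", "x", "biomass", "g_per_stem", [1.0, 2.0], [0.5, 1.0])
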