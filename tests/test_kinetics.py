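"""Reaction-order fits: closed-form oracles, paper transforms, monotone trends."""

import numpy as np
import pytest
from hypothesis import given
from hypothesis import strategies as st

from photokin import (
    CatalystRecord,
    DegradationSeries,
    ValidationError,
    fit_first_order,
    fit_modified,
    fit_pseudo_n_order,
    intrinsic_rate,
    log_ratio_transform,
    predict_ratio,
)
from photokin.kinetics import FIRST_ORDER_METHODS, NonDecayingWarning, degradation_percent

GRID = np.array([0, 10, 20, 30, 60, 90, 120, 180.0])


def exp_series(k1=0.01, label="exp", x=0.0):
    return DegradationSeries(label, x, GRID, np.exp(-k1 * GRID))


class TestLogRatioTransform:
    def test_matches_printed_transform_values(self, table2):
        by_x = {s.x: s for s in table2}
        out = log_ratio_transform(by_x[0.5])
        assert out[-1][1] == pytest.approx(-2.1832, abs=5e-5)  # ln(0.11268)
        out0 = log_ratio_transform(by_x[0.0])
        # the printed -0.15879 is one last-digit unit above ln(0.85318)
        assert out0[-1][1] == pytest.approx(-0.15879, abs=1e-5)
        assert out0[0][1] == 0.0  # ln(1)


class TestFirstOrder:
    @pytest.mark.parametrize("method", FIRST_ORDER_METHODS)
    def test_exact_law_recovered_by_every_method(self, method):
        fit = fit_first_order(exp_series(0.01), method)
        assert fit.k1 == pytest.approx(0.01, rel=1e-10)
        assert fit.correlation == pytest.approx(1.0)

    def test_through_origin_matches_closed_form_on_fixture(self, table2):
        s = table2[0]
        t, y = s.times, np.log(s.ratios)
        oracle = -sum(ti * yi for ti, yi in zip(t, y)) / sum(ti * ti for ti in t)
        assert fit_first_order(s, "through_origin").k1 == pytest.approx(
            oracle, rel=1e-14
        )

    @given(
        k=st.floats(1e-4, 0.05),
        noise=st.lists(st.floats(-0.05, 0.05), min_size=7, max_size=7),
    )
    def test_through_origin_equals_oracle_on_random_series(self, k, noise):
        ratios = np.exp(-k * GRID[1:] + np.array(noise))
        ratios = np.concatenate([[1.0], np.clip(ratios, 1e-6, 1.0)])
        s = DegradationSeries("h", 0.0, GRID, ratios)
        t, y = s.times, s.log_ratios()
        oracle = -float(np.dot(t, y) / np.dot(t, t))
        fit = fit_first_order(s, "through_origin")
        assert fit.k1 == pytest.approx(oracle, rel=1e-12, abs=1e-15)

    def test_non_decaying_series_warns_not_raises(self):
        flat = DegradationSeries("flat", 0.0, GRID, np.ones_like(GRID))
        with pytest.warns(NonDecayingWarning):
            fit = fit_first_order(flat)
        assert fit.k1 <= 0

    def test_unknown_method_rejected(self):
        with pytest.raises(ValidationError):
            fit_first_order(exp_series(), "total_least_squares")


class TestDegradationPercent:
    def test_fixture_values(self, table2):
        by_x = {s.x: degradation_percent(s) for s in table2}
        assert by_x[0.5] == pytest.approx(88.73, abs=5e-3)
        assert by_x[0.2] == pytest.approx(37.62, abs=5e-3)

    def test_no_decay_gives_zero(self):
        flat = DegradationSeries("flat", 0.0, GRID, np.ones_like(GRID))
        assert degradation_percent(flat) == 0.0


class TestIntrinsicRate:
    def test_identity_point(self):
        rec = CatalystRecord(x=0.0, surface_area=1.0)
        assert intrinsic_rate(1.0, rec, catalyst_load=1.0, volume=1.0) == 1.0

    def test_doubled_area_halves_rate(self):
        r1 = intrinsic_rate(0.01, CatalystRecord(x=0.0, surface_area=50.0))
        r2 = intrinsic_rate(0.01, CatalystRecord(x=0.0, surface_area=100.0))
        assert r1 == pytest.approx(2 * r2)

    def test_ln_intrinsic_rate_increases_with_x_on_fixtures(self, table1, table3):
        # printed rate constants over printed areas: the area drop does not
        # reverse the trend, so the per-m2 rate still rises with doping
        areas = {r.x: r.surface_area for r in table1}
        lnk = [
            np.log(intrinsic_rate(table3.k1[x], CatalystRecord(x=x, surface_area=areas[x])))
            for x in sorted(areas)
        ]
        assert np.all(np.diff(lnk) > 0)


class TestPseudoNOrder:
    def test_recovers_generating_parameters(self):
        truth_n, truth_kn = 2.0, 0.005
        ratios = ((truth_n - 1) * truth_kn * GRID + 1) ** (-1 / (truth_n - 1))
        s = DegradationSeries("n2", 0.0, GRID, ratios)
        fit = fit_pseudo_n_order(s)
        assert fit.n == pytest.approx(truth_n, abs=1e-6)
        assert fit.kn_single() == pytest.approx(truth_kn, abs=1e-6)
        assert fit.converged and not fit.at_lower_bound

    def test_first_order_data_drives_n_to_one(self):
        fit = fit_pseudo_n_order(exp_series(0.01))
        pred = predict_ratio(
            "n_order", {"n": max(fit.n, 1 + 1e-9), "kn": fit.kn_single()}, GRID
        )
        assert np.max(np.abs(pred - np.exp(-0.01 * GRID))) < 1e-4
        assert fit.at_lower_bound

    def test_too_few_points_rejected(self):
        s = DegradationSeries("short", 0.0, [0, 10, 20], [1.0, 0.9, 0.8])
        with pytest.raises(ValidationError):
            fit_pseudo_n_order(s)


class TestModifiedFit:
    def test_exact_recovery_from_generating_law(self):
        a1, a2 = 0.01, 1e-5
        s = DegradationSeries("mod", 0.0, GRID, np.exp(-a1 * GRID + a2 * GRID**2))
        fit = fit_modified(s)
        assert fit.a1 == pytest.approx(a1, abs=1e-12)
        assert fit.a2 == pytest.approx(a2, abs=1e-12)
        assert fit.alpha == fit.a2 / fit.a1

    def test_matches_independent_normal_equation_oracle(self, table2):
        # solve the same least-squares problem by generic dense linear algebra
        for s in table2:
            t, y = s.times, s.log_ratios()
            X = np.column_stack([-t, t**2])
            coef = np.linalg.solve(X.T @ X, X.T @ y)
            fit = fit_modified(s)
            assert fit.a1 == pytest.approx(coef[0], rel=1e-9)
            assert fit.a2 == pytest.approx(coef[1], rel=1e-9)

    def test_degenerates_to_first_order_on_exponential_data(self):
        fit = fit_modified(exp_series(0.01))
        assert abs(fit.a2) < 1e-10
        assert fit.a1 == pytest.approx(0.01, rel=1e-8)


class TestPredictRatio:
    def test_zero_rate_is_identity(self):
        assert np.all(predict_ratio("first_order", {"k1": 0.0}, [0, 50, 100]) == 1.0)

    def test_modified_reduces_to_exponential(self):
        out = predict_ratio("modified", {"a1": 0.01, "a2": 0.0}, [100.0])
        assert out[0] == pytest.approx(np.exp(-1.0))

    def test_n_order_closed_form_value(self):
        out = predict_ratio("n_order", {"n": 2.0, "kn": 0.005}, [200.0])
        assert out[0] == pytest.approx(0.5)  # 1/(1 + 0.005*200)

    def test_every_law_starts_at_one(self):
        for model, params in [
            ("first_order", {"k1": 0.01}),
            ("n_order", {"n": 1.5, "kn": 0.01}),
            ("modified", {"a1": 0.01, "a2": 1e-5}),
            ("intradiffusion", {"kd": 0.1}),
        ]:
            assert predict_ratio(model, params, [0.0])[0] == 1.0

    def test_unknown_model_rejected(self):
        with pytest.raises(ValidationError):
            predict_ratio("zeroth_order", {"k": 1.0}, [0.0])

    @pytest.mark.parametrize("n", [1 + 1e-4, 1 - 1e-4])
    def test_n_order_limit_approaches_exponential(self, n):
        t = np.linspace(0, 180, 50)
        pred = predict_ratio("n_order", {"n": n, "kn": 0.01}, t)
        assert np.max(np.abs(pred - np.exp(-0.01 * t))) <= 1e-3


class TestFixtureTrends:
    @pytest.mark.parametrize("method", FIRST_ORDER_METHODS)
    def test_k1_strictly_increases_with_doping(self, table2, method):
        k1 = [fit_first_order(s, method).k1 for s in table2]
        assert np.all(np.diff(k1) > 0)

    def test_a1_and_degradation_strictly_increase_with_doping(self, table2):
        a1 = [fit_modified(s).a1 for s in table2]
        dp = [degradation_percent(s) for s in table2]
        assert np.all(np.diff(a1) > 0)
        assert np.all(np.diff(dp) > 0)
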