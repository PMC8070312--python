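"""Sqrt-t kinetics, the tau/Kd duality, tau(x) domains and segmentation."""

from itertools import combinations

import numpy as np
import pytest
from hypothesis import given
from hypothesis import strategies as st

from photokin import (
    DegradationSeries,
    ValidationError,
    fit_intradiffusion,
    fit_tau_exponential,
    kd_from_tau,
    kd_x_predict,
    segment_domains,
    tau_from_kd,
)
from photokin.data import PhotokinWarning
from photokin.diffusion import ExtrapolationWarning
from photokin.simulate import simulate_tau_profile

GRID = np.array([0, 10, 20, 30, 60, 90, 120, 180.0])


class TestIntraDiffusionFit:
    def test_exact_sqrt_law(self):
        s = DegradationSeries("sq", 0.0, GRID, np.exp(-0.1 * np.sqrt(GRID)))
        fit = fit_intradiffusion(s)
        assert fit.kd == pytest.approx(0.1, rel=1e-12)
        assert fit.tau == pytest.approx(100.0, rel=1e-12)
        assert fit.correlation == pytest.approx(1.0)

    def test_matches_closed_form_oracle_on_fixture(self, table2):
        s = table2[0]
        t, y = s.times, np.log(s.ratios)
        oracle = -sum(np.sqrt(ti) * yi for ti, yi in zip(t, y)) / sum(t)
        assert fit_intradiffusion(s).kd == pytest.approx(oracle, rel=1e-14)

    def test_kd_increases_and_tau_decreases_with_doping(self, table2):
        fits = [fit_intradiffusion(s) for s in table2]
        assert np.all(np.diff([f.kd for f in fits]) > 0)
        assert np.all(np.diff([f.tau for f in fits]) < 0)


class TestTauKdDuality:
    def test_printed_value_pair(self):
        assert tau_from_kd(0.011922) == pytest.approx(7035.6, abs=0.05)
        assert kd_from_tau(7035.6) == pytest.approx(0.011922, abs=5e-7)

    def test_identity_points(self):
        assert tau_from_kd(1.0) == 1.0
        assert kd_from_tau(4.0) == 0.5

    @pytest.mark.parametrize("func", [tau_from_kd, kd_from_tau])
    @pytest.mark.parametrize("bad", [0.0, -1.0])
    def test_nonpositive_argument_rejected(self, func, bad):
        with pytest.raises(ValidationError):
            func(bad)

    @given(st.floats(1e-6, 1e6))
    def test_mutually_inverse(self, kd):
        assert kd_from_tau(tau_from_kd(kd)) == pytest.approx(kd, rel=1e-12)
        tau = tau_from_kd(kd)
        assert tau * kd * kd == pytest.approx(1.0, rel=1e-12)


class TestTauExponentialModel:
    def test_exact_recovery_single_domain(self):
        tau0, theta, x0 = 5000.0, 10.0, 0.05
        xs = [0.0, 0.1, 0.2, 0.3, 0.4, 0.5]
        pts = simulate_tau_profile(tau0, [(0.0, 0.5, theta, x0)], xs)
        model = fit_tau_exponential(pts, tau0=tau0, boundaries=())
        seg = model.segments[0]
        assert seg.theta == pytest.approx(theta, abs=1e-10)
        assert seg.x0 == pytest.approx(x0, abs=1e-10)

    def test_constant_profile_flagged_non_decaying(self):
        pts = [(x, 7035.6) for x in (0.0, 0.1, 0.2, 0.3)]
        with pytest.warns(PhotokinWarning, match="not decaying"):
            model = fit_tau_exponential(pts, boundaries=())
        assert model.segments[0].theta == pytest.approx(0.0, abs=1e-12)
        assert not model.segments[0].decaying

    def test_sparse_domain_raises_naming_segment(self):
        pts = [(0.0, 5000.0), (0.05, 4500.0), (0.5, 100.0)]
        with pytest.raises(ValidationError, match=r"domain \[0.2"):
            fit_tau_exponential(pts, boundaries=(0.2,))

    def test_fixture_taus_fit_three_decaying_domains(self, table2):
        pts = [(s.x, fit_intradiffusion(s).tau) for s in table2]
        model = fit_tau_exponential(pts)
        assert len(model.segments) == 3
        assert all(seg.theta > 0 for seg in model.segments)
        # quasi-linearity of ln(tau/tau0) within each domain
        assert all(seg.correlation > 0.9 for seg in model.segments)


class TestKdPrediction:
    def test_printed_tau0_gives_printed_kd0(self):
        pts = [(0.0, 7035.6), (0.25, 1000.0), (0.5, 100.0)]
        model = fit_tau_exponential(pts, tau0=7035.6, boundaries=())
        x0 = model.segments[0].x0
        assert kd_x_predict(model, x0) == pytest.approx(0.011922, abs=5e-7)

    def test_flat_model_predicts_constant_kd(self):
        pts = [(x, 500.0) for x in (0.0, 0.2, 0.4)]
        with pytest.warns(PhotokinWarning):
            model = fit_tau_exponential(pts, tau0=500.0, boundaries=())
        for x in (0.0, 0.2, 0.4):
            assert kd_x_predict(model, x) == pytest.approx(kd_from_tau(500.0))

    @given(
        theta=st.floats(0.1, 20.0),
        x0=st.floats(-0.2, 0.2),
        x=st.floats(0.0, 0.5),
        tau0=st.floats(10.0, 1e5),
    )
    def test_kd_prediction_equals_tau_route(self, theta, x0, x, tau0):
        xs = [0.0, 0.25, 0.5]
        pts = simulate_tau_profile(tau0, [(0.0, 0.5, theta, x0)], xs)
        model = fit_tau_exponential(pts, tau0=tau0, boundaries=())
        direct = kd_x_predict(model, x)
        via_tau = kd_from_tau(model.predict_tau(x))
        assert direct == pytest.approx(via_tau, rel=1e-12)

    def test_extrapolation_warns(self):
        pts = [(0.0, 5000.0), (0.2, 1000.0), (0.4, 200.0)]
        model = fit_tau_exponential(pts, boundaries=())
        with pytest.warns(ExtrapolationWarning):
            kd_x_predict(model, 0.45)


def brute_force_segmentation(points, n_breakpoints=2, min_points=2):
    """Independent exhaustive oracle: try every cut combination directly."""
    pts = sorted(points)
    xs = np.array([p[0] for p in pts])
    ys = np.array([p[1] for p in pts])
    n = len(pts)
    best = (np.inf, None)
    for cuts in combinations(range(1, n), n_breakpoints):
        bounds = (0,) + cuts + (n,)
        if any(b - a < min_points for a, b in zip(bounds[:-1], bounds[1:])):
            continue
        sse = 0.0
        for a, b in zip(bounds[:-1], bounds[1:]):
            coef = np.polyfit(xs[a:b], ys[a:b], 1)
            sse += float(np.sum((ys[a:b] - np.polyval(coef, xs[a:b])) ** 2))
        if sse < best[0]:
            best = (sse, cuts)
    return best


class TestSegmentation:
    def test_recovers_exact_piecewise_breaks(self):
        # 8 points; kinks placed between observed x so midpoints hit 0.2, 0.3
        xs = np.array([0.05, 0.1, 0.15, 0.25, 0.3, 0.35, 0.45, 0.55])
        ys = np.where(xs < 0.2, 2 * xs, np.where(xs < 0.3 + 0.05, 1.0 - 3 * xs, 5 * xs - 2))
        seg = segment_domains(list(zip(xs, ys)))
        assert seg.breakpoints == (pytest.approx(0.2), pytest.approx(0.325))
        assert seg.total_sse == pytest.approx(0.0, abs=1e-20)

    def test_matches_brute_force_oracle_on_random_inputs(self, rng):
        for _ in range(20):
            xs = np.sort(rng.uniform(0, 1, size=8))
            ys = rng.normal(size=8)
            pts = list(zip(xs, ys))
            seg = segment_domains(pts)
            oracle_sse, _ = brute_force_segmentation(pts)
            assert seg.total_sse == pytest.approx(oracle_sse, rel=1e-9, abs=1e-12)

    def test_never_worse_than_single_global_line(self, table2):
        from photokin import fit_first_order

        pts = [(s.x, np.log(fit_first_order(s).k1)) for s in table2]
        seg = segment_domains(pts)
        xs = np.array([p[0] for p in pts])
        ys = np.array([p[1] for p in pts])
        coef = np.polyfit(xs, ys, 1)
        global_sse = float(np.sum((ys - np.polyval(coef, xs)) ** 2))
        assert seg.total_sse <= global_sse + 1e-15

    def test_fixture_lnk1_domains_bracket_the_reported_boundaries(self, table2):
        from photokin import fit_first_order

        pts = [(s.x, np.log(fit_first_order(s).k1)) for s in table2]
        seg = segment_domains(pts)
        b1, b2 = seg.breakpoints
        assert b1 <= 0.2 < b2  # first domain edge below x=0.2
        assert b2 >= 0.3  # last domain starts above x=0.3

    def test_too_few_points_rejected(self):
        with pytest.raises(ValidationError):
            segment_domains([(0, 0), (0.1, 1), (0.2, 2)], n_breakpoints=2)
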