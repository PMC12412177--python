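"""Pass counting, bypass measurement and the t_pp linear model."""

import dataclasses
import warnings

import numpy as np
import pytest
from hypothesis import given, settings, strategies as st

import cimscal as c
from cimscal.errors import (
    AmbiguousPassCountWarning,
    InsufficientDataError,
    MinPassesWarning,
    RankDeficiencyError,
    ValidationError,
)
from cimscal.multipass import SeparationPoint

from conftest import make_gaussian_trace


def normal_equations_ols(n, t_nd):
    """Independent closed-form OLS (slope, intercept) via normal equations."""
    n = np.asarray(n, float)
    t = np.asarray(t_nd, float)
    m = n.size
    sxx = np.sum(n * n) - np.sum(n) ** 2 / m
    sxy = np.sum(n * t) - np.sum(n) * np.sum(t) / m
    slope = sxy / sxx
    return slope, t.mean() - slope * n.mean()


def make_points(n_values, t_nd_values):
    return [
        SeparationPoint(
            separation_time=10.0 * n, arrival_time=t + 5.0, n_passes=int(n),
            total_drift=float(t), analyte_id="ala8",
        )
        for n, t in zip(n_values, t_nd_values)
    ]


class TestCountPasses:
    @pytest.mark.parametrize(
        "t_n,t_p1,bypass,expected",
        [
            (105.0, 25.0, 5.0, 5),  # ratio exactly 5
            (25.0, 25.0, 5.0, 1),  # arrival equals single-pass time
            (104.3, 25.0, 5.0, 5),  # ratio 4.965 rounds to 5
            (5.0, 25.0, 5.0, 0),  # arrival equals bypass
        ],
    )
    def test_rounding(self, t_n, t_p1, bypass, expected):
        with warnings.catch_warnings():
            warnings.simplefilter("ignore", AmbiguousPassCountWarning)
            assert c.count_passes(t_n, t_p1, bypass) == expected

    def test_half_integer_ratio_warns(self):
        with pytest.warns(AmbiguousPassCountWarning):
            c.count_passes(95.0, 25.0, 5.0)  # ratio 4.5

    def test_invalid_reference_rejected(self):
        with pytest.raises(ValidationError):
            c.count_passes(100.0, 5.0, 5.0)

    @settings(derandomize=True, max_examples=50, deadline=None)
    @given(
        t_a=st.floats(5.0, 500.0),
        t_b=st.floats(5.0, 500.0),
        t_p1=st.floats(20.0, 30.0),
    )
    def test_nondecreasing_in_arrival_time(self, t_a, t_b, t_p1):
        lo, hi = sorted([t_a, t_b])
        with warnings.catch_warnings():
            warnings.simplefilter("ignore", AmbiguousPassCountWarning)
            assert c.count_passes(lo, t_p1, 5.0) <= c.count_passes(hi, t_p1, 5.0)


class TestMeasureBypass:
    def test_recovers_center(self):
        trace = make_gaussian_trace(center=5.2, lo=3.0, hi=7.0,
                                    separation_time=0.01)
        assert c.measure_bypass(trace) == pytest.approx(5.2, abs=1e-3)

    def test_strict_mode_rejects_wrong_separation_time(self):
        trace = make_gaussian_trace(center=5.2, lo=3.0, hi=7.0,
                                    separation_time=100.0)
        with pytest.raises(ValidationError):
            c.measure_bypass(trace, strict=True)

    def test_noisy_matches_grid_search_oracle(self):
        trace = make_gaussian_trace(center=5.2, lo=3.0, hi=7.0, sigma=0.4,
                                    separation_time=0.01, noise_sd=20.0, seed=9)
        measured = c.measure_bypass(trace)
        from test_peakfit import grid_search_gaussian

        ctr, _ = grid_search_gaussian(
            trace, np.arange(5.1, 5.3, 1e-4), np.arange(0.3, 0.5, 1e-3)
        )
        assert measured == pytest.approx(ctr, abs=0.01)


class TestPerturbationModel:
    def test_perfect_line(self):
        pts = make_points([4, 5, 6, 7, 8, 9], [80, 100, 120, 140, 160, 180])
        model = c.fit_perturbation_model(pts, bypass_time=5.0, t_p1=25.0)
        assert model.t_pp == pytest.approx(20.0, abs=1e-12)
        assert model.intercept == pytest.approx(0.0, abs=1e-10)
        assert model.r_squared == pytest.approx(1.0, abs=1e-12)

    def test_hand_evaluated_ols(self):
        pts = make_points(
            [4, 5, 6, 7, 8, 9], [80.4, 100.6, 120.2, 140.4, 160.3, 180.5]
        )
        model = c.fit_perturbation_model(pts, bypass_time=5.0, t_p1=25.0)
        assert model.t_pp == pytest.approx(19.994286, abs=1e-6)
        assert model.intercept == pytest.approx(0.437143, abs=1e-6)

    def test_five_points_rejected_citing_minimum(self):
        pts = make_points([4, 5, 6, 7, 8], [80, 100, 120, 140, 160])
        with pytest.raises(InsufficientDataError, match="minimum of 6"):
            c.fit_perturbation_model(pts, bypass_time=5.0, t_p1=25.0)

    def test_excluded_points_do_not_count(self):
        pts = make_points([4, 5, 6, 7, 8, 9], [80, 100, 120, 140, 160, 180])
        pts[0] = dataclasses.replace(pts[0], excluded=True, reason="wraparound")
        with pytest.raises(InsufficientDataError):
            c.fit_perturbation_model(pts, bypass_time=5.0, t_p1=25.0)

    def test_single_pass_count_is_rank_deficient(self):
        pts = make_points([5] * 6, [100.1, 99.9, 100.0, 100.2, 99.8, 100.0])
        with pytest.raises(RankDeficiencyError):
            c.fit_perturbation_model(pts, bypass_time=5.0, t_p1=25.0)

    def test_matches_normal_equations_on_random_inputs(self):
        rng = np.random.default_rng(123)
        for _ in range(200):
            m = rng.integers(6, 13)
            n = rng.integers(1, 20, size=m)
            while np.unique(n).size < 2:
                n = rng.integers(1, 20, size=m)
            t_nd = rng.uniform(10, 25) * n + rng.normal(0, 0.2, m)
            model = c.fit_perturbation_model(
                make_points(n, t_nd), bypass_time=5.0, t_p1=25.0
            )
            slope, intercept = normal_equations_ols(n, t_nd)
            assert model.t_pp == pytest.approx(slope, rel=1e-12)
            assert model.intercept == pytest.approx(intercept, rel=1e-12, abs=1e-12)

    @settings(derandomize=True, max_examples=30, deadline=None)
    @given(shift=st.floats(-50.0, 50.0))
    def test_slope_invariant_under_drift_offset(self, shift):
        """Adding a constant to every t_nd moves only the intercept."""
        t_nd = [80.4, 100.6, 120.2, 140.4, 160.3, 180.5]
        base = c.fit_perturbation_model(
            make_points([4, 5, 6, 7, 8, 9], t_nd), bypass_time=5.0, t_p1=25.0
        )
        shifted = c.fit_perturbation_model(
            make_points([4, 5, 6, 7, 8, 9], [t + shift for t in t_nd]),
            bypass_time=5.0, t_p1=25.0,
        )
        assert shifted.t_pp == pytest.approx(base.t_pp, abs=1e-12)
        assert shifted.intercept - base.intercept == pytest.approx(shift, abs=1e-10)


class TestBuildSeparationSeries:
    def test_clean_fixtures_give_increasing_pass_counts(self, noisy_dataset):
        traces, truths = noisy_dataset
        truth = truths[0]
        group = [t for t in traces if t.analyte_id == truth.analyte_id]
        multis = [t for t in group if t.separation_time > 25.0]
        bypass = c.measure_bypass(
            next(t for t in group if t.separation_time <= 0.05)
        )
        with warnings.catch_warnings():
            warnings.simplefilter("ignore", AmbiguousPassCountWarning)
            pts = c.build_separation_series(multis, bypass, truth.true_t_p1)
        included = [p for p in pts if not p.excluded]
        assert len(included) == 6
        ns = [p.n_passes for p in included]
        assert all(b >= a for a, b in zip(ns, ns[1:])) and ns[-1] > ns[0]
        true_ns = {ts: n for ts, n, _ in truth.runs}
        assert all(true_ns[p.separation_time] == p.n_passes for p in included)

    def test_wraparound_split_trace_excluded(self, noisy_dataset):
        traces, truths = noisy_dataset
        truth = truths[0]
        group = [t for t in traces if t.analyte_id == truth.analyte_id]
        multis = sorted(
            (t for t in group if t.separation_time > 25.0),
            key=lambda t: t.separation_time,
        )
        multis[2] = c.inject_wraparound(multis[2], period=100.0, fraction=0.4)
        with warnings.catch_warnings():
            warnings.simplefilter("ignore", AmbiguousPassCountWarning)
            pts = c.build_separation_series(multis, 5.0, truth.true_t_p1)
        flagged = [p for p in pts if p.excluded]
        assert len(flagged) == 1
        assert flagged[0].reason == "wraparound"

    def test_low_pass_analyte_triggers_four_pass_warning(self):
        traces = [
            make_gaussian_trace(center=5.0 + n * 20.0, lo=5.0 + n * 20 - 3,
                                hi=5.0 + n * 20 + 3, separation_time=20.0 * n)
            for n in (1, 2, 3)
        ]
        with pytest.warns(MinPassesWarning):
            c.build_separation_series(traces, bypass=5.0, t_p1=25.0)

    def test_mixed_analytes_rejected(self):
        a = make_gaussian_trace(analyte="a")
        b = make_gaussian_trace(analyte="b")
        with pytest.raises(ValidationError):
            c.build_separation_series([a, b], bypass=5.0, t_p1=25.0)
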