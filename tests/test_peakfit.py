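"""Gaussian arrival-time extraction and wrap-around handling."""

import dataclasses

import numpy as np
import pytest
from hypothesis import given, settings, strategies as st

import cimscal as c
from cimscal.errors import FitError, ValidationError
from cimscal.peakfit import has_secondary_component

from conftest import make_gaussian_trace


def grid_search_gaussian(trace, centers, sigmas):
    """Independent brute-force oracle: best (center, sigma) over a grid.

    For each candidate (center, sigma) the optimal amplitude and baseline
    follow from linear least squares, so only the two nonlinear
    parameters are scanned.
    """
    t, y = trace.times, trace.intensities
    best = (np.inf, None, None)
    for ctr in centers:
        for sig in sigmas:
            g = np.exp(-((t - ctr) ** 2) / (2 * sig**2))
            X = np.column_stack([g, np.ones_like(g)])
            coef, _, _, _ = np.linalg.lstsq(X, y, rcond=None)
            sse = float(np.sum((X @ coef - y) ** 2))
            if sse < best[0]:
                best = (sse, ctr, sig)
    return best[1], best[2]


class TestFitGaussian:
    def test_noiseless_exact_recovery(self):
        trace = make_gaussian_trace(amplitude=1000, center=25.0, sigma=0.5)
        fit = c.fit_gaussian(trace)
        assert fit.center == pytest.approx(25.0, abs=1e-6)
        assert fit.sigma == pytest.approx(0.5, abs=1e-6)
        assert fit.amplitude == pytest.approx(1000.0, rel=1e-6)
        assert fit.baseline == pytest.approx(0.0, abs=1e-6)
        assert fit.converged and fit.r_squared > 1 - 1e-12

    def test_noisy_center_matches_grid_search_oracle(self):
        trace = make_gaussian_trace(noise_sd=20.0, seed=42)
        fit = c.fit_gaussian(trace)
        # coarse-to-fine scan at 1e-4 ms resolution around the optimum
        ctr, sig = grid_search_gaussian(
            trace, np.arange(24.9, 25.1, 1e-3), np.arange(0.4, 0.6, 1e-3)
        )
        ctr, sig = grid_search_gaussian(
            trace,
            np.arange(ctr - 2e-3, ctr + 2e-3, 1e-4),
            np.arange(sig - 2e-3, sig + 2e-3, 1e-4),
        )
        assert fit.center == pytest.approx(ctr, abs=0.01)

    def test_flat_trace_rejected(self):
        t = np.arange(20, 30, 0.05)
        trace = c.ATDTrace("flat", 100.0, t, np.full_like(t, 100.0))
        with pytest.raises(FitError):
            c.fit_gaussian(trace)

    def test_window_excluding_all_points_rejected(self, gaussian_trace):
        with pytest.raises(ValidationError):
            c.fit_gaussian(gaussian_trace, window=(50.0, 60.0))

    @settings(derandomize=True, max_examples=25, deadline=None)
    @given(
        amplitude=st.floats(10.0, 1e5),
        center=st.floats(22.0, 28.0),
        sigma=st.floats(0.15, 1.5),
        baseline=st.floats(0.0, 500.0),
    )
    def test_noiseless_recovery_property(self, amplitude, center, sigma, baseline):
        """Any (amplitude, center, sigma >= 2 grid steps, baseline) is
        recovered to 1e-6 relative from noiseless samples."""
        trace = make_gaussian_trace(
            amplitude=amplitude, center=center, sigma=sigma, baseline=baseline
        )
        fit = c.fit_gaussian(trace)
        assert fit.center == pytest.approx(center, rel=1e-6, abs=1e-6)
        assert fit.sigma == pytest.approx(sigma, rel=1e-6)
        assert fit.amplitude == pytest.approx(amplitude, rel=1e-6)
        assert fit.baseline == pytest.approx(baseline, rel=1e-6, abs=1e-4)

    @pytest.mark.parametrize("noise_sd", [0.0, 20.0])
    def test_translation_equivariance(self, noise_sd):
        trace = make_gaussian_trace(noise_sd=noise_sd, seed=7)
        delta = 13.25
        shifted = dataclasses.replace(trace, times=trace.times + delta)
        f0 = c.fit_gaussian(trace)
        f1 = c.fit_gaussian(shifted)
        assert f1.center - f0.center == pytest.approx(delta, abs=1e-9)
        assert f1.sigma == pytest.approx(f0.sigma, abs=1e-9)

    @pytest.mark.parametrize("noise_sd", [0.0, 20.0])
    def test_intensity_scaling(self, noise_sd):
        trace = make_gaussian_trace(baseline=50.0, noise_sd=noise_sd, seed=3)
        scale = 7.5
        scaled = dataclasses.replace(trace, intensities=trace.intensities * scale)
        f0 = c.fit_gaussian(trace)
        f1 = c.fit_gaussian(scaled)
        assert f1.center == pytest.approx(f0.center, abs=1e-9)
        assert f1.sigma == pytest.approx(f0.sigma, abs=1e-9)
        assert f1.amplitude == pytest.approx(scale * f0.amplitude, rel=1e-9)
        assert f1.baseline == pytest.approx(scale * f0.baseline, rel=1e-8, abs=1e-6)


class TestPickPrimaryPeak:
    def test_window_selects_most_intense_peak(self):
        t = np.arange(20, 30, 0.05)
        y = 1000 * np.exp(-((t - 25) ** 2) / (2 * 0.4**2))
        y += 400 * np.exp(-((t - 28) ** 2) / (2 * 0.4**2))
        lo, hi = c.pick_primary_peak(c.ATDTrace("two", 100.0, t, y))
        assert lo <= 25.0 <= hi
        assert not (lo <= 28.0 <= hi)

    def test_single_peak_window_contains_apex(self, gaussian_trace):
        lo, hi = c.pick_primary_peak(gaussian_trace)
        assert lo <= 25.0 <= hi

    def test_tie_broken_toward_earliest_time(self):
        t = np.arange(20, 30, 0.05)
        y = 1000 * np.exp(-((t - 23) ** 2) / (2 * 0.3**2))
        y += 1000 * np.exp(-((t - 27) ** 2) / (2 * 0.3**2))
        # identical sampled maxima at 23 and 27 ms
        lo, hi = c.pick_primary_peak(c.ATDTrace("tie", 100.0, t, y))
        assert lo <= 23.0 <= hi and not (lo <= 27.0 <= hi)

    def test_flat_trace_rejected(self):
        t = np.arange(20, 30, 0.05)
        with pytest.raises(FitError):
            c.pick_primary_peak(c.ATDTrace("flat", 1.0, t, np.ones_like(t)))


class TestMultiGaussian:
    @staticmethod
    def _two_peaks(noise_sd=0.0, seed=0):
        t = np.arange(21, 29, 0.05)
        y = 1000 * np.exp(-((t - 24.0) ** 2) / (2 * 0.4**2))
        y += 700 * np.exp(-((t - 25.5) ** 2) / (2 * 0.4**2))
        if noise_sd > 0:
            y = y + np.random.default_rng(seed).normal(0, noise_sd, t.size)
            y = np.clip(y, 0, None)
        return c.ATDTrace("isomers", 100.0, t, y)

    def test_noiseless_two_component_recovery(self):
        fit = c.fit_multi_gaussian(self._two_peaks(), k=2)
        centers = sorted(g.center for g in fit.components)
        assert centers[0] == pytest.approx(24.0, abs=1e-4)
        assert centers[1] == pytest.approx(25.5, abs=1e-4)
        assert fit.components[0].amplitude > fit.components[1].amplitude

    def test_noisy_centers_match_grid_search_oracle(self):
        trace = self._two_peaks(noise_sd=20.0, seed=5)
        fit = c.fit_multi_gaussian(trace, k=2)
        # 2-component oracle: scan both centers, shared sigma; amplitudes
        # and baseline solved linearly
        t, y = trace.times, trace.intensities
        best = (np.inf, None, None)
        for c1 in np.arange(23.9, 24.1, 2e-3):
            for c2 in np.arange(25.4, 25.6, 2e-3):
                for sig in np.arange(0.38, 0.42, 2e-3):
                    X = np.column_stack(
                        [
                            np.exp(-((t - c1) ** 2) / (2 * sig**2)),
                            np.exp(-((t - c2) ** 2) / (2 * sig**2)),
                            np.ones_like(t),
                        ]
                    )
                    coef, _, _, _ = np.linalg.lstsq(X, y, rcond=None)
                    sse = float(np.sum((X @ coef - y) ** 2))
                    if sse < best[0]:
                        best = (sse, c1, c2)
        centers = sorted(g.center for g in fit.components)
        assert centers[0] == pytest.approx(best[1], abs=0.02)
        assert centers[1] == pytest.approx(best[2], abs=0.02)

    def test_k1_equals_single_gaussian_fit(self, gaussian_trace):
        single = c.fit_gaussian(gaussian_trace)
        multi = c.fit_multi_gaussian(gaussian_trace, k=1)
        comp = multi.components[0]
        assert comp.center == pytest.approx(single.center, abs=1e-9)
        assert comp.sigma == pytest.approx(single.sigma, abs=1e-9)
        assert comp.amplitude == pytest.approx(single.amplitude, rel=1e-9)

    def test_k_below_one_rejected(self, gaussian_trace):
        with pytest.raises(ValidationError):
            c.fit_multi_gaussian(gaussian_trace, k=0)


class TestWraparound:
    def test_shift_conserves_points_and_intensity(self):
        trace = make_gaussian_trace(center=2.0, lo=0.05, hi=4.0, step=0.05,
                                    sigma=0.3)
        split = c.inject_wraparound(trace, period=100.0, fraction=0.5)
        rec = c.reconstruct_wraparound(split, period=100.0, split_time=50.0)
        assert rec.times.size == trace.times.size
        assert rec.intensities.sum() == trace.intensities.sum()

    def test_split_time_below_all_times_is_identity(self, gaussian_trace):
        rec = c.reconstruct_wraparound(gaussian_trace, period=100.0,
                                       split_time=1.0)
        np.testing.assert_array_equal(rec.times, gaussian_trace.times)
        np.testing.assert_array_equal(rec.intensities,
                                      gaussian_trace.intensities)

    def test_reconstruction_restores_unimodal_fit(self):
        """A reconstructed split trace refits as a single clean Gaussian
        while the raw split trace is flagged multi-modal."""
        trace = make_gaussian_trace()
        split = c.inject_wraparound(trace, period=100.0, fraction=0.5)
        assert has_secondary_component(split)
        rec = c.reconstruct_wraparound(split, period=100.0)
        assert not has_secondary_component(rec)
        fit = c.fit_gaussian(rec)
        assert fit.converged
        assert fit.center == pytest.approx(25.0, abs=1e-6)

    def test_duplicate_timestamps_rejected(self):
        t = np.array([1.0, 2.0, 3.0, 4.0, 5.0])
        y = np.array([1.0, 5.0, 1.0, 5.0, 1.0])
        trace = c.ATDTrace("x", 1.0, t, y)
        with pytest.raises(ValidationError):
            # shifting points below 3 ms by exactly 2 ms collides with 3,4
            c.reconstruct_wraparound(trace, period=2.0, split_time=2.5)
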