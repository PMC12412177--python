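"""Gaussian peak extraction from arrival-time distributions.

The precise arrival time ``t_n`` of an ion at a given separation time is
taken as the center of a Gaussian fitted to the raw ATD by nonlinear least
squares.  Multi-component ATDs (e.g. partially resolved isomers) are
handled by a sum-of-Gaussians fit with a shared constant baseline, and
peaks split by wrap-around (part of the population completing an extra
lap of the cyclic cell) can be reconstructed by shifting the wrapped
segment by one period.
"""

from __future__ import annotations

import dataclasses
from dataclasses import dataclass

import numpy as np
from scipy.optimize import least_squares
from scipy.signal import find_peaks

from .core import ATDTrace
from .errors import FitError, ValidationError

__all__ = [
    "GaussianFit",
    "MultiGaussianFit",
    "fit_gaussian",
    "fit_multi_gaussian",
    "pick_primary_peak",
    "reconstruct_wraparound",
    "has_secondary_component",
]

# Half-width conversion: FWHM = 2*sqrt(2*ln 2) * sigma
_FWHM_FACTOR = 2.3548200450309493


@dataclass(frozen=True)
class GaussianFit:
    """Parameters of a fitted Gaussian ``a*exp(-(t-c)^2/(2 s^2)) + b``.

    ``center`` is the arrival time ``t_n`` in ms; ``sigma`` the peak
    standard deviation in ms; ``r_squared`` the coefficient of
    determination of the fit on the fitted window.
    """

    amplitude: float
    center: float
    sigma: float
    baseline: float
    r_squared: float
    converged: bool

    def __post_init__(self) -> None:
        if not self.sigma > 0:
            raise FitError(f"fitted sigma must be positive, got {self.sigma}")

    def __call__(self, t: np.ndarray) -> np.ndarray:
        t = np.asarray(t, dtype=float)
        return self.amplitude * np.exp(
            -((t - self.center) ** 2) / (2.0 * self.sigma**2)
        ) + self.baseline


@dataclass(frozen=True)
class MultiGaussianFit:
    """A sum-of-Gaussians fit; components ordered by descending amplitude."""

    components: tuple[GaussianFit, ...]
    k: int
    r_squared: float
    converged: bool

    def __post_init__(self) -> None:
        if self.k < 1 or len(self.components) != self.k:
            raise FitError("component count mismatch")
        centers = [c.center for c in self.components]
        if len(set(centers)) != len(centers):
            raise FitError("component centers must be pairwise distinct")

    def __call__(self, t: np.ndarray) -> np.ndarray:
        t = np.asarray(t, dtype=float)
        out = np.full_like(t, self.components[0].baseline, dtype=float)
        for c in self.components:
            out += c.amplitude * np.exp(-((t - c.center) ** 2) / (2.0 * c.sigma**2))
        return out


def _interp_crossing(t0, y0, t1, y1, level):
    """Linear interpolation of the time where intensity crosses ``level``."""
    if y1 == y0:
        return t0
    return t0 + (level - y0) * (t1 - t0) / (y1 - y0)


def _estimate_fwhm(times: np.ndarray, intens: np.ndarray, i_apex: int) -> float:
    """FWHM at the apex, by linear interpolation of the half-height crossings.

    Falls back to grid-step-based widths when a flank never drops below
    half height (peak truncated at the trace edge).
    """
    base = float(intens.min())
    half = base + (float(intens[i_apex]) - base) / 2.0
    step = float(np.median(np.diff(times)))

    t_left = None
    for i in range(i_apex, 0, -1):
        if intens[i - 1] < half <= intens[i]:
            t_left = _interp_crossing(times[i - 1], intens[i - 1], times[i], intens[i], half)
            break
    t_right = None
    for i in range(i_apex, len(times) - 1):
        if intens[i + 1] < half <= intens[i]:
            t_right = _interp_crossing(times[i], intens[i], times[i + 1], intens[i + 1], half)
            break

    apex_t = float(times[i_apex])
    if t_left is not None and t_right is not None:
        fwhm = t_right - t_left
    elif t_left is not None:
        fwhm = 2.0 * (apex_t - t_left)
    elif t_right is not None:
        fwhm = 2.0 * (t_right - apex_t)
    else:
        fwhm = (times[-1] - times[0]) / 4.0
    return max(float(fwhm), 2.0 * step)


def pick_primary_peak(
    trace: ATDTrace, width_fwhm: float = 6.0
) -> tuple[float, float]:
    """Window around the most intense ATD peak.

    Returns a ``(lo, hi)`` time interval centered on the global intensity
    maximum, of total width ``width_fwhm`` times a local FWHM estimate,
    clipped to the trace span.  Ties in the maximum are broken toward the
    earliest time.
    """
    intens = trace.intensities
    if np.ptp(intens) == 0:
        raise FitError(f"trace '{trace.analyte_id}' is flat; no peak to pick")
    i_apex = int(np.argmax(intens))  # argmax returns the first (earliest) tie
    fwhm = _estimate_fwhm(trace.times, intens, i_apex)
    half_width = width_fwhm * fwhm / 2.0
    apex_t = float(trace.times[i_apex])
    lo, hi = trace.span
    return max(lo, apex_t - half_width), min(hi, apex_t + half_width)


def _prepare(trace: ATDTrace, window) -> ATDTrace:
    sub = trace.windowed(window) if window is not None else trace
    if sub.times.size < 5:
        raise ValidationError(
            f"trace '{trace.analyte_id}': need >= 5 points in fit window, "
            f"got {sub.times.size}"
        )
    if np.ptp(sub.intensities) == 0:
        raise FitError(
            f"trace '{trace.analyte_id}': all intensities equal; cannot fit"
        )
    return sub


def fit_gaussian(
    trace: ATDTrace,
    window: tuple[float, float] | None = None,
    fit_baseline: bool = True,
    max_nfev: int = 2000,
) -> GaussianFit:
    """Least-squares Gaussian fit; the fitted center is the arrival time t_n.

    Initialization: center at the intensity argmax, amplitude = max - min,
    baseline = min, sigma = FWHM/2.3548 with the FWHM interpolated at half
    height.  The center is bounded to the fitted window and sigma to
    (0, window span].
    """
    sub = _prepare(trace, window)
    t, y = sub.times, sub.intensities
    t0, t1 = sub.span
    span = t1 - t0
    i_apex = int(np.argmax(y))
    amp0 = float(y.max() - y.min())
    base0 = float(y.min())
    sigma0 = _estimate_fwhm(t, y, i_apex) / _FWHM_FACTOR
    sigma0 = min(max(sigma0, 1e-6 * span), span)

    if fit_baseline:
        x0 = np.array([amp0, t[i_apex], sigma0, base0])
        lower = np.array([0.0, t0, 1e-9 * max(span, 1.0), -np.inf])
        upper = np.array([np.inf, t1, span, np.inf])

        def resid(p):
            a, c, s, b = p
            return a * np.exp(-((t - c) ** 2) / (2.0 * s * s)) + b - y

    else:
        x0 = np.array([amp0 + base0, t[i_apex], sigma0])
        lower = np.array([0.0, t0, 1e-9 * max(span, 1.0)])
        upper = np.array([np.inf, t1, span])

        def resid(p):
            a, c, s = p
            return a * np.exp(-((t - c) ** 2) / (2.0 * s * s)) - y

    sol = least_squares(
        resid, x0, bounds=(lower, upper), ftol=1e-12, xtol=1e-12, gtol=1e-12,
        max_nfev=max_nfev,
    )
    if fit_baseline:
        amp, center, sigma, base = sol.x
    else:
        amp, center, sigma = sol.x
        base = 0.0
    ss_res = float(np.sum(sol.fun**2))
    ss_tot = float(np.sum((y - y.mean()) ** 2))
    r2 = 1.0 - ss_res / ss_tot if ss_tot > 0 else 0.0
    return GaussianFit(
        amplitude=float(amp),
        center=float(center),
        sigma=float(sigma),
        baseline=float(base),
        r_squared=min(r2, 1.0),
        converged=bool(sol.status != 0),
    )


def _initial_centers(trace: ATDTrace, k: int, min_sep_steps: int = 3) -> list[int]:
    """Indices of the k highest local maxima separated by >= min_sep_steps.

    Ties are broken toward earlier times; if fewer than k local maxima
    exist, remaining starts are spread over the span.
    """
    y = trace.intensities
    idx, _ = find_peaks(y, distance=min_sep_steps)
    if len(idx) == 0:
        idx = np.array([int(np.argmax(y))])
    # stable sort on -intensity keeps earlier-time peaks first among ties
    order = np.argsort(-y[idx], kind="stable")
    chosen = list(idx[order][:k])
    while len(chosen) < k:
        # fallback starts at evenly spaced positions not yet used
        extras = np.linspace(0, len(y) - 1, k + 2)[1:-1].astype(int)
        for e in extras:
            if len(chosen) == k:
                break
            if all(abs(e - c) >= min_sep_steps for c in chosen):
                chosen.append(int(e))
        if len(chosen) < k:
            chosen.append(int((chosen[-1] + min_sep_steps) % len(y)))
    return chosen[:k]


def fit_multi_gaussian(
    trace: ATDTrace,
    k: int,
    window: tuple[float, float] | None = None,
    max_nfev: int = 5000,
) -> MultiGaussianFit:
    """Fit a sum of ``k`` Gaussians plus a shared constant baseline.

    Components are returned sorted by descending amplitude.  If the
    optimizer stops at its evaluation cap the partial result is returned
    with ``converged=False`` rather than raising.
    """
    if k < 1:
        raise ValidationError("k must be >= 1")
    sub = _prepare(trace, window)
    t, y = sub.times, sub.intensities
    if t.size < 3 * k + 2:
        raise ValidationError(
            f"trace '{trace.analyte_id}': need >= {3 * k + 2} points for k={k}"
        )
    t0, t1 = sub.span
    span = t1 - t0
    base0 = float(y.min())
    centers0 = _initial_centers(sub, k)
    sigma0 = _estimate_fwhm(t, y, centers0[0]) / _FWHM_FACTOR
    sigma0 = min(max(sigma0, 1e-6 * span), span / max(k, 1))

    x0, lower, upper = [], [], []
    for i in centers0:
        x0 += [max(float(y[i]) - base0, 1e-9), float(t[i]), sigma0]
        lower += [0.0, t0, 1e-9 * max(span, 1.0)]
        upper += [np.inf, t1, span]
    x0.append(base0)
    lower.append(-np.inf)
    upper.append(np.inf)

    def resid(p):
        out = np.full_like(t, p[-1])
        for j in range(k):
            a, c, s = p[3 * j : 3 * j + 3]
            out = out + a * np.exp(-((t - c) ** 2) / (2.0 * s * s))
        return out - y

    sol = least_squares(
        resid, np.array(x0), bounds=(np.array(lower), np.array(upper)),
        ftol=1e-12, xtol=1e-12, gtol=1e-12, max_nfev=max_nfev,
    )
    ss_res = float(np.sum(sol.fun**2))
    ss_tot = float(np.sum((y - y.mean()) ** 2))
    r2 = min(1.0 - ss_res / ss_tot if ss_tot > 0 else 0.0, 1.0)
    converged = bool(sol.status != 0)
    base = float(sol.x[-1])
    comps = []
    for j in range(k):
        a, c, s = sol.x[3 * j : 3 * j + 3]
        comps.append(
            GaussianFit(
                amplitude=float(a), center=float(c), sigma=float(s),
                baseline=base, r_squared=r2, converged=converged,
            )
        )
    comps.sort(key=lambda g: -g.amplitude)
    return MultiGaussianFit(
        components=tuple(comps), k=k, r_squared=r2, converged=converged
    )


def _auto_split_time(trace: ATDTrace) -> float:
    """Locate the split point of a wrap-around-split ATD.

    A wrapped segment usually sits far from the main peak, so the split is
    placed in the dominant gap between consecutive time stamps when one
    exists; for contiguous grids it falls back to the intensity minimum
    between the two most prominent peaks.
    """
    gaps = np.diff(trace.times)
    step = float(np.median(gaps))
    i_gap = int(np.argmax(gaps))
    if gaps[i_gap] > 10.0 * step:
        return float((trace.times[i_gap] + trace.times[i_gap + 1]) / 2.0)
    y = trace.intensities
    idx, props = find_peaks(y, prominence=0.0)
    if len(idx) < 2:
        raise FitError(
            f"trace '{trace.analyte_id}': fewer than two peaks and no time "
            "gap; cannot locate the wrap-around split"
        )
    top = idx[np.argsort(-props["prominences"], kind="stable")[:2]]
    i0, i1 = sorted(int(i) for i in top)
    between = y[i0 : i1 + 1]
    j = i0 + int(np.argmin(between))
    return float(trace.times[j])


def reconstruct_wraparound(
    trace: ATDTrace, period: float, split_time: float | None = None
) -> ATDTrace:
    """Undo wrap-around peak splitting by shifting the wrapped segment.

    Points arriving before ``split_time`` are assumed to have completed one
    extra lap of the cyclic cell and are shifted late by ``period`` ms; the
    trace is re-sorted by time.  Intensities and point count are conserved
    exactly.  If ``split_time`` is omitted it is placed at the intensity
    minimum between the two most prominent peaks.
    """
    if not period > 0:
        raise ValidationError("period must be positive")
    if split_time is None:
        split_time = _auto_split_time(trace)
    times = trace.times.copy()
    mask = times < split_time
    times[mask] += period
    order = np.argsort(times, kind="stable")
    new_t = times[order]
    if np.any(np.diff(new_t) <= 0):
        raise ValidationError(
            f"trace '{trace.analyte_id}': shift by {period} ms produces "
            "duplicate or non-increasing time stamps"
        )
    return dataclasses.replace(
        trace, times=new_t, intensities=trace.intensities[order]
    )


def has_secondary_component(trace: ATDTrace, threshold: float = 0.1) -> bool:
    """Heuristic detector for split/multi-modal ATDs.

    Two signatures are checked: a dominant gap in the time stamps (a
    wrapped segment recorded in a detached time block), and
    baseline-subtracted intensity outside the primary-peak window
    exceeding ``threshold`` of the total (a second well-separated
    component).  The baseline is estimated by the median so that symmetric
    noise cancels.
    """
    gaps = np.diff(trace.times)
    if gaps.max() > 10.0 * float(np.median(gaps)):
        return True
    lo, hi = pick_primary_peak(trace)
    resid = trace.intensities - float(np.median(trace.intensities))
    resid = np.clip(resid, 0.0, None)
    total = float(resid.sum())
    if total <= 0:
        return False
    outside = float(resid[(trace.times < lo) | (trace.times > hi)].sum())
    return outside / total > threshold
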