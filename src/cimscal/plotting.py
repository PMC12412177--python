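"""Diagnostic plots: ATD + Gaussian fit, linear model, calibration curve."""

from __future__ import annotations

import matplotlib

matplotlib.use("Agg")

import matplotlib.pyplot as plt
import numpy as np

from .calibration import CalibrationCurve
from .core import ATDTrace
from .multipass import PerturbationModel, SeparationPoint
from .peakfit import GaussianFit, MultiGaussianFit

__all__ = ["plot_atd_fit", "plot_linear_model", "plot_calibration_curve"]


def plot_atd_fit(
    trace: ATDTrace,
    fit: GaussianFit | MultiGaussianFit | None = None,
    ax: plt.Axes | None = None,
) -> plt.Axes:
    """Raw ATD with the fitted Gaussian (or Gaussian sum) overlaid."""
    if ax is None:
        _, ax = plt.subplots(figsize=(5, 3.2))
    ax.plot(trace.times, trace.intensities, color="0.3", lw=0.8, label="ATD")
    if fit is not None:
        dense = np.linspace(trace.times[0], trace.times[-1], 1000)
        ax.plot(dense, fit(dense), color="crimson", lw=1.3, label="Gaussian fit")
    ax.set_xlabel("drift time (ms)")
    ax.set_ylabel("intensity")
    ax.set_title(f"{trace.analyte_id}  (t$_s$ = {trace.separation_time:g} ms)")
    ax.legend(frameon=False, fontsize=8)
    return ax


def plot_linear_model(
    points: list[SeparationPoint],
    model: PerturbationModel,
    ax: plt.Axes | None = None,
) -> plt.Axes:
    """Total drift time vs pass count with the fitted t_pp line."""
    if ax is None:
        _, ax = plt.subplots(figsize=(4.2, 3.2))
    inc = [p for p in points if not p.excluded]
    exc = [p for p in points if p.excluded]
    ax.scatter(
        [p.n_passes for p in inc], [p.total_drift for p in inc],
        color="tab:blue", s=25, label="included",
    )
    if exc:
        ax.scatter(
            [p.n_passes for p in exc], [p.total_drift for p in exc],
            facecolor="none", edgecolor="tab:red", s=25, label="excluded",
        )
    if inc:
        n = np.array([p.n_passes for p in inc], dtype=float)
        xs = np.array([n.min() - 0.5, n.max() + 0.5])
        ax.plot(xs, model.intercept + model.t_pp * xs, color="0.2", lw=1)
    ax.set_xlabel("passes n")
    ax.set_ylabel("total drift time t$_{nd}$ (ms)")
    ax.set_title(
        f"{model.analyte_id}: t$_{{pp}}$ = {model.t_pp:.4f} ms/pass, "
        f"r$^2$ = {model.r_squared:.5f}"
    )
    ax.legend(frameon=False, fontsize=8)
    return ax


def plot_calibration_curve(
    curve: CalibrationCurve, ax: plt.Axes | None = None
) -> plt.Axes:
    """Scaled CCS vs drift value for the calibrants, with the power-law fit."""
    if ax is None:
        _, ax = plt.subplots(figsize=(4.2, 3.2))
    drifts = np.array([row["drift_ms"] for row in curve.calibrant_table])
    scaled = np.array([row["scaled_ccs"] for row in curve.calibrant_table])
    ax.scatter(drifts, scaled, color="tab:blue", s=25, label="calibrants")
    dense = np.linspace(drifts.min() * 0.9, drifts.max() * 1.1, 200)
    ax.plot(
        dense, curve.A * dense**curve.B, color="0.2", lw=1,
        label=f"$\\Omega' = {curve.A:.1f}\\,t^{{{curve.B:.3f}}}$",
    )
    ax.set_xlabel("drift value (ms)")
    ax.set_ylabel("scaled CCS $\\Omega'\\ (\\AA^2\\sqrt{Da}/z)$")
    ax.set_title(f"{curve.mode} calibration (r$^2$ = {curve.fit_r_squared:.5f})")
    ax.legend(frameon=False, fontsize=8)
    return ax
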