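"""Synthetic cyclic-IMS datasets with known ground truth.

The generator emulates the arrival-time structure the calibration
pipeline assumes: for an ion with true periodic (per-pass) drift time
``t_pp`` the arrival time of an acquisition at separation time ``t_s`` is

    t_n = bypass_offset + n * t_pp + p,    n = floor(t_s / t_pp),

where ``p`` is a per-acquisition perturbation drawn uniformly from
[-delta, +delta] (shared by all analytes in the same run, emulating the
field-switch artifact) and ``n`` is the largest number of passes
completing within ``t_s``.  Each arrival renders as a Gaussian ATD with
additive intensity noise floored at zero.  True per-pass drift times are
derived from each calibrant's reference CCS through a known power-law
curve, so that the full pipeline (peak fit → pass count → linear model →
calibration → prediction) can be checked against exact truth.
"""

from __future__ import annotations

import dataclasses
from dataclasses import dataclass
from pathlib import Path

import numpy as np
import pandas as pd

from .calibration import N2_MASS, reduced_mass, scale_ccs
from .core import ATDTrace, CalibrantSpec
from .errors import ValidationError
from .io import write_atd_workbook

__all__ = [
    "InstrumentModel",
    "TruthRecord",
    "default_calibrants",
    "default_separation_times",
    "generate_dataset",
    "generate_workbook",
    "inject_wraparound",
]


@dataclass(frozen=True)
class InstrumentModel:
    """Geometry and noise settings of the emulated cyclic-IMS instrument.

    Defaults resemble a ~1 m cyclic cell: 5 ms transit to the detector
    when ions bypass the separation region, per-pass drift times on the
    tens-of-ms scale, 0.5 ms wide peaks sampled every 0.05 ms, additive
    intensity noise at 2% of the default peak amplitude, and a +/-0.2 ms
    uniform per-run arrival-time perturbation.
    """

    bypass_offset: float = 5.0  # ms
    perturbation_amplitude: float = 0.2  # delta, ms
    peak_sigma: float = 0.5  # ms
    noise_sd: float = 20.0  # intensity units
    sampling_step: float = 0.05  # ms
    wraparound_period: float | None = None  # ms

    def __post_init__(self) -> None:
        for name in ("bypass_offset", "peak_sigma", "sampling_step"):
            if not getattr(self, name) > 0:
                raise ValidationError(f"{name} must be positive")
        if self.perturbation_amplitude < 0 or self.noise_sd < 0:
            raise ValidationError("noise settings must be non-negative")
        if not self.sampling_step < self.peak_sigma:
            raise ValidationError("sampling_step must be smaller than peak_sigma")
        if self.wraparound_period is not None and not self.wraparound_period > 0:
            raise ValidationError("wraparound_period must be positive")


@dataclass(frozen=True)
class TruthRecord:
    """Ground truth for one generated calibrant."""

    analyte_id: str
    true_ccs: float
    true_t_pp: float
    true_t_p1: float
    mz: float
    charge: int
    runs: tuple[tuple[float, int, float], ...]  # (t_s, n, true t_n)
    flags: tuple[str, ...] = ()


def default_calibrants(n: int = 6) -> list[CalibrantSpec]:
    """A synthetic singly-charged calibrant series (lipid-like m/z and CCS).

    m/z from 600 to 850 Th and reference CCS from 230 to 300 sq. angstrom,
    a range narrow enough that one shared separation-time schedule yields
    exactly one pass for every calibrant at the single-pass setting.
    """
    if n < 3:
        raise ValidationError("need at least 3 calibrants")
    mzs = np.linspace(600.0, 850.0, n)
    ccss = np.linspace(230.0, 300.0, n)
    return [
        CalibrantSpec(name=f"cal{i + 1:02d}", mz=float(m), charge=1, ccs_ref=float(c))
        for i, (m, c) in enumerate(zip(mzs, ccss))
    ]


def true_periodic_drift(
    calibrant: CalibrantSpec, curve_truth: tuple[float, float],
    gas_mass: float = N2_MASS,
) -> float:
    """Invert the truth power law: t_pp = (scaled_ccs / A)^(1/B)."""
    A, B = curve_truth
    mu = reduced_mass(calibrant.mz * calibrant.charge, gas_mass)
    scaled = scale_ccs(calibrant.ccs_ref, calibrant.charge, mu)
    return float((scaled / A) ** (1.0 / B))


def default_separation_times(
    calibrants: list[CalibrantSpec],
    curve_truth: tuple[float, float] = (300.0, 0.55),
    n_multipass: int = 6,
    min_passes: int = 4,
) -> list[float]:
    """Separation-time schedule valid for all calibrants at once.

    Returns ``[0.01 (bypass), t_single, t_1..t_n_multipass]`` where the
    single-pass setting gives exactly one pass for every calibrant and the
    multipass settings start above ``min_passes`` times the slowest
    per-pass drift.
    """
    tpps = [true_periodic_drift(c, curve_truth) for c in calibrants]
    t_max, t_min = max(tpps), min(tpps)
    single = round(1.1 * t_max, 2)  # settings rounded like real instrument input
    if single >= 2.0 * t_min:
        raise ValidationError(
            "calibrant per-pass drift times span more than a factor of ~1.8; "
            "no shared single-pass separation time exists"
        )
    start = (min_passes + 0.25) * t_max
    stop = 2.0 * start
    multis = np.round(np.linspace(start, stop, n_multipass), 1)
    return [0.01, float(single)] + [float(t) for t in multis]


def _render_trace(
    analyte: str, ts: float, center: float, instrument: InstrumentModel,
    amplitude: float, rng: np.random.Generator, mz: float, charge: int,
) -> ATDTrace:
    sigma, step = instrument.peak_sigma, instrument.sampling_step
    grid = np.arange(center - 5.0 * sigma, center + 5.0 * sigma + step / 2, step)
    signal = amplitude * np.exp(-((grid - center) ** 2) / (2.0 * sigma**2))
    if instrument.noise_sd > 0:
        signal = signal + rng.normal(0.0, instrument.noise_sd, grid.size)
    signal = np.clip(signal, 0.0, None)
    return ATDTrace(
        analyte_id=analyte, separation_time=ts, times=grid,
        intensities=signal, mz=mz, charge=charge,
    )


def generate_dataset(
    calibrants: list[CalibrantSpec] | None = None,
    curve_truth: tuple[float, float] = (300.0, 0.55),
    instrument: InstrumentModel | None = None,
    separation_times: list[float] | None = None,
    seed: int = 0,
    amplitude: float = 1000.0,
    gas_mass: float = N2_MASS,
) -> tuple[list[ATDTrace], list[TruthRecord]]:
    """Generate ATD traces plus ground truth for a calibrant panel.

    ``separation_times`` must include the 0.01 ms bypass setting and one
    setting giving a single pass for every calibrant (the defaults do).
    Deterministic for a fixed seed.  Runs whose separation time completes
    no pass (other than the bypass) are flagged in the truth record.
    """
    if calibrants is None:
        calibrants = default_calibrants()
    if instrument is None:
        instrument = InstrumentModel()
    if separation_times is None:
        separation_times = default_separation_times(calibrants, curve_truth)
    if not any(0.005 <= t <= 0.05 for t in separation_times):
        raise ValidationError(
            "separation_times must include the 0.01 ms bypass setting"
        )
    rng = np.random.default_rng(seed)
    delta = instrument.perturbation_amplitude
    # one field-switch perturbation per acquisition run, shared by analytes
    perts = {
        ts: (rng.uniform(-delta, delta) if delta > 0 else 0.0)
        for ts in separation_times
    }
    traces: list[ATDTrace] = []
    truths: list[TruthRecord] = []
    for cal in calibrants:
        t_pp = true_periodic_drift(cal, curve_truth, gas_mass)
        runs = []
        flags: list[str] = []
        t_p1_true = float("nan")
        for ts in separation_times:
            if 0.005 <= ts <= 0.05:
                n = 0
            else:
                n = int(ts // t_pp)
                if n == 0:
                    flags.append(f"no_pass_at_ts_{ts:g}")
                if n == 1:
                    t_p1_true = instrument.bypass_offset + t_pp + perts[ts]
            center = instrument.bypass_offset + n * t_pp + perts[ts]
            traces.append(
                _render_trace(
                    cal.name, ts, center, instrument, amplitude, rng,
                    cal.mz, cal.charge,
                )
            )
            runs.append((float(ts), n, float(center)))
        truths.append(
            TruthRecord(
                analyte_id=cal.name,
                true_ccs=cal.ccs_ref,
                true_t_pp=t_pp,
                true_t_p1=t_p1_true,
                mz=cal.mz,
                charge=cal.charge,
                runs=tuple(runs),
                flags=tuple(flags),
            )
        )
    return traces, truths


def generate_workbook(
    workbook_path: str | Path,
    truth_path: str | Path | None = None,
    **kwargs,
) -> tuple[list[ATDTrace], list[TruthRecord]]:
    """Generate a dataset and write it as a canonical workbook (+ truth CSV)."""
    traces, truths = generate_dataset(**kwargs)
    write_atd_workbook(traces, workbook_path)
    if truth_path is not None:
        rows = [
            {
                "analyte": t.analyte_id,
                "true_ccs": t.true_ccs,
                "true_t_pp": t.true_t_pp,
                "true_t_p1": t.true_t_p1,
                "mz": t.mz,
                "charge": t.charge,
                "flags": ";".join(t.flags),
            }
            for t in truths
        ]
        pd.DataFrame(rows).to_csv(truth_path, index=False)
    return traces, truths


def inject_wraparound(
    trace: ATDTrace, period: float, fraction: float
) -> ATDTrace:
    """Split a peak by wrapping its late points one period early.

    The late ``fraction`` of the trace's points are shifted by ``-period``
    ms, emulating part of the ion population completing an extra lap and
    being recorded in the wrong cycle.  Exact inverse of
    ``peakfit.reconstruct_wraparound`` at the same period with a split
    time between the two resulting segments.
    """
    if not 0 < fraction < 1:
        raise ValidationError("fraction must lie strictly between 0 and 1")
    if not period > 0:
        raise ValidationError("period must be positive")
    n = trace.times.size
    n_late = int(round(fraction * n))
    if n_late == 0:
        return trace
    times = trace.times.copy()
    times[-n_late:] -= period
    order = np.argsort(times, kind="stable")
    new_t = times[order]
    if np.any(np.diff(new_t) <= 0):
        raise ValidationError(
            "period too small: wrapped segment overlaps the remaining points"
        )
    return dataclasses.replace(
        trace, times=new_t, intensities=trace.intensities[order]
    )
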