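"""Pass counting and the perturbation-corrected periodic drift time.

In a cyclic traveling-wave mobility cell the measured arrival time of an
ion is perturbed by the electric-field switching that ejects ions to the
detector, so the per-pass drift time cannot be read off a single
acquisition.  Following the Lin & Costello linear-model method, each
acquisition at separation time ``t_s`` yields one point
``(n, t_nd)`` where ``n`` is the number of completed passes and
``t_nd = t_n - t_bypass`` is the total drift time (arrival time minus the
bypass time measured at ``t_s = 0.01 ms``).  The slope of the ordinary
least-squares line of ``t_nd`` on ``n`` is the perturbation-corrected
periodic drift time ``t_pp``; the per-acquisition perturbation is absorbed
by the residuals and the fixed transit offset by the intercept.
"""

from __future__ import annotations

import warnings
from dataclasses import dataclass

import numpy as np
from scipy import stats

from .core import ATDTrace
from .errors import (
    AmbiguousPassCountWarning,
    BypassToleranceWarning,
    InsufficientDataError,
    MinPassesWarning,
    RankDeficiencyError,
    FitError,
    ValidationError,
)
from .peakfit import fit_gaussian, has_secondary_component, pick_primary_peak

__all__ = [
    "SeparationPoint",
    "PerturbationModel",
    "measure_bypass",
    "count_passes",
    "build_separation_series",
    "fit_perturbation_model",
]

#: Nominal bypass separation time, ms.
BYPASS_TS = 0.01
#: Lenient acceptance window for the bypass separation time, ms.
BYPASS_TS_WINDOW = (0.005, 0.05)


@dataclass(frozen=True)
class SeparationPoint:
    """One (t_s, n, t_nd) observation feeding the linear model."""

    separation_time: float  # t_s, ms
    arrival_time: float  # fitted t_n, ms
    n_passes: int
    total_drift: float  # t_nd = t_n - bypass, ms
    excluded: bool = False
    reason: str = ""
    flags: tuple[str, ...] = ()
    analyte_id: str = ""


@dataclass(frozen=True)
class PerturbationModel:
    """OLS line of total drift time on pass count for one analyte.

    ``t_pp`` (the slope, ms per pass) is the perturbation-corrected
    periodic drift time used for multipass calibration; ``t_p1`` is the
    single-pass arrival time used for pass counting and single-pass
    calibration.
    """

    t_pp: float
    intercept: float
    r_squared: float
    n_points: int
    bypass_time: float
    t_p1: float
    analyte_id: str = ""

    def __post_init__(self) -> None:
        if not self.t_pp > 0:
            raise FitError(
                f"analyte '{self.analyte_id}': fitted periodic drift time "
                f"must be positive, got {self.t_pp}"
            )


def measure_bypass(
    trace_at_min_ts: ATDTrace, strict: bool = False
) -> float:
    """Bypass time: primary-peak arrival time of the t_s = 0.01 ms trace.

    In strict mode the trace's separation time must lie inside the
    accepted bypass window [0.005, 0.05] ms; in lenient mode (default) an
    out-of-window trace only triggers a warning.
    """
    ts = trace_at_min_ts.separation_time
    lo, hi = BYPASS_TS_WINDOW
    if not (lo <= ts <= hi):
        msg = (
            f"trace '{trace_at_min_ts.analyte_id}': separation time {ts} ms is "
            f"outside the bypass window [{lo}, {hi}] ms (nominal {BYPASS_TS} ms)"
        )
        if strict:
            raise ValidationError(msg)
        warnings.warn(msg, BypassToleranceWarning, stacklevel=2)
    window = pick_primary_peak(trace_at_min_ts)
    return fit_gaussian(trace_at_min_ts, window=window).center


def count_passes(
    t_n: float,
    t_p1: float,
    bypass: float,
    ambiguity_margin: float = 0.25,
) -> int:
    """Number of passes from arrival, single-pass and bypass times.

    ``n = round((t_n - bypass) / (t_p1 - bypass))``.  Ratios within
    ``ambiguity_margin`` of a half-integer (i.e. farther than
    ``0.5 - margin`` from the nearest integer) emit an
    :class:`AmbiguousPassCountWarning`.
    """
    if t_p1 <= bypass:
        raise ValidationError(
            f"single-pass time {t_p1} ms must exceed bypass time {bypass} ms"
        )
    if t_n < bypass:
        raise ValidationError(
            f"arrival time {t_n} ms precedes bypass time {bypass} ms"
        )
    ratio = (t_n - bypass) / (t_p1 - bypass)
    n = int(round(ratio))
    if abs(ratio - n) >= ambiguity_margin:
        warnings.warn(
            f"pass-count ratio {ratio:.3f} is near a half-integer; "
            f"rounded to n={n}",
            AmbiguousPassCountWarning,
            stacklevel=2,
        )
    return n


def build_separation_series(
    traces: list[ATDTrace],
    bypass: float,
    t_p1: float,
    min_passes: int = 4,
    split_threshold: float = 0.1,
) -> list[SeparationPoint]:
    """Turn one analyte's multipass traces into (n, t_nd) model points.

    For each trace the arrival time is the primary-peak Gaussian center,
    the pass count comes from :func:`count_passes`, and
    ``t_nd = t_n - bypass``.  Traces whose ATD shows a second
    well-separated component (wrap-around splitting that was not
    reconstructed upstream) are excluded with reason ``"wraparound"``;
    acquisitions that complete no pass are excluded with reason
    ``"no_pass"``.  Points below ``min_passes`` are flagged
    ``"below_min_passes"`` but kept; if the whole series stays below the
    minimum a :class:`MinPassesWarning` is emitted.
    """
    if not traces:
        raise ValidationError("no traces supplied")
    analytes = {t.analyte_id for t in traces}
    if len(analytes) > 1:
        raise ValidationError(
            f"traces mix analytes: {sorted(analytes)}"
        )
    points: list[SeparationPoint] = []
    for trace in sorted(traces, key=lambda t: t.separation_time):
        if has_secondary_component(trace, threshold=split_threshold):
            # still report a best-effort arrival time for diagnostics
            fit = fit_gaussian(trace, window=pick_primary_peak(trace))
            points.append(
                SeparationPoint(
                    separation_time=trace.separation_time,
                    arrival_time=fit.center,
                    n_passes=0,
                    total_drift=fit.center - bypass,
                    excluded=True,
                    reason="wraparound",
                    analyte_id=trace.analyte_id,
                )
            )
            continue
        fit = fit_gaussian(trace, window=pick_primary_peak(trace))
        n = count_passes(fit.center, t_p1, bypass)
        flags: tuple[str, ...] = ()
        excluded, reason = False, ""
        if n < 1:
            excluded, reason = True, "no_pass"
        elif n < min_passes:
            flags = ("below_min_passes",)
        points.append(
            SeparationPoint(
                separation_time=trace.separation_time,
                arrival_time=fit.center,
                n_passes=n,
                total_drift=fit.center - bypass,
                excluded=excluded,
                reason=reason,
                flags=flags,
                analyte_id=trace.analyte_id,
            )
        )
    included = [p for p in points if not p.excluded]
    if included and max(p.n_passes for p in included) < min_passes:
        warnings.warn(
            f"analyte '{traces[0].analyte_id}': no acquisition reaches the "
            f"{min_passes}-pass minimum (max n = "
            f"{max(p.n_passes for p in included)})",
            MinPassesWarning,
            stacklevel=2,
        )
    return points


def fit_perturbation_model(
    points: list[SeparationPoint],
    bypass_time: float,
    t_p1: float,
    min_points: int = 6,
    analyte_id: str | None = None,
) -> PerturbationModel:
    """OLS of total drift time on pass count; the slope is ``t_pp``.

    Requires at least ``min_points`` included points (six by default) at
    two or more distinct pass counts.  Excluded points never enter the
    regression or its r².
    """
    if analyte_id is None:
        analyte_id = next((p.analyte_id for p in points if p.analyte_id), "")
    included = [p for p in points if not p.excluded]
    if len(included) < min_points:
        raise InsufficientDataError(
            f"analyte '{analyte_id}': {len(included)} usable points, but a "
            f"minimum of {min_points} data points is required for the "
            "perturbation-corrected periodic drift time"
        )
    n = np.array([p.n_passes for p in included], dtype=float)
    t_nd = np.array([p.total_drift for p in included], dtype=float)
    if np.unique(n).size < 2:
        raise RankDeficiencyError(
            f"analyte '{analyte_id}': all points share pass count "
            f"{int(n[0])}; slope is undetermined"
        )
    res = stats.linregress(n, t_nd)
    return PerturbationModel(
        t_pp=float(res.slope),
        intercept=float(res.intercept),
        r_squared=float(res.rvalue**2),
        n_points=len(included),
        bypass_time=bypass_time,
        t_p1=t_p1,
        analyte_id=analyte_id,
    )
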