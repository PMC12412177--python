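"""End-to-end workflows: workbook traces -> drift values -> curve -> CCS.

These functions tie the stages together the way the CLI (and the
examples) use them: group traces per analyte, measure the bypass and
single-pass reference times, build the per-analyte separation series and
perturbation model, then either fit a calibration curve from reference
CCS values or predict CCS for unknowns from a saved curve.
"""

from __future__ import annotations

from dataclasses import dataclass, field

from .calibration import CalibrationCurve, N2_MASS, build_curve, predict_ccs
from .core import ATDTrace, CalibrantSpec, ResultRecord
from .errors import InsufficientDataError, ValidationError
from .multipass import (
    BYPASS_TS_WINDOW,
    PerturbationModel,
    build_separation_series,
    fit_perturbation_model,
    measure_bypass,
)
from .peakfit import fit_gaussian, pick_primary_peak

__all__ = ["RunConfig", "AnalyteDrifts", "analyze_analyte", "calibrate", "process"]


@dataclass(frozen=True)
class RunConfig:
    """Knobs shared by the calibrate and process workflows.

    ``min_points`` is the minimum number of linear-model points per
    analyte (six, matching the acquisition protocol); ``min_passes`` the
    minimum pass count expected of multipass acquisitions (four).
    """

    mode: str = "multipass"  # "single-pass" | "multipass"
    min_points: int = 6
    min_passes: int = 4
    gas_mass: float = N2_MASS
    strict: bool = False
    single_pass_ts: float | None = None
    extrapolation_factor: float = 1.5

    def __post_init__(self) -> None:
        if self.min_points < 3:
            raise ValidationError("min_points must be >= 3")
        if self.min_passes < 1:
            raise ValidationError("min_passes must be >= 1")
        if self.mode not in ("single-pass", "multipass"):
            raise ValidationError(f"unknown mode '{self.mode}'")


@dataclass
class AnalyteDrifts:
    """Per-analyte measured quantities feeding calibration or prediction."""

    analyte_id: str
    bypass_time: float
    t_p1: float
    model: PerturbationModel | None = None
    points: list = field(default_factory=list)
    mz: float | None = None
    charge: int = 1

    def drift(self, mode: str) -> float:
        if mode == "single-pass":
            return self.t_p1
        if self.model is None:
            raise InsufficientDataError(
                f"analyte '{self.analyte_id}' has no perturbation model; "
                "multipass drift unavailable"
            )
        return self.model.t_pp


def _group_by_analyte(traces: list[ATDTrace]) -> dict[str, list[ATDTrace]]:
    groups: dict[str, list[ATDTrace]] = {}
    for t in traces:
        groups.setdefault(t.analyte_id, []).append(t)
    return groups


def analyze_analyte(
    traces: list[ATDTrace],
    config: RunConfig = RunConfig(),
    need_model: bool = True,
) -> AnalyteDrifts:
    """Measure bypass, single-pass and (optionally) t_pp for one analyte.

    The bypass trace is the one with separation time inside the bypass
    window [0.005, 0.05] ms; the single-pass trace is the one at
    ``config.single_pass_ts`` if set, otherwise the smallest remaining
    separation time.  All other traces form the linear-model series.
    """
    if not traces:
        raise ValidationError("no traces supplied")
    analyte = traces[0].analyte_id
    traces = sorted(traces, key=lambda t: t.separation_time)
    lo, hi = BYPASS_TS_WINDOW
    bypass_traces = [t for t in traces if lo <= t.separation_time <= hi]
    if not bypass_traces:
        raise InsufficientDataError(
            f"analyte '{analyte}': no bypass acquisition "
            f"(separation time in [{lo}, {hi}] ms) found"
        )
    rest = [t for t in traces if t not in bypass_traces]
    if not rest:
        raise InsufficientDataError(
            f"analyte '{analyte}': no acquisitions beyond the bypass trace"
        )
    if config.single_pass_ts is not None:
        sp = [t for t in rest if abs(t.separation_time - config.single_pass_ts) < 1e-9]
        if not sp:
            raise InsufficientDataError(
                f"analyte '{analyte}': no acquisition at the configured "
                f"single-pass separation time {config.single_pass_ts} ms"
            )
        sp_trace = sp[0]
    else:
        sp_trace = rest[0]
    multis = [t for t in rest if t is not sp_trace]

    bypass = measure_bypass(bypass_traces[0], strict=config.strict)
    t_p1 = fit_gaussian(sp_trace, window=pick_primary_peak(sp_trace)).center
    if t_p1 <= bypass:
        raise ValidationError(
            f"analyte '{analyte}': single-pass arrival {t_p1:.3f} ms does not "
            f"exceed the bypass time {bypass:.3f} ms"
        )
    result = AnalyteDrifts(
        analyte_id=analyte,
        bypass_time=bypass,
        t_p1=t_p1,
        mz=traces[0].mz,
        charge=traces[0].charge,
    )
    if need_model:
        points = build_separation_series(
            multis, bypass, t_p1, min_passes=config.min_passes
        )
        result.points = points
        result.model = fit_perturbation_model(
            points, bypass, t_p1, min_points=config.min_points, analyte_id=analyte
        )
    return result


def calibrate(
    traces: list[ATDTrace],
    calibrants: list[CalibrantSpec],
    config: RunConfig = RunConfig(),
) -> tuple[CalibrationCurve, dict[str, AnalyteDrifts]]:
    """Build a calibration curve from a workbook's traces and calibrant list.

    Every calibrant must appear among the trace analyte ids.  Returns the
    fitted curve plus the per-analyte measurements (for audit/plotting).
    """
    groups = _group_by_analyte(traces)
    missing = [c.name for c in calibrants if c.name not in groups]
    if missing:
        raise InsufficientDataError(
            f"no traces found for calibrant(s): {', '.join(missing)}"
        )
    need_model = config.mode == "multipass"
    per_analyte: dict[str, AnalyteDrifts] = {}
    drift_values: dict[str, float] = {}
    for cal in calibrants:
        drifts = analyze_analyte(groups[cal.name], config, need_model=need_model)
        per_analyte[cal.name] = drifts
        drift_values[cal.name] = drifts.drift(config.mode)
    curve = build_curve(
        calibrants,
        drift_values,
        mode=config.mode,
        gas_mass=config.gas_mass,
        created_with={
            "min_points": config.min_points,
            "min_passes": config.min_passes,
            "strict": config.strict,
        },
    )
    return curve, per_analyte


def process(
    traces: list[ATDTrace],
    curve: CalibrationCurve,
    config: RunConfig | None = None,
    references: dict[str, CalibrantSpec] | None = None,
) -> list[ResultRecord]:
    """Compute CCS for every analyte in the traces against a saved curve.

    ``references`` (name -> spec) supplies m/z, charge and optionally a
    reference CCS for percent-difference columns; analytes lacking both a
    reference entry and in-trace m/z metadata are an error.
    """
    if config is None:
        config = RunConfig(mode=curve.mode)
    if config.mode != curve.mode:
        raise ValidationError(
            f"run mode '{config.mode}' does not match curve mode '{curve.mode}'"
        )
    references = references or {}
    results: list[ResultRecord] = []
    for analyte, group in _group_by_analyte(traces).items():
        ref = references.get(analyte)
        if ref is not None:
            mz, charge = ref.mz, ref.charge
        elif group[0].mz is not None:
            mz, charge = group[0].mz, group[0].charge
        else:
            raise ValidationError(
                f"analyte '{analyte}': m/z and charge unknown (supply a "
                "references list or workbook metadata)"
            )
        drifts = analyze_analyte(
            group, config, need_model=(curve.mode == "multipass")
        )
        ccs_res = predict_ccs(
            curve,
            drifts.drift(curve.mode),
            mz=mz,
            charge=charge,
            analyte_id=analyte,
            ccs_reference=ref.ccs_ref if ref is not None else None,
            extrapolation_factor=config.extrapolation_factor,
        )
        diagnostics = {
            "drift_ms": ccs_res.drift_value,
            "bypass_ms": drifts.bypass_time,
            "t_p1_ms": drifts.t_p1,
            "extrapolated": ccs_res.extrapolated,
        }
        if drifts.model is not None:
            diagnostics["t_pp_ms"] = drifts.model.t_pp
            diagnostics["model_r_squared"] = drifts.model.r_squared
            diagnostics["n_points"] = drifts.model.n_points
            excluded = [p for p in drifts.points if p.excluded]
            if excluded:
                diagnostics["excluded"] = ";".join(
                    f"ts{p.separation_time:g}:{p.reason}" for p in excluded
                )
        results.append(
            ResultRecord(
                analyte_id=analyte,
                mode=curve.mode,
                ccs_measured=ccs_res.ccs,
                ccs_reference=ccs_res.ccs_reference,
                percent_difference=ccs_res.percent_difference,
                diagnostics=diagnostics,
            )
        )
    return results
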